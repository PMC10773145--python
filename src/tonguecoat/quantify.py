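"""Origin-partitioned quantification matrices, sample QC and aggregation.

The central container is :class:`QuantTable`: a feature-by-sample intensity
matrix (missing = not identified, stored as NaN) plus per-feature
annotations (origin, taxon, COG, KO).  Operations cover the sample-level
identification QC used for cohort inclusion, host/microbe abundance ratios,
aggregation of protein intensities to taxonomic ranks or functional
categories, and the cross-cohort overlap arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonomyTree

__all__ = [
    "QuantTable",
    "CohortMetadata",
    "qc_filter",
    "host_microbe_ratio",
    "aggregate",
    "cohort_overlap_report",
]

META_COLUMNS = ["subject", "center", "group", "stage", "timepoint", "replicate"]


@dataclass
class QuantTable:
    """Feature x sample intensities with per-feature annotations.

    ``values`` is indexed by feature id with one column per sample; NaN
    means the feature was not identified in that sample.  ``annotations``
    shares the feature index and may carry ``origin`` ("human"/"microbial"),
    ``taxon_id``, ``cog_id`` and ``ko_id`` columns.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in quantification table")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids in quantification table")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative intensities are not allowed")
        if self.annotations.empty:
            self.annotations = pd.DataFrame(index=self.values.index)
        else:
            self.annotations = self.annotations.reindex(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def identified(self) -> pd.DataFrame:
        """Boolean identification mask (non-missing intensity)."""
        return self.values.notna()

    def subset_samples(self, samples: Iterable[str]) -> "QuantTable":
        return QuantTable(self.values[list(samples)].copy(), self.annotations.copy())

    def subset_features(self, features: Iterable[str]) -> "QuantTable":
        features = list(features)
        return QuantTable(self.values.loc[features].copy(), self.annotations.loc[features].copy())

    # --- I/O ----------------------------------------------------------------
    @classmethod
    def read_wide(cls, path: str | Path, annotation_columns: tuple[str, ...] = ("origin", "taxon_id", "cog_id", "ko_id")) -> "QuantTable":
        """Read a DIA-NN-style wide TSV: feature rows, sample columns.

        Columns whose names appear in ``annotation_columns`` are split off
        into the annotation frame; the rest are sample intensities.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        ann_cols = [c for c in df.columns if c in annotation_columns]
        ann = df[ann_cols].copy()
        values = df.drop(columns=ann_cols).astype(float)
        return cls(values, ann)

    @classmethod
    def read_long(cls, path: str | Path) -> "QuantTable":
        """Read a long TSV with columns feature, sample, intensity."""
        df = pd.read_csv(path, sep="\t", dtype={"feature": str, "sample": str})
        wide = df.pivot(index="feature", columns="sample", values="intensity")
        wide.columns.name = None
        wide.index.name = None
        return cls(wide)

    def write_wide(self, path: str | Path) -> None:
        out = pd.concat([self.annotations, self.values], axis=1)
        out.to_csv(path, sep="\t", index_label="feature")


@dataclass
class CohortMetadata:
    """Sample-level study design: subject, center, group, stage, timepoint, replicate."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata lacks column(s) {missing}")
        if self.df.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    def group_labels(self, samples: Iterable[str] | None = None) -> pd.Series:
        s = self.df["group"]
        return s.loc[list(samples)] if samples is not None else s

    def subset(self, samples: Iterable[str]) -> "CohortMetadata":
        return CohortMetadata(self.df.loc[list(samples)].copy())

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample")


def qc_filter(
    protein_table: QuantTable,
    min_human: int = 800,
    min_microbial: int = 2000,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude samples with too few identified proteins of either origin.

    A sample is kept when it has at least ``min_human`` identified
    human-origin proteins AND at least ``min_microbial`` identified
    microbial-origin proteins (identification = non-missing intensity).
    Returns the kept sample ids and a per-sample report with counts and
    exclusion reasons.  Idempotent: re-filtering the kept samples keeps all
    of them.
    """
    if "origin" not in protein_table.annotations.columns:
        raise ValueError("protein table lacks an 'origin' annotation column")
    origin = protein_table.annotations["origin"]
    mask = protein_table.identified()
    human_counts = mask.loc[origin == "human"].sum(axis=0)
    microbial_counts = mask.loc[origin == "microbial"].sum(axis=0)
    report = pd.DataFrame(
        {
            "human_proteins": human_counts.astype(int),
            "microbial_proteins": microbial_counts.astype(int),
        }
    )
    reasons = []
    for sample in report.index:
        r = []
        if report.at[sample, "human_proteins"] < min_human:
            r.append(f"human_proteins<{min_human}")
        if report.at[sample, "microbial_proteins"] < min_microbial:
            r.append(f"microbial_proteins<{min_microbial}")
        reasons.append(";".join(r))
    report["excluded"] = [bool(r) for r in reasons]
    report["reason"] = reasons
    kept = [s for s in protein_table.samples if not report.at[s, "excluded"]]
    return kept, report


def host_microbe_ratio(protein_table: QuantTable, sample: str) -> float:
    """Ratio of total human-origin to total microbial-origin intensity.

    Missing intensities count as 0.  A zero microbial total makes the ratio
    undefined and raises.
    """
    if "origin" not in protein_table.annotations.columns:
        raise ValueError("protein table lacks an 'origin' annotation column")
    if sample not in protein_table.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = protein_table.values[sample].fillna(0.0)
    origin = protein_table.annotations["origin"]
    human_total = float(col[origin == "human"].sum())
    microbial_total = float(col[origin == "microbial"].sum())
    if microbial_total == 0:
        raise ZeroDivisionError(f"sample {sample!r} has zero microbial intensity")
    return human_total / microbial_total


def aggregate(
    table: QuantTable,
    level: str,
    tree: TaxonomyTree | None = None,
) -> tuple[QuantTable, pd.DataFrame]:
    """Sum feature intensities into taxonomic-rank or functional groups.

    ``level`` is a taxonomic rank name (requires ``tree`` and a
    ``taxon_id`` annotation; each feature's taxon is walked up its lineage
    to the requested rank), or ``"cog"`` / ``"ko"`` (requires the matching
    annotation column).  Features without the needed annotation, or whose
    lineage lacks the requested rank, are dropped and counted in the
    returned report.  Missing intensities are treated as absent (group sums
    over identified members only; a group with no identified member in a
    sample stays missing).
    """
    if level in ("cog", "ko"):
        col = f"{level}_id"
        if col not in table.annotations.columns:
            raise ValueError(f"table lacks annotation column {col!r}")
        keys = table.annotations[col]
    elif level in RANKS:
        if tree is None:
            raise ValueError("taxonomic aggregation requires a TaxonomyTree")
        if "taxon_id" not in table.annotations.columns:
            raise ValueError("table lacks annotation column 'taxon_id'")
        def up_rank(t):
            if pd.isna(t) or t is None:
                return None
            return tree.ancestor_at_rank(str(t), level)
        keys = table.annotations["taxon_id"].map(up_rank)
    else:
        raise ValueError(f"unknown aggregation level {level!r}")

    dropped = keys.isna()
    report = pd.DataFrame(
        {
            "n_features": [len(table.features)],
            "n_dropped_unannotated": [int(dropped.sum())],
        }
    )
    kept = table.values.loc[~dropped]
    group_keys = keys.loc[~dropped]
    grouped = kept.groupby(group_keys.astype(str)).sum(min_count=1)
    grouped.index.name = None
    return QuantTable(grouped), report


def cohort_overlap_report(set_a: Iterable, set_b: Iterable) -> dict:
    """Sizes and shared percentage of two identified-feature sets.

    shared percentage = 100 * |A ∩ B| / |A ∪ B|, rounded to one decimal
    place — the fraction of everything identified across both cohorts that
    was identified in both.  Symmetric in its arguments; undefined when
    both sets are empty.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("overlap of two empty sets is undefined")
    inter = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_union": len(union),
        "n_intersection": len(inter),
        "shared_pct": round(100.0 * len(inter) / len(union), 1),
    }
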