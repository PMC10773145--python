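"""Two-step search-database reduction.

A first-pass search of each run against the full combined database yields a
PSM table; the proteins actually matched at the q-value cutoff form a
per-run simplified database.  Simplified databases from all runs are merged
with the host database into the combined database used for the second-pass
search.  The search engines themselves are external; this module consumes
their tabular output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "load_psm_table",
    "simplify_database",
    "merge_databases",
    "write_fasta",
]

PSM_COLUMNS = ["run", "peptide", "proteins", "q_value"]


def load_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV with columns run, peptide, proteins, q_value.

    ``proteins`` holds semicolon-separated accession lists.  q-values must
    lie in [0, 1] and every row must name at least one accession.
    """
    df = pd.read_csv(path, sep="\t", dtype={"run": str, "peptide": str, "proteins": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks column(s) {missing}")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ValueError("q_value outside [0, 1] in PSM table")
    if df["proteins"].isna().any() or (df["proteins"].str.strip() == "").any():
        raise ValueError("PSM row with empty protein accession list")
    return df[PSM_COLUMNS]


def _read_fasta(path: str | Path) -> dict[str, SeqRecord]:
    records: dict[str, SeqRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        records.setdefault(accession, rec)
    return records


def simplify_database(
    psms: pd.DataFrame, source_db: str | Path, q_cutoff: float = 0.01
) -> list[SeqRecord]:
    """Per-run simplified database: source records matched at q <= cutoff.

    Returns the source FASTA records whose accession appears in at least one
    PSM row with ``q_value <= q_cutoff``, deduplicated, in order of first
    appearance in the table.  Accessions absent from ``source_db`` raise a
    reconciliation error listing them.
    """
    kept = psms.loc[psms["q_value"] <= q_cutoff, "proteins"]
    ordered: list[str] = []
    seen: set[str] = set()
    for cell in kept:
        for acc in str(cell).split(";"):
            acc = acc.strip()
            if acc and acc not in seen:
                seen.add(acc)
                ordered.append(acc)
    source = _read_fasta(source_db)
    missing = [a for a in ordered if a not in source]
    if missing:
        raise KeyError(f"accession(s) not in source database: {', '.join(sorted(missing))}")
    return [source[a] for a in ordered]


def merge_databases(
    reduced: Sequence[Iterable[SeqRecord]], host_db: str | Path | None = None
) -> list[SeqRecord]:
    """Union of the per-run simplified databases with the host database.

    Records are keyed by accession; on collision the host record wins.
    Output is canonicalized by accession sort, so it is invariant to the
    order of the reduced sets.
    """
    merged: dict[str, SeqRecord] = {}
    for record_set in reduced:
        for rec in record_set:
            acc = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
            merged.setdefault(acc, rec)
    if host_db is not None:
        for acc, rec in _read_fasta(host_db).items():
            merged[acc] = rec  # host record wins on collision
    return [merged[a] for a in sorted(merged)]


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")
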