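"""Synthetic tongue-coating study generator with known ground truth.

Emulates the study designs this pipeline targets: a time-series cohort
(5 subjects x 4 timepoints x 3 replicates, one subject absent at the last
timepoint, 57 samples), a single-center case/control cohort (120 cancer /
120 non-cancer) and a multi-center validation cohort (60/60 across three
centers).  Protein intensities follow a log-normal model with a
subject-level random effect (so intra-subject correlation exceeds
inter-subject correlation), planted differential proteins, a risk species
whose abundance is tied to the outcome through a logistic link, and
planted discriminative features for the screening model.  Every planted
effect is recorded in a truth ledger so downstream recovery tests never
re-derive ground truth from regeneration.

The generator is deliberately desk-scale: protein counts default to about
a tenth of a real tongue-coating survey while preserving the ~9:1
microbial-to-human protein ratio and the cohort layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .peptides import canonicalize_and_filter, tryptic_digest
from .quantify import CohortMetadata, QuantTable
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "GeneratorConfig",
    "ProteinRecord",
    "Reference",
    "SimulationResult",
    "generate_reference",
    "generate_cohort",
    "simulate_intensities",
    "emit_psm_table",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

COHORT_DESIGNS = ("time_series", "zjc_like", "multicenter_like")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Taxonomy shape and protein counts set the reference database; the
    intensity model is log-normal on the log2 scale with a per-(feature,
    subject) random effect of sd ``subject_sd`` on top of per-observation
    noise ``noise_sd``.  Planted effects are expressed as log2 fold changes
    in the cancer group; the risk species' abundance is coupled to the
    outcome so that a logistic regression on its z-scored log2 abundance
    has true odds ratio ``risk_or`` per SD.
    """

    seed: int = 0
    # taxonomy shape
    n_phyla: int = 4
    genera_per_phylum: int = 3
    species_per_genus: int = 3
    proteins_per_species: int = 30
    human_proteins: int = 120  # ~9:1 microbial:human with the default shape
    protein_length: tuple[int, int] = (80, 400)
    n_cogs: int = 40
    n_kos: int = 40
    # intensity model (log2 scale)
    base_mean: float = 20.0
    base_sd: float = 2.0  # spread of species (and human protein) baselines
    protein_sd: float = 0.5  # within-species spread of protein baselines
    subject_sd: float = 0.8
    noise_sd: float = 1.0
    missingness: float = 0.1
    # planted effects
    dep_count: int = 10
    dep_log2fc: float = 2.0
    dep_features: dict[str, float] | None = None
    discriminative_count: int = 10
    discriminative_log2fc: float = 2.0
    risk_species: str | None = "auto"  # species taxon id, "auto", or None
    risk_or: float = 3.0
    risk_predictor_scale: float = 2.5  # log2-SD of the risk species' abundance swing
    # stage displacement multipliers applied to discriminative features
    stage_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.0,
            "gastritis": 0.25,
            "I": 1.0,
            "II": 1.0,
            "III": 1.25,
            "IV": 1.25,
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "n_phyla",
            "genera_per_phylum",
            "species_per_genus",
            "proteins_per_species",
            "human_proteins",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.missingness < 1):
            raise ValueError("missingness must lie in [0, 1)")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    origin: str  # "human" | "microbial"
    taxon_id: str | None

    def fasta_header(self) -> str:
        if self.origin == "human":
            return f"sp|{self.accession}|{self.accession}_HUMAN synthetic human protein"
        return f"{self.accession} taxid={self.taxon_id} synthetic microbial protein"


@dataclass
class Reference:
    """Synthetic taxonomy + protein databases + functional annotations."""

    tree: TaxonomyTree
    proteins: list[ProteinRecord]
    annotations: pd.DataFrame  # index accession; origin, taxon_id, cog_id, ko_id

    @property
    def microbial(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.origin == "microbial"]

    @property
    def human(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.origin == "human"]

    @property
    def species(self) -> list[str]:
        return sorted({p.taxon_id for p in self.microbial})

    def proteins_of_species(self, taxon_id: str) -> list[str]:
        return [p.accession for p in self.microbial if p.taxon_id == taxon_id]

    def write_fasta(self, microbial_path: str | Path, human_path: str | Path) -> None:
        with open(microbial_path, "w") as fh:
            for p in self.microbial:
                fh.write(f">{p.fasta_header()}\n{p.sequence}\n")
        with open(human_path, "w") as fh:
            for p in self.human:
                fh.write(f">{p.fasta_header()}\n{p.sequence}\n")

    def write_taxonomy(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for node in self.tree.nodes.values():
                fh.write(f"{node.taxon_id}\t{node.parent_id}\t{node.rank}\t{node.name}\n")

    def write_annotations(self, path: str | Path) -> None:
        self.annotations.to_csv(path, sep="\t", index_label="accession")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def generate_reference(config: GeneratorConfig) -> Reference:
    """Build the synthetic taxonomy and protein databases.

    The taxonomy is a balanced root -> phylum -> genus -> species tree of
    the configured shape.  Each species carries ``proteins_per_species``
    random proteins (length uniform in ``protein_length``) with
    ``taxid=``-labelled FASTA headers; the host database uses
    UniProt-style headers.  Each microbial protein is assigned one COG and
    one KO from the configured vocabularies.
    """
    rng = np.random.default_rng(config.seed)
    nodes: dict[str, TaxonNode] = {"1": TaxonNode("1", "1", "no_rank", "root")}
    species_ids: list[str] = []
    for p in range(1, config.n_phyla + 1):
        pid = f"p{p}"
        nodes[pid] = TaxonNode(pid, "1", "phylum", f"Phylum_{p}")
        for g in range(1, config.genera_per_phylum + 1):
            gid = f"{pid}.g{g}"
            nodes[gid] = TaxonNode(gid, pid, "genus", f"Genus_{p}_{g}")
            for s in range(1, config.species_per_genus + 1):
                sid = f"{gid}.s{s}"
                nodes[sid] = TaxonNode(sid, gid, "species", f"Species_{p}_{g}_{s}")
                species_ids.append(sid)
    tree = TaxonomyTree(nodes=nodes, root_id="1")

    proteins: list[ProteinRecord] = []
    lo, hi = config.protein_length
    for sid in species_ids:
        tag = sid.replace(".", "").upper()
        for i in range(config.proteins_per_species):
            seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            proteins.append(ProteinRecord(f"M{tag}_{i:04d}", seq, "microbial", sid))
    for i in range(config.human_proteins):
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        proteins.append(ProteinRecord(f"HUM{i:04d}", seq, "human", None))

    # baseline log2 abundances are a property of the reference community:
    # species biomass drives all of a species' proteins, with a smaller
    # protein-specific offset; human proteins draw directly from the
    # baseline distribution
    species_base = {
        sid: rng.normal(config.base_mean, config.base_sd) for sid in species_ids
    }
    baselines = [
        species_base[p.taxon_id] + rng.normal(0.0, config.protein_sd)
        if p.origin == "microbial"
        else rng.normal(config.base_mean, config.base_sd)
        for p in proteins
    ]

    ann = pd.DataFrame(
        {
            "origin": [p.origin for p in proteins],
            "taxon_id": [p.taxon_id for p in proteins],
            "baseline_log2": baselines,
        },
        index=[p.accession for p in proteins],
    )
    is_microbial = ann["origin"] == "microbial"
    n_mic = int(is_microbial.sum())
    ann["cog_id"] = None
    ann["ko_id"] = None
    ann.loc[is_microbial, "cog_id"] = [
        f"COG{int(i):04d}" for i in rng.integers(0, config.n_cogs, size=n_mic)
    ]
    ann.loc[is_microbial, "ko_id"] = [
        f"K{int(i):05d}" for i in rng.integers(0, config.n_kos, size=n_mic)
    ]
    return Reference(tree=tree, proteins=proteins, annotations=ann)


def generate_cohort(design: str, seed: int = 0) -> CohortMetadata:
    """Sample metadata for one of the emulated cohort designs.

    ``time_series``: 5 healthy subjects sampled on days 0/3/6/9 with 3
    replicates per visit; subject 5 misses the final visit (57 samples).
    ``zjc_like``: 120 cancer / 120 non-cancer at one center, with cancer
    stages I-IV and a gastritis subset among the non-cancer samples.
    ``multicenter_like``: 60/60 over three centers.
    """
    rows: list[dict] = []
    if design == "time_series":
        for subj in range(1, 6):
            for day in (0, 3, 6, 9):
                if subj == 5 and day == 9:
                    continue  # one volunteer absent at the last sampling
                for rep in (1, 2, 3):
                    rows.append(
                        {
                            "sample": f"TS_S{subj}_D{day}_R{rep}",
                            "subject": f"TS_S{subj}",
                            "center": "time-series",
                            "group": "non_cancer",
                            "stage": "none",
                            "timepoint": day,
                            "replicate": rep,
                        }
                    )
    elif design == "zjc_like":
        stages = ["I", "II", "III", "IV"]
        for i in range(120):
            rows.append(
                {
                    "sample": f"ZJC_C{i:03d}",
                    "subject": f"ZJC_C{i:03d}",
                    "center": "ZJC",
                    "group": "cancer",
                    "stage": stages[i % 4],
                    "timepoint": 0,
                    "replicate": 1,
                }
            )
        for i in range(120):
            rows.append(
                {
                    "sample": f"ZJC_N{i:03d}",
                    "subject": f"ZJC_N{i:03d}",
                    "center": "ZJC",
                    "group": "non_cancer",
                    "stage": "gastritis" if i % 3 == 0 else "none",
                    "timepoint": 0,
                    "replicate": 1,
                }
            )
    elif design == "multicenter_like":
        centers = ["WZ", "ZJT", "SCC"]
        stages = ["I", "II", "III", "IV"]
        for i in range(60):
            rows.append(
                {
                    "sample": f"MC_C{i:03d}",
                    "subject": f"MC_C{i:03d}",
                    "center": centers[i % 3],
                    "group": "cancer",
                    "stage": stages[i % 4],
                    "timepoint": 0,
                    "replicate": 1,
                }
            )
        for i in range(60):
            rows.append(
                {
                    "sample": f"MC_N{i:03d}",
                    "subject": f"MC_N{i:03d}",
                    "center": centers[i % 3],
                    "group": "non_cancer",
                    "stage": "gastritis" if i % 3 == 0 else "none",
                    "timepoint": 0,
                    "replicate": 1,
                }
            )
    else:
        raise ValueError(f"unknown cohort design {design!r}; expected one of {COHORT_DESIGNS}")
    df = pd.DataFrame(rows).set_index("sample")
    return CohortMetadata(df)


def _risk_predictor_params(odds_ratio: float) -> tuple[float, float]:
    """Per-group mean +/-m and within-group sd s of the risk predictor.

    Chosen so the pooled predictor has mean 0 and variance 1 and the true
    logistic slope equals log(odds_ratio): with x|group ~ N(+/-m, s^2) and
    equal group sizes the log-odds are linear in x with slope 2m/s^2, and
    the pooled variance is s^2 + m^2.  Solving 2m/s^2 = beta and
    s^2 + m^2 = 1 gives s^2 = 2(sqrt(1+beta^2)-1)/beta^2, m = beta s^2/2.

    Scaling m and s by a common factor leaves the slope per pooled SD
    unchanged, so the generator can widen the species' abundance swing
    (``risk_predictor_scale``) without moving the target odds ratio on the
    z-scored analysis scale.
    """
    beta = float(np.log(odds_ratio))
    if beta == 0.0:
        return 0.0, 1.0
    s2 = 2.0 * (np.sqrt(1.0 + beta**2) - 1.0) / beta**2
    m = beta * s2 / 2.0
    return m, float(np.sqrt(s2))


@dataclass
class SimulationResult:
    protein_table: QuantTable
    peptide_table: QuantTable | None
    truth: dict


def simulate_intensities(
    reference: Reference,
    metadata: CohortMetadata,
    config: GeneratorConfig,
    emit_peptides: bool = False,
    peptides_per_protein: int = 2,
) -> SimulationResult:
    """Draw a protein (and optionally peptide) intensity matrix.

    log2 intensity of feature f in sample s =
        mu_f + u_{f,subject(s)} + planted effects(f, s) + eps_{f,s},
    with mu_f the reference's fixed baseline, u ~ N(0, subject_sd) shared
    by all samples of one subject, eps ~ N(0, noise_sd).  Planted differential
    and discriminative features receive their log2 shift in cancer samples
    (discriminative shifts scaled by the per-stage multiplier).  Every
    protein of the risk species shares a per-sample predictor drawn from
    the logistic-link construction of :func:`_risk_predictor_params`.
    Missing-at-random masking at rate ``missingness`` is applied last.
    """
    rng = np.random.default_rng(config.seed + 1)
    accessions = [p.accession for p in reference.proteins]
    microbial_acc = [p.accession for p in reference.microbial]
    samples = metadata.samples
    subjects = metadata.df["subject"]
    groups = metadata.df["group"]
    stages = metadata.df["stage"]
    n_feat, n_samp = len(accessions), len(samples)
    acc_pos = {a: i for i, a in enumerate(accessions)}

    risk_taxon: str | None = None
    risk_proteins: set[str] = set()
    if config.risk_species is not None:
        risk_taxon = (
            reference.species[0] if config.risk_species == "auto" else config.risk_species
        )
        if risk_taxon not in set(reference.species):
            raise ValueError(f"risk species {risk_taxon!r} not in reference taxonomy")
        risk_proteins = set(reference.proteins_of_species(risk_taxon))

    # planted differential features (microbial by default; dict overrides);
    # the risk species' proteins are kept out of the group-shift pools so the
    # planted odds ratio is not confounded by an extra cancer fold change
    if config.dep_features is not None:
        dep = dict(config.dep_features)
        unknown = [f for f in dep if f not in acc_pos]
        if unknown:
            raise ValueError(f"planted feature(s) not in reference: {unknown}")
    else:
        pool = [a for a in microbial_acc if a not in risk_proteins]
        chosen = rng.choice(pool, size=min(config.dep_count, len(pool)), replace=False)
        dep = {str(a): config.dep_log2fc for a in chosen}

    remaining = [a for a in microbial_acc if a not in dep and a not in risk_proteins]
    disc = [str(a) for a in rng.choice(remaining, size=min(config.discriminative_count, len(remaining)), replace=False)]

    # baselines come from the reference (fixed per community); per-replicate
    # randomness is subject effects, planted effects and observation noise
    mu = reference.annotations["baseline_log2"].to_numpy(dtype=float)
    log2 = np.tile(mu[:, None], (1, n_samp))

    # subject random effects, shared across a subject's samples
    unique_subjects = sorted(subjects.unique())
    subj_idx = np.array([unique_subjects.index(subjects[s]) for s in samples])
    u = rng.normal(0.0, config.subject_sd, size=(n_feat, len(unique_subjects)))
    log2 += u[:, subj_idx]

    is_cancer = np.array([groups[s] == "cancer" for s in samples], dtype=float)
    stage_mult = np.array([config.stage_multipliers.get(str(stages[s]), 0.0) for s in samples])

    for feat, lfc in dep.items():
        log2[acc_pos[feat]] += lfc * is_cancer
    for feat in disc:
        log2[acc_pos[feat]] += config.discriminative_log2fc * stage_mult

    risk_predictor = None
    if risk_taxon is not None:
        m, s = _risk_predictor_params(config.risk_or)
        c = config.risk_predictor_scale
        centers = np.where(is_cancer == 1.0, c * m, -c * m)
        risk_predictor = rng.normal(centers, c * s)
        for acc in reference.proteins_of_species(risk_taxon):
            log2[acc_pos[acc]] += risk_predictor

    log2 += rng.normal(0.0, config.noise_sd, size=(n_feat, n_samp))
    intensities = np.power(2.0, log2)
    if config.missingness > 0:
        mask = rng.random(size=(n_feat, n_samp)) < config.missingness
        intensities = np.where(mask, np.nan, intensities)

    values = pd.DataFrame(intensities, index=accessions, columns=samples)
    protein_table = QuantTable(values, reference.annotations.copy())

    peptide_table = None
    if emit_peptides:
        pep_rows, pep_index, pep_ann = [], [], []
        for prot in reference.proteins:
            frags = canonicalize_and_filter(tryptic_digest(prot.sequence, 0))
            for j, frag in enumerate(frags[:peptides_per_protein]):
                share = rng.uniform(0.2, 1.0)
                pep_rows.append(values.loc[prot.accession].to_numpy() * share)
                pep_index.append(f"{prot.accession}:{frag}")
                pep_ann.append((prot.origin, prot.taxon_id))
        pep_values = pd.DataFrame(np.vstack(pep_rows), index=pep_index, columns=samples)
        ann = pd.DataFrame(pep_ann, columns=["origin", "taxon_id"], index=pep_index)
        peptide_table = QuantTable(pep_values, ann)

    truth = {
        "seed": config.seed,
        "dep_features": dep,
        "discriminative_features": disc,
        "risk_species": risk_taxon,
        "risk_or": config.risk_or if risk_taxon is not None else None,
        "risk_predictor": (
            dict(zip(samples, map(float, risk_predictor))) if risk_predictor is not None else None
        ),
        "protein_taxon": {p.accession: p.taxon_id for p in reference.microbial},
        "group_of_sample": {s: str(groups[s]) for s in samples},
    }
    return SimulationResult(protein_table=protein_table, peptide_table=peptide_table, truth=truth)


def emit_psm_table(
    reference: Reference,
    seed: int = 0,
    n_runs: int = 3,
    sampled_fraction: float = 0.4,
    decoy_fraction: float = 0.1,
) -> tuple[pd.DataFrame, set[str]]:
    """Mock first-pass PSM table: the desk-scale stand-in for a DDA search.

    A random ``sampled_fraction`` of proteins per run are "truly present"
    and receive PSM rows at q <= 0.01; a further ``decoy_fraction`` appear
    only at q > 0.01 and must not survive the cutoff.  Returns the table
    and the set of truly sampled accessions (per the truth ledger
    contract, recovery tests compare against this set, not a re-draw).
    """
    rng = np.random.default_rng(seed + 7)
    rows = []
    truly_sampled: set[str] = set()
    accessions = [p.accession for p in reference.proteins]
    seq_of = {p.accession: p.sequence for p in reference.proteins}
    for run in range(1, n_runs + 1):
        hits = rng.choice(accessions, size=max(1, int(sampled_fraction * len(accessions))), replace=False)
        truly_sampled.update(map(str, hits))
        for acc in hits:
            frags = canonicalize_and_filter(tryptic_digest(seq_of[str(acc)], 0))
            pep = frags[0] if frags else seq_of[str(acc)][:10]
            rows.append((f"run{run}", pep, str(acc), float(rng.uniform(0.0, 0.01))))
        decoys = rng.choice(accessions, size=max(1, int(decoy_fraction * len(accessions))), replace=False)
        for acc in decoys:
            if str(acc) in truly_sampled:
                continue
            rows.append((f"run{run}", seq_of[str(acc)][:8], str(acc), float(rng.uniform(0.02, 0.5))))
    psms = pd.DataFrame(rows, columns=["run", "peptide", "proteins", "q_value"])
    return psms, truly_sampled
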