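"""In-silico tryptic digestion and peptide-centric taxonomic annotation.

Observed peptides from a DIA search may carry missed cleavages, so they are
re-digested in silico into fully tryptic subpeptides, canonicalized under
the I/L-equivalence rule, length-filtered, and looked up in a peptide index
built from the host and microbial protein databases.  Each subpeptide's
database hits are collapsed to one taxon by LCA, and the subpeptide taxa
are then combined with the branch rule: same branch -> narrowest taxon,
diverging branches -> broad consensus (see :mod:`tonguecoat.taxonomy`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .taxonomy import TaxonomyTree, resolve_taxa

__all__ = [
    "STANDARD_RESIDUES",
    "PeptideRecord",
    "PeptideIndex",
    "IndexEntry",
    "tryptic_digest",
    "canonicalize",
    "canonicalize_and_filter",
    "build_peptide_index",
    "annotate_peptide",
]

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIN_PEPTIDE_LEN = 5
MAX_PEPTIDE_LEN = 50


def _cleavage_sites(sequence: str, proline_rule: bool) -> list[int]:
    """Positions after which trypsin cuts (cut between i and i+1)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def tryptic_digest(
    sequence: str, max_missed: int = 0, *, proline_rule: bool = True
) -> list[str]:
    """All tryptic fragments of ``sequence`` with at most ``max_missed``
    internal cleavage sites, ordered by start position.

    Trypsin cuts C-terminal to K or R; with ``proline_rule`` (the standard
    convention) a K/R followed by P is not cut.  ``max_missed=0`` gives the
    fully tryptic partition of the sequence.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = sorted(set(sequence) - STANDARD_RESIDUES)
    if bad:
        raise ValueError(f"non-standard residue(s) {''.join(bad)!r} in sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0, *_cleavage_sites(sequence, proline_rule), len(sequence)]
    fragments: list[tuple[int, str]] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            fragments.append((bounds[i], sequence[bounds[i] : bounds[j]]))
    fragments.sort(key=lambda t: (t[0], len(t[1])))
    return [f for _, f in fragments]


def canonicalize(sequence: str) -> str:
    """I/L-equivalent canonical form: every L rewritten as I."""
    return sequence.replace("L", "I")


def canonicalize_and_filter(
    fragments: Iterable[str],
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[str]:
    """Canonicalize fragments and drop those outside [min_len, max_len]."""
    return [canonicalize(f) for f in fragments if min_len <= len(f) <= max_len]


@dataclass(frozen=True)
class IndexEntry:
    accession: str
    origin: str  # "human" | "microbial"
    taxon_id: str | None  # None for human entries


@dataclass
class PeptideIndex:
    """Canonical tryptic peptide -> database hits (accession, origin, taxon)."""

    entries: dict[str, list[IndexEntry]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return canonicalize(peptide) in self.entries

    def hits(self, peptide: str) -> list[IndexEntry]:
        return self.entries.get(canonicalize(peptide), [])

    def add(self, peptide: str, entry: IndexEntry) -> None:
        self.entries.setdefault(peptide, [])
        if entry not in self.entries[peptide]:
            self.entries[peptide].append(entry)


_TAXID_RE = re.compile(r"taxid=(\S+)")
_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def parse_header(description: str, origin: str) -> tuple[str, str | None]:
    """Extract (accession, taxon_id) from a FASTA description line.

    Human headers follow the UniProt convention ``sp|ACC|NAME``; microbial
    headers carry an explicit ``taxid=<id>`` token after the accession.
    """
    first = description.split()[0]
    m = _UNIPROT_RE.match(first)
    accession = m.group(1) if m else first
    if origin == "human":
        return accession, None
    m = _TAXID_RE.search(description)
    if m is None:
        raise ValueError(f"microbial FASTA header lacks a taxid= token: {description!r}")
    return accession, m.group(1)


def build_peptide_index(
    databases: Sequence[tuple[str | Path, str]],
    max_missed: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> PeptideIndex:
    """Digest every protein of the given FASTA databases into an index.

    Parameters
    ----------
    databases
        Sequence of ``(fasta_path, origin)`` pairs with origin ``"human"``
        or ``"microbial"``.  Accession collisions across databases keep the
        first occurrence and log a warning.
    max_missed
        Missed-cleavage depth of the index; 2 matches common search-engine
        settings.
    """
    index = PeptideIndex()
    seen_accessions: set[str] = set()
    for path, origin in databases:
        if origin not in ("human", "microbial"):
            raise ValueError(f"origin must be 'human' or 'microbial', got {origin!r}")
        for record in SeqIO.parse(str(path), "fasta"):
            accession, taxon_id = parse_header(record.description, origin)
            if accession in seen_accessions:
                logger.warning("duplicate accession %s in %s skipped", accession, path)
                continue
            seen_accessions.add(accession)
            entry = IndexEntry(accession, origin, taxon_id)
            fragments = tryptic_digest(str(record.seq), max_missed)
            for pep in canonicalize_and_filter(fragments, min_len, max_len):
                index.add(pep, entry)
    return index


@dataclass
class PeptideRecord:
    """An observed peptide and its derived annotation state."""

    observed_sequence: str
    canonical_sequence: str = ""
    subpeptides: list[str] = field(default_factory=list)
    assigned_taxon: str | None = None

    @classmethod
    def from_observed(cls, sequence: str, max_missed_resplit: int = 0) -> "PeptideRecord":
        """Split an observed peptide into fully tryptic, length-filtered
        canonical subpeptides (``max_missed_resplit=0`` is the re-digestion
        used before annotation)."""
        canonical = canonicalize(sequence)
        fragments = tryptic_digest(sequence, max_missed_resplit)
        return cls(
            observed_sequence=sequence,
            canonical_sequence=canonical,
            subpeptides=canonicalize_and_filter(fragments),
        )


def annotate_peptide(
    record: PeptideRecord,
    index: PeptideIndex,
    tree: TaxonomyTree,
    broad_mode: str = "lca",
    host_first: bool = True,
) -> str | None:
    """Assign a taxon to an observed peptide via its tryptic subpeptides.

    Each subpeptide is looked up in the index and its hit taxa are collapsed
    by LCA.  Subpeptides with no hits are ignored.  The per-subpeptide taxa
    are then combined with the branch rule: one branch -> narrowest member;
    diverging branches -> ``broad_mode`` consensus.  Returns ``None`` when
    no subpeptide has any microbial hit.

    With ``host_first`` (default), a subpeptide that matches any human
    protein is treated as host-derived and excluded from taxonomic
    evidence — conservative, avoids inflating microbial signal from shared
    sequence.
    """
    per_subpeptide: list[str] = []
    for sub in record.subpeptides:
        hits = index.hits(sub)
        if not hits:
            continue
        if host_first and any(h.origin == "human" for h in hits):
            continue
        taxa = {h.taxon_id for h in hits if h.taxon_id is not None}
        if taxa:
            per_subpeptide.append(resolve_taxa(tree, taxa, broad_mode="lca"))
    if not per_subpeptide:
        record.assigned_taxon = None
        return None
    record.assigned_taxon = resolve_taxa(tree, set(per_subpeptide), broad_mode=broad_mode)
    return record.assigned_taxon


def annotate_peptides(
    sequences: Iterable[str],
    index: PeptideIndex,
    tree: TaxonomyTree,
    broad_mode: str = "lca",
) -> dict[str, str | None]:
    """Vectorized convenience wrapper: observed sequence -> assigned taxon."""
    out: dict[str, str | None] = {}
    for seq in sequences:
        record = PeptideRecord.from_observed(seq)
        out[seq] = annotate_peptide(record, index, tree, broad_mode=broad_mode)
    return out
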