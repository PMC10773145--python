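"""Taxonomy trees and peptide-style taxon resolution.

A :class:`TaxonomyTree` is a rooted tree of named, rank-labelled nodes
(superkingdom down to species, with ``no_rank`` for everything else).  It
answers lineage and lowest-common-ancestor queries and implements the
branch-resolution rule used for shared-peptide annotation: taxa that all
lie on one root-to-leaf path are collapsed to the narrowest (deepest)
member, while taxa from diverging branches are collapsed to a broad
consensus taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "RANKS",
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "load_taxonomy",
    "is_single_branch",
    "resolve_taxa",
]

#: Named ranks from broadest to narrowest; anything else maps to ``no_rank``.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy: cycle, orphan, or unknown taxon."""


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Rooted taxonomy supporting lineage, depth and LCA queries.

    The root's ``parent_id`` points to itself.  Lineages run root-first and
    end at the queried node.
    """

    nodes: dict[str, TaxonNode]
    root_id: str
    _lineages: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].taxon_id != self.root_id:
            raise TaxonomyError(f"declared root {self.root_id!r} is not the self-parented node")
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"orphan node {node.taxon_id!r}: parent {node.parent_id!r} is absent"
                )
        # cycle check doubles as lineage precomputation
        for tid in self.nodes:
            self.lineage(tid)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        """Root-first chain of taxon ids ending at ``taxon_id``."""
        cached = self._lineages.get(taxon_id)
        if cached is not None:
            return cached
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        chain: list[str] = []
        seen: set[str] = set()
        tid = taxon_id
        while True:
            if tid in seen:
                raise TaxonomyError(f"cycle detected through taxon {tid!r}")
            seen.add(tid)
            chain.append(tid)
            node = self.nodes[tid]
            if node.parent_id == tid:
                break
            tid = node.parent_id
        lin = tuple(reversed(chain))
        self._lineages[taxon_id] = lin
        return lin

    def depth(self, taxon_id: str) -> int:
        return len(self.lineage(taxon_id)) - 1

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True iff ``ancestor`` lies on the lineage of ``descendant`` (or equals it)."""
        return ancestor in self.lineage(descendant)

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor: deepest node shared by every lineage."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        common = None
        for tid in taxa:
            lin = self.lineage(tid)
            if common is None:
                common = list(lin)
            else:
                keep = 0
                for a, b in zip(common, lin):
                    if a != b:
                        break
                    keep += 1
                del common[keep:]
        assert common  # root is always shared
        return common[-1]

    def rank_of(self, taxon_id: str) -> str:
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        return self.nodes[taxon_id].rank

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Lineage member of ``taxon_id`` carrying the named rank, if any.

        ``no_rank`` nodes participate in the lineage but are never reported
        at a named rank.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        for tid in self.lineage(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def lineage_names(self, taxon_id: str) -> str:
        return ";".join(self.nodes[t].name for t in self.lineage(taxon_id))


def _normalize_rank(rank: str) -> str:
    rank = rank.strip().lower()
    return rank if rank in RANKS else "no_rank"


def _load_flat_tsv(path: Path) -> dict[str, TaxonNode]:
    nodes: dict[str, TaxonNode] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["taxon_id", "parent_id", "rank", "name"]
        if [c.strip().lower() for c in header[:4]] != expected:
            raise TaxonomyError(f"flat_tsv taxonomy needs header columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise TaxonomyError(f"{path}:{lineno}: expected 4 tab-separated fields")
            tid, pid, rank, name = (p.strip() for p in parts[:4])
            nodes[tid] = TaxonNode(tid, pid, _normalize_rank(rank), name)
    return nodes


def _parse_dmp_line(line: str) -> list[str]:
    # NCBI dump rows are "field\t|\tfield\t|\t...\t|\n"
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def _load_ncbi_dump(path: Path) -> dict[str, TaxonNode]:
    path = Path(path)
    if path.is_dir():
        nodes_file, names_file = path / "nodes.dmp", path / "names.dmp"
    else:  # path points at nodes.dmp; names.dmp sits alongside
        nodes_file, names_file = path, path.parent / "names.dmp"
    names: dict[str, str] = {}
    with open(names_file) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[fields[0]] = fields[1]
    nodes: dict[str, TaxonNode] = {}
    with open(nodes_file) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes.dmp row: {line!r}")
            tid, pid, rank = fields[0], fields[1], fields[2]
            nodes[tid] = TaxonNode(tid, pid, _normalize_rank(rank), names.get(tid, tid))
    return nodes


def load_taxonomy(path: str | Path, dialect: str = "flat_tsv") -> TaxonomyTree:
    """Load a taxonomy from a flat TSV or an NCBI-style nodes/names dump.

    Parameters
    ----------
    path
        ``flat_tsv``: a 4-column TSV (taxon_id, parent_id, rank, name) with a
        header row.  ``ncbi_dump``: a directory holding ``nodes.dmp`` and
        ``names.dmp`` (or the path to ``nodes.dmp`` itself); only the
        ``scientific name`` class is read from names.dmp.
    dialect
        ``"flat_tsv"`` or ``"ncbi_dump"``.
    """
    path = Path(path)
    if dialect == "flat_tsv":
        nodes = _load_flat_tsv(path)
    elif dialect == "ncbi_dump":
        nodes = _load_ncbi_dump(path)
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    if not nodes:
        raise TaxonomyError(f"no taxa parsed from {path}")
    roots = [n.taxon_id for n in nodes.values() if n.parent_id == n.taxon_id]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parented root, found {len(roots)}")
    return TaxonomyTree(nodes=nodes, root_id=roots[0])


def is_single_branch(tree: TaxonomyTree, taxa: Iterable[str]) -> bool:
    """True iff the taxa all lie on a single root-to-leaf path.

    Equivalently, every pair is in an ancestor-descendant relation: sorting
    by depth, each taxon's lineage must contain all shallower members.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    deepest = max(taxa, key=lambda t: tree.depth(t))
    lin = set(tree.lineage(deepest))
    return taxa <= lin


def resolve_taxa(tree: TaxonomyTree, taxa: Iterable[str], broad_mode: str = "lca") -> str:
    """Collapse a set of candidate taxa to one consensus taxon.

    Singleton sets resolve to their member.  Taxa on a single branch resolve
    to the narrowest (deepest) member.  Taxa from diverging branches resolve
    broadly: ``broad_mode="lca"`` returns their lowest common ancestor
    (Unipept-style semantics), ``broad_mode="literal_broadest"`` returns the
    shallowest member itself, ties broken by smallest taxon id.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("cannot resolve an empty taxon set")
    for t in taxa:
        if t not in tree:
            raise TaxonomyError(f"unknown taxon {t!r}")
    if len(taxa) == 1:
        return next(iter(taxa))
    if is_single_branch(tree, taxa):
        return max(taxa, key=lambda t: (tree.depth(t), t))
    if broad_mode == "lca":
        return tree.lca(taxa)
    if broad_mode == "literal_broadest":
        return min(taxa, key=lambda t: (tree.depth(t), t))
    raise ValueError(f"unknown broad_mode {broad_mode!r}")
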