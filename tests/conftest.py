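import numpy as np
import pandas as pd
import pytest

from tonguecoat.quantify import CohortMetadata
from tonguecoat.simulate import GeneratorConfig, generate_reference
from tonguecoat.taxonomy import TaxonNode, TaxonomyTree


def build_toy_tree() -> TaxonomyTree:
    """20-node taxonomy: root, 2 phyla, one no_rank clade, 4 genera, 12 species."""
    nodes = {}

    def add(tid, pid, rank, name=None):
        nodes[tid] = TaxonNode(tid, pid, rank, name or tid)

    add("1", "1", "no_rank", "root")
    add("pA", "1", "phylum")
    add("pB", "1", "phylum")
    add("xA", "pA", "no_rank")  # unranked clade inside phylum A
    add("gA1", "xA", "genus")
    add("gA2", "pA", "genus")
    add("gB1", "pB", "genus")
    add("gB2", "pB", "genus")
    for g in ("gA1", "gA2", "gB1", "gB2"):
        for i in (1, 2, 3):
            add(f"{g}.s{i}", g, "species")
    tree = TaxonomyTree(nodes=nodes, root_id="1")
    assert len(tree.nodes) == 20
    return tree


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    return build_toy_tree()


@pytest.fixture(scope="session")
def small_reference():
    """Tiny synthetic reference: 8 species x 3 proteins + 5 human proteins."""
    config = GeneratorConfig(
        seed=5,
        n_phyla=2,
        genera_per_phylum=2,
        species_per_genus=2,
        proteins_per_species=3,
        human_proteins=5,
    )
    return config, generate_reference(config)


def make_metadata(n_cancer: int, n_control: int, prefix: str = "S") -> CohortMetadata:
    samples = [f"{prefix}C{i}" for i in range(n_cancer)] + [
        f"{prefix}N{i}" for i in range(n_control)
    ]
    df = pd.DataFrame(
        {
            "subject": samples,
            "center": "ZJC",
            "group": ["cancer"] * n_cancer + ["non_cancer"] * n_control,
            "stage": ["II"] * n_cancer + ["none"] * n_control,
            "timepoint": 0,
            "replicate": 1,
        },
        index=samples,
    )
    return CohortMetadata(df)


# --- independent oracles -----------------------------------------------------

def oracle_digest(sequence: str, max_missed: int) -> list[str]:
    """Brute-force tryptic enumerator: mark cleavage sites, emit every
    boundary-to-boundary window containing at most max_missed sites."""
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(sequence)]
    out = []
    for si in range(len(bounds) - 1):
        for sj in range(si + 1, len(bounds)):
            start, end = bounds[si], bounds[sj]
            internal = sum(1 for s in sites if start < s < end)
            if internal <= max_missed:
                out.append((start, sequence[start:end]))
    out.sort(key=lambda t: (t[0], len(t[1])))
    return [f for _, f in out]


def oracle_is_single_branch(tree: TaxonomyTree, taxa) -> bool:
    """Pairwise ancestor check after sorting by depth."""
    ordered = sorted(taxa, key=tree.depth)
    for a, b in zip(ordered, ordered[1:]):
        if a not in tree.lineage(b):
            return False
    return True


def oracle_lca(tree: TaxonomyTree, taxa) -> str:
    """LCA by explicit lineage intersection, keeping lineage order."""
    lineages = [tree.lineage(t) for t in taxa]
    common = set(lineages[0]).intersection(*map(set, lineages[1:]))
    return max(common, key=tree.depth)


def oracle_resolve(tree: TaxonomyTree, taxa, broad_mode: str) -> str:
    taxa = set(taxa)
    if len(taxa) == 1:
        return next(iter(taxa))
    if oracle_is_single_branch(tree, taxa):
        return max(taxa, key=lambda t: (tree.depth(t), t))
    if broad_mode == "lca":
        return oracle_lca(tree, taxa)
    return min(taxa, key=lambda t: (tree.depth(t), t))


def oracle_fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric summation: sum the
    probabilities of all tables (same margins) no more likely than the
    observed one."""
    from math import comb

    denom = comb(N, n)
    lo, hi = max(0, n - (N - K)), min(n, K)
    probs = {kk: comb(K, kk) * comb(N - K, n - kk) / denom for kk in range(lo, hi + 1)}
    p_obs = probs[k]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def random_aa_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
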