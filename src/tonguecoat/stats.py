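"""Cohort statistics: stability, differential abundance, enrichment, risk.

All tests are the field's standard nonparametrics.  Stability is the
Spearman correlation of feature abundances between sample pairs, stratified
into intra-individual (same subject) and inter-individual pairs.
Differential abundance uses the two-sided Wilcoxon rank-sum test with a
fold-change threshold; category enrichment uses Fisher's exact test; and
per-species gastric-cancer risk is a univariate logistic regression
reported as an odds ratio with Wald confidence interval.
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .quantify import CohortMetadata, QuantTable

__all__ = [
    "stability_summary",
    "pairwise_spearman",
    "rank_sum_test",
    "differential_proteins",
    "fisher_exact_2x2",
    "fisher_enrichment",
    "species_risk",
    "host_microbe_correlation",
]

logger = logging.getLogger(__name__)


# --- stability ---------------------------------------------------------------

def pairwise_spearman(
    table: QuantTable, min_shared: int = 3
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Spearman correlation for every sample pair on pairwise-complete features.

    Returns a long frame (sample_a, sample_b, rho, n_shared) and the list of
    pairs dropped for having fewer than ``min_shared`` jointly identified
    features.
    """
    samples = table.samples
    vals = table.values
    rows, dropped = [], []
    for a, b in itertools.combinations(samples, 2):
        x, y = vals[a], vals[b]
        mask = x.notna() & y.notna()
        n = int(mask.sum())
        if n < min_shared:
            dropped.append((a, b))
            continue
        rho = sps.spearmanr(x[mask], y[mask]).statistic
        rows.append((a, b, float(rho), n))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "rho", "n_shared"]), dropped


def stability_summary(
    table: QuantTable, meta: CohortMetadata, layer: str = "protein"
) -> pd.DataFrame:
    """Mean +/- sd of pairwise Spearman correlations, intra vs inter subject.

    ``layer`` is a label recorded in the output (e.g. human_protein,
    microbial_protein, phylum, cog); the caller supplies ``table`` already
    restricted or aggregated to that layer.
    """
    if len(table.samples) < 2:
        raise ValueError("stability needs at least two samples")
    pairs, dropped = pairwise_spearman(table)
    if dropped:
        logger.info("stability: %d sample pairs dropped (<3 shared features)", len(dropped))
    if pairs.empty:
        return pd.DataFrame(
            columns=["stratum", "layer", "mean_rho", "sd_rho", "n_pairs"]
        )
    subject = meta.df["subject"]
    same = pairs.apply(lambda r: subject[r.sample_a] == subject[r.sample_b], axis=1)
    out = []
    for stratum, sel in (("intra_individual", same), ("inter_individual", ~same)):
        sub = pairs.loc[sel, "rho"]
        if len(sub) == 0:
            continue
        out.append(
            {
                "stratum": stratum,
                "layer": layer,
                "mean_rho": float(sub.mean()),
                "sd_rho": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
                "n_pairs": int(len(sub)),
            }
        )
    return pd.DataFrame(out)


# --- differential abundance --------------------------------------------------

def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def differential_proteins(
    table: QuantTable,
    meta: CohortMetadata,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    adjust: str = "none",
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential abundance, cancer vs non-cancer.

    Per feature: two-sided rank-sum p on the non-missing intensities of the
    two groups, and log2 fold change of linear-scale group means (cancer
    over non-cancer; both means offset by +1 when either is zero).
    Features with fewer than ``min_per_group`` non-missing values in either
    group are skipped (``tested=False``).  The significant set requires
    ``|log2fc| > lfc_threshold`` and (raw or BH-adjusted, per ``adjust``)
    p below ``alpha``.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    groups = meta.group_labels(table.samples)
    if groups.nunique() < 2:
        raise ValueError("differential analysis needs both cancer and non-cancer samples")
    cancer = [s for s in table.samples if groups[s] == "cancer"]
    control = [s for s in table.samples if groups[s] == "non_cancer"]
    rows = []
    for feat in table.features:
        xv = table.values.loc[feat, cancer].dropna().to_numpy(dtype=float)
        yv = table.values.loc[feat, control].dropna().to_numpy(dtype=float)
        if len(xv) < min_per_group or len(yv) < min_per_group:
            rows.append((feat, np.nan, np.nan, False))
            continue
        mx, my = float(xv.mean()), float(yv.mean())
        if mx == 0.0 or my == 0.0:
            mx, my = mx + 1.0, my + 1.0
        lfc = float(np.log2(mx / my))
        p = rank_sum_test(xv, yv)
        rows.append((feat, lfc, p, True))
    out = pd.DataFrame(rows, columns=["feature", "log2fc", "p", "tested"]).set_index("feature")
    tested = out["tested"] & out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    p_used = out["p_adj"] if adjust == "bh" else out["p"]
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.loc[~tested, "direction"] = ""
    out["significant"] = tested & (out["log2fc"].abs() > lfc_threshold) & (p_used < alpha)
    return out


# --- enrichment --------------------------------------------------------------

def fisher_exact_2x2(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a k-of-n vs K-of-N 2x2 table.

    The table is [[k, n-k], [K-k, (N-n)-(K-k)]]; returns (odds ratio, p).
    """
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def fisher_enrichment(
    foreground: Iterable,
    background: Iterable,
    category_map: Mapping | Callable[[object], Iterable],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of categories in a foreground set.

    For each category the 2x2 table over the background is (in/out of
    foreground) x (in/out of category); ``k`` of ``K`` category members are
    in the foreground of size ``n`` drawn from a background of ``N``.
    ``category_map`` maps a feature to its categories (a mapping or a
    callable; a scalar value is treated as one category).
    """
    fg, bg = set(foreground), set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")

    def cats(feature) -> set:
        val = category_map(feature) if callable(category_map) else category_map.get(feature)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return set()
        if isinstance(val, (str, bytes)) or not isinstance(val, Iterable):
            return {val}
        return set(val)

    members: dict[object, set] = {}
    for feat in bg:
        for c in cats(feat):
            members.setdefault(c, set()).add(feat)
    rows = []
    N, n = len(bg), len(fg)
    for cat in sorted(members, key=str):
        K = len(members[cat])
        k = len(members[cat] & fg)
        odds, p = fisher_exact_2x2(k, n, K, N)
        rows.append((cat, k, K, n, N, odds, p))
    out = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "odds_ratio", "p"])
    out["significant"] = out["p"] < alpha
    return out.set_index("category")


# --- species risk ------------------------------------------------------------

def species_risk(
    abundance: QuantTable,
    meta: CohortMetadata,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-species univariate logistic regression of cancer status.

    The predictor is the z-score of log2(intensity + 1) across samples
    (``standardize=False`` keeps the raw intensity column, e.g. for a
    binary presence/absence predictor).  Reports OR = exp(coefficient)
    with Wald 95% CI and Wald p.  Species whose fit fails to converge
    (e.g. quasi-separation) are flagged with ``converged=False`` and carry
    no estimate.
    """
    groups = meta.group_labels(abundance.samples)
    if groups.nunique() < 2:
        raise ValueError("risk regression needs both outcome classes")
    y = (groups == "cancer").astype(float).to_numpy()
    rows = []
    for taxon in abundance.features:
        x = abundance.values.loc[taxon].fillna(0.0).to_numpy(dtype=float)
        if standardize:
            x = np.log2(x + 1.0)
            sd = x.std(ddof=0)
            if sd == 0:
                rows.append((taxon, np.nan, np.nan, np.nan, np.nan, False))
                continue
            x = (x - x.mean()) / sd
        X = sm.add_constant(x)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta = fit.params[1]
            se = fit.bse[1]
            ok = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se) and se < 50
        except Exception:  # separation, singular matrix, ...
            ok = False
        if not ok:
            rows.append((taxon, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rows.append(
            (
                taxon,
                float(np.exp(beta)),
                float(np.exp(beta - 1.959963984540054 * se)),
                float(np.exp(beta + 1.959963984540054 * se)),
                float(fit.pvalues[1]),
                True,
            )
        )
    return pd.DataFrame(
        rows, columns=["taxon", "odds_ratio", "ci_low", "ci_high", "p", "converged"]
    ).set_index("taxon")


# --- host-microbe correlation ------------------------------------------------

def host_microbe_correlation(
    human_table: QuantTable, cog_table: QuantTable
) -> pd.DataFrame:
    """Spearman rho and p for every (human feature, COG) pair.

    Computed over the samples shared by the two tables (at least 3
    required), sorted by decreasing |rho|.
    """
    shared = [s for s in human_table.samples if s in set(cog_table.samples)]
    if len(shared) < 3:
        raise ValueError("host-microbe correlation needs at least 3 shared samples")
    rows = []
    for hf in human_table.features:
        hx = human_table.values.loc[hf, shared]
        for cf in cog_table.features:
            cy = cog_table.values.loc[cf, shared]
            mask = hx.notna() & cy.notna()
            if mask.sum() < 3:
                continue
            res = sps.spearmanr(hx[mask], cy[mask])
            rows.append((hf, cf, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["human_feature", "cog", "rho", "p"])
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index).reset_index(drop=True)
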