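import numpy as np
import pandas as pd
import pytest

from tonguecoat.quantify import QuantTable
from tonguecoat.simulate import GeneratorConfig, generate_cohort, generate_reference, simulate_intensities
from tonguecoat.stats import (
    differential_proteins,
    fisher_enrichment,
    host_microbe_correlation,
    rank_sum_test,
    species_risk,
    stability_summary,
)

from conftest import make_metadata, oracle_fisher_two_sided


def quant(values: dict, samples=None) -> QuantTable:
    return QuantTable(pd.DataFrame(values).T if samples is None else pd.DataFrame(values, index=samples).T)


class TestStability:
    def meta(self):
        samples = ["a", "b", "c"]
        df = pd.DataFrame(
            {
                "subject": ["u1", "u1", "u2"],
                "center": "time-series",
                "group": "non_cancer",
                "stage": "none",
                "timepoint": [0, 3, 0],
                "replicate": 1,
            },
            index=samples,
        )
        from tonguecoat.quantify import CohortMetadata

        return CohortMetadata(df)

    def test_identical_samples_correlate_perfectly(self):
        x = np.arange(10, dtype=float)
        table = QuantTable(pd.DataFrame({"a": x, "b": x, "c": x[::-1]}))
        out = stability_summary(table, self.meta()).set_index("stratum")
        assert out.at["intra_individual", "mean_rho"] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        x = np.arange(10, dtype=float)
        table = QuantTable(pd.DataFrame({"a": x, "b": x[::-1], "c": x}))
        out = stability_summary(table, self.meta()).set_index("stratum")
        assert out.at["intra_individual", "mean_rho"] == pytest.approx(-1.0)

    def test_subject_effects_push_intra_above_inter(self):
        """Subject-level random effects in the generator guarantee higher
        intra- than inter-individual correlation for microbial proteins."""
        config = GeneratorConfig(
            seed=21, n_phyla=2, genera_per_phylum=2, species_per_genus=2,
            proteins_per_species=8, human_proteins=10,
        )
        ref = generate_reference(config)
        meta = generate_cohort("time_series", 21)
        wins = 0
        for rep in range(20):
            c = GeneratorConfig(
                seed=500 + rep, n_phyla=2, genera_per_phylum=2, species_per_genus=2,
                proteins_per_species=8, human_proteins=10,
            )
            sim = simulate_intensities(ref, meta, c)
            origin = sim.protein_table.annotations["origin"]
            microbial = sim.protein_table.subset_features(
                sim.protein_table.values.index[origin == "microbial"]
            )
            out = stability_summary(microbial, meta, "microbial_protein").set_index("stratum")
            wins += (
                out.at["intra_individual", "mean_rho"]
                > out.at["inter_individual", "mean_rho"]
            )
        assert wins == 20


class TestRankSum:
    def test_exact_small_sample_p(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree_at_n20(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            x, y = rng.normal(size=10), rng.normal(size=10)
            exact = rank_sum_test(x, y, exact_max_n=20)
            approx = rank_sum_test(x, y, exact_max_n=0)
            assert abs(exact - approx) < 0.02


class TestDifferential:
    def test_null_feature_not_significant(self):
        samples = [f"s{i}" for i in range(12)]
        meta = make_metadata(6, 6, prefix="")
        vals = pd.DataFrame(
            [list(range(1, 7)) * 2], index=["f"], columns=meta.samples
        ).astype(float)
        out = differential_proteins(QuantTable(vals), meta)
        assert not out.at["f", "significant"]

    def test_planted_shift_detected(self):
        meta = make_metadata(10, 10, prefix="")
        rng = np.random.default_rng(23)
        base = rng.normal(10, 1, size=20)
        shifted = base.copy()
        shifted[:10] += 2  # 4-fold on the log2 scale feeding linear intensities
        vals = pd.DataFrame(
            {"f": np.power(2.0, shifted), "null": np.power(2.0, base)}, index=meta.samples
        ).T
        out = differential_proteins(QuantTable(vals), meta)
        assert out.at["f", "significant"]
        assert out.at["f", "direction"] == "up"

    def test_min_per_group_skips_and_reports(self):
        meta = make_metadata(4, 4, prefix="")
        vals = pd.DataFrame(
            {s: [1.0] for s in meta.samples}, index=["f"]
        )
        vals.loc["f", meta.samples[:2]] = np.nan
        out = differential_proteins(QuantTable(vals), meta)
        assert not out.at["f", "tested"]

    def test_single_group_raises(self):
        meta = make_metadata(6, 0, prefix="")
        vals = pd.DataFrame({s: [1.0] for s in meta.samples}, index=["f"])
        with pytest.raises(ValueError):
            differential_proteins(QuantTable(vals), meta)

    def test_bh_adjustment_bounds_and_order(self):
        meta = make_metadata(8, 8, prefix="")
        rng = np.random.default_rng(24)
        vals = pd.DataFrame(
            rng.lognormal(3, 1, size=(40, 16)),
            index=[f"f{i}" for i in range(40)],
            columns=meta.samples,
        )
        out = differential_proteins(QuantTable(vals), meta, adjust="bh")
        tested = out[out["tested"]]
        assert (tested["p_adj"] >= tested["p"] - 1e-12).all()
        assert (tested["p_adj"] <= 1.0).all()
        by_p = tested.sort_values("p")
        assert by_p["p_adj"].is_monotonic_increasing


class TestFisher:
    def test_no_enrichment_gives_unit_odds(self):
        bg = set(range(40))
        fg = set(range(10))
        # category holds 2 of 10 foreground and 6 of 30 background-only
        members = {0, 4} | set(range(10, 16))
        cmap = {f: "c1" if f in members else "c2" for f in bg}
        out = fisher_enrichment(fg, bg, cmap)
        assert out.at["c1", "odds_ratio"] == pytest.approx(1.0)
        assert out.at["c1", "p"] == pytest.approx(1.0)

    def test_extreme_table_minimal_p(self):
        bg = set(range(20))
        fg = set(range(10))
        cmap = {f: "hit" if f < 10 else "other" for f in bg}
        out = fisher_enrichment(fg, bg, cmap)
        assert out.at["hit", "p"] == pytest.approx(oracle_fisher_two_sided(10, 10, 10, 20))

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            fisher_enrichment({1, 99}, {1, 2}, {1: "a", 2: "a"})

    def test_random_tables_match_hypergeometric_oracle(self):
        rng = np.random.default_rng(25)
        for _ in range(60):
            N = int(rng.integers(4, 15))
            n = int(rng.integers(1, N))
            K = int(rng.integers(1, N))
            bg = set(range(N))
            fg = set(range(n))
            members = set(rng.choice(sorted(bg), size=K, replace=False))
            cmap = {f: "cat" if f in members else "rest" for f in bg}
            out = fisher_enrichment(fg, bg, cmap)
            k = len(members & fg)
            assert out.at["cat", "p"] == pytest.approx(
                oracle_fisher_two_sided(k, n, K, N), abs=1e-9
            )


class TestSpeciesRisk:
    def test_binary_predictor_matches_cross_product_odds(self):
        meta = make_metadata(100, 100, prefix="")
        x = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        table = QuantTable(pd.DataFrame([x], index=["sp"], columns=meta.samples))
        out = species_risk(table, meta, standardize=False)
        assert out.at["sp", "odds_ratio"] == pytest.approx((20 * 90) / (80 * 10), rel=1e-4)

    def test_null_species_ci_contains_one(self):
        meta = make_metadata(100, 100, prefix="")
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(10, 1, size=200)
            table = QuantTable(pd.DataFrame([x], index=["sp"], columns=meta.samples))
            out = species_risk(table, meta)
            hits += out.at["sp", "ci_low"] <= 1.0 <= out.at["sp", "ci_high"]
        assert hits >= 18

    def test_constant_species_flagged_unconverged(self):
        meta = make_metadata(5, 5, prefix="")
        table = QuantTable(pd.DataFrame([np.ones(10)], index=["sp"], columns=meta.samples))
        out = species_risk(table, meta)
        assert not out.at["sp", "converged"]


class TestHostMicrobeCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        samples = [f"s{i}" for i in range(8)]
        x = np.arange(1.0, 9.0)
        human = QuantTable(pd.DataFrame([x], index=["KRT2"], columns=samples))
        cogs = QuantTable(pd.DataFrame([2 * x], index=["COG1136"], columns=samples))
        out = host_microbe_correlation(human, cogs)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(26)
        samples = [f"s{i}" for i in range(40)]
        krt = rng.lognormal(3, 1, size=40)
        human = QuantTable(pd.DataFrame([krt], index=["KRT9"], columns=samples))
        cog_rows = {f"COG{i}": rng.lognormal(3, 1, size=40) for i in range(20)}
        cog_rows["COG1136"] = krt * rng.lognormal(0, 0.05, size=40)  # tightly coupled
        cogs = QuantTable(pd.DataFrame(cog_rows, index=samples).T)
        out = host_microbe_correlation(human, cogs)
        assert out.loc[0, "cog"] == "COG1136"

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(27)
        samples = [f"s{i}" for i in range(30)]
        human = QuantTable(
            pd.DataFrame(rng.normal(size=(10, 30)) ** 2, index=[f"h{i}" for i in range(10)], columns=samples)
        )
        cogs = QuantTable(
            pd.DataFrame(rng.normal(size=(10, 30)) ** 2, index=[f"c{i}" for i in range(10)], columns=samples)
        )
        out = host_microbe_correlation(human, cogs)
        frac = (out["p"] < 0.05).mean()
        assert 0.0 <= frac <= 0.12

    def test_no_shared_samples_raises(self):
        a = QuantTable(pd.DataFrame({"s1": [1.0]}, index=["h"]))
        b = QuantTable(pd.DataFrame({"t1": [1.0]}, index=["c"]))
        with pytest.raises(ValueError):
            host_microbe_correlation(a, b)


def test_pairwise_spearman_invariant_to_monotone_transforms():
    from tonguecoat.stats import pairwise_spearman

    rng = np.random.default_rng(28)
    vals = pd.DataFrame(
        rng.lognormal(2, 1, size=(25, 3)), index=[f"f{i}" for i in range(25)], columns=list("abc")
    )
    base, _ = pairwise_spearman(QuantTable(vals))
    transformed = vals.copy()
    transformed["a"] = np.exp(transformed["a"] / transformed["a"].max())  # strictly increasing
    transformed["b"] = transformed["b"] ** 3
    again, _ = pairwise_spearman(QuantTable(transformed))
    assert np.allclose(base["rho"], again["rho"])
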