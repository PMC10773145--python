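import numpy as np
import pandas as pd
import pytest

from tonguecoat.model import (
    ModelConfig,
    embedding_diagnostics,
    rank_features,
    split_cohort,
    train_and_evaluate,
)
from tonguecoat.quantify import CohortMetadata, QuantTable

from conftest import make_metadata


def random_table(rng, n_features, samples, label_feature=None, labels=None):
    vals = rng.lognormal(8, 1, size=(n_features, len(samples)))
    idx = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(vals, index=idx, columns=samples)
    if label_feature is not None:
        df.loc[label_feature] = np.where(labels, 4000.0, 10.0)
    return QuantTable(df)


class TestSplit:
    def test_exact_arithmetic(self):
        meta = make_metadata(8, 8)
        train, test = split_cohort(meta, 0.75, seed=1)
        groups = meta.df["group"]
        assert len(train) == 12 and len(test) == 4
        assert sum(groups[s] == "cancer" for s in train) == 6
        assert set(train) | set(test) == set(meta.samples)
        assert set(train) & set(test) == set()

    def test_deterministic(self):
        meta = make_metadata(20, 20)
        assert split_cohort(meta, 0.75, seed=7) == split_cohort(meta, 0.75, seed=7)
        assert split_cohort(meta, 0.75, seed=7) != split_cohort(meta, 0.75, seed=8)

    def test_233_samples_at_three_to_one(self):
        meta = make_metadata(120, 113)
        train, test = split_cohort(meta, 0.75, seed=2)
        assert abs(len(train) - 175) <= 2 and abs(len(test) - 58) <= 2
        groups = meta.df["group"]
        assert abs(sum(groups[s] == "cancer" for s in train) - 90) <= 1
        assert abs(sum(groups[s] == "non_cancer" for s in train) - 85) <= 1

    def test_tiny_class_raises(self):
        meta = make_metadata(1, 10)
        with pytest.raises(ValueError):
            split_cohort(meta, 0.75, seed=0)


class TestRankFeatures:
    def test_perfect_predictor_ranks_first(self):
        rng = np.random.default_rng(30)
        meta = make_metadata(20, 20)
        labels = [meta.df.at[s, "group"] == "cancer" for s in meta.samples]
        table = random_table(rng, 30, meta.samples, "f0", labels)
        config = ModelConfig(seed=0, cv_folds=0)
        ranking = rank_features(table, meta, config)
        assert ranking.index[0] == "f0"
        assert ranking["influence"].iloc[0] > 50
        assert ranking["influence"].sum() == pytest.approx(100.0)

    def test_pure_noise_contract(self):
        meta = make_metadata(15, 15)
        overlaps = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            table = random_table(rng, 60, meta.samples)
            ranking = rank_features(table, meta, ModelConfig(seed=seed, cv_folds=0))
            overlaps.append(set(ranking.index[:50]))
        assert len(overlaps[0] & overlaps[1]) >= 0  # no crash, report computable

    def test_nonfinite_rejected(self):
        meta = make_metadata(12, 12)
        # infinities cannot occur in a QuantTable, so corrupt the values after
        rng = np.random.default_rng(31)
        table = random_table(rng, 5, meta.samples)
        table.values.iloc[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            rank_features(table, meta, ModelConfig(cv_folds=0))

    def test_cv_requires_enough_samples(self):
        meta = make_metadata(5, 5)
        rng = np.random.default_rng(32)
        table = random_table(rng, 5, meta.samples)
        with pytest.raises(ValueError, match="cv_folds"):
            rank_features(table, meta, ModelConfig(cv_folds=10))

    def test_selection_ignores_test_samples(self):
        """Feature ranking is a function of the training samples only."""
        rng = np.random.default_rng(33)
        meta = make_metadata(20, 20)
        table = random_table(rng, 40, meta.samples)
        train, test = split_cohort(meta, 0.75, seed=0)
        config = ModelConfig(seed=0, cv_folds=0)
        r1 = rank_features(table.subset_samples(train), meta.subset(train), config)
        perturbed = QuantTable(table.values.copy(), table.annotations.copy())
        perturbed.values[test] = perturbed.values[test] * 100.0
        r2 = rank_features(perturbed.subset_samples(train), meta.subset(train), config)
        assert list(r1.index) == list(r2.index)


class TestTrainAndEvaluate:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(34)
        meta = make_metadata(20, 20)
        labels = [meta.df.at[s, "group"] == "cancer" for s in meta.samples]
        table = random_table(rng, 10, meta.samples, "f0", labels)
        config = ModelConfig(seed=0, cv_folds=0, top_k=3)
        _, reports = train_and_evaluate(
            table, meta, ["f0", "f1", "f2"], {"train": (table, meta)}, config
        )
        assert reports["train"].auc == pytest.approx(1.0)
        assert reports["train"].accuracy == pytest.approx(1.0)
        lo, hi = reports["train"].accuracy_ci
        assert lo <= reports["train"].accuracy <= hi

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(35)
        meta = make_metadata(100, 100)
        table = random_table(rng, 20, meta.samples)
        config = ModelConfig(seed=0, cv_folds=0)
        aucs = []
        for seed in range(20):
            pdf = meta.df.copy()
            pdf["group"] = np.random.default_rng(seed).permutation(pdf["group"].to_numpy())
            _, reports = train_and_evaluate(
                table, meta, [f"f{i}" for i in range(20)],
                {"perm": (table, CohortMetadata(pdf))}, config,
            )
            aucs.append(reports["perm"].auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_missing_feature_is_schema_error(self):
        rng = np.random.default_rng(36)
        meta = make_metadata(10, 10)
        table = random_table(rng, 5, meta.samples)
        with pytest.raises(KeyError, match="ghost"):
            train_and_evaluate(
                table, meta, ["f0", "ghost"], {}, ModelConfig(cv_folds=0)
            )

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(37)
        meta = make_metadata(15, 15)
        table = random_table(rng, 8, meta.samples)
        _, reports = train_and_evaluate(
            table, meta, [f"f{i}" for i in range(8)], {"train": (table, meta)},
            ModelConfig(cv_folds=0),
        )
        assert sum(reports["train"].confusion.values()) == reports["train"].n


class TestEmbedding:
    def meta_with_stages(self, n=12):
        samples = [f"s{i}" for i in range(n)]
        stages = (["none"] * 3 + ["gastritis"] * 3 + ["I", "II"] + ["III", "IV"] * 2)[:n]
        groups = ["non_cancer" if st in ("none", "gastritis") else "cancer" for st in stages]
        df = pd.DataFrame(
            {
                "subject": samples, "center": "ZJC", "group": groups,
                "stage": stages, "timepoint": 0, "replicate": 1,
            },
            index=samples,
        )
        return CohortMetadata(df)

    def test_metric_axioms_small_sample(self):
        rng = np.random.default_rng(38)
        meta = self.meta_with_stages(3)
        table = random_table(rng, 6, meta.samples)
        coords, dist, _ = embedding_diagnostics(table, meta, seed=0)
        assert dist.shape == (3, 3)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)
        assert coords.shape == (3, 2)

    def test_duplicated_sample_at_zero_distance(self):
        rng = np.random.default_rng(39)
        meta = self.meta_with_stages(4)
        table = random_table(rng, 6, meta.samples)
        table.values["s1"] = table.values["s0"]
        _, dist, _ = embedding_diagnostics(table, meta, seed=0)
        assert dist.at["s0", "s1"] == pytest.approx(0.0)

    def test_constant_features_degenerate(self):
        meta = self.meta_with_stages(4)
        table = QuantTable(pd.DataFrame(1.0, index=["f0", "f1"], columns=meta.samples))
        with pytest.raises(ValueError, match="constant"):
            embedding_diagnostics(table, meta, seed=0)

    def test_displaced_stage_farther_than_gastritis(self):
        """Cancer stages shifted away from controls show larger control
        distances than the mildly shifted gastritis stratum."""
        rng = np.random.default_rng(40)
        meta = self.meta_with_stages(12)
        table = random_table(rng, 20, meta.samples)
        stage = meta.df["stage"]
        shift = {"none": 0.0, "gastritis": 0.5, "I": 3.0, "II": 3.0, "III": 4.0, "IV": 4.0}
        for s in meta.samples:
            table.values[s] *= 2.0 ** shift[str(stage[s])]
        _, _, gd = embedding_diagnostics(table, meta, seed=0)
        assert gd["control_vs_stage_III_IV"] > gd["control_vs_gastritis"]
        assert gd["control_vs_stage_I_II"] > gd["control_vs_gastritis"]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(41)
        meta = self.meta_with_stages(10)
        table = random_table(rng, 10, meta.samples)
        c1, d1, _ = embedding_diagnostics(table, meta, seed=3)
        c2, d2, _ = embedding_diagnostics(table, meta, seed=3)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(d1, d2)
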