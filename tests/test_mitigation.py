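"""The five mitigation techniques: worked examples, independence and
fixed-point properties, brute-force threshold oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from fairdep import (
    Cohort,
    GroupScoreSpec,
    ScoreSetConfig,
    ScoredPredictions,
    cpp_apply,
    cpp_fit,
    dir_apply,
    dir_fit,
    generate_scored_population,
    psta_apply,
    psta_fit,
    reweigh,
    suppress,
)
from fairdep.errors import UndefinedMetricError, UnsupportedFeatureError


def make_cohort(groups, labels, features=None):
    n = len(groups)
    return Cohort(
        ids=pd.RangeIndex(n),
        protected=pd.DataFrame({"g": list(groups)}),
        features=features if features is not None
        else pd.DataFrame({"x": np.zeros(n)}),
        labels=np.asarray(labels),
    )


class TestSuppress:
    def test_removes_feature_column_keeps_evaluation_groups(self):
        n = 6
        cohort = Cohort(
            ids=pd.RangeIndex(n),
            protected=pd.DataFrame({"sex": ["m", "f"] * 3, "age": ["y", "o"] * 3}),
            features=pd.DataFrame({"sex": ["m", "f"] * 3, "x": np.ones(n)}),
            labels=np.array([0, 1] * 3),
        )
        out = suppress(cohort, "sex")
        assert "sex" not in out.features.columns
        assert "sex" in out.protected.columns  # evaluation partition survives
        assert "age" in out.protected.columns

    def test_suppress_all_protected(self):
        cohort = make_cohort("abab", [0, 1, 0, 1])
        out = suppress(cohort, ["g"])
        assert list(out.features.columns) == ["x"]

    def test_idempotent(self):
        cohort = make_cohort("abab", [0, 1, 0, 1])
        once = suppress(cohort, "g")
        twice = suppress(once, "g")
        pd.testing.assert_frame_equal(once.features, twice.features)

    def test_unknown_attribute_key_error(self):
        with pytest.raises(KeyError):
            suppress(make_cohort("ab", [0, 1]), "income")


class TestReweigh:
    def test_independent_attribute_gives_unit_weights(self):
        # same prevalence 0.5 in both groups -> X and C independent
        groups = ["a"] * 4 + ["b"] * 8
        labels = [0, 0, 1, 1] + [0] * 4 + [1] * 4
        w = reweigh(make_cohort(groups, labels), "g")
        np.testing.assert_allclose(w.weights, 1.0)

    def test_worked_example(self):
        # A: 30 pos / 70 neg, B: 10 pos / 90 neg; overall prevalence 0.2
        groups = ["A"] * 100 + ["B"] * 100
        labels = [1] * 30 + [0] * 70 + [1] * 10 + [0] * 90
        w = reweigh(make_cohort(groups, labels), "g")
        assert w.cell_weights[("A", 1)] == pytest.approx(2 / 3)
        assert w.cell_weights[("A", 0)] == pytest.approx(8 / 7)
        assert w.cell_weights[("B", 1)] == pytest.approx(2.0)
        assert w.cell_weights[("B", 0)] == pytest.approx(8 / 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_table_factorizes_and_mass_is_preserved(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        cells = rng.integers(1, 50, size=(k, 2))
        groups, labels = [], []
        for g in range(k):
            for c in (0, 1):
                groups += [f"g{g}"] * cells[g, c]
                labels += [c] * cells[g, c]
        cohort = make_cohort(groups, labels)
        w = reweigh(cohort, "g")
        assert w.weights.sum() == pytest.approx(cohort.n, rel=1e-12)
        # weighted joint equals product of weighted marginals
        df = pd.DataFrame(
            {"g": groups, "c": labels, "w": w.weights}
        )
        total = df["w"].sum()
        joint = df.groupby(["g", "c"])["w"].sum() / total
        pg = df.groupby("g")["w"].sum() / total
        pc = df.groupby("c")["w"].sum() / total
        for (g, c), p in joint.items():
            assert p == pytest.approx(pg[g] * pc[c], abs=1e-10)


class TestDir:
    def gaussian_cohort(self, locs, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.concatenate([[g] * n for g in locs])
        vals = np.concatenate([rng.normal(loc, 1, n) for loc in locs.values()])
        return make_cohort(
            groups, rng.integers(0, 2, len(groups)),
            features=pd.DataFrame({"f": vals}),
        )

    def test_lambda_zero_is_identity(self):
        cohort = self.gaussian_cohort({"a": 0.0, "b": 2.0}, n=200)
        model = dir_fit(cohort, "g", lam=0.0)
        out = dir_apply(model, cohort)
        np.testing.assert_array_equal(
            out.features["f"].to_numpy(), cohort.features["f"].to_numpy()
        )

    def test_identical_distributions_near_fixed_point(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 1000)
        cohort = make_cohort(
            ["a"] * 1000 + ["b"] * 1000, rng.integers(0, 2, 2000),
            features=pd.DataFrame({"f": np.r_[vals, vals]}),
        )
        model = dir_fit(cohort, "g", lam=1.0)
        out = dir_apply(model, cohort)
        # identical group distributions: repair is identity up to quantile
        # discretization (interpolation between adjacent order statistics)
        diff = np.abs(out.features["f"].to_numpy() - cohort.features["f"].to_numpy())
        assert np.quantile(diff, 0.95) < 0.05
        assert ks_2samp(out.features["f"], cohort.features["f"]).statistic < 0.01

    def test_full_repair_equalizes_shifted_gaussians(self):
        cohort = self.gaussian_cohort({"a": 0.0, "b": 2.0}, n=5000, seed=2)
        model = dir_fit(cohort, "g", lam=1.0)
        out = dir_apply(model, cohort)
        f = out.features["f"].to_numpy()
        ga = cohort.protected["g"] == "a"
        ks = ks_2samp(f[ga], f[~ga]).statistic
        assert ks < 0.05

    def test_partial_repair_interpolates(self):
        cohort = self.gaussian_cohort({"a": 0.0, "b": 2.0}, n=2000, seed=3)
        full = dir_apply(dir_fit(cohort, "g", lam=1.0), cohort).features["f"]
        half = dir_apply(dir_fit(cohort, "g", lam=0.5), cohort).features["f"]
        orig = cohort.features["f"]
        np.testing.assert_allclose(half, 0.5 * orig + 0.5 * full, atol=1e-10)

    def test_categorical_feature_rejected(self):
        cohort = make_cohort(
            "abab", [0, 1, 0, 1],
            features=pd.DataFrame({"site": ["x", "y", "x", "y"]}),
        )
        with pytest.raises(UnsupportedFeatureError):
            dir_fit(cohort, "g", features=["site"])

    def test_invalid_lambda_rejected(self):
        cohort = self.gaussian_cohort({"a": 0.0, "b": 1.0}, n=50)
        with pytest.raises(ValueError):
            dir_fit(cohort, "g", lam=1.5)


def unequal_cost_population(seed=0, n_pos=3000, n_neg=7000):
    return generate_scored_population(
        ScoreSetConfig(
            groups={
                "female": GroupScoreSpec(n_pos=n_pos, n_neg=n_neg,
                                         pos_loc=0.70, neg_loc=0.35),
                "male": GroupScoreSpec(n_pos=n_pos, n_neg=n_neg,
                                       pos_loc=0.55, neg_loc=0.25),
            },
            seed=seed,
        )
    )


def generalized_fnr(pred, group):
    mask = (pred.group == group) & (pred.labels == 1)
    return (1 - pred.scores[mask]).mean()


class TestCpp:
    def test_equal_costs_pass_through(self):
        spec = GroupScoreSpec(n_pos=500, n_neg=500)
        cfg = ScoreSetConfig(groups={"a": spec, "b": spec}, seed=1)
        pred = generate_scored_population(cfg)
        # force exactly equal costs by mirroring scores across groups
        half = pred.n // 2
        scores = pred.scores.copy()
        scores[half:] = scores[:half]
        labels = pred.labels.copy()
        labels[half:] = labels[:half]
        pred = ScoredPredictions.from_scores(scores, labels, pred.group)
        policy = cpp_fit(pred, seed=3)
        assert all(a == 0 for a in policy.alphas.values())
        out = cpp_apply(policy, pred)
        np.testing.assert_array_equal(out.scores, pred.scores)

    def test_alpha_matches_closed_form(self):
        pred = unequal_cost_population(seed=2)
        policy = cpp_fit(pred, seed=0)
        g = {x: generalized_fnr(pred, x) for x in ("female", "male")}
        hi, lo = max(g, key=g.get), min(g, key=g.get)
        base_rate_lo = pred.labels[pred.group == lo].mean()
        expected = (g[hi] - g[lo]) / ((1 - base_rate_lo) - g[lo])
        assert policy.alphas[hi] == 0.0
        assert policy.alphas[lo] == pytest.approx(expected, abs=1e-12)
        assert 0 <= policy.alphas[lo] <= 1

    def test_post_mix_costs_equalized(self):
        pred = unequal_cost_population(seed=4, n_pos=6000, n_neg=14000)
        policy = cpp_fit(pred, seed=7)
        out = cpp_apply(policy, pred)
        g_f = generalized_fnr(out, "female")
        g_m = generalized_fnr(out, "male")
        assert abs(g_f - g_m) < 0.01

    def test_group_without_positives_raises(self):
        pred = ScoredPredictions.from_scores(
            scores=[0.2, 0.8, 0.3, 0.4],
            labels=[0, 1, 0, 0],
            group=["a", "a", "b", "b"],
        )
        with pytest.raises(UndefinedMetricError):
            cpp_fit(pred)


def shifted_population(seed=0, n=10000):
    """Male scores location-shifted down: male group is under-detected at 0.5."""
    return generate_scored_population(
        ScoreSetConfig(
            groups={
                "female": GroupScoreSpec(n_pos=n // 5, n_neg=4 * n // 5,
                                         pos_loc=0.65, neg_loc=0.35),
                "male": GroupScoreSpec(n_pos=n // 5, n_neg=4 * n // 5,
                                       pos_loc=0.50, neg_loc=0.20),
            },
            seed=seed,
        )
    )


def brute_force_psta_threshold(pred, group, t0=0.5, delta=0.10):
    """Independent exhaustive-grid search over observed positive scores."""
    y, s, g = pred.labels, pred.scores, pred.group
    s_star = (s[y == 1] >= t0).mean()
    f_star = (s[y == 0] >= t0).mean()
    pos = s[(g == group) & (y == 1)]
    neg = s[(g == group) & (y == 0)]
    cands = sorted(set(list(pos[(pos <= t0) & (pos > 0)]) + [t0]), reverse=True)
    feasible = [
        t for t in cands
        if (pos >= t).mean() >= s_star and (neg >= t).mean() <= f_star + delta
    ]
    if feasible:
        return max(feasible)
    capped = [t for t in cands if (neg >= t).mean() <= f_star + delta]
    return max(capped, key=lambda t: ((pos >= t).mean(), t))


class TestPsta:
    def test_single_group_keeps_t0(self):
        pred = ScoredPredictions.from_scores(
            [0.2, 0.7, 0.4, 0.9], [0, 1, 0, 1], ["a"] * 4
        )
        policy = psta_fit(pred)
        assert policy.thresholds == {"a": 0.5}

    def test_all_privileged_returns_all_t0(self):
        # mirror one group's scores into the other so every group's
        # sensitivity exactly equals the overall sensitivity
        spec = GroupScoreSpec(n_pos=500, n_neg=500)
        base = generate_scored_population(
            ScoreSetConfig(groups={"a": spec}, seed=5)
        )
        pred = ScoredPredictions.from_scores(
            np.r_[base.scores, base.scores],
            np.r_[base.labels, base.labels],
            np.r_[np.full(base.n, "a", dtype=object), np.full(base.n, "b", dtype=object)],
        )
        policy = psta_fit(pred)
        assert policy.thresholds == {"a": 0.5, "b": 0.5}

    def test_shifted_group_matches_brute_force_and_reaches_sensitivity(self):
        pred = shifted_population(seed=6)
        policy = psta_fit(pred, t0=0.5, delta=0.10)
        assert policy.thresholds["female"] == 0.5
        t_male = policy.thresholds["male"]
        assert t_male < 0.5
        assert t_male == pytest.approx(
            brute_force_psta_threshold(pred, "male"), abs=1e-12
        )
        pos = pred.scores[(pred.group == "male") & (pred.labels == 1)]
        assert (pos >= t_male).mean() >= policy.overall_sensitivity

    def test_fit_invariant_to_sample_order(self):
        pred = shifted_population(seed=8, n=2000)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pred.n)
        policy_a = psta_fit(pred)
        policy_b = psta_fit(pred.subset(perm))
        assert policy_a.thresholds == policy_b.thresholds

    def test_group_without_positives_untreated_with_warning(self):
        pred = ScoredPredictions.from_scores(
            [0.9, 0.8, 0.2, 0.3, 0.4, 0.45],
            [1, 1, 0, 0, 0, 0],
            ["a", "a", "a", "b", "b", "b"],
        )
        with pytest.warns(UserWarning, match="no positive"):
            policy = psta_fit(pred)
        assert policy.thresholds["b"] == 0.5

    def test_apply_matches_plain_thresholding_at_t0(self):
        pred = shifted_population(seed=9, n=1000)
        policy = psta_fit(pred)
        policy.thresholds = {g: 0.5 for g in policy.thresholds}
        out = psta_apply(policy, pred)
        np.testing.assert_array_equal(out.predictions, (pred.scores >= 0.5))

    @pytest.mark.parametrize("seed", range(3))
    def test_lowering_threshold_is_monotone_in_rates(self, seed):
        pred = shifted_population(seed=seed, n=1000)
        policy_hi = psta_fit(pred)
        t_m = policy_hi.thresholds["male"]
        lower = {"male": max(t_m - 0.1, 0.01), "female": 0.5}
        policy_lo = psta_fit(pred)
        policy_lo.thresholds = lower
        hi_out = psta_apply(policy_hi, pred)
        lo_out = psta_apply(policy_lo, pred)
        m = pred.group == "male"
        y = pred.labels
        tpr_hi = hi_out.predictions[m & (y == 1)].mean()
        tpr_lo = lo_out.predictions[m & (y == 1)].mean()
        fpr_hi = hi_out.predictions[m & (y == 0)].mean()
        fpr_lo = lo_out.predictions[m & (y == 0)].mean()
        assert tpr_lo >= tpr_hi
        assert fpr_lo >= fpr_hi

    def test_unseen_group_falls_back_to_t0(self):
        pred = shifted_population(seed=10, n=500)
        policy = psta_fit(pred)
        new = ScoredPredictions.from_scores([0.6, 0.4], [1, 0], ["other", "other"])
        with pytest.warns(UserWarning, match="unseen"):
            out = psta_apply(policy, new)
        np.testing.assert_array_equal(out.predictions, [1, 0])

    def test_scores_unchanged_by_apply(self):
        pred = shifted_population(seed=11, n=500)
        out = psta_apply(psta_fit(pred), pred)
        np.testing.assert_array_equal(out.scores, pred.scores)
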