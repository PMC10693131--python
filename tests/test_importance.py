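"""Permutation importance and the joint-shuffle interaction statistic."""

import numpy as np
import pandas as pd
import pytest

from asthmacast.columns import INPUT_COLUMNS
from asthmacast.importance import (
    ImportanceRecord,
    InteractionRecord,
    _permutation,
    importance_report,
    interaction,
    permutation_importance,
)
from asthmacast.nets import HyperConfig, TrainSpec, build_model, predict, train
from asthmacast.preprocess import WindowSet, make_windows


def _table(n=150, seed=0):
    """Weekly-style table whose inputs are independent standard normals."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(INPUT_COLUMNS))), columns=INPUT_COLUMNS)
    df["year"] = 2015
    df["week_of_year"] = np.arange(1, n + 1)
    return df


def _oracle(expr, noise_seed=1, noise_sd=0.1):
    """predict_fn whose 'model' is an exact function of the raw table and
    whose observations add fixed noise (so the baseline MSE is nonzero)."""
    rng = np.random.default_rng(noise_seed)

    def fn(table):
        pred = expr(table)
        return fn.obs, pred

    fn.obs = None

    def init(table):
        fn.obs = expr(table) + rng.normal(0, noise_sd, len(table))

    fn.init = init
    return fn


class TestPermutationImportance:
    def test_identity_permutation_gives_zero(self, monkeypatch):
        import asthmacast.importance as imp

        monkeypatch.setattr(imp, "_permutation",
                            lambda seed, f, r, n: np.arange(n))
        t = _table()
        fn = _oracle(lambda d: d["pm10"].to_numpy())
        fn.init(t)
        rec = imp.permutation_importance(fn, t, "pm10", n_repeats=5, seed=0)
        assert rec.delta_mse == 0.0

    def test_ignored_feature_gives_exactly_zero(self):
        """A feature with all input weights zeroed has no path to the output;
        its importance must be exactly 0, not merely small."""
        t = _table(n=60)
        w = make_windows(t, target_column="co")
        m = build_model(HyperConfig("lstm", 4, 4, 3), n_features=22, seed=0)
        trained = train(m, w, w, TrainSpec(max_epochs=10, seed=0))
        j = INPUT_COLUMNS.index("pm10")
        trained.model.params["Wx"][j, :] = 0.0

        def fn(table):
            wn = make_windows(table, target_column="co")
            return w.y, predict(trained, wn)

        rec = permutation_importance(fn, t, "pm10", n_repeats=5, seed=0)
        assert rec.delta_mse == 0.0
        assert not rec.significant

    def test_matches_brute_force_with_shared_draws(self):
        """ΔMSE for the linear oracle y = x_A equals a direct recomputation
        using the same permutation draws."""
        t = _table(n=100, seed=2)
        fn = _oracle(lambda d: d["no2"].to_numpy(), noise_sd=0.2)
        fn.init(t)
        n_rep, seed = 8, 3
        rec = permutation_importance(fn, t, "no2", n_repeats=n_rep, seed=seed)

        obs, base_pred = fn(t)
        baseline = np.mean((obs - base_pred) ** 2)
        x = t["no2"].to_numpy()
        mses = []
        for r in range(n_rep):
            perm = _permutation(seed, "no2", r, len(t))
            mses.append(np.mean((obs - x[perm]) ** 2))
        assert rec.baseline_mse == pytest.approx(baseline, rel=1e-12)
        assert rec.delta_mse == pytest.approx(np.mean(mses) - baseline, rel=1e-12)

    def test_seed_contract_bit_identical(self):
        t = _table()
        fn = _oracle(lambda d: d["so2"].to_numpy())
        fn.init(t)
        a = permutation_importance(fn, t, "so2", n_repeats=6, seed=9)
        b = permutation_importance(fn, t, "so2", n_repeats=6, seed=9)
        assert a == b

    def test_unknown_feature_rejected(self):
        t = _table()
        fn = _oracle(lambda d: d["so2"].to_numpy())
        fn.init(t)
        with pytest.raises(ValueError, match="ozone_total"):
            permutation_importance(fn, t, "ozone_total", n_repeats=2, seed=0)


class TestInteraction:
    def test_additive_oracle_has_null_interaction(self):
        t = _table(n=250, seed=4)
        fn = _oracle(lambda d: d["pm10"].to_numpy() + d["no2"].to_numpy())
        fn.init(t)
        rec = interaction(fn, t, "pm10", "no2", n_repeats=50, seed=5)
        assert abs(rec.interaction) < 2 * rec.se_ab

    def test_multiplicative_oracle_redundancy_signature(self):
        """For a pure product of centered independent unit-variance features a
        single shuffle already destroys the prediction entirely, so FI_A =
        FI_B = FI_AB = 2 and I = -2: joint destruction is subadditive and the
        statistic flags redundancy, not synergy."""
        t = _table(n=600, seed=6)
        fn = _oracle(lambda d: d["pm10"].to_numpy() * d["no2"].to_numpy())
        fn.init(t)
        rec = interaction(fn, t, "pm10", "no2", n_repeats=50, seed=7)
        assert rec.interaction < -2 * rec.se_ab
        assert rec.interaction == pytest.approx(-2.0, abs=0.4)

    def test_correlated_features_give_positive_interaction(self):
        """A model leaning on two positively correlated features loses more
        than additively when both are shuffled: I -> 2*Cov(A, B) for a linear
        sum — the synergy signature."""
        rng = np.random.default_rng(12)
        t = _table(n=600, seed=13)
        z = rng.normal(size=600)
        t["pm10"] = z + 0.3 * rng.normal(size=600)
        t["no2"] = z + 0.3 * rng.normal(size=600)
        fn = _oracle(lambda d: d["pm10"].to_numpy() + d["no2"].to_numpy())
        fn.init(t)
        rec = interaction(fn, t, "pm10", "no2", n_repeats=50, seed=14)
        cov = float(np.cov(t["pm10"], t["no2"])[0, 1])
        assert rec.interaction > 2 * rec.se_ab
        assert rec.interaction == pytest.approx(2 * cov, rel=0.25)

    def test_direct_arithmetic(self):
        rec = InteractionRecord("a", "b", fi_a=2.0, fi_b=1.0, fi_ab=5.0,
                                se_ab=0.1, n_repeats=10, seed=0)
        assert rec.interaction == 2.0

    def test_same_feature_rejected(self):
        t = _table()
        fn = _oracle(lambda d: d["pm10"].to_numpy())
        fn.init(t)
        with pytest.raises(ValueError):
            interaction(fn, t, "pm10", "pm10", n_repeats=2, seed=0)

    def test_components_match_single_feature_importance(self):
        """FI_A inside the interaction equals the standalone record because
        the permutation draws are keyed by (seed, feature, repeat)."""
        t = _table(n=120, seed=8)
        fn = _oracle(lambda d: d["pm10"].to_numpy() - 2 * d["o3"].to_numpy())
        fn.init(t)
        rec = interaction(fn, t, "pm10", "o3", n_repeats=10, seed=11)
        solo = permutation_importance(fn, t, "pm10", n_repeats=10, seed=11)
        assert rec.fi_a == pytest.approx(solo.delta_mse, rel=1e-12)


class TestReport:
    def _rec(self, feature, delta, baseline=1.0):
        return ImportanceRecord(feature=feature, baseline_mse=baseline,
                                mean_shuffled_mse=baseline + delta,
                                delta_mse=delta, se=0.01, n_repeats=5, seed=0)

    def test_no_positive_delta_no_flags(self):
        rep = importance_report([self._rec("pm10", 0.0), self._rec("no2", -0.1)])
        assert not rep["importance"]["significant"].any()

    def test_single_positive_flagged_and_sorted(self):
        rep = importance_report(
            [self._rec("pm10", 0.0), self._rec("no2", 0.5), self._rec("co", -0.2)])
        imp = rep["importance"]
        assert list(imp["feature"]) == ["no2", "pm10", "co"]
        assert imp["significant"].sum() == 1
        assert imp.loc[imp["significant"], "feature"].tolist() == ["no2"]

    def test_interaction_matrix_symmetric(self):
        ints = [InteractionRecord("pm10", "no2", 1.0, 1.0, 3.0, 0.1, 5, 0),
                InteractionRecord("pm10", "co", 1.0, 0.5, 1.2, 0.1, 5, 0)]
        rep = importance_report([self._rec("pm10", 0.1)], ints)
        mat = rep["interaction_matrix"]
        assert mat.loc["pm10", "no2"] == mat.loc["no2", "pm10"] == 1.0
        assert mat.equals(mat.T)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            importance_report([])
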