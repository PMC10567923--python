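"""Cytokine normalization, screening, decomposition, and resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

import stresstraj as st
from stresstraj.biomarkers import inverse_normal_transform, partial_correlation

from conftest import make_prediction_data


def _panel(values: dict, batch=None, ids=None):
    n = len(next(iter(values.values())))
    df = pd.DataFrame(values)
    df.insert(0, "batch", batch if batch is not None else ["A"] * n)
    df.insert(0, "participant_id",
              ids if ids is not None else [f"s{i:03d}" for i in range(n)])
    return df


class TestPrepareCytokines:
    def test_inverse_normal_three_values(self):
        got = inverse_normal_transform(np.array([5.0, 1.0, 9.0]))
        want = stats.norm.ppf([1.5 / 3, 0.5 / 3, 2.5 / 3])
        assert np.allclose(got, want)
        assert got[0] == 0.0
        assert got[1] == -got[2]

    def test_missingness_boundary(self):
        n = 100
        a = np.arange(n, dtype=float)
        b = a.copy()
        a[:16] = np.nan   # exactly 16% -> retained
        b[:17] = np.nan   # over the ceiling -> dropped
        panel = _panel({"keep": a, "drop": b})
        out = st.prepare_cytokines(panel)
        assert out.dropped == ["drop"]
        assert list(out.values.columns) == ["keep"]
        assert int(out.n_imputed["keep"]) == 16

    def test_batch_offset_removed(self):
        rng = np.random.default_rng(0)
        n = 200
        batch = np.where(np.arange(n) % 2 == 0, "A", "B")
        x = rng.normal(0, 1, n) + np.where(batch == "B", 2.0, 0.0)
        out = st.prepare_cytokines(_panel({"m": x}, batch=batch))
        v = out.values["m"].to_numpy()
        diff = v[batch == "A"].mean() - v[batch == "B"].mean()
        assert abs(diff) < 1e-10

    def test_detection_limit_clipping(self):
        x = np.array([0.1, 1.0, 2.0, 3.0, 50.0])
        limits = pd.DataFrame({"marker": ["m"], "lower": [0.5],
                               "upper": [10.0]})
        out = st.prepare_cytokines(_panel({"m": x}), detection_limits=limits)
        assert int(out.n_censored_low["m"]) == 1
        assert int(out.n_censored_high["m"]) == 1
        # the censored-low value ties at the bottom rank after being set to 0
        assert out.values["m"].iloc[0] == out.values["m"].min()

    @settings(max_examples=25, deadline=None)
    @given(hst.lists(hst.integers(min_value=-2000, max_value=2000),
                     min_size=8, max_size=40, unique=True))
    def test_rank_transform_monotone_invariance(self, xs):
        x = np.array(xs, dtype=float) / 100.0
        assert np.allclose(inverse_normal_transform(x),
                           inverse_normal_transform(np.exp(x / 25.0)))
        assert np.allclose(inverse_normal_transform(x),
                           inverse_normal_transform(x ** 3))

    def test_transform_approximately_standard_normal(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(1.0, 1.0, 150)
        z = inverse_normal_transform(x)
        assert abs(z.mean()) < 0.1
        assert abs(z.std() - 1.0) < 0.15

    def test_all_dropped_is_an_error(self):
        x = np.full(10, np.nan)
        x[0] = 1.0
        with pytest.raises(ValueError, match="missingness"):
            st.prepare_cytokines(_panel({"m": x}))

    def test_custom_imputer_hook(self):
        x = np.arange(20, dtype=float)
        x[0] = np.nan
        called = {}

        def imputer(df):
            called["yes"] = True
            return df.fillna(99.0)

        out = st.prepare_cytokines(_panel({"m": x}), imputer=imputer)
        assert called and (out.values["m"] == 99.0).any()


class TestScreening:
    def test_planted_partial_correlation_selected(self):
        fm, part = make_prediction_data(n=148, p=4, seed=0)
        rng = np.random.default_rng(3)
        y = part["bmi"].to_numpy()
        z = (y - y.mean()) / y.std()
        eps = rng.standard_normal(148)
        eps -= z * np.dot(eps, z) / np.dot(z, z)  # exact sample corr 0.4
        eps /= eps.std()
        marker = 0.4 * z + np.sqrt(1 - 0.16) * eps
        panel = st.prepare_cytokines(_panel(
            {"hit": marker, "noise": rng.standard_normal(148)},
            ids=list(part.participant_id)))
        scr = st.screen_markers(panel, part).set_index("marker")
        assert bool(scr.loc["hit", "selected"])
        assert scr.loc["hit", "p"] < 1e-4

    def test_marker_equal_to_outcome_has_partial_r_one(self):
        fm, part = make_prediction_data(n=60, p=4, seed=1)
        panel = st.prepare_cytokines(
            _panel({"same": part["bmi"].to_numpy()},
                   ids=list(part.participant_id)))
        # bypass the normal transform: partial correlation is rank-invariant
        scr = st.screen_markers(panel, part).set_index("marker")
        assert scr.loc["same", "partial_r"] > 0.95
        assert bool(scr.loc["same", "selected"])

    def test_null_selection_rate_is_nominal(self):
        rng = np.random.default_rng(7)
        hits, total = 0, 0
        for _ in range(200):
            n = 60
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            Z = rng.standard_normal((n, 3))
            _r, p = partial_correlation(x, y, Z)
            hits += p < 0.05
            total += 1
        # 95% binomial interval around 0.05 with 200 trials
        assert 0.02 <= hits / total <= 0.08

    def test_partial_correlation_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 80
        df = pd.DataFrame(rng.standard_normal((n, 4)),
                          columns=["x", "y", "c1", "c2"])
        df["y"] += 0.5 * df["x"]
        r, p = partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(),
                                   df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)


class TestDecomposition:
    def _result(self, observed, predicted):
        cfg = st.PredictionConfig(seed=0)
        n = len(observed)
        return st.PredictionResult(
            [f"s{i}" for i in range(n)], np.asarray(observed, float),
            np.asarray(predicted, float), np.zeros(n),
            np.zeros(n, dtype=int), 0.0, 0.0, 0.0,
            pd.DataFrame(np.zeros((2, 1)), columns=["f"]), np.zeros(2), cfg)

    def test_subtraction_and_sum_identity(self):
        res = self._result([25.0, 30.0], [23.5, 31.0])
        comp = st.decompose_outcome(res)
        assert comp["residual"].tolist() == [1.5, -1.0]
        assert np.allclose(comp["predicted"] + comp["residual"],
                           comp["observed"])

    def test_null_model_residual_variance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(24, 4, 50)
        res = self._result(y, np.full(50, y.mean()))
        comp = st.decompose_outcome(res)
        assert comp["residual"].var() == pytest.approx(y.var(ddof=1))

    def test_marker_regression_terms(self):
        rng = np.random.default_rng(4)
        fm, part = make_prediction_data(n=100, p=4, seed=3)
        pred = rng.normal(0, 1, 100)
        comp = pd.DataFrame({"participant_id": part.participant_id,
                             "observed": pred + rng.normal(0, 1, 100),
                             "predicted": pred,
                             "residual": rng.normal(0, 1, 100)})
        marker = pred + 0.3 * rng.standard_normal(100)
        panel = st.prepare_cytokines(
            _panel({"m": marker}, ids=list(part.participant_id)))
        out = st.marker_component_regression(panel, comp, part)
        assert set(out.component) == {"observed", "predicted", "residual"}
        assert set(out.term) == {"marker", "sex", "marker:sex"}
        row = out[(out.marker == "m") & (out.component == "predicted")
                  & (out.term == "marker")].iloc[0]
        assert row.p < 1e-6


class TestResampling:
    def test_weights_nonnegative_and_normalized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(24, 2.8, 70)
        res = st.weighted_resample_match(x, (23.4, 4.6), seed=1,
                                         n_resamples=50)
        assert np.all(res.weights >= 0)
        assert res.weights.sum() == pytest.approx(1.0)

    def test_moment_matching_to_printed_female_moments(self):
        """Male outcomes reweighted to the female reference moments."""
        spec = st.CohortSpec(seed=31)
        p = st.simulate_participants(spec)
        males = p.loc[p.sex == "male", "bmi"].to_numpy()
        res = st.weighted_resample_match(males, (23.4, 4.6), seed=2,
                                         n_resamples=1000)
        assert abs(res.achieved_mean - 23.4) < 0.3
        assert abs(res.achieved_sd - 4.6) < 0.5

    def test_identity_reference_is_ordinary_bootstrap(self):
        rng = np.random.default_rng(3)
        x = rng.normal(24, 3, 60)
        res = st.weighted_resample_match(
            x, (float(x.mean()), float(x.std(ddof=1))), seed=4,
            n_resamples=50)
        assert np.allclose(res.weights, 1.0 / 60, atol=1e-8)

    def test_estimate_moves_monotonically_with_strength(self):
        """Importance-weighting oracle on a 10-point toy sample: the weighted
        mean moves from the group mean toward the reference mean as the
        tilting strength grows."""
        x = np.arange(10, dtype=float)
        ref = (7.0, float(x.std(ddof=1)))
        means = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            res = st.weighted_resample_match(x, ref, seed=5, n_resamples=400,
                                             strength=s)
            means.append(float(np.sum(res.weights * x)))
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(means, means[1:]))
        assert means[0] == pytest.approx(x.mean())
        assert means[-1] == pytest.approx(7.0, abs=1e-6)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.weighted_resample_match(np.full(10, 24.0), (23.4, 4.6))

    def test_group_wrapper(self):
        spec = st.CohortSpec(seed=33)
        p = st.simulate_participants(spec)
        res = st.resample_match_group(p, statistic=None, n_resamples=100,
                                      seed=6)
        f = p.loc[p.sex == "female", "bmi"]
        assert res.target_mean == pytest.approx(f.mean())
        lo, hi = res.percentile_interval
        assert lo <= res.estimate <= hi
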