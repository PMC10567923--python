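"""Edge hierarchical models, partial pooling, and feature aggregation."""

import numpy as np
import pandas as pd
import pytest

import stresstraj as st
from stresstraj.design import TIMEPOINTS
from stresstraj.features import (ACT_TERMS, FC_TERMS, EdgeEstimates,
                                 EdgeModelSpec, fit_edge_model)
from stresstraj.pooling import pool_term
from stresstraj.prep import SegmentTimeseries, match_offsets

TASK_BLOCKS = [f"block{b:02d}" for b in range(1, 16)]


class TestEdgeModel:
    def test_single_subject_estimates_equal_ols(self, toy_cohort, toy_concats):
        """With one subject the per-subject estimates are that subject's OLS
        coefficients; checked against an independent lstsq solve."""
        design = toy_cohort.design
        est = fit_edge_model(toy_concats[:1], ("roi01", "roi02"), design)
        concat = toy_concats[0]
        # independent design assembly
        ind = concat.timepoint_indicators()
        roi2 = concat.data["roi02"].to_numpy()
        roi2c = roi2 - roi2.mean()
        from stresstraj.features import convolved_event_regressor
        motor = convolved_event_regressor(design, "motor_response",
                                          concat.segment, concat.times)
        fb = convolved_event_regressor(design, "verbal_feedback",
                                       concat.segment, concat.times)
        X = np.column_stack([np.ones(len(roi2)), ind, roi2c,
                             ind * roi2c[:, None], motor, fb])
        beta, *_ = np.linalg.lstsq(X, concat.data["roi01"].to_numpy(),
                                   rcond=None)
        got = np.concatenate([est.activation.iloc[0].to_numpy(),
                              est.connectivity.iloc[0].to_numpy()])
        want = np.concatenate([beta[1:18], beta[19:36]])
        assert np.allclose(got, want, atol=1e-6)

    def test_noiseless_planted_block_effect_recovered(self, toy_atlas,
                                                      compact_design):
        spec = st.CohortSpec(n_female=2, n_male=2, seed=3, noise_sd=0.0,
                             drift_amp=0.0, nuisance_amp=0.0, between_sd=0.0,
                             between_sd_fc=0.0, intrinsic_sd=1e-3,
                             effect_activation={}, female_specific=False)
        p = st.simulate_participants(spec)
        truth = st.make_ground_truth(p, toy_atlas, compact_design, spec)
        truth.activation[:] = 0.0
        truth.activation[:, 0, 7] = 1.0
        truth.fc[:] = 0.0
        truth.fc_baseline[:] = 0.0
        ts = st.simulate_timeseries(p, truth, compact_design, spec)
        concats = []
        for sub in p.participant_id:
            segs = {s: SegmentTimeseries.from_table(
                sub, s, compact_design.segment(s).tr, ts.data[(sub, s)])
                for s in ("rest1", "task", "rest2")}
            concats.append(match_offsets(segs["rest1"], segs["task"],
                                         segs["rest2"], compact_design))
        est = fit_edge_model(concats, ("roi01", "roi02"), compact_design)
        assert est.fixed["act|block07"] == pytest.approx(1.0, abs=1e-3)
        assert abs(est.fixed["act|block06"]) < 1e-3

    def test_tau2_override_gives_no_pooling_limit(self, toy_cohort,
                                                  toy_concats):
        est = fit_edge_model(toy_concats, ("roi01", "roi03"),
                             toy_cohort.design, tau2_override=1e12)
        assert np.allclose(est.activation.to_numpy(),
                           est.ols_activation.to_numpy(), atol=1e-6)

    def test_shrinkage_variance_inequality(self, toy_edges):
        for est in toy_edges:
            v_pool = est.activation[TASK_BLOCKS].to_numpy().var(axis=0)
            v_ols = est.ols_activation[TASK_BLOCKS].to_numpy().var(axis=0)
            assert np.all(v_pool <= v_ols + 1e-10)

    def test_per_subject_estimates_average_to_fixed_effect(self, toy_edges):
        est = toy_edges[0]
        for term, col in zip(ACT_TERMS, TIMEPOINTS):
            mean_est = est.activation[col].mean()
            # precision weights are near-uniform on balanced synthetic data
            assert mean_est == pytest.approx(est.fixed[term], abs=0.05)


class TestPooling:
    def test_two_stage_reml_matches_mixedlm_oracle(self):
        """Independent oracle: statsmodels MixedLM (random intercept, REML) on
        a balanced problem agrees with per-term REML + BLUP pooling."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n_sub, n_obs = 30, 200
        b = rng.normal(0, 1.5, n_sub)
        y = 2.0 + b[:, None] + rng.normal(0, 1.0, (n_sub, n_obs))
        beta_i = y.mean(axis=1)
        v_i = y.var(axis=1, ddof=1) / n_obs
        res = pool_term(beta_i, v_i)
        md = sm.MixedLM(y.ravel(), np.ones((n_sub * n_obs, 1)),
                        groups=np.repeat(np.arange(n_sub), n_obs)).fit(reml=True)
        assert res.tau2 == pytest.approx(float(np.asarray(md.cov_re)[0, 0]),
                                         rel=0.02)
        assert res.fixed == pytest.approx(float(np.asarray(md.fe_params)[0]),
                                          abs=1e-3)
        blup = (float(np.asarray(md.fe_params)[0])
                + np.array([float(np.asarray(md.random_effects[g])[0])
                            for g in range(n_sub)]))
        assert np.abs(res.estimates - blup).max() < 0.01

    def test_zero_heterogeneity_fully_pools(self):
        rng = np.random.default_rng(1)
        beta = 3.0 + rng.normal(0, 0.01, 40)
        v = np.full(40, 1.0)  # sampling noise dwarfs spread -> tau2 ~ 0
        res = pool_term(beta, v)
        assert res.tau2 < 1e-3
        assert np.allclose(res.estimates, res.fixed, atol=1e-3)


class TestFitAllEdges:
    def test_edge_counts(self, toy_cohort, toy_concats, toy_edges):
        assert st.RoiAtlas.stress_network().n_edges == 210
        assert st.RoiAtlas.toy(3).n_edges == 3
        assert len(toy_edges) == toy_cohort.atlas.n_edges == 6

    def test_subject_order_invariance(self, toy_cohort, toy_concats):
        design = toy_cohort.design
        atlas = toy_cohort.atlas
        fwd = st.fit_all_edges(toy_concats, atlas, design)
        rev = st.fit_all_edges(list(reversed(toy_concats)), atlas, design)
        for a, b in zip(fwd, rev):
            pd.testing.assert_frame_equal(a.activation, b.activation)


def _constant_estimates(atlas, subjects, c_act, c_fc):
    out = []
    tp = list(TIMEPOINTS)
    for edge in atlas.edges():
        act = pd.DataFrame(c_act, index=subjects, columns=tp, dtype=float)
        fc = pd.DataFrame(c_fc, index=subjects, columns=tp, dtype=float)
        fixed = pd.Series(0.0, index=list(EdgeModelSpec(*edge).columns))
        tau2 = pd.Series(0.0, index=list(ACT_TERMS + FC_TERMS))
        out.append(EdgeEstimates(edge, tuple(subjects), act, fc, act.copy(),
                                 fc.copy(), fixed, tau2))
    return out


class TestAggregation:
    def test_feature_counts_toy(self, toy_cohort, toy_edges):
        atlas = toy_cohort.atlas
        act = st.aggregate_activation(toy_edges, atlas)
        fc = st.aggregate_connectivity(toy_edges, atlas)
        assert act.n_features == len(atlas.regions) * 15
        assert fc.n_features == len(atlas.subnetworks) * 17
        comb = st.assemble_feature_matrix(act, fc, "combined")
        assert comb.n_features == act.n_features + fc.n_features
        assert st.assemble_feature_matrix(act, fc, "activation").n_features \
            == act.n_features
        assert st.assemble_feature_matrix(act, fc, "fc").n_features \
            == fc.n_features

    def test_constant_estimates_average_to_constant(self, toy_atlas):
        edges = _constant_estimates(toy_atlas, ["a", "b"], 2.5, -1.0)
        act = st.aggregate_activation(edges, toy_atlas)
        fc = st.aggregate_connectivity(edges, toy_atlas)
        assert np.allclose(act.data.to_numpy(), 2.5)
        assert np.allclose(fc.data.to_numpy(), -1.0)

    def test_brute_force_averaging_oracle(self, toy_cohort, toy_edges):
        """Hand-computed average over dependent-ROI models, then over
        hemispheres, equals the matrix output."""
        atlas = toy_cohort.atlas
        act = st.aggregate_activation(toy_edges, atlas)
        region = atlas.regions[0]
        rois = atlas.rois_of_region(region)
        per_roi = []
        for roi in rois:
            mats = [e.activation[TASK_BLOCKS].to_numpy()
                    for e in toy_edges if e.edge[0] == roi]
            if mats:
                per_roi.append(np.mean(mats, axis=0))
        want = np.mean(per_roi, axis=0)
        got = act.data[[f"act|{region}|{b}" for b in TASK_BLOCKS]].to_numpy()
        assert np.allclose(got, want, atol=1e-12)

    def test_aggregation_linearity(self, toy_atlas):
        rng = np.random.default_rng(5)
        subs = ["a", "b", "c"]
        tp = list(TIMEPOINTS)

        def rand_estimates():
            out = []
            for edge in toy_atlas.edges():
                act = pd.DataFrame(rng.standard_normal((3, 17)), index=subs,
                                   columns=tp)
                fc = pd.DataFrame(rng.standard_normal((3, 17)), index=subs,
                                  columns=tp)
                fixed = pd.Series(0.0,
                                  index=list(EdgeModelSpec(*edge).columns))
                tau2 = pd.Series(0.0, index=list(ACT_TERMS + FC_TERMS))
                out.append(EdgeEstimates(edge, tuple(subs), act, fc,
                                         act.copy(), fc.copy(), fixed, tau2))
            return out

        e1, e2 = rand_estimates(), rand_estimates()
        alpha, beta = 0.3, -1.7
        combo = []
        for a, b in zip(e1, e2):
            act = alpha * a.activation + beta * b.activation
            fc = alpha * a.connectivity + beta * b.connectivity
            combo.append(EdgeEstimates(a.edge, a.subjects, act, fc,
                                       act.copy(), fc.copy(), a.fixed,
                                       a.tau2))
        lhs = st.aggregate_activation(combo, toy_atlas).data.to_numpy()
        rhs = (alpha * st.aggregate_activation(e1, toy_atlas).data.to_numpy()
               + beta * st.aggregate_activation(e2, toy_atlas).data.to_numpy())
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_label_integrity(self, toy_edges, toy_cohort):
        act = st.aggregate_activation(toy_edges, toy_cohort.atlas)
        fc = st.aggregate_connectivity(toy_edges, toy_cohort.atlas)
        comb = st.assemble_feature_matrix(act, fc)
        lf = comb.labels_frame()
        triples = list(map(tuple, lf.to_numpy()))
        assert len(set(triples)) == comb.n_features
        assert set(lf.kind) == {"act", "fc"}

    def test_subject_mismatch_rejected(self, toy_edges, toy_cohort):
        act = st.aggregate_activation(toy_edges, toy_cohort.atlas)
        fc = st.aggregate_connectivity(toy_edges, toy_cohort.atlas)
        fc_bad = st.FeatureMatrix(fc.data.iloc[:-1])
        with pytest.raises(ValueError):
            st.assemble_feature_matrix(act, fc_bad)


def test_clustered_subnetworks_partition_edges():
    rng = np.random.default_rng(0)
    atlas = st.RoiAtlas.toy(6)
    traj = rng.standard_normal((atlas.n_edges, 17))
    sub = st.cluster_edge_subnetworks(traj, atlas.edges(), n_subnetworks=3,
                                      seed=1)
    assert set(sub) == set(atlas.edges())
    assert set(sub.values()) <= {1, 2, 3}
    # deterministic under the seed
    sub2 = st.cluster_edge_subnetworks(traj, atlas.edges(), n_subnetworks=3,
                                       seed=1)
    assert sub == sub2


def test_full_atlas_structure():
    atlas = st.RoiAtlas.stress_network()
    assert len(atlas.rois) == 21
    assert len(atlas.regions) == 12
    assert atlas.n_edges == 210
    assert set(atlas.subnetwork.values()) == {1, 2, 3, 4}
    # dependent-model counts range 20..1 over the first 20 ROIs; the last ROI
    # is bilateral so every anatomical region keeps coverage
    counts = {r: 0 for r in atlas.rois}
    for a, _b in atlas.edges():
        counts[a] += 1
    assert sorted(counts.values(), reverse=True) == list(range(20, -1, -1))
    last = atlas.rois[-1]
    assert atlas.hemisphere[last] in ("l", "r")
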