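"""Affect scores, cortisol responses, IBI filtering, and association models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import stresstraj as st
from stresstraj.synthetic import AFFECT_ITEMS, NEGATIVE_ITEMS, POSITIVE_ITEMS


def _ratings(pos=4, neg=2, timepoints=("T3", "T6", "T8"), pid="sub-001"):
    rows = []
    for tp in timepoints:
        row = {"participant_id": pid, "timepoint": tp}
        row.update({i: pos for i in POSITIVE_ITEMS})
        row.update({i: neg for i in NEGATIVE_ITEMS})
        rows.append(row)
    return pd.DataFrame(rows)


class TestAffect:
    def test_sum_score_bounds_and_arithmetic(self):
        top = st.affect_scores(_ratings(pos=6, neg=1))
        assert (top.positive == 30).all()
        assert (top.negative == 10).all()
        r = _ratings()
        r.loc[0, list(POSITIVE_ITEMS)] = [2, 3, 4, 5, 6]
        assert st.affect_scores(r).positive.iloc[0] == 20

    def test_missing_item_marks_score_missing(self):
        r = _ratings()
        r.loc[0, "anxiety"] = np.nan
        sc = st.affect_scores(r)
        assert np.isnan(sc.negative.iloc[0])
        assert not np.isnan(sc.positive.iloc[0])

    @settings(max_examples=20, deadline=None)
    @given(hst.permutations(list(AFFECT_ITEMS)))
    def test_sums_invariant_to_item_order(self, order):
        rng = np.random.default_rng(0)
        r = _ratings()
        vals = rng.integers(1, 7, size=(len(r), 15))
        r[list(AFFECT_ITEMS)] = vals
        shuffled = r[["participant_id", "timepoint", *order]]
        pd.testing.assert_frame_equal(st.affect_scores(r),
                                      st.affect_scores(shuffled))

    def test_deltas(self):
        r = _ratings(neg=2)
        r.loc[r.timepoint == "T3", list(NEGATIVE_ITEMS)] = 1  # T3 sum 10
        r.loc[r.timepoint == "T6", list(NEGATIVE_ITEMS)[:2]] = 6
        d = st.affect_deltas(st.affect_scores(r))
        # T6 negative sum: 2x6 + 8x2 = 28; baseline 10 -> delta 18
        assert d.delta_neg_T6.iloc[0] == 18
        assert d.delta_pos_T6.iloc[0] == 0

    def test_planted_bmi_affect_slope_sign(self):
        """Cohorts with a planted BMI -> negative-affect response recover a
        positive female slope of delta-negative-affect at T8 (sign test)."""
        hits = 0
        for seed in range(20):
            spec = st.CohortSpec(n_female=120, n_male=70, seed=700 + seed,
                                 effect_activation={})
            p = st.simulate_participants(spec)
            truth = st.make_ground_truth(p, st.RoiAtlas.toy(4),
                                         st.TaskDesign.compact(), spec)
            mk = st.simulate_biomarkers(p, truth, spec)
            d = st.affect_deltas(st.affect_scores(mk.affect))
            merged = d.merge(p, on="participant_id")
            fem = merged[merged.sex == "female"]
            slope = np.polyfit(fem.bmi, fem.delta_neg_T8, 1)[0]
            hits += slope > 0
        assert hits >= 17


class TestCortisol:
    def test_response_deltas(self):
        s = pd.DataFrame({"participant_id": ["a", "b"],
                          "T0": [5.0, 5.0], "T1": [5.5, 5.0],
                          "T2": [5.0, 4.0], "T6": [7.5, 4.0],
                          "T8": [5.5, 4.0]})
        out = st.cortisol_response(s)
        assert out.delta_cort_T6.tolist() == [2.5, 0.0]
        assert out.delta_cort_T8.tolist() == [0.5, 0.0]

    def test_responder_threshold_is_strict(self):
        s = pd.DataFrame({"participant_id": ["a", "b", "c", "d"],
                          "T0": [5.0, 5.0, 5.0, np.nan],
                          "T1": [7.6, 7.5, 4.0, 6.0]})
        flags = st.classify_pre_task_responder(s)
        assert flags.tolist()[:3] == [True, False, False]
        assert pd.isna(flags.iloc[3])


class TestIbi:
    def test_out_of_range_removed(self):
        clean, rep = st.filter_ibi(np.array([0.25, 0.8, 0.8, 2.5, 0.8]))
        assert rep["removed_out_of_range"] == 2
        assert np.all((clean >= 0.3) & (clean <= 2.4))

    def test_hand_traced_deviation_rule(self):
        """60-beat steady 0.8 s train with one 1.2 s interval (50% deviation
        from neighbours and the running mean): only that beat is removed."""
        x = np.full(60, 0.8)
        x[30] = 1.2
        clean, rep = st.filter_ibi(x)
        assert rep["removed_deviation"] == 1
        assert len(clean) == 59
        assert np.all(clean == 0.8)

    def test_isolated_deviation_from_one_side_only_is_kept(self):
        # a level shift (both neighbours agree with the new level's
        # continuation) must not be removed: dev from following is small
        x = np.concatenate([np.full(30, 0.8), np.full(30, 1.0)])
        clean, rep = st.filter_ibi(x)
        assert rep["removed_deviation"] == 0

    @settings(max_examples=20, deadline=None)
    @given(hst.integers(min_value=0, max_value=10 ** 6))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(0.8, 0.2, 80)) + 0.05
        once, _ = st.filter_ibi(x)
        if len(once) >= 2:
            twice, rep = st.filter_ibi(once)
            assert np.array_equal(once, twice)
            assert rep["removed_out_of_range"] == 0
            assert rep["removed_deviation"] == 0

    def test_all_removed_flagged_unusable(self):
        _clean, rep = st.filter_ibi(np.array([0.1, 2.9]))
        assert not rep["usable"]


class TestHeartRate:
    def test_constant_ibi_gives_75_bpm(self):
        ibi = pd.DataFrame({"participant_id": "a",
                            "block_index": np.repeat(np.arange(1, 16), 20),
                            "ibi_s": 0.8})
        hr = st.block_heart_rate(ibi)
        assert hr.hr_prestress.iloc[0] == pytest.approx(75.0)
        assert hr.delta_hr_stress.iloc[0] == pytest.approx(0.0)

    def test_phase_contrast_arithmetic(self):
        rows = []
        for b in range(1, 16):
            hr = 76.7 if 6 <= b <= 10 else 70.0
            rows.append(pd.DataFrame({"participant_id": "a",
                                      "block_index": b,
                                      "ibi_s": np.full(40, 60.0 / hr)}))
        hr_tab = st.block_heart_rate(pd.concat(rows, ignore_index=True))
        assert hr_tab.delta_hr_stress.iloc[0] == pytest.approx(6.7, abs=1e-9)
        assert hr_tab.delta_hr_poststress.iloc[0] == pytest.approx(0.0)

    def test_split_vs_global_filtering_equivalence(self):
        """Filtering a clean series globally or per block gives the same
        blocks (no boundary effects on artifact-free data)."""
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(0.8, 0.02, 150)) + 0.05
        table = pd.DataFrame({"participant_id": "a",
                              "block_index": np.repeat([1, 2, 3], 50),
                              "ibi_s": x})
        per_block = st.filter_ibi_table(table)
        global_clean, _ = st.filter_ibi(x)
        assert np.allclose(per_block.ibi_s.to_numpy(), global_clean)


class TestAssociationModels:
    def test_coefficients_match_normal_equations_oracle(self):
        """Fixed 12-row toy data: the regression table equals the direct
        normal-equations least-squares solution."""
        rng = np.random.default_rng(9)
        n = 12
        part = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n)],
            "bmi": rng.normal(24, 4, n).round(1),
            "sex": ["female", "male"] * 6,
            "age": rng.normal(35, 10, n).round(1),
            "diagnosis": [0, 1, 1, 0] * 3,
            "pretask_responder": [0, 0, 1] * 4,
        })
        responses = pd.DataFrame({
            "participant_id": part.participant_id,
            "delta_neg_T6": rng.normal(8, 3, n).round(2),
        })
        out = st.stress_association_models(responses, part)
        coef = out.coefficients.set_index("term")
        sex = (part.sex == "male").astype(float).to_numpy()
        X = np.column_stack([np.ones(n), part.bmi, sex, part.bmi * sex,
                             part.age, part.diagnosis,
                             part.pretask_responder])
        beta = np.linalg.solve(X.T @ X,
                               X.T @ responses.delta_neg_T6.to_numpy())
        assert coef.loc["bmi", "estimate"] == pytest.approx(beta[1],
                                                            abs=1e-8)
        assert coef.loc["bmi:sex_male", "estimate"] == pytest.approx(
            beta[3], abs=1e-8)

    def test_female_specific_affect_association(self, toy_atlas,
                                                compact_design):
        """Planted female-specific BMI effect on negative affect: female
        stratified slope positive, male slope near zero (20-seed property)."""
        fem_hits, male_small = 0, 0
        for seed in range(20):
            spec = st.CohortSpec(n_female=120, n_male=70, seed=800 + seed,
                                 effect_activation={}, female_specific=True,
                                 affect_bmi_slope=0.6)
            p = st.simulate_participants(spec)
            truth = st.make_ground_truth(p, toy_atlas, compact_design, spec)
            mk = st.simulate_biomarkers(p, truth, spec)
            d = st.affect_deltas(st.affect_scores(mk.affect)).merge(
                p, on="participant_id")
            fem = d[d.sex == "female"]
            mal = d[d.sex == "male"]
            bf = np.polyfit(fem.bmi, fem.delta_neg_T6, 1)[0]
            bm = np.polyfit(mal.bmi, mal.delta_neg_T6, 1)[0]
            fem_hits += bf > 0
            male_small += abs(bm) < abs(bf) + 0.5
        assert fem_hits >= 18

    def test_null_cohort_nominal_rate(self):
        rng = np.random.default_rng(10)
        hits = 0
        for s in range(60):
            n = 80
            part = pd.DataFrame({
                "participant_id": [f"s{i}" for i in range(n)],
                "bmi": rng.normal(24, 4, n),
                "sex": rng.choice(["female", "male"], n),
                "age": rng.normal(35, 10, n),
                "diagnosis": rng.random(n) < 0.4,
                "pretask_responder": rng.random(n) < 0.16,
            })
            responses = pd.DataFrame({
                "participant_id": part.participant_id,
                "delta_neg_T6": rng.normal(8, 3, n)})
            out = st.stress_association_models(responses, part)
            coef = out.coefficients.set_index("term")
            hits += coef.loc["bmi", "p"] < 0.05
        assert hits <= 9  # 60 null fits: P(>9 hits at 5%) < 0.1%

    def test_pipeline_table_shapes(self, toy_cohort):
        mk = toy_cohort.markers
        table = st.stress_response_table(mk.affect, mk.cortisol, mk.ibi)
        assert {"delta_neg_T6", "delta_cort_T8",
                "delta_hr_stress"} <= set(table.columns)
        assert len(table) == len(toy_cohort.participants)
        out = st.stress_association_models(table, toy_cohort.participants)
        assert not out.coefficients.empty
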