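"""Subjective, endocrine, and cardiovascular stress-response variables.

Affect sum scores (5 positive items, range 5-30; 10 negative items, range
10-60) and their changes from the pre-task baseline (T3); salivary cortisol
changes from the pre-scanner sample (T2) and the pre-task responder rule
(T1 - T0 > 2.5 nmol/l); interbeat-interval artifact filtering and block-wise
heart rate; and the multiple-regression association models with BMI, sex and
their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA

from .design import TaskDesign, block_phase
from .synthetic import NEGATIVE_ITEMS, POSITIVE_ITEMS

RESPONDER_THRESHOLD_NMOL_L = 2.5


# ---------------------------------------------------------------------------
# affect
# ---------------------------------------------------------------------------

def affect_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Positive/negative sum scores per participant and timepoint.

    Rows with any missing item are marked missing (NaN sums), excluding the
    subject-timepoint from affect analyses."""
    for item in POSITIVE_ITEMS + NEGATIVE_ITEMS:
        if item not in ratings.columns:
            raise ValueError(f"missing affect item column {item!r}")
    pos = ratings[list(POSITIVE_ITEMS)].astype(float)
    neg = ratings[list(NEGATIVE_ITEMS)].astype(float)
    out = pd.DataFrame({
        "participant_id": ratings["participant_id"],
        "timepoint": ratings["timepoint"],
        "positive": pos.sum(axis=1, min_count=len(POSITIVE_ITEMS)),
        "negative": neg.sum(axis=1, min_count=len(NEGATIVE_ITEMS)),
    })
    return out


def affect_deltas(scores: pd.DataFrame) -> pd.DataFrame:
    """Changes from the pre-task baseline (T3) at T6 and T8, both scales."""
    wide_p = scores.pivot(index="participant_id", columns="timepoint",
                          values="positive")
    wide_n = scores.pivot(index="participant_id", columns="timepoint",
                          values="negative")
    if "T3" not in wide_n.columns:
        raise ValueError("baseline timepoint T3 is required")
    out = pd.DataFrame(index=wide_n.index)
    for t in ("T6", "T8"):
        out[f"delta_neg_{t}"] = (wide_n[t] - wide_n["T3"]
                                 if t in wide_n.columns else np.nan)
        out[f"delta_pos_{t}"] = (wide_p[t] - wide_p["T3"]
                                 if t in wide_p.columns else np.nan)
    return out.reset_index()


# ---------------------------------------------------------------------------
# cortisol
# ---------------------------------------------------------------------------

def cortisol_response(series: pd.DataFrame) -> pd.DataFrame:
    """Cortisol changes from the pre-scanner sample: T6 - T2 and T8 - T2."""
    if "T2" not in series.columns:
        raise ValueError("T2 sample required")
    out = pd.DataFrame({"participant_id": series["participant_id"]})
    for t in ("T6", "T8"):
        out[f"delta_cort_{t}"] = (series[t] - series["T2"]
                                  if t in series.columns else np.nan)
    return out


def classify_pre_task_responder(series: pd.DataFrame) -> pd.Series:
    """Pre-task cortisol responder: T1 - T0 strictly above 2.5 nmol/l.

    Missing T0 or T1 yields a missing flag."""
    rise = series["T1"] - series["T0"]
    flag = rise > RESPONDER_THRESHOLD_NMOL_L
    return flag.where(rise.notna(), other=pd.NA)


# ---------------------------------------------------------------------------
# interbeat intervals
# ---------------------------------------------------------------------------

def filter_ibi(ibi: np.ndarray, window: int = 50,
               initial_threshold: float = 0.13,
               min_ibi: float = 0.3, max_ibi: float = 2.4,
               max_threshold: float = 0.30) -> tuple[np.ndarray, dict]:
    """Artifact filtering of one interbeat-interval series (seconds).

    Intervals outside [0.3, 2.4] s are removed.  An interval is then removed
    when its relative deviation from the previous accepted interval, from the
    following interval, and from the trailing running mean of up to ``window``
    accepted beats all exceed the current threshold.  After each accepted
    beat the threshold is updated to twice the mean absolute successive
    relative difference over the trailing accepted beats, bounded to
    [initial_threshold, max_threshold].  The deviation pass is iterated to a
    fixed point (removing one artifact can expose its neighbour), so the
    filter is idempotent on its own output.
    """
    x = np.asarray(ibi, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two intervals")
    in_range = (x >= min_ibi) & (x <= max_ibi)
    removed_range = int(np.sum(~in_range))
    x = x[in_range]

    removed_dev = 0
    while True:
        accepted: list[float] = []
        succ_diffs: list[float] = []
        thr = initial_threshold
        removed_pass = 0
        for i, val in enumerate(x):
            if not accepted:
                accepted.append(val)
                continue
            prev = accepted[-1]
            run = float(np.mean(accepted[-window:]))
            nxt = x[i + 1] if i + 1 < len(x) else None
            dev_prev = abs(val - prev) / prev
            dev_run = abs(val - run) / run
            dev_next = abs(val - nxt) / nxt if nxt is not None else np.inf
            if dev_prev > thr and dev_next > thr and dev_run > thr:
                removed_pass += 1
                continue
            succ_diffs.append(dev_prev)
            accepted.append(val)
            recent = succ_diffs[-window:]
            thr = min(max(initial_threshold, 2.0 * float(np.mean(recent))),
                      max_threshold)
        removed_dev += removed_pass
        x = np.asarray(accepted)
        if removed_pass == 0 or len(x) < 2:
            break
    report = {"removed_out_of_range": removed_range,
              "removed_deviation": removed_dev,
              "n_accepted": len(x),
              "usable": len(x) > 0}
    return x, report


def filter_ibi_table(ibi: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply ``filter_ibi`` per participant and block; unusable blocks are
    dropped with a warning."""
    rows = []
    for (pid, blk), grp in ibi.groupby(["participant_id", "block_index"],
                                       sort=True):
        cleaned, rep = filter_ibi(grp["ibi_s"].to_numpy(), **kwargs)
        if not rep["usable"]:
            warnings.warn(f"{pid} block {blk}: all intervals removed")
            continue
        rows.append(pd.DataFrame({"participant_id": pid, "block_index": blk,
                                  "ibi_s": cleaned}))
    return pd.concat(rows, ignore_index=True)


def block_heart_rate(cleaned: pd.DataFrame,
                     design: TaskDesign | None = None) -> pd.DataFrame:
    """Average heart rate per block (60 / mean IBI, bpm) and phase contrasts.

    Returns one row per participant with per-phase means, delta_hr_stress
    (Stress - PreStress) and delta_hr_poststress (PostStress - PreStress).
    Phases with no usable block are missing."""
    hr = (cleaned.groupby(["participant_id", "block_index"])["ibi_s"]
          .mean().rdiv(60.0).rename("hr_bpm").reset_index())
    hr["phase"] = hr["block_index"].map(block_phase)
    phase = hr.pivot_table(index="participant_id", columns="phase",
                           values="hr_bpm", aggfunc="mean")
    out = pd.DataFrame(index=phase.index)
    for p in ("prestress", "stress", "poststress"):
        out[f"hr_{p}"] = phase[p] if p in phase.columns else np.nan
    out["delta_hr_stress"] = out["hr_stress"] - out["hr_prestress"]
    out["delta_hr_poststress"] = out["hr_poststress"] - out["hr_prestress"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# response table and association models
# ---------------------------------------------------------------------------

def stress_response_table(affect: pd.DataFrame, cortisol: pd.DataFrame,
                          ibi: pd.DataFrame) -> pd.DataFrame:
    """One row per participant with all stress-response variables."""
    deltas = affect_deltas(affect_scores(affect))
    cort = cortisol_response(cortisol)
    cort["pretask_responder_derived"] = classify_pre_task_responder(
        cortisol).to_numpy()
    hr = block_heart_rate(filter_ibi_table(ibi))
    out = deltas.merge(cort, on="participant_id", how="outer")
    out = out.merge(hr[["participant_id", "delta_hr_stress",
                        "delta_hr_poststress"]],
                    on="participant_id", how="outer")
    return out


RESPONSE_VARS = ("delta_neg_T6", "delta_neg_T8", "delta_pos_T6",
                 "delta_pos_T8", "delta_cort_T6", "delta_cort_T8",
                 "delta_hr_stress", "delta_hr_poststress")


@dataclass
class AssociationModels:
    coefficients: pd.DataFrame   # response x term table (estimate, t, p, df)
    multivariate_affect: dict    # joint test of BMI across affect deltas


def stress_association_models(responses: pd.DataFrame,
                              participants: pd.DataFrame) -> AssociationModels:
    """Multiple regressions ``response ~ bmi * sex + age + diagnosis +
    responder`` per stress-response variable, plus a joint multivariate test
    of BMI across the four affect deltas."""
    data = responses.merge(participants, on="participant_id", how="inner")
    data["sex_male"] = (data["sex"] == "male").astype(float)
    data["diagnosis"] = data["diagnosis"].astype(float)
    data["responder"] = data["pretask_responder"].astype(float)
    rhs = "bmi + sex_male + bmi:sex_male + age + diagnosis + responder"
    rows = []
    for var in RESPONSE_VARS:
        if var not in data.columns:
            continue
        sub = data.dropna(subset=[var, "bmi", "age"])
        if len(sub) < 10:
            continue
        fit = smf.ols(f"{var} ~ {rhs}", data=sub).fit()
        for term in fit.params.index:
            rows.append((var, term, fit.params[term], fit.tvalues[term],
                         fit.pvalues[term], int(fit.df_resid)))
    coef = pd.DataFrame(rows, columns=["response", "term", "estimate", "t",
                                       "p", "df"])

    affect_vars = [v for v in ("delta_neg_T6", "delta_neg_T8",
                               "delta_pos_T6", "delta_pos_T8")
                   if v in data.columns]
    mv: dict = {}
    sub = data.dropna(subset=affect_vars + ["bmi", "age"])
    if len(affect_vars) >= 2 and len(sub) > 20:
        lhs = " + ".join(affect_vars)
        mano = MANOVA.from_formula(f"{lhs} ~ {rhs}", data=sub)
        res = mano.mv_test()
        tbl = res.results["bmi"]["stat"]
        mv = {"statistic": float(tbl.loc["Pillai's trace", "Value"]),
              "F": float(tbl.loc["Pillai's trace", "F Value"]),
              "p": float(tbl.loc["Pillai's trace", "Pr > F"])}
    return AssociationModels(coef, mv)
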