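"""Cytokine normalization, marker screening, and predicted/residual outcome
attribution.

The cytokine panel is detection-limit clipped (below the lower limit -> 0,
above the upper -> upper limit), filtered for missingness (> 16% excluded),
rank-based inverse-normal transformed (Phi^-1((r - 0.5)/n), midranks for
ties), batch-residualized per marker, and median-imputed.  Markers partially
correlated with the outcome (uncorrected p < 0.05, screening only) are then
regressed against the observed outcome, the out-of-fold model-predicted
outcome, and the residual outcome: association with the predicted component
indicates variance shared with the brain response, association with the
residual indicates independent variance.

A weighted bootstrap matches the male outcome distribution to the female
moments (normal-density importance ratio, 99th-percentile weight clipping) to
check whether sex differences in associations reflect sampling differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .prediction import PredictionResult

SCREEN_COVARIATES = ("age", "sex", "diagnosis", "medication")


@dataclass
class NormalizedPanel:
    values: pd.DataFrame          # participants x retained markers
    batch: pd.Series
    dropped: list[str]            # markers over the missingness ceiling
    n_imputed: pd.Series          # per retained marker
    n_censored_low: pd.Series
    n_censored_high: pd.Series


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((r - 0.5)/n), midranks for
    ties; NaNs stay NaN."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def prepare_cytokines(panel: pd.DataFrame,
                      detection_limits: pd.DataFrame | None = None,
                      max_missing: float = 0.16,
                      batch_col: str = "batch",
                      id_col: str = "participant_id",
                      imputer=None) -> NormalizedPanel:
    """Censor-clip, filter, inverse-normal transform, batch-residualize, and
    impute the cytokine panel.

    ``imputer``: optional callable ``(values: DataFrame) -> DataFrame``
    replacing the default per-marker median imputation.
    """
    if panel.empty:
        raise ValueError("empty cytokine panel")
    markers = [c for c in panel.columns if c not in (batch_col, id_col)]
    batch = panel[batch_col].astype(str)
    if batch.isna().any():
        raise ValueError("batch label missing for some rows")
    values = panel[markers].astype(float).copy()

    limits = {}
    if detection_limits is not None:
        limits = {r["marker"]: (float(r["lower"]), float(r["upper"]))
                  for _, r in detection_limits.iterrows()}
    n_low = pd.Series(0, index=markers)
    n_high = pd.Series(0, index=markers)
    for m in markers:
        if m in limits:
            lo, hi = limits[m]
            below = values[m] < lo
            above = values[m] > hi
            values.loc[below, m] = 0.0   # below detection limit -> zero
            values.loc[above, m] = hi    # above upper limit -> upper limit
            n_low[m] = int(below.sum())
            n_high[m] = int(above.sum())

    miss_frac = values.isna().mean()
    dropped = list(miss_frac.index[miss_frac > max_missing])
    kept = [m for m in markers if m not in dropped]
    if not kept:
        raise ValueError("all markers exceed the missingness ceiling")
    values = values[kept]

    normed = values.apply(lambda col: inverse_normal_transform(col.to_numpy()))

    # per-marker batch residualization (linear model on batch dummies)
    dummies = pd.get_dummies(batch, drop_first=False).to_numpy(dtype=float)
    resid = normed.copy()
    for m in kept:
        col = normed[m].to_numpy()
        ok = ~np.isnan(col)
        coef, *_ = np.linalg.lstsq(dummies[ok], col[ok], rcond=None)
        resid[m] = col - dummies @ coef

    n_imputed = resid.isna().sum()
    if imputer is not None:
        resid = imputer(resid)
    else:
        resid = resid.fillna(resid.median())
    out = resid.copy()
    out.index = panel[id_col] if id_col in panel.columns else panel.index
    return NormalizedPanel(out, batch, dropped, n_imputed, n_low, n_high)


# ---------------------------------------------------------------------------
# screening and decomposition
# ---------------------------------------------------------------------------

def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates, with the
    t-based p-value on n - k - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(x)), covariates])
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)
    R = np.column_stack([x, y]) - Z @ coef
    rx, ry = R[:, 0], R[:, 1]
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    dof = len(x) - np.linalg.matrix_rank(Z) - 1
    if dof <= 0:
        raise ValueError("too few subjects for partial correlation")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), dof)
    return r, float(p)


def screen_markers(panel: NormalizedPanel, participants: pd.DataFrame,
                   outcome: str = "bmi",
                   covariates: tuple[str, ...] = SCREEN_COVARIATES,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Partial correlation of each marker with the outcome given covariates;
    markers with uncorrected p < alpha are flagged selected."""
    part = participants.set_index("participant_id").loc[panel.values.index]
    n = len(part)
    if n <= len(covariates) + 2:
        raise ValueError("too few subjects for partial correlation")
    y = part[outcome].to_numpy(dtype=float)
    Z = np.column_stack([
        (part[c] == "male").astype(float) if c == "sex"
        else part[c].astype(float)
        for c in covariates])
    rows = []
    for m in panel.values.columns:
        r, p = partial_correlation(panel.values[m].to_numpy(), y, Z)
        rows.append((m, r, p, p < alpha))
    return pd.DataFrame(rows, columns=["marker", "partial_r", "p", "selected"])


def decompose_outcome(prediction: PredictionResult) -> pd.DataFrame:
    """Split the observed outcome into its out-of-fold prediction and the
    residual; observed = predicted + residual holds exactly per subject."""
    if prediction.predicted is None or len(prediction.predicted) == 0:
        raise ValueError("prediction result holds no out-of-fold predictions")
    return pd.DataFrame({
        "participant_id": prediction.subjects,
        "observed": prediction.observed,
        "predicted": prediction.predicted,
        "residual": prediction.observed - prediction.predicted,
    })


def marker_component_regression(panel: NormalizedPanel,
                                components: pd.DataFrame,
                                participants: pd.DataFrame,
                                markers: list[str] | None = None
                                ) -> pd.DataFrame:
    """For each marker and component in {observed, predicted, residual}:
    ``component ~ marker + sex + marker:sex + age + diagnosis + medication``.

    Returns the long coefficient table (marker x component x term)."""
    markers = list(markers if markers is not None else panel.values.columns)
    if not markers:
        raise ValueError("no markers to regress")
    part = participants.set_index("participant_id")
    comp = components.set_index("participant_id")
    ids = [i for i in panel.values.index if i in comp.index]
    base = pd.DataFrame({
        "sex": (part.loc[ids, "sex"] == "male").astype(float),
        "age": part.loc[ids, "age"].astype(float),
        "diagnosis": part.loc[ids, "diagnosis"].astype(float),
        "medication": part.loc[ids, "medication"].astype(float),
    }, index=ids)
    rows = []
    for m in markers:
        data = base.copy()
        data["marker"] = panel.values.loc[ids, m]
        for comp_name in ("observed", "predicted", "residual"):
            data["y"] = comp.loc[ids, comp_name]
            fit = smf.ols("y ~ marker + sex + marker:sex + age + diagnosis"
                          " + medication", data=data).fit()
            for term in ("marker", "sex", "marker:sex"):
                rows.append((m, comp_name, term, fit.params[term],
                             fit.tvalues[term], fit.pvalues[term]))
    return pd.DataFrame(rows, columns=["marker", "component", "term",
                                       "estimate", "t", "p"])


# ---------------------------------------------------------------------------
# distribution-matched resampling
# ---------------------------------------------------------------------------

@dataclass
class ResamplingResult:
    weights: np.ndarray
    statistics: np.ndarray
    estimate: float
    percentile_interval: tuple[float, float]
    achieved_mean: float
    achieved_sd: float
    target_mean: float
    target_sd: float


def _tilt_weights(values: np.ndarray, m_r: float, s_r: float) -> np.ndarray:
    """Exponential-tilting (entropy-balancing) weights w_i ~ exp(a*x + b*x^2)
    whose weighted mean and SD equal the reference moments, when feasible on
    the sample's support."""
    from scipy.optimize import fsolve

    n = len(values)
    s1 = values.std(ddof=1)
    x = (values - values.mean()) / s1  # scale for conditioning
    t_m = (m_r - values.mean()) / s1
    # sample-variance convention on both sides: reference == group -> lam = 0
    t_v = (s_r / s1) ** 2 * (n - 1) / n + t_m ** 2

    def eqs(lam):
        logw = lam[0] * x + lam[1] * x ** 2
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        return [np.sum(w * x) - t_m, np.sum(w * x ** 2) - t_v]

    lam, _info, _ier, _msg = fsolve(eqs, [0.0, 0.0], full_output=True)
    if np.max(np.abs(eqs(lam))) > 1e-6:
        raise ValueError("moment-matching weights did not converge; the "
                         "reference moments may be infeasible on this sample")
    logw = lam[0] * x + lam[1] * x ** 2
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def weighted_resample_match(values: np.ndarray,
                            reference_moments: tuple[float, float],
                            statistic=None,
                            n_resamples: int = 1000, seed: int = 0,
                            strength: float = 1.0) -> ResamplingResult:
    """Weighted bootstrap matching a group's outcome distribution to reference
    moments.

    Observations are drawn with exponential-tilting weights solved so that the
    weighted mean and SD of the group equal the reference moments (high- and
    low-outcome members receive higher weight when the reference is wider).
    ``statistic(idx)`` receives the resampled indices and is recomputed on
    each weighted resample.  ``strength`` interpolates between an ordinary
    bootstrap (0) and full moment matching (1).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    m_g, s_g = float(values.mean()), float(values.std(ddof=1))
    if s_g == 0:
        raise ValueError("degenerate group SD")
    m_r, s_r = reference_moments
    w_full = _tilt_weights(values, m_r, s_r)
    if strength == 1.0:
        w = w_full
    else:
        logw = strength * np.log(np.maximum(w_full, 1e-300))
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()

    if statistic is None:
        statistic = (lambda idx: float(np.mean(values[idx])))
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_resamples)
    means = np.empty(n_resamples)
    sds = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.choice(n, size=n, replace=True, p=w)
        stats_out[b] = statistic(idx)
        means[b] = values[idx].mean()
        sds[b] = values[idx].std(ddof=1)
    lo, hi = np.percentile(stats_out, [2.5, 97.5])
    return ResamplingResult(w, stats_out, float(np.mean(stats_out)),
                            (float(lo), float(hi)), float(means.mean()),
                            float(sds.mean()), float(m_r), float(s_r))


def resample_match_group(participants: pd.DataFrame, group: str = "male",
                         reference: str = "female", outcome: str = "bmi",
                         statistic=None, n_resamples: int = 1000,
                         seed: int = 0) -> ResamplingResult:
    """Convenience wrapper: match ``group``'s outcome moments to ``reference``'s."""
    g = participants.loc[participants["sex"] == group, outcome].to_numpy(float)
    r = participants.loc[participants["sex"] == reference, outcome].to_numpy(float)
    if len(g) == 0 or len(r) == 0:
        raise ValueError("both groups must be nonempty")
    return weighted_resample_match(g, (float(r.mean()), float(r.std(ddof=1))),
                                   statistic=statistic,
                                   n_resamples=n_resamples, seed=seed)
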