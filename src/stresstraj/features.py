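"""Per-edge hierarchical trajectory models and feature aggregation.

One model per unordered ROI pair (210 for the full atlas): the first ROI of
the pair under the canonical atlas ordering is the dependent variable, the
second the predictor.  The design holds an intercept, 17 timepoint regressors
(15 task blocks plus the two flanking resting-states), the centered predictor
timeseries, the 17 timepoint x predictor interactions that carry connectivity
changes, and HRF-convolved motor-response and verbal-feedback regressors.
Activation and interaction coefficients get participant random effects
(diagonal covariance, estimated by per-term REML; see ``pooling``).

Per-subject estimates (fixed effect + shrunken deviation) are aggregated into
feature matrices: block activation averaged over the models sharing a
dependent ROI and then over hemispheres (12 regions x 15 blocks = 180),
timepoint connectivity averaged within four subnetworks (4 x 17 = 68),
or both (248).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Edge, RoiAtlas
from .design import TIMEPOINTS, TaskDesign
from .pooling import pool_term
from .prep import ConcatenatedTimeseries

ACT_TERMS = tuple(f"act|{tp}" for tp in TIMEPOINTS)
FC_TERMS = tuple(f"fc|{tp}" for tp in TIMEPOINTS)
TASK_BLOCKS = tuple(f"block{i:02d}" for i in range(1, 16))


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, sampled every ``tr`` s."""
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / np.max(h)


def convolved_event_regressor(design: TaskDesign, kind: str,
                              concat_segment: np.ndarray,
                              times: np.ndarray) -> np.ndarray:
    """HRF-convolved boxcar for auxiliary events, zero outside the task."""
    out = np.zeros(len(times))
    task_rows = np.flatnonzero(concat_segment == "task")
    if task_rows.size == 0:
        return out
    tr = design.task_segment.tr
    task_t = times[task_rows] - times[task_rows][0]
    box = np.zeros(task_rows.size)
    for onset, dur, k in design.auxiliary_events:
        if k == kind:
            box[(task_t >= onset) & (task_t < onset + dur)] = 1.0
    conv = np.convolve(box, double_gamma_hrf(tr))[:task_rows.size]
    out[task_rows] = conv
    return out


@dataclass(frozen=True)
class EdgeModelSpec:
    """Design description of one edge model."""

    roi_dependent: str
    roi_predictor: str

    @property
    def columns(self) -> tuple[str, ...]:
        return (("intercept",) + ACT_TERMS + ("roi2",) + FC_TERMS
                + ("motor", "feedback"))

    @property
    def random_terms(self) -> tuple[str, ...]:
        return ACT_TERMS + FC_TERMS


@dataclass
class EdgeEstimates:
    """Group fixed effects and per-subject partial-pooled estimates."""

    edge: Edge
    subjects: tuple[str, ...]
    activation: pd.DataFrame      # subjects x 17 timepoints, pooled
    connectivity: pd.DataFrame    # subjects x 17 timepoints, pooled
    ols_activation: pd.DataFrame  # per-subject OLS, for diagnostics/oracles
    ols_connectivity: pd.DataFrame
    fixed: pd.Series              # fixed effect for every design column
    tau2: pd.Series               # between-subject variance per random term
    diagnostics: dict = field(default_factory=dict)


class _SubjectContext:
    """Shared design pieces for one subject, reused across all edges."""

    def __init__(self, concat: ConcatenatedTimeseries, design: TaskDesign):
        self.subject = concat.subject
        self.rois = concat.rois
        self.y = concat.data.to_numpy(dtype=float)
        ind = concat.timepoint_indicators()
        motor = convolved_event_regressor(design, "motor_response",
                                          concat.segment, concat.times)
        feedback = convolved_event_regressor(design, "verbal_feedback",
                                             concat.segment, concat.times)
        n = len(concat.times)
        self.indicators = ind
        self.base = np.column_stack([np.ones(n), ind, motor, feedback])

    def design_matrix(self, predictor_idx: int) -> np.ndarray:
        roi2 = self.y[:, predictor_idx]
        roi2c = roi2 - roi2.mean()
        inter = self.indicators * roi2c[:, None]
        # column order: intercept, act x17, roi2, fc x17, motor, feedback
        return np.column_stack([self.base[:, :18], roi2c, inter,
                                self.base[:, 18:]])


def _subject_ols(ctx: _SubjectContext, dep_idx: int, pred_idx: int
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """OLS coefficients and their sampling variances for one subject/edge."""
    x = ctx.design_matrix(pred_idx)
    y = ctx.y[:, dep_idx]
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    ok = True
    try:
        beta = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        ok = False
        xtx_inv = np.linalg.pinv(xtx)
        beta = xtx_inv @ xty
    rss = float(np.sum((y - x @ beta) ** 2))
    dof = max(n - p, 1)
    sigma2 = rss / dof
    v = sigma2 * np.diag(xtx_inv)
    return beta, np.maximum(v, 1e-12), ok


def fit_edge_model(concats: list[ConcatenatedTimeseries], edge: Edge,
                   design: TaskDesign,
                   tau2_override: float | None = None,
                   _contexts: list[_SubjectContext] | None = None
                   ) -> EdgeEstimates:
    """Fit the hierarchical model for one edge.

    ``tau2_override`` fixes the random-effect variances (e.g. very large to
    obtain the no-pooling / per-subject OLS limit).  With a single subject the
    per-subject estimates are that subject's OLS coefficients.
    """
    if not concats:
        raise ValueError("no subjects")
    spec = EdgeModelSpec(*edge)
    cols = list(spec.columns)
    contexts = _contexts or [_SubjectContext(c, design) for c in concats]
    rois = contexts[0].rois
    if edge[0] not in rois or edge[1] not in rois:
        raise ValueError(f"edge {edge} not covered by ROI set")
    dep, pred = rois.index(edge[0]), rois.index(edge[1])

    betas, variances, flags = [], [], []
    for ctx in contexts:
        b, v, ok = _subject_ols(ctx, dep, pred)
        betas.append(b)
        variances.append(v)
        flags.append(ok)
    B = np.vstack(betas)
    V = np.vstack(variances)
    subjects = tuple(ctx.subject for ctx in contexts)

    fixed = pd.Series(index=cols, dtype=float)
    tau2 = pd.Series(index=list(spec.random_terms), dtype=float)
    pooled = np.array(B, copy=True)
    if len(contexts) == 1:
        fixed[:] = B[0]
        tau2[:] = np.nan
    else:
        for j, c in enumerate(cols):
            if c in spec.random_terms:
                res = pool_term(B[:, j], V[:, j], tau2=tau2_override)
                fixed[c] = res.fixed
                tau2[c] = res.tau2
                pooled[:, j] = res.estimates
            else:
                w = 1.0 / V[:, j]
                fixed[c] = float(np.sum(w * B[:, j]) / np.sum(w))

    act_idx = [cols.index(c) for c in ACT_TERMS]
    fc_idx = [cols.index(c) for c in FC_TERMS]
    tp = list(TIMEPOINTS)
    mk = lambda arr, idx: pd.DataFrame(arr[:, idx], index=list(subjects),
                                       columns=tp)
    diag = {"ols_rank_ok": all(flags),
            "n_subjects": len(subjects),
            "tau2_override": tau2_override}
    return EdgeEstimates(edge, subjects, mk(pooled, act_idx),
                         mk(pooled, fc_idx), mk(B, act_idx), mk(B, fc_idx),
                         fixed, tau2, diag)


def fit_all_edges(concats: list[ConcatenatedTimeseries], atlas: RoiAtlas,
                  design: TaskDesign, n_jobs: int = 1,
                  tau2_override: float | None = None) -> list[EdgeEstimates]:
    """Fit every edge of the atlas; failed edges are dropped with a warning."""
    contexts = [_SubjectContext(c, design) for c in concats]
    order = {s: i for i, s in enumerate(sorted(c.subject for c in concats))}
    contexts.sort(key=lambda c: order[c.subject])  # subject-order invariance

    def one(edge: Edge) -> EdgeEstimates | None:
        try:
            return fit_edge_model(concats, edge, design,
                                  tau2_override=tau2_override,
                                  _contexts=contexts)
        except Exception as exc:  # noqa: BLE001 - record and continue
            warnings.warn(f"edge {edge} failed: {exc}")
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(delayed(one)(e)
                                          for e in atlas.edges())
    else:
        results = [one(e) for e in atlas.edges()]
    return [r for r in results if r is not None]


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects x labelled spatio-temporal features.

    Column labels are ``kind|unit|timepoint`` triples, e.g.
    ``act|amygdala|block07`` or ``fc|sn2|rest1``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix must have no missing cells")
        bad = [c for c in self.data.columns if len(str(c).split("|")) != 3]
        if bad:
            raise ValueError(f"malformed feature labels: {bad[:3]}")
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("duplicate feature labels")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def labels_frame(self) -> pd.DataFrame:
        parts = [str(c).split("|") for c in self.data.columns]
        return pd.DataFrame(parts, columns=["kind", "unit", "timepoint"],
                            index=self.data.columns)

    def groups(self) -> dict[str, list[str]]:
        """Feature-set grouping: all timepoints of one region/subnetwork."""
        lf = self.labels_frame()
        out: dict[str, list[str]] = {}
        for col, (kind, unit, _tp) in lf.iterrows():
            out.setdefault(f"{kind}|{unit}", []).append(col)
        return out


def aggregate_activation(edges: list[EdgeEstimates],
                         atlas: RoiAtlas) -> FeatureMatrix:
    """Average per-subject block-activation estimates across the models in
    which each ROI is dependent, then across hemispheres: 12 regions x 15
    task blocks for the full atlas."""
    by_roi: dict[str, list[pd.DataFrame]] = {}
    for est in edges:
        by_roi.setdefault(est.edge[0], []).append(est.activation[list(TASK_BLOCKS)])
    subjects = edges[0].activation.index
    cols = {}
    for region in atlas.regions:
        stacks = []
        for roi in atlas.rois_of_region(region):
            mats = by_roi.get(roi)
            if mats:
                stacks.append(sum(m.to_numpy() for m in mats) / len(mats))
        if not stacks:
            raise ValueError(f"region {region!r} has no dependent-ROI models")
        region_mat = np.mean(stacks, axis=0)
        for b_i, blk in enumerate(TASK_BLOCKS):
            cols[f"act|{region}|{blk}"] = region_mat[:, b_i]
    return FeatureMatrix(pd.DataFrame(cols, index=subjects))


def aggregate_connectivity(edges: list[EdgeEstimates],
                           atlas: RoiAtlas) -> FeatureMatrix:
    """Average per-subject timepoint-connectivity estimates within each of the
    four subnetworks: 4 x 17 features for the full atlas."""
    if not atlas.subnetwork:
        raise ValueError("atlas has no subnetwork map")
    by_edge = {est.edge: est.connectivity for est in edges}
    subjects = edges[0].connectivity.index
    cols = {}
    for k in atlas.subnetworks:
        member = [by_edge[e] for e in atlas.edges_of_subnetwork(k)
                  if e in by_edge]
        if not member:
            raise ValueError(f"subnetwork {k} has no fitted edges")
        mat = sum(m.to_numpy() for m in member) / len(member)
        for t_i, tp in enumerate(TIMEPOINTS):
            cols[f"fc|sn{k}|{tp}"] = mat[:, t_i]
    return FeatureMatrix(pd.DataFrame(cols, index=subjects))


def assemble_feature_matrix(activation: FeatureMatrix | None,
                            connectivity: FeatureMatrix | None,
                            mode: str = "combined") -> FeatureMatrix:
    """Column-concatenate the feature blocks: activation (180), fc (68), or
    combined (248) for the full atlas."""
    if mode not in ("activation", "fc", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "activation":
        if activation is None:
            raise ValueError("activation block required")
        return FeatureMatrix(activation.data.copy())
    if mode == "fc":
        if connectivity is None:
            raise ValueError("fc block required")
        return FeatureMatrix(connectivity.data.copy())
    if activation is None or connectivity is None:
        raise ValueError("combined mode needs both blocks")
    if list(activation.data.index) != list(connectivity.data.index):
        raise ValueError("subject sets differ between blocks")
    return FeatureMatrix(pd.concat([activation.data, connectivity.data],
                                   axis=1))
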