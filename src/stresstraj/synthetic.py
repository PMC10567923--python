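"""Synthetic stress-cohort generator.

Emulates the study's data layout end to end: a participants table with the
cohort's demographic structure, per-subject three-segment ROI timeseries with
the block-design task structure and plantable trajectory->BMI associations,
and all peripheral markers (cytokine panel, salivary and baseline cortisol,
affect ratings, interbeat intervals).  Ground truth is exported alongside so
recovery experiments can score every stage.

Generative model
----------------
BMI is drawn per sex from a truncated normal (clip-and-redraw) and split into
two independent standard-normal components, ``z = sqrt(w) g + sqrt(1-w) h``:
``g`` drives the brain (planted trajectory effects load on it), ``h`` is the
brain-independent remainder.  Markers labelled ``brain_mediated`` load on the
planted brain signal, ``independent`` markers load on ``h`` — so out-of-fold
predicted BMI should recover marker associations on the ``g`` pathway and the
residual on the ``h`` pathway.

ROI signals are baseline drift + per-block boxcar activation (group mean +
subject deviation) + edge-wise shared latent coupling (the dependent ROI of an
edge receives ``coupling * predictor-ROI intrinsic signal``, with block-
modulated coupling, matching the regression structure the edge estimator
assumes) + nuisance components + Gaussian noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RoiAtlas
from .design import SEGMENTS, TIMEPOINTS, TaskDesign, block_phase

POSITIVE_ITEMS = ("activity", "wakefulness", "self_certainty", "focus", "relaxed")
NEGATIVE_ITEMS = ("agitation_int", "agitation_ext", "anxiety", "sadness", "anger",
                  "dysphoria", "sensitivity", "somatic_1", "somatic_2", "somatic_3")
AFFECT_ITEMS = POSITIVE_ITEMS + NEGATIVE_ITEMS
AFFECT_TIMEPOINTS = ("T3", "T6", "T8")
CORTISOL_TIMEPOINTS = ("T0", "T1", "T2", "T6", "T8")


def _default_effect_activation() -> dict[tuple[str, int], float]:
    # positive loading of anterior hippocampus and dACC trajectories on BMI,
    # negative loading of posterior insula and posterior hippocampus, during
    # the Stress and PostStress blocks
    eff: dict[tuple[str, int], float] = {}
    for b in range(6, 16):
        eff[("hippocampus_ant", b)] = 0.3
        eff[("dacc", b)] = 0.3
        eff[("insula_post", b)] = -0.3
        eff[("hippocampus_post", b)] = -0.3
    return eff


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort structure of the study sample: n = 190
    (120 female), female BMI mean 23.4 / SD 4.6 / range 17.7-41.9 kg/m2, male
    24.0 / 2.8 / 18.9-33.1, 42% with a mood/anxiety diagnosis, 16% pre-task
    cortisol responders.  Planted effect magnitudes are free parameters of the
    recovery experiments, not quantities estimated by the study.
    """

    n_female: int = 120
    n_male: int = 70
    seed: int = 20230
    # per-sex BMI (mean, sd, min, max) in kg/m2
    bmi_female: tuple[float, float, float, float] = (23.4, 4.6, 17.7, 41.9)
    bmi_male: tuple[float, float, float, float] = (24.0, 2.8, 18.9, 33.1)
    diagnosis_rate: float = 0.42
    pretask_responder_rate: float = 0.16
    medication_rate: float = 0.04
    # planted trajectory -> BMI effects, feature units per BMI SD
    effect_activation: dict[tuple[str, int], float] = field(
        default_factory=_default_effect_activation)
    effect_fc: dict[tuple[int, str], float] = field(default_factory=dict)
    female_specific: bool = True
    brain_variance_frac: float = 0.5  # share of BMI variance visible to the brain
    # signal geometry
    noise_sd: float = 0.5          # measurement noise, signal units
    intrinsic_sd: float = 0.6      # intrinsic ROI fluctuation feeding FC
    between_sd: float = 0.6        # between-subject SD of block activation
    between_sd_fc: float = 0.15    # between-subject SD of timepoint coupling
    drift_amp: float = 0.002       # linear drift, signal units per second
    nuisance_amp: float = 0.3
    # peripheral markers
    n_cytokines: int = 42
    cytokine_bmi_corr: tuple[float, ...] | None = None
    n_brain_mediated: int = 5
    n_independent: int = 5
    marker_corr: float = 0.35  # loading of non-null markers on their pathway
    cortisol_bmi_corr: float = -0.27
    missing_rate: float = 0.05
    affect_bmi_slope: float = 0.4  # negative-affect response per BMI SD
    delta_hr_stress: float = 6.7   # mean HR increase during Stress, bpm
    ibi_artifact_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_female < 2 or self.n_male < 2:
            raise ValueError("need at least 2 participants per sex")
        for r in (self.diagnosis_rate, self.pretask_responder_rate,
                  self.missing_rate, self.medication_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for params in (self.bmi_female, self.bmi_male):
            _m, sd, lo, hi = params
            if not lo < hi:
                raise ValueError("BMI min must be below max")
            if sd <= 0:
                raise ValueError("BMI SD must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.brain_variance_frac <= 1.0:
            raise ValueError("brain_variance_frac must be in (0, 1]")
        if self.cortisol_bmi_corr >= 0:
            raise ValueError("cortisol_bmi_corr must be negative")

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male

    def marker_names(self) -> list[str]:
        return [f"cyt{i:02d}" for i in range(1, self.n_cytokines + 1)]

    def marker_plan(self) -> tuple[np.ndarray, list[str]]:
        """Per-marker target correlation and pathway label."""
        if self.cytokine_bmi_corr is not None:
            corr = np.asarray(self.cytokine_bmi_corr, dtype=float)
            if corr.size != self.n_cytokines:
                raise ValueError("cytokine_bmi_corr length must match n_cytokines")
            labels = ["independent"] * self.n_cytokines
            return corr, labels
        corr = np.zeros(self.n_cytokines)
        labels = ["independent"] * self.n_cytokines
        n_ind = min(self.n_independent, self.n_cytokines)
        n_bm = min(self.n_brain_mediated, max(self.n_cytokines - n_ind, 0))
        corr[:n_ind] = self.marker_corr
        for i in range(n_ind, n_ind + n_bm):
            corr[i] = self.marker_corr
            labels[i] = "brain_mediated"
        return corr, labels


def _rng(spec: CohortSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), salt])


def _truncnorm_params(mean: float, sd: float, lo: float,
                      hi: float) -> tuple[float, float]:
    """Location/scale of a truncated normal whose *truncated* mean and SD hit
    the targets (truncation shrinks the realized SD, so the scale parameter
    must exceed the target SD)."""
    from scipy.optimize import fsolve

    def eqs(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    (loc, log_scale), info, ier, _msg = fsolve(eqs, [mean, np.log(sd)],
                                               full_output=True)
    if ier != 1:
        # fall back to the naive parameters rather than fail outright
        return mean, sd
    return float(loc), float(np.exp(log_scale))


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def simulate_participants(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject: id, sex, age, BMI (truncated normal within per-sex
    bounds), diagnosis and pre-task responder flags, medication flag, and log
    mean framewise displacement.  Pure function of the spec (incl. its seed)."""
    rng = _rng(spec, 1)
    rows = []
    for sex, n, params in (("female", spec.n_female, spec.bmi_female),
                           ("male", spec.n_male, spec.bmi_male)):
        mean, sd, lo, hi = params
        loc, scale = _truncnorm_params(mean, sd, lo, hi)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        bmi = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                                  random_state=rng)
        age = np.clip(rng.normal(35.0, 12.3, size=n), 18, 70)
        diag = rng.random(n) < spec.diagnosis_rate
        resp = rng.random(n) < spec.pretask_responder_rate
        medication = diag & (rng.random(n) < (spec.medication_rate /
                                              max(spec.diagnosis_rate, 1e-9)))
        # heavier participants move slightly more in the scanner
        log_fd = rng.normal(-1.6, 0.3, size=n) + 0.02 * (bmi - 23.7)
        for i in range(n):
            rows.append((sex, age[i], bmi[i], bool(diag[i]), bool(resp[i]),
                         bool(medication[i]), log_fd[i]))
    df = pd.DataFrame(rows, columns=["sex", "age", "bmi", "diagnosis",
                                     "pretask_responder", "medication",
                                     "log_mean_fd"])
    df.insert(0, "participant_id", [f"sub-{i + 1:03d}" for i in range(len(df))])
    return df


def _bmi_z(participants: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """BMI standardized with the spec's per-sex moments (slope units)."""
    z = np.empty(len(participants))
    for sex, params in (("female", spec.bmi_female), ("male", spec.bmi_male)):
        m = (participants["sex"] == sex).to_numpy()
        z[m] = (participants.loc[m, "bmi"].to_numpy() - params[0]) / params[1]
    return z


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent per-subject trajectory effects and the planted coefficients.

    ``activation``: (n_subj, n_roi, 17) block-activation effects (rest
    timepoints are zero by construction, since offset matching pins the
    resting-state means to the PreStress fixation baseline).
    ``fc``: (n_subj, n_edge, 17) timepoint-specific coupling on top of
    ``fc_baseline``.  ``coef_*`` record the planted slopes (per BMI SD) and
    are zero outside the declared effect features.
    """

    subjects: tuple[str, ...]
    rois: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    activation: np.ndarray
    fc: np.ndarray
    fc_baseline: np.ndarray
    coef_activation: np.ndarray
    coef_fc: np.ndarray
    brain_z: np.ndarray
    other_z: np.ndarray
    planted_mask: np.ndarray
    marker_pathways: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns, nr, ne = len(self.subjects), len(self.rois), len(self.edges)
        nt = len(TIMEPOINTS)
        if self.activation.shape != (ns, nr, nt):
            raise ValueError("activation shape mismatch")
        if self.fc.shape != (ns, ne, nt):
            raise ValueError("fc shape mismatch")
        if self.fc_baseline.shape != (ns, ne):
            raise ValueError("fc_baseline shape mismatch")
        if self.coef_activation.shape != (nr, nt):
            raise ValueError("coef_activation shape mismatch")
        if self.coef_fc.shape != (ne, nt):
            raise ValueError("coef_fc shape mismatch")

    @property
    def brain_signal(self) -> np.ndarray:
        """Standardized planted brain component per subject (zero outside the
        planting group); the quantity brain-mediated markers load on."""
        s = self.brain_z * self.planted_mask
        sd = s.std()
        return s / sd if sd > 0 else s


def make_ground_truth(participants: pd.DataFrame, atlas: RoiAtlas,
                      design: TaskDesign, spec: CohortSpec) -> GroundTruth:
    rng = _rng(spec, 2)
    subjects = tuple(participants["participant_id"])
    rois = atlas.rois
    edges = tuple(atlas.edges())
    ns, nr, ne, nt = len(subjects), len(rois), len(edges), len(TIMEPOINTS)

    z = _bmi_z(participants, spec)
    w = spec.brain_variance_frac
    u = rng.standard_normal(ns)
    brain_z = np.sqrt(w) * z + np.sqrt(1 - w) * u
    other_z = np.sqrt(1 - w) * z - np.sqrt(w) * u
    planted = (participants["sex"] == "female").to_numpy() \
        if spec.female_specific else np.ones(ns, dtype=bool)

    # group-mean activation: per-ROI loading on a PreStress/Stress/PostStress
    # profile, applied to the 15 task blocks only
    phase_level = {"prestress": 0.2, "stress": 0.6, "poststress": 0.3}
    loading = rng.uniform(0.5, 1.5, size=nr)
    mean_act = np.zeros((nr, nt))
    for b in range(1, 16):
        mean_act[:, b] = loading * phase_level[block_phase(b)]
    activation = np.tile(mean_act, (ns, 1, 1))
    dev = rng.normal(0.0, spec.between_sd, size=(ns, nr, 15))
    activation[:, :, 1:16] += dev

    coef_act = np.zeros((nr, nt))
    for (region, b), slope in spec.effect_activation.items():
        cols = [i for i, r in enumerate(rois) if atlas.region[r] == region]
        if not cols:
            raise ValueError(f"effect region {region!r} not in atlas")
        if not 1 <= b <= 15:
            raise ValueError("effect blocks must be 1..15")
        coef_act[cols, b] = slope
    # planted component loads on the brain-visible BMI component only, and
    # only for subjects in the planting group
    activation += (brain_z * planted)[:, None, None] * coef_act[None, :, :]

    # connectivity: baseline coupling plus timepoint-specific modulation
    fc_baseline = 0.15 + rng.normal(0.0, 0.05, size=(ns, ne))
    mean_fc = np.zeros(nt)
    for b in range(6, 11):
        mean_fc[b] = 0.1  # mild coupling increase during Stress blocks
    fc = np.tile(mean_fc, (ns, ne, 1))
    fc += rng.normal(0.0, spec.between_sd_fc, size=(ns, ne, nt))

    coef_fc = np.zeros((ne, nt))
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    for (sn, tp), slope in spec.effect_fc.items():
        rows = [i for i, e in enumerate(edges) if atlas.subnetwork.get(e) == sn]
        if not rows:
            raise ValueError(f"effect subnetwork {sn} has no edges")
        coef_fc[rows, tp_index[tp]] = slope
    fc += (brain_z * planted)[:, None, None] * coef_fc[None, :, :]

    _corr, labels = spec.marker_plan()
    pathways = dict(zip(spec.marker_names(), labels))
    return GroundTruth(subjects, rois, edges, activation, fc, fc_baseline,
                       coef_act, coef_fc, brain_z, other_z, planted, pathways)


# ---------------------------------------------------------------------------
# ROI timeseries
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeseriesSet:
    """Per-subject, per-segment ROI timeseries plus nuisance tables.

    ``data[(subject, segment)]`` is a DataFrame with a ``time_s`` column then
    one column per ROI; ``nuisance`` has matching row counts.
    """

    subjects: tuple[str, ...]
    atlas: RoiAtlas
    design: TaskDesign
    data: dict[tuple[str, str], pd.DataFrame]
    nuisance: dict[tuple[str, str], pd.DataFrame]


NUISANCE_MOTION = tuple(f"mot_{ax}" for ax in
                        ("tx", "ty", "tz", "rx", "ry", "rz"))
NUISANCE_COLS = (NUISANCE_MOTION
                 + tuple(f"dmot_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz"))
                 + tuple(f"comp_{i:02d}" for i in range(1, 11))
                 + ("fd",))


def _segment_timepoint_index(design: TaskDesign, segment: str) -> np.ndarray:
    """Per-volume timepoint index into TIMEPOINTS, -1 where unlabeled."""
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    if segment == "rest1":
        return np.full(design.segment("rest1").n_volumes, tp_index["rest1"])
    if segment == "rest2":
        return np.full(design.segment("rest2").n_volumes, tp_index["rest2"])
    labels = design.task_sample_labels()
    out = np.array([tp_index.get(lb, -1) for lb in labels])
    return out


def simulate_timeseries(participants: pd.DataFrame, truth: GroundTruth,
                        design: TaskDesign, spec: CohortSpec) -> RoiTimeseriesSet:
    """Generate three-segment ROI timeseries realizing the ground truth."""
    atlas_rois = truth.rois
    subjects = list(participants["participant_id"])
    if tuple(subjects) != truth.subjects:
        raise ValueError("participants do not match ground truth subjects")
    rng = _rng(spec, 3)
    nr = len(atlas_rois)
    roi_pos = {r: i for i, r in enumerate(atlas_rois)}
    dep = [roi_pos[a] for a, _ in truth.edges]
    pred = [roi_pos[b] for _, b in truth.edges]

    data: dict[tuple[str, str], pd.DataFrame] = {}
    nuis: dict[tuple[str, str], pd.DataFrame] = {}
    log_fd = participants["log_mean_fd"].to_numpy()
    for s_i, sub in enumerate(subjects):
        drift = rng.normal(0.0, spec.drift_amp, size=nr)
        level = rng.normal(500.0, 10.0, size=nr)
        w_nuis = rng.normal(0.0, spec.nuisance_amp, size=(4, nr))
        for seg in SEGMENTS:
            seginfo = design.segment(seg)
            T = seginfo.n_volumes
            times = seginfo.times()
            tp = _segment_timepoint_index(design, seg)

            intrinsic = rng.normal(0.0, spec.intrinsic_sd, size=(T, nr))
            sig = intrinsic.copy()
            # block-activation: group mean + subject deviation at each
            # labelled sample
            lab = tp >= 0
            act = np.zeros((T, nr))
            act[lab] = truth.activation[s_i][:, tp[lab]].T
            sig += act
            # edge coupling: dependent ROI receives coupling * predictor
            # intrinsic signal; coupling = baseline + timepoint modulation
            coup = np.zeros((T, len(truth.edges)))
            coup += truth.fc_baseline[s_i][None, :]
            coup[lab] += truth.fc[s_i][:, tp[lab]].T
            contrib = coup * intrinsic[:, pred]
            for e_i, d in enumerate(dep):
                sig[:, d] += contrib[:, e_i]

            # nuisance table and its leakage into the signal
            fd_scale = float(np.exp(log_fd[s_i]))
            motion = np.cumsum(rng.normal(0.0, 0.02 * fd_scale / 0.2,
                                          size=(T, 6)), axis=0)
            dmot = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
            comps = rng.normal(0.0, 1.0, size=(T, 10))
            fd = np.abs(dmot).sum(axis=1)
            ntab = pd.DataFrame(
                np.column_stack([motion, dmot, comps, fd]),
                columns=list(NUISANCE_COLS))
            z_sel = np.column_stack([motion[:, 0], motion[:, 5],
                                     comps[:, 0], comps[:, 5]])
            sig += z_sel @ w_nuis

            sig += level[None, :] + drift[:, None].T * times[:, None]
            if spec.noise_sd > 0:
                sig += rng.normal(0.0, spec.noise_sd, size=(T, nr))

            df = pd.DataFrame(sig, columns=list(atlas_rois))
            df.insert(0, "time_s", times)
            data[(sub, seg)] = df
            nuis[(sub, seg)] = ntab
    return RoiTimeseriesSet(tuple(subjects), _atlas_from_truth(truth),
                            design, data, nuis)


def _atlas_from_truth(truth: GroundTruth) -> RoiAtlas:
    # minimal atlas reconstruction (region/hemisphere unknown -> identity);
    # callers that need the real atlas should pass it along explicitly
    return RoiAtlas(truth.rois, {r: r for r in truth.rois},
                    {r: "m" for r in truth.rois},
                    {e: 1 for e in truth.edges})


# ---------------------------------------------------------------------------
# peripheral markers
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerTables:
    cytokines: pd.DataFrame          # participant_id, batch, marker columns
    detection_limits: pd.DataFrame   # marker, lower, upper
    baseline_cortisol: pd.DataFrame  # participant_id, cortisol_nmol_l
    cortisol: pd.DataFrame           # participant_id, T0, T1, T2, T6, T8
    affect: pd.DataFrame             # participant_id, timepoint, 15 items
    ibi: pd.DataFrame                # participant_id, block_index, ibi_s
    marker_pathways: dict[str, str]


def simulate_biomarkers(participants: pd.DataFrame, truth: GroundTruth,
                        spec: CohortSpec) -> BiomarkerTables:
    rng = _rng(spec, 4)
    n = len(participants)
    ids = participants["participant_id"].to_numpy()
    bmi = participants["bmi"].to_numpy()
    z_bmi = (bmi - bmi.mean()) / bmi.std()

    corr, labels = spec.marker_plan()
    brain = truth.brain_signal
    other = (truth.other_z - truth.other_z.mean()) / truth.other_z.std()

    names = spec.marker_names()
    panel = {}
    limits = []
    for j, name in enumerate(names):
        driver = brain if labels[j] == "brain_mediated" else other
        c = float(corr[j])
        zm = c * driver + np.sqrt(max(1 - c * c, 0.0)) * rng.standard_normal(n)
        raw = np.exp(1.5 + 0.8 * zm)  # skewed assay-like concentrations
        batch_eff = rng.normal(0.0, 0.3)
        raw = raw * np.exp(batch_eff * (np.arange(n) % 2))
        lo, hi = np.percentile(raw, [2.5, 97.5])
        miss = rng.random(n) < spec.missing_rate
        raw = raw.astype(object)
        raw[miss] = np.nan
        panel[name] = raw
        limits.append((name, lo, hi))
    cyt = pd.DataFrame(panel)
    cyt.insert(0, "batch", np.where(np.arange(n) % 2 == 0, "A", "B"))
    cyt.insert(0, "participant_id", ids)
    cyt = cyt.astype({name: float for name in names})
    limits_df = pd.DataFrame(limits, columns=["marker", "lower", "upper"])

    # baseline (morning plasma) cortisol, negatively correlated with BMI
    rc = spec.cortisol_bmi_corr
    cz = rc * z_bmi + np.sqrt(1 - rc * rc) * rng.standard_normal(n)
    baseline = pd.DataFrame({
        "participant_id": ids,
        "cortisol_nmol_l": np.clip(350.0 + 80.0 * cz, 50.0, None),
    })

    # salivary cortisol series: responders rise > 2.5 nmol/l before the task
    resp = participants["pretask_responder"].to_numpy()
    t0 = np.clip(rng.normal(6.0, 1.5, size=n), 1.0, None)
    rise = np.where(resp, 3.0 + np.abs(rng.normal(0.0, 0.8, size=n)),
                    np.clip(rng.normal(0.3, 0.6, size=n), None, 2.0))
    t1 = np.clip(t0 + rise, 0.5, None)
    t2 = np.clip(t0 + 0.3 * rise + rng.normal(0.0, 0.4, size=n), 0.5, None)
    bump = np.clip(rng.normal(1.2, 0.9, size=n), -0.5, None)
    t6 = np.clip(t2 + bump, 0.5, None)
    t8 = np.clip(t2 + 0.2 * bump + rng.normal(0.0, 0.4, size=n), 0.5, None)
    cortisol = pd.DataFrame({"participant_id": ids, "T0": t0, "T1": t1,
                             "T2": t2, "T6": t6, "T8": t8})

    # affect ratings: one latent factor per scale (loading 0.6), BMI-scaled
    # negative-affect response after stress in the planting group
    z_planted = z_bmi * truth.planted_mask
    neg_resp = {"T3": 0.0, "T6": 1.2, "T8": 0.4}
    pos_resp = {"T3": 0.0, "T6": -0.8, "T8": -0.3}
    bmi_gain = {"T3": 0.0, "T6": spec.affect_bmi_slope,
                "T8": spec.affect_bmi_slope * 0.8}
    rows = []
    for tp in AFFECT_TIMEPOINTS:
        f_pos = rng.standard_normal(n)
        f_neg = rng.standard_normal(n)
        for i in range(n):
            vals = {}
            for item in POSITIVE_ITEMS:
                lat = 4.0 + pos_resp[tp] + 0.6 * f_pos[i] + rng.normal(0, 0.8)
                vals[item] = int(np.clip(round(lat), 1, 6))
            for item in NEGATIVE_ITEMS:
                lat = (2.0 + neg_resp[tp] + bmi_gain[tp] * z_planted[i]
                       + 0.6 * f_neg[i] + rng.normal(0, 0.8))
                vals[item] = int(np.clip(round(lat), 1, 6))
            rows.append({"participant_id": ids[i], "timepoint": tp, **vals})
    affect = pd.DataFrame(rows, columns=["participant_id", "timepoint",
                                         *AFFECT_ITEMS])

    # interbeat intervals per task block with injected artifacts
    hr_pre = rng.normal(70.0, 8.0, size=n)
    d_stress = rng.normal(spec.delta_hr_stress, 2.0, size=n)
    d_post = rng.normal(0.9, 1.5, size=n)
    ibi_rows = []
    for i in range(n):
        for b in range(1, 16):
            phase = block_phase(b)
            hr = hr_pre[i] + (d_stress[i] if phase == "stress"
                              else d_post[i] if phase == "poststress" else 0.0)
            base = 60.0 / max(hr, 30.0)
            t = 0.0
            while t < 60.0:
                ibi = max(base + rng.normal(0.0, 0.03), 0.35)
                u = rng.random()
                if u < spec.ibi_artifact_rate:
                    ibi = 2.0 * ibi  # missed beat
                elif u < 2 * spec.ibi_artifact_rate:
                    ibi = 0.25      # spurious detection
                ibi_rows.append((ids[i], b, ibi))
                t += ibi
    ibi = pd.DataFrame(ibi_rows, columns=["participant_id", "block_index",
                                          "ibi_s"])
    return BiomarkerTables(cyt, limits_df, baseline, cortisol, affect, ibi,
                           dict(truth.marker_pathways))


# ---------------------------------------------------------------------------
# feature-level shortcut
# ---------------------------------------------------------------------------

def simulate_feature_matrix(participants: pd.DataFrame, truth: GroundTruth,
                            atlas: RoiAtlas, spec: CohortSpec,
                            estimation_noise_sd: float = 0.2,
                            mode: str = "combined"):
    """Spatio-temporal feature matrix taken directly from the ground-truth
    latents plus estimation noise.

    Emulates what the edge-model + aggregation stage recovers, without the
    cost of generating and fitting full timeseries — used for experiments that
    exercise the prediction and decomposition stages.
    """
    from .features import FeatureMatrix, assemble_feature_matrix

    rng = _rng(spec, 5)
    ids = list(participants["participant_id"])
    roi_pos = {r: i for i, r in enumerate(truth.rois)}

    act_cols = {}
    for region in atlas.regions:
        pos = [roi_pos[r] for r in atlas.rois_of_region(region)]
        for b in range(1, 16):
            vals = truth.activation[:, pos, b].mean(axis=1)
            vals = vals + rng.normal(0.0, estimation_noise_sd, size=len(ids))
            act_cols[f"act|{region}|block{b:02d}"] = vals
    act = FeatureMatrix(pd.DataFrame(act_cols, index=ids))

    edge_pos = {e: i for i, e in enumerate(truth.edges)}
    fc_cols = {}
    for k in atlas.subnetworks:
        pos = [edge_pos[e] for e in atlas.edges_of_subnetwork(k)]
        for t_i, tp in enumerate(TIMEPOINTS):
            vals = truth.fc[:, pos, t_i].mean(axis=1)
            vals = vals + rng.normal(0.0, estimation_noise_sd, size=len(ids))
            fc_cols[f"fc|sn{k}|{tp}"] = vals
    fc = FeatureMatrix(pd.DataFrame(fc_cols, index=ids))
    return assemble_feature_matrix(act, fc, mode=mode)


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

def export_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as TSV + JSON metadata; round-trips losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def wide(arr3: np.ndarray, row_labels: list[tuple], label_cols: list[str],
             fname: str) -> None:
        nt = arr3.shape[-1]
        flat = arr3.reshape(-1, nt)
        df = pd.DataFrame(flat, columns=list(TIMEPOINTS[:nt]))
        for c, vals in zip(reversed(label_cols),
                           reversed(list(zip(*row_labels)))):
            df.insert(0, c, list(vals))
        df.to_csv(path / fname, sep="\t", index=False, float_format="%.17g")

    subj_roi = [(s, r) for s in truth.subjects for r in truth.rois]
    wide(truth.activation, subj_roi, ["subject", "roi"], "activation.tsv")
    subj_edge = [(s, a, b) for s in truth.subjects for a, b in truth.edges]
    wide(truth.fc, subj_edge, ["subject", "roi_a", "roi_b"], "fc.tsv")
    base = pd.DataFrame(truth.fc_baseline,
                        columns=[f"{a}--{b}" for a, b in truth.edges])
    base.insert(0, "subject", list(truth.subjects))
    base.to_csv(path / "fc_baseline.tsv", sep="\t", index=False, float_format="%.17g")
    ca = pd.DataFrame(truth.coef_activation, columns=list(TIMEPOINTS))
    ca.insert(0, "roi", list(truth.rois))
    ca.to_csv(path / "coef_activation.tsv", sep="\t", index=False, float_format="%.17g")
    cf = pd.DataFrame(truth.coef_fc, columns=list(TIMEPOINTS))
    cf.insert(0, "edge", [f"{a}--{b}" for a, b in truth.edges])
    cf.to_csv(path / "coef_fc.tsv", sep="\t", index=False, float_format="%.17g")
    lat = pd.DataFrame({"subject": list(truth.subjects),
                        "brain_z": truth.brain_z, "other_z": truth.other_z,
                        "planted": truth.planted_mask.astype(int)})
    lat.to_csv(path / "subject_latents.tsv", sep="\t", index=False, float_format="%.17g")
    meta = {"rois": list(truth.rois),
            "edges": [[a, b] for a, b in truth.edges],
            "marker_pathways": truth.marker_pathways}
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    rois = tuple(meta["rois"])
    edges = tuple((a, b) for a, b in meta["edges"])
    nt = len(TIMEPOINTS)

    act_df = pd.read_csv(path / "activation.tsv", sep="\t", float_precision="round_trip")
    subjects = tuple(dict.fromkeys(act_df["subject"]))
    ns, nr, ne = len(subjects), len(rois), len(edges)
    activation = act_df[list(TIMEPOINTS)].to_numpy().reshape(ns, nr, nt)
    fc_df = pd.read_csv(path / "fc.tsv", sep="\t", float_precision="round_trip")
    fc = fc_df[list(TIMEPOINTS)].to_numpy().reshape(ns, ne, nt)
    base = pd.read_csv(path / "fc_baseline.tsv", sep="\t", float_precision="round_trip")
    fc_baseline = base.drop(columns="subject").to_numpy()
    ca = pd.read_csv(path / "coef_activation.tsv", sep="\t", float_precision="round_trip")
    coef_act = ca[list(TIMEPOINTS)].to_numpy()
    cf = pd.read_csv(path / "coef_fc.tsv", sep="\t", float_precision="round_trip")
    coef_fc = cf[list(TIMEPOINTS)].to_numpy()
    lat = pd.read_csv(path / "subject_latents.tsv", sep="\t", float_precision="round_trip")
    return GroundTruth(subjects, rois, edges, activation, fc, fc_baseline,
                       coef_act, coef_fc, lat["brain_z"].to_numpy(),
                       lat["other_z"].to_numpy(),
                       lat["planted"].to_numpy().astype(bool),
                       dict(meta["marker_pathways"]))


def ground_truth_checksum(truth: GroundTruth) -> str:
    h = hashlib.sha256()
    for arr in (truth.activation, truth.fc, truth.fc_baseline,
                truth.coef_activation, truth.coef_fc, truth.brain_z,
                truth.other_z, truth.planted_mask.astype(np.int64)):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# orchestration and file export
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: CohortSpec
    design: TaskDesign
    atlas: RoiAtlas
    participants: pd.DataFrame
    truth: GroundTruth
    timeseries: RoiTimeseriesSet
    markers: BiomarkerTables


def simulate_cohort(spec: CohortSpec, design: TaskDesign | None = None,
                    atlas: RoiAtlas | None = None,
                    with_timeseries: bool = True) -> Cohort:
    """Generate a full synthetic cohort (all tables; pure function of spec)."""
    design = design or TaskDesign.default()
    atlas = atlas or RoiAtlas.stress_network()
    participants = simulate_participants(spec)
    truth = make_ground_truth(participants, atlas, design, spec)
    ts = (simulate_timeseries(participants, truth, design, spec)
          if with_timeseries else
          RoiTimeseriesSet(truth.subjects, atlas, design, {}, {}))
    ts = replace(ts, atlas=atlas)
    markers = simulate_biomarkers(participants, truth, spec)
    return Cohort(spec, design, atlas, participants, truth, ts, markers)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the package's TSV + JSON-sidecar layout."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    cohort.design.events_frame().to_csv(out / "events.tsv", sep="\t",
                                        index=False)
    cohort.atlas.write(out)
    m = cohort.markers
    m.cytokines.to_csv(out / "cytokines.tsv", sep="\t", index=False)
    m.detection_limits.to_csv(out / "detection_limits.tsv", sep="\t",
                              index=False)
    m.baseline_cortisol.to_csv(out / "cortisol_baseline.tsv", sep="\t",
                               index=False)
    m.cortisol.to_csv(out / "cortisol.tsv", sep="\t", index=False)
    m.affect.to_csv(out / "affect.tsv", sep="\t", index=False)
    m.ibi.to_csv(out / "ibi.tsv", sep="\t", index=False)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for (sub, seg), df in cohort.timeseries.data.items():
        stem = f"{sub}_{seg}"
        df.to_csv(ts_dir / f"{stem}.tsv", sep="\t", index=False)
        tr = cohort.design.segment(seg).tr
        (ts_dir / f"{stem}.json").write_text(json.dumps(
            {"subject": sub, "segment": seg, "repetition_time_s": tr}))
        cohort.timeseries.nuisance[(sub, seg)].to_csv(
            ts_dir / f"{stem}_nuisance.tsv", sep="\t", index=False)
    export_ground_truth(cohort.truth, out / "truth")
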