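"""Segment denoising and rest-task-rest concatenation.

Each segment is linearly detrended (no quadratic term, which could absorb the
task's non-stress/stress/non-stress profile), despiked by winsorizing against
a running median, residualized against the nuisance table, and demeaned.  The
three segments are then concatenated with baseline offset matching: the mean
over PreStress fixation samples is subtracted from the whole task segment, and
each flanking resting-state is shifted so its mean equals that (now zero)
baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .design import SEGMENTS, TIMEPOINTS, TaskDesign
from .synthetic import RoiTimeseriesSet


@dataclass
class SegmentTimeseries:
    """One subject's ROI timeseries for one segment."""

    subject: str
    segment: str  # rest1 / task / rest2
    tr: float
    data: pd.DataFrame  # rows = volumes, columns = ROI labels
    times: np.ndarray   # seconds, strictly increasing

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if len(self.times) != len(self.data):
            raise ValueError("times and data length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.data.isna().any().any():
            raise ValueError("missing samples are not allowed")

    @property
    def rois(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_table(cls, subject: str, segment: str, tr: float,
                   table: pd.DataFrame) -> "SegmentTimeseries":
        """Build from the external TSV layout (time_s column + ROI columns)."""
        times = table["time_s"].to_numpy(dtype=float)
        return cls(subject, segment, tr, table.drop(columns="time_s"), times)


@dataclass
class ConcatenatedTimeseries:
    """Concatenated rest1-task-rest2 series with per-sample annotation.

    ``timepoint`` holds one of the 17 trajectory labels, ``task_fixation`` for
    fixation samples inside the task, or ``gap`` for unlabeled task samples;
    ``segment`` holds rest1/task/rest2.  ``prestress_fixation`` flags the
    offset-matching baseline samples.
    """

    subject: str
    data: pd.DataFrame
    times: np.ndarray
    segment: np.ndarray     # object array of segment names
    timepoint: np.ndarray   # object array of annotations
    prestress_fixation: np.ndarray  # bool mask

    @property
    def rois(self) -> list[str]:
        return list(self.data.columns)

    def timepoint_indicators(self) -> np.ndarray:
        """(n_samples, 17) indicator matrix over the trajectory timepoints."""
        return np.column_stack([(self.timepoint == tp).astype(float)
                                for tp in TIMEPOINTS])

    def to_table(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "timepoint", self.timepoint)
        out.insert(0, "segment", self.segment)
        out.insert(0, "time_s", self.times)
        return out

    @classmethod
    def from_table(cls, subject: str, table: pd.DataFrame,
                   design: TaskDesign) -> "ConcatenatedTimeseries":
        seg = table["segment"].to_numpy(dtype=object)
        tp = table["timepoint"].to_numpy(dtype=object)
        times = table["time_s"].to_numpy(dtype=float)
        data = table.drop(columns=["time_s", "segment", "timepoint"])
        fix_mask = np.zeros(len(table), dtype=bool)
        task_rows = np.flatnonzero(seg == "task")
        fix = design.prestress_fixation_mask()
        fix_mask[task_rows] = fix
        return cls(subject, data.reset_index(drop=True), times, seg, tp,
                   fix_mask)


# ---------------------------------------------------------------------------
# per-segment denoising
# ---------------------------------------------------------------------------

def _drop_collinear(z: np.ndarray, cols: list[str],
                    tol: float = 1e-10) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    keep: list[int] = []
    for j in range(z.shape[1]):
        cand = z[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(z.shape)) == len(keep) + 1:
            keep.append(j)
    dropped = [cols[j] for j in range(z.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping collinear nuisance columns: {dropped}",
                      stacklevel=3)
    return z[:, keep], dropped


def preprocess_segment(ts: SegmentTimeseries, nuisance: pd.DataFrame | None,
                       despike_k: float = 4.0,
                       despike_window: int = 11) -> SegmentTimeseries:
    """Detrend, despike, residualize against nuisance regressors, demean.

    Despiking winsorizes samples further than ``despike_k`` robust standard
    deviations (1.4826 x MAD) from a running median of ``despike_window``
    samples.
    """
    x = ts.data.to_numpy(dtype=float).copy()
    t = ts.times
    n = len(t)
    if nuisance is not None and len(nuisance) != n:
        raise ValueError("nuisance rows must match segment volumes")

    # linear detrend (explicitly no quadratic term)
    dm = np.column_stack([np.ones(n), t - t.mean()])
    beta, *_ = np.linalg.lstsq(dm, x, rcond=None)
    x = x - dm @ beta

    # despike: winsorize against a running median
    med = median_filter(x, size=(despike_window, 1), mode="nearest")
    resid = x - med
    mad = np.median(np.abs(resid), axis=0)
    sigma = 1.4826 * mad
    lim = despike_k * np.where(sigma > 0, sigma, np.inf)
    x = np.clip(x, med - lim, med + lim)

    # project out nuisance regressors
    if nuisance is not None and nuisance.shape[1] > 0:
        z = nuisance.to_numpy(dtype=float)
        z = z - z.mean(axis=0)
        z, _dropped = _drop_collinear(z, list(nuisance.columns))
        if z.shape[1] > 0:
            coef, *_ = np.linalg.lstsq(z, x, rcond=None)
            x = x - z @ coef

    x = x - x.mean(axis=0)
    return SegmentTimeseries(ts.subject, ts.segment, ts.tr,
                             pd.DataFrame(x, columns=ts.rois), t.copy())


# ---------------------------------------------------------------------------
# offset matching and concatenation
# ---------------------------------------------------------------------------

def match_offsets(rest1: SegmentTimeseries, task: SegmentTimeseries,
                  rest2: SegmentTimeseries,
                  design: TaskDesign) -> ConcatenatedTimeseries:
    """Concatenate the three segments with baseline offset matching.

    Per ROI the mean over PreStress fixation samples is subtracted from the
    entire task segment; each resting-state is shifted so its own mean equals
    that (now zero) baseline.  Within-segment differences are untouched.
    """
    if not (rest1.rois == task.rois == rest2.rois):
        raise ValueError("segments must share the same ROI set")
    subject = task.subject
    fix = design.prestress_fixation_mask()
    if len(fix) != len(task.data):
        raise ValueError("design does not match task segment length")

    task_x = task.data.to_numpy(dtype=float)
    offset = task_x[fix].mean(axis=0)
    task_x = task_x - offset
    r1 = rest1.data.to_numpy(dtype=float)
    r1 = r1 - r1.mean(axis=0)
    r2 = rest2.data.to_numpy(dtype=float)
    r2 = r2 - r2.mean(axis=0)

    task_labels = design.task_sample_labels()
    parts, labels, segs, times = [], [], [], []
    t0 = 0.0
    for seg_ts, x, lab in (
            (rest1, r1, np.full(len(r1), "rest1", dtype=object)),
            (task, task_x, task_labels),
            (rest2, r2, np.full(len(r2), "rest2", dtype=object))):
        parts.append(x)
        labels.append(lab)
        segs.append(np.full(len(x), seg_ts.segment, dtype=object))
        times.append(seg_ts.times + t0)
        t0 = times[-1][-1] + seg_ts.tr

    data = pd.DataFrame(np.vstack(parts), columns=task.rois)
    fix_mask = np.concatenate([np.zeros(len(r1), dtype=bool), fix,
                               np.zeros(len(r2), dtype=bool)])
    return ConcatenatedTimeseries(subject, data, np.concatenate(times),
                                  np.concatenate(segs),
                                  np.concatenate(labels), fix_mask)


def preprocess_and_concatenate(ts_set: RoiTimeseriesSet,
                               despike_k: float = 4.0
                               ) -> list[ConcatenatedTimeseries]:
    """Run the full per-subject preparation on an in-memory timeseries set."""
    out = []
    for sub in ts_set.subjects:
        segs = {}
        for seg in SEGMENTS:
            tr = ts_set.design.segment(seg).tr
            st = SegmentTimeseries.from_table(sub, seg, tr,
                                              ts_set.data[(sub, seg)])
            segs[seg] = preprocess_segment(st, ts_set.nuisance[(sub, seg)],
                                           despike_k=despike_k)
        out.append(match_offsets(segs["rest1"], segs["task"], segs["rest2"],
                                 ts_set.design))
    return out


# ---------------------------------------------------------------------------
# cohort-level file driver
# ---------------------------------------------------------------------------

@dataclass
class ConcatenationReport:
    written: list[str]
    excluded: dict[str, str]  # subject -> reason


def concatenate_cohort(in_dir: str | Path, out_dir: str | Path,
                       design: TaskDesign,
                       despike_k: float = 4.0) -> ConcatenationReport:
    """Concatenate every subject found under ``in_dir/timeseries``.

    Subjects with missing segment files are skipped and reported, mirroring
    per-analysis exclusion of incomplete cases.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    ts_dir = in_dir / "timeseries" if (in_dir / "timeseries").exists() else in_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    subjects = sorted({p.name.rsplit("_", 1)[0] for p in ts_dir.glob("*_*.tsv")
                       if not p.name.endswith("_nuisance.tsv")})
    written, excluded = [], {}
    if not subjects:
        warnings.warn(f"no segment files found under {ts_dir}")
    for sub in subjects:
        missing = [seg for seg in SEGMENTS
                   if not (ts_dir / f"{sub}_{seg}.tsv").exists()]
        if missing:
            excluded[sub] = f"missing segments: {', '.join(missing)}"
            continue
        segs = {}
        for seg in SEGMENTS:
            table = pd.read_csv(ts_dir / f"{sub}_{seg}.tsv", sep="\t")
            sidecar = ts_dir / f"{sub}_{seg}.json"
            tr = (json.loads(sidecar.read_text())["repetition_time_s"]
                  if sidecar.exists() else design.segment(seg).tr)
            st = SegmentTimeseries.from_table(sub, seg, tr, table)
            npath = ts_dir / f"{sub}_{seg}_nuisance.tsv"
            nuisance = pd.read_csv(npath, sep="\t") if npath.exists() else None
            segs[seg] = preprocess_segment(st, nuisance, despike_k=despike_k)
        concat = match_offsets(segs["rest1"], segs["task"], segs["rest2"],
                               design)
        concat.to_table().to_csv(out_dir / f"{sub}_concat.tsv", sep="\t",
                                 index=False)
        written.append(sub)
    return ConcatenationReport(written, excluded)
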