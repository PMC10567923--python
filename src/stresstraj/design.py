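"""Block design of the psycho-social stress session.

The session is three fMRI segments in fixed order: a flanking resting-state,
the arithmetic stress task, and a second flanking resting-state.  The task
segment holds 15 arithmetic blocks (5 PreStress, 5 Stress, 5 PostStress)
interleaved with fixation-cross rest blocks.  Together with the two resting
states this yields 17 "timepoints" along which activation and connectivity
trajectories are estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENTS = ("rest1", "task", "rest2")

#: the 17 trajectory timepoints, in temporal/design order
TIMEPOINTS = ("rest1",) + tuple(f"block{i:02d}" for i in range(1, 16)) + ("rest2",)

PHASES = ("prestress", "stress", "poststress")
TASK_CONDITIONS = ("prestress_task", "stress_task", "poststress_task")


@dataclass(frozen=True)
class Segment:
    name: str
    tr: float  # repetition time, seconds
    n_volumes: int

    @property
    def duration(self) -> float:
        return self.tr * self.n_volumes

    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr


@dataclass(frozen=True)
class Block:
    onset: float  # seconds within the task segment
    duration: float
    condition: str  # prestress_task / stress_task / poststress_task / rest_fixation
    block_index: int  # 1..15 for task blocks, 0 for fixation


@dataclass(frozen=True)
class TaskDesign:
    """Segment layout, task/fixation blocks, and auxiliary events.

    ``auxiliary_events`` are (onset, duration, kind) tuples within the task
    segment; kinds are ``motor_response`` and ``verbal_feedback``.
    """

    segments: tuple[Segment, Segment, Segment]
    blocks: tuple[Block, ...]
    auxiliary_events: tuple[tuple[float, float, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = tuple(s.name for s in self.segments)
        if names != SEGMENTS:
            raise ValueError(f"segments must be {SEGMENTS} in order, got {names}")
        task_blocks = [b for b in self.blocks if b.condition != "rest_fixation"]
        if len(task_blocks) != 15:
            raise ValueError(f"expected 15 task blocks, got {len(task_blocks)}")
        for phase, cond in zip(PHASES, TASK_CONDITIONS):
            n = sum(b.condition == cond for b in task_blocks)
            if n != 5:
                raise ValueError(f"expected 5 {cond} blocks, got {n}")
        idx = sorted(b.block_index for b in task_blocks)
        if idx != list(range(1, 16)):
            raise ValueError("task block_index must be 1..15")
        end = self.task_segment.duration
        for b in self.blocks:
            if b.onset < 0 or b.onset + b.duration > end + 1e-9:
                raise ValueError("block extends beyond task segment bounds")
        for onset, dur, _kind in self.auxiliary_events:
            if onset < 0 or onset + dur > end + 1e-9:
                raise ValueError("auxiliary event beyond task segment bounds")

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls) -> "TaskDesign":
        """Acquisition layout of the study: rest 155 volumes @ 2.5 s, task 755
        volumes @ 2.0 s, 60 s arithmetic blocks interleaved with 40 s fixation."""
        return cls.custom(task_block_s=60.0, fixation_s=40.0, lead_s=5.0,
                          tr_task=2.0, tr_rest=2.5, rest_volumes=155,
                          task_volumes=755)

    @classmethod
    def compact(cls, task_block_s: float = 20.0, fixation_s: float = 6.0,
                lead_s: float = 4.0, tr_task: float = 2.0, tr_rest: float = 2.5,
                rest_volumes: int = 40) -> "TaskDesign":
        """A shortened design with the same 15-block structure, for small
        simulation studies where full-length segments are unnecessary."""
        return cls.custom(task_block_s=task_block_s, fixation_s=fixation_s,
                          lead_s=lead_s, tr_task=tr_task, tr_rest=tr_rest,
                          rest_volumes=rest_volumes)

    @classmethod
    def custom(cls, task_block_s: float, fixation_s: float, lead_s: float,
               tr_task: float, tr_rest: float, rest_volumes: int,
               task_volumes: int | None = None) -> "TaskDesign":
        blocks: list[Block] = []
        events: list[tuple[float, float, str]] = []
        t = lead_s
        k = 0
        for cond in TASK_CONDITIONS:
            for _ in range(5):
                k += 1
                blocks.append(Block(t, task_block_s, cond, k))
                # button presses roughly every 6 s while solving arithmetic
                m = t + 2.0
                while m + 0.5 <= t + task_block_s:
                    events.append((m, 0.5, "motor_response"))
                    m += 6.0
                t += task_block_s
                blocks.append(Block(t, fixation_s, "rest_fixation", 0))
                if cond == "stress_task" and fixation_s > 3.0:
                    events.append((t + 1.0, min(4.0, fixation_s - 2.0),
                                   "verbal_feedback"))
                t += fixation_s
        needed = math.ceil(t / tr_task)
        n_task = needed if task_volumes is None else task_volumes
        if n_task < needed:
            raise ValueError("task_volumes too small for the block layout")
        segs = (Segment("rest1", tr_rest, rest_volumes),
                Segment("task", tr_task, n_task),
                Segment("rest2", tr_rest, rest_volumes))
        return cls(segments=segs, blocks=tuple(blocks),
                   auxiliary_events=tuple(events))

    # -- accessors --------------------------------------------------------

    @property
    def task_segment(self) -> Segment:
        return self.segments[1]

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def task_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition != "rest_fixation"]

    def fixation_blocks(self, phase: str | None = None) -> list[Block]:
        """Fixation blocks, optionally restricted to one phase.  A fixation
        block belongs to the phase of the task block that precedes it."""
        out = []
        last_cond = None
        for b in self.blocks:
            if b.condition == "rest_fixation":
                if phase is None:
                    out.append(b)
                elif last_cond == f"{phase}_task":
                    out.append(b)
            else:
                last_cond = b.condition
        return out

    def task_sample_labels(self) -> np.ndarray:
        """Per-volume annotation of the task segment.

        Returns an object array with values ``block01``..``block15`` for
        samples inside arithmetic blocks, ``task_fixation`` inside fixation
        blocks, and ``gap`` elsewhere (lead-in, feedback tail)."""
        seg = self.task_segment
        times = seg.times()
        labels = np.full(seg.n_volumes, "gap", dtype=object)
        for b in self.blocks:
            inside = (times >= b.onset) & (times < b.onset + b.duration)
            if b.condition == "rest_fixation":
                labels[inside] = "task_fixation"
            else:
                labels[inside] = f"block{b.block_index:02d}"
        return labels

    def prestress_fixation_mask(self) -> np.ndarray:
        """Boolean mask over task-segment volumes: PreStress fixation samples,
        the baseline against which all segments are offset-matched."""
        seg = self.task_segment
        times = seg.times()
        mask = np.zeros(seg.n_volumes, dtype=bool)
        fix = self.fixation_blocks("prestress")
        if not fix:
            raise ValueError("design has no PreStress fixation blocks")
        for b in fix:
            mask |= (times >= b.onset) & (times < b.onset + b.duration)
        return mask

    def events_frame(self) -> pd.DataFrame:
        """Block-design events table (onset, duration, trial_type, block_index)."""
        rows = [(b.onset, b.duration, b.condition, b.block_index)
                for b in self.blocks]
        rows += [(o, d, kind, 0) for o, d, kind in self.auxiliary_events]
        df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                         "block_index"])
        return df.sort_values("onset", kind="stable").reset_index(drop=True)

    @classmethod
    def from_events_frame(cls, events: pd.DataFrame,
                          segments: tuple[Segment, Segment, Segment]) -> "TaskDesign":
        blocks = []
        aux = []
        for _, r in events.iterrows():
            if r["trial_type"] in ("motor_response", "verbal_feedback"):
                aux.append((float(r["onset"]), float(r["duration"]),
                            str(r["trial_type"])))
            else:
                blocks.append(Block(float(r["onset"]), float(r["duration"]),
                                    str(r["trial_type"]), int(r["block_index"])))
        return cls(segments=segments, blocks=tuple(blocks),
                   auxiliary_events=tuple(aux))


def block_phase(block_index: int) -> str:
    """Phase of a task block: 1-5 PreStress, 6-10 Stress, 11-15 PostStress."""
    if not 1 <= block_index <= 15:
        raise ValueError("block_index must be 1..15")
    return PHASES[(block_index - 1) // 5]
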