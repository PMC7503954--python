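"""Task timelines and GLM design information.

Three neuropsychological protocols are modelled:

* SWG (silent word generation): 5 blocks, each 3 x 10 s letter slides
  (stimulation) and 3 x 10 s nonsense-symbol slides (within-task baseline),
  flanked by 1-min rests.
* DS backward (digit span): a single unstructured task epoch whose duration
  depends on performance (the task stops on two consecutive errors), flanked
  by 1-min rests.
* SS (symbol search): a single 2-min unstructured epoch, flanked by
  1-min rests.

Unstructured epochs have no stimulation/rest alternation, so they are
analysed with the window-variance statistic rather than the GLM; the 1 min
of rest before the task serves as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_SAMPLING_RATE

__all__ = [
    "EventTable",
    "TaskDesign",
    "build_swg",
    "build_unstructured",
    "design_vector",
]


class ProtocolError(ValueError):
    """Invalid task timeline."""


@dataclass
class EventTable:
    """Sorted, non-overlapping labeled epochs (label, onset s, duration s)."""

    events: list
    total_duration: float
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self):
        evs = sorted(
            [(str(l), float(o), float(d)) for l, o, d in self.events],
            key=lambda e: e[1],
        )
        prev_end = 0.0
        for label, onset, dur in evs:
            if onset < -1e-9 or onset + dur > self.total_duration + 1e-9:
                raise ProtocolError(f"event {label!r} outside [0, total_duration]")
            if onset < prev_end - 1e-9:
                raise ProtocolError(f"event {label!r} overlaps its predecessor")
            prev_end = onset + dur
        self.events = evs

    def to_csv(self, path) -> None:
        pd.DataFrame(self.events, columns=["label", "onset", "duration"]).to_csv(
            path, index=False, float_format="%.6f"
        )

    @classmethod
    def from_csv(cls, path, total_duration=None, sampling_rate=DEFAULT_SAMPLING_RATE):
        df = pd.read_csv(path)
        evs = list(df[["label", "onset", "duration"]].itertuples(index=False, name=None))
        if total_duration is None:
            total_duration = max(o + d for _, o, d in evs)
        return cls(evs, float(total_duration), sampling_rate)

    def epochs(self, labels) -> list:
        """(onset, duration) of events whose label is in `labels`."""
        labels = {labels} if isinstance(labels, str) else set(labels)
        return [(o, d) for l, o, d in self.events if l in labels]


@dataclass
class TaskDesign:
    """An event table plus which labels count as stimulation."""

    task_name: str
    event_table: EventTable
    stimulation_labels: set = field(default_factory=set)
    baseline_window: tuple = (0.0, 60.0)

    @property
    def total_duration(self) -> float:
        return self.event_table.total_duration

    def stimulation_epochs(self) -> list:
        return self.event_table.epochs(self.stimulation_labels)


def build_swg(
    n_blocks: int = 5,
    slide_duration: float = 10.0,
    slides_per_condition: int = 3,
    rest: float = 60.0,
) -> TaskDesign:
    """Block-design word-generation timeline.

    rest | n_blocks x [letters (stim) | symbols (baseline)] | rest, with
    each condition shown as `slides_per_condition` contiguous slides of
    `slide_duration` s (defaults give 60 s blocks, 420 s total).
    """
    if slide_duration <= 0 or rest <= 0:
        raise ProtocolError("durations must be positive")
    cond = slides_per_condition * slide_duration
    events = [("rest", 0.0, rest)]
    t = rest
    for _ in range(int(n_blocks)):
        events.append(("letter", t, cond))
        t += cond
        events.append(("symbol", t, cond))
        t += cond
    events.append(("rest", t, rest))
    total = t + rest
    table = EventTable(events, total)
    return TaskDesign("SWG", table, {"letter"}, baseline_window=(0.0, rest))


def build_unstructured(
    task_name: str, task_duration: float, rest: float = 60.0, min_window: float = 10.0
) -> TaskDesign:
    """Single-epoch timeline: rest | task | rest.

    SS default duration is 120 s; DS backward duration is performance
    dependent and must be supplied.  The pre-task rest minute is the
    baseline window for the variance statistic.
    """
    if rest <= 0:
        raise ProtocolError("a flanking rest (baseline) is required")
    if task_duration < min_window:
        raise ProtocolError(
            f"task duration {task_duration} s is shorter than one "
            f"{min_window} s analysis window"
        )
    events = [
        ("rest", 0.0, rest),
        ("task", rest, task_duration),
        ("rest", rest + task_duration, rest),
    ]
    table = EventTable(events, rest + task_duration + rest)
    return TaskDesign(task_name, table, {"task"}, baseline_window=(0.0, rest))


def build_ss(task_duration: float = 120.0, rest: float = 60.0) -> TaskDesign:
    return build_unstructured("SS", task_duration, rest)


def build_ds_backward(task_duration: float = 180.0, rest: float = 60.0) -> TaskDesign:
    return build_unstructured("DS_backward", task_duration, rest)


def design_vector(
    design: TaskDesign, n_samples: int, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> np.ndarray:
    """Sampled binary stimulation indicator (1 during stimulation epochs)."""
    expected = design.total_duration * sampling_rate
    if abs(n_samples - expected) > 1.0 + 1e-6:
        raise ValueError(
            f"n_samples={n_samples} inconsistent with duration "
            f"{design.total_duration}s at {sampling_rate} Hz (~{expected:.0f})"
        )
    t = np.arange(n_samples) / sampling_rate
    out = np.zeros(n_samples)
    for onset, dur in design.stimulation_epochs():
        out[(t >= onset) & (t < onset + dur)] = 1.0
    return out
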