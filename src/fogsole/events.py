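"""Gait-event extraction and phase segmentation from combined contact signals.

Foot-strike (FS) is a 0->1 transition of a foot's combined signal, foot-off
(FO) a 1->0 transition.  Maximal runs of 1 are single-support (stance)
episodes, maximal runs of 0 swing episodes; double-support episodes are the
interval intersections of left and right stance.  The running-duration
accumulators mirror the firmware recursion: a per-sample counter that grows
by dt while its phase condition holds and resets to zero the sample it
fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyInputError
from .signals import CombinedSignal, check_aligned

PHASES = ("single_support", "swing", "double_support")


@dataclass(frozen=True)
class GaitEvent:
    foot: str
    kind: str  # "FS" or "FO"
    sample_index: int
    time: float


@dataclass(frozen=True)
class PhaseEpisode:
    """A maximal stance/swing/double-support interval.

    ``interval`` is half-open ``[start_s, end_s)``; an episode covering
    samples a..b maps to ``[a*dt, (b+1)*dt)`` so ``duration`` equals the
    sample count times dt.  ``truncated`` marks episodes touching a recording
    boundary, whose duration is an underestimate of the true phase duration.
    """

    phase: str
    foot: str  # "left", "right", or "both" for double support
    start_s: float
    end_s: float
    truncated: bool

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return self.start_s < end_s and start_s < self.end_s


@dataclass(frozen=True)
class RunningDurations:
    """Per-sample running durations of each phase condition, in seconds."""

    t_ss_left: np.ndarray
    t_sw_left: np.ndarray
    t_ss_right: np.ndarray
    t_sw_right: np.ndarray
    t_ds: np.ndarray


def detect_events(combined: CombinedSignal) -> list[GaitEvent]:
    """FS at every 0->1 transition, FO at every 1->0 transition, in order.

    No events are emitted at recording boundaries: the state before sample 0
    and after the last sample is unknown.
    """
    bits = combined.bits
    if bits.size == 0:
        raise EmptyInputError("empty combined signal")
    d = np.diff(bits.astype(np.int8))
    events: list[GaitEvent] = []
    dt = combined.dt
    for idx in np.nonzero(d)[0]:
        n = int(idx) + 1
        kind = "FS" if d[idx] > 0 else "FO"
        events.append(
            GaitEvent(foot=combined.foot, kind=kind, sample_index=n, time=combined.t0 + n * dt)
        )
    return events


def _runs(bits: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Yield (value, start_sample, end_sample_exclusive) for maximal runs."""
    if bits.size == 0:
        return
    change = np.nonzero(np.diff(bits))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [bits.size]))
    for s, e in zip(starts, ends):
        yield int(bits[s]), int(s), int(e)


def _foot_episodes(signal: CombinedSignal) -> list[PhaseEpisode]:
    n = len(signal)
    dt = signal.dt
    out = []
    for value, s, e in _runs(signal.bits):
        out.append(
            PhaseEpisode(
                phase="single_support" if value == 1 else "swing",
                foot=signal.foot,
                start_s=signal.t0 + s * dt,
                end_s=signal.t0 + e * dt,
                truncated=(s == 0 or e == n),
            )
        )
    return out


def segment_phases(left: CombinedSignal, right: CombinedSignal) -> list[PhaseEpisode]:
    """Stance/swing episodes per foot plus bilateral double-support episodes.

    Double support is the per-sample AND of the two contact signals; its
    episodes are exactly the interval intersections of left and right stance.
    The result is sorted by start time (ties: left, right, both).
    """
    check_aligned(left, right)
    episodes = _foot_episodes(left) + _foot_episodes(right)
    both = (left.bits & right.bits).astype(np.uint8)
    n = len(left)
    dt = left.dt
    for value, s, e in _runs(both):
        if value == 1:
            episodes.append(
                PhaseEpisode(
                    phase="double_support",
                    foot="both",
                    start_s=left.t0 + s * dt,
                    end_s=left.t0 + e * dt,
                    truncated=(s == 0 or e == n),
                )
            )
    order = {"left": 0, "right": 1, "both": 2}
    episodes.sort(key=lambda ep: (ep.start_s, order[ep.foot]))
    return episodes


def _accumulate(condition: np.ndarray, dt: float) -> np.ndarray:
    """T[n] = T[n-1] + dt while condition holds, else 0 (T[-1] = 0)."""
    c = condition.astype(np.int64)
    # cumulative count within each run of ones: cumsum minus its value at the
    # most recent zero
    cs = np.cumsum(c)
    reset = np.where(c == 0, cs, 0)
    run = cs - np.maximum.accumulate(reset)
    return run * dt


def running_durations(left: CombinedSignal, right: CombinedSignal) -> RunningDurations:
    """Real-time single-support, swing, and double-support accumulators."""
    check_aligned(left, right)
    dt = left.dt
    lb = left.bits.astype(bool)
    rb = right.bits.astype(bool)
    return RunningDurations(
        t_ss_left=_accumulate(lb, dt),
        t_sw_left=_accumulate(~lb, dt),
        t_ss_right=_accumulate(rb, dt),
        t_sw_right=_accumulate(~rb, dt),
        t_ds=_accumulate(lb & rb, dt),
    )


def double_support_episodes(episodes: Sequence[PhaseEpisode]) -> list[PhaseEpisode]:
    return [ep for ep in episodes if ep.phase == "double_support"]


def swing_episodes(episodes: Sequence[PhaseEpisode], foot: str | None = None) -> list[PhaseEpisode]:
    return [ep for ep in episodes if ep.phase == "swing" and (foot is None or ep.foot == foot)]
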