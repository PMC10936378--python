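"""Per-user calibration, FoG indices, and offline/online FoG detection.

The method normalizes two temporal gait features against a FoG-free
calibration walk:

* long double support — a double-support episode whose duration reaches
  ``k_ds`` times the calibration-mean double-support duration flags the
  akinetic/trembling manifestation (both feet stay loaded);
* continuous short swings — a swing is "short" when its duration falls to
  ``baseline_sw / k_sw`` or below (equivalently its reciprocal reaches
  ``k_sw`` times the reciprocal of the calibration-mean swing); ``m_sw``
  consecutive short swings of the same foot flag the shuffling
  manifestation.

FoG is declared when either index fires.  The online detector applies the
same decisions causally, sample by sample: the long-double-support onset is
the first sample at which the running double-support accumulator crosses its
threshold, and the short-swing onset is the foot-strike that terminates the
``m_sw``-th consecutive short swing.  Offline and online detection produce
identical event sets on any finite recording.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CalibrationRequiredError,
    InsufficientCalibrationError,
    ParameterError,
    SequencingError,
)
from .events import PhaseEpisode, segment_phases, swing_episodes, double_support_episodes
from .signals import CombinedSignal, check_aligned

_EPS = 1e-9

EVENT_KINDS = ("LDDS", "SSW_L", "SSW_R")


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-user baselines from a FoG-free calibration walk.

    ``baseline_ds`` / ``baseline_sw`` are arithmetic means of the
    non-truncated double-support and (pooled, both feet) swing episode
    durations; ``baseline_sw_recip`` is the reciprocal of the swing mean.
    """

    baseline_ds: float
    baseline_sw: float
    baseline_sw_recip: float
    n_ds: int
    n_sw: int

    def __post_init__(self) -> None:
        if not (self.baseline_ds > 0 and self.baseline_sw > 0):
            raise ParameterError("calibration baselines must be positive")
        if abs(self.baseline_sw_recip * self.baseline_sw - 1.0) > 1e-9:
            raise ParameterError("baseline_sw_recip must equal 1/baseline_sw")

    @classmethod
    def from_baselines(cls, baseline_ds: float, baseline_sw: float, n_ds: int = 0, n_sw: int = 0):
        return cls(baseline_ds, baseline_sw, 1.0 / baseline_sw, n_ds, n_sw)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_ds": round(self.baseline_ds, 6),
                "baseline_sw": round(self.baseline_sw, 6),
                "baseline_sw_recip": round(self.baseline_sw_recip, 6),
                "n_ds": self.n_ds,
                "n_sw": self.n_sw,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationProfile":
        d = json.loads(text)
        return cls.from_baselines(d["baseline_ds"], d["baseline_sw"], d["n_ds"], d["n_sw"])


@dataclass(frozen=True)
class DetectionThresholds:
    """Dimensionless multipliers turning baselines into decision thresholds.

    Shipped defaults k_ds = 4.7 and k_sw = 4.5 are the values trained on the
    original 35-trial clinical dataset.
    """

    k_ds: float = 4.7
    k_sw: float = 4.5
    m_sw: int = 2
    merge_gap: float = 0.5

    def __post_init__(self) -> None:
        if not (self.k_ds > 1 and self.k_sw > 1):
            raise ParameterError("k_ds and k_sw must exceed 1")
        if self.m_sw < 1:
            raise ParameterError("m_sw must be at least 1")
        if self.merge_gap < 0:
            raise ParameterError("merge_gap must be non-negative")

    def ds_bound(self, profile: CalibrationProfile) -> float:
        """Minimum double-support duration that flags, in seconds."""
        return self.k_ds * profile.baseline_ds

    def short_swing_bound(self, profile: CalibrationProfile) -> float:
        """Maximum swing duration that counts as short, in seconds."""
        return profile.baseline_sw / self.k_sw

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_ds": round(self.k_ds, 6),
                "k_sw": round(self.k_sw, 6),
                "m_sw": self.m_sw,
                "merge_gap": round(self.merge_gap, 6),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DetectionThresholds":
        d = json.loads(text)
        return cls(d["k_ds"], d["k_sw"], d["m_sw"], d["merge_gap"])


@dataclass(frozen=True)
class FogEvent:
    """A detected FoG interval with the time the online criterion first fires."""

    kind: str
    start_s: float
    end_s: float
    onset_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ParameterError(f"unknown event kind {self.kind!r}")

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return self.start_s < end_s and start_s < self.end_s


@dataclass(frozen=True)
class FogDecision:
    """Per-sample FoG flags; fog = i_ds OR i_sw at every sample."""

    i_ds: np.ndarray
    i_sw: np.ndarray

    @property
    def fog(self) -> np.ndarray:
        return self.i_ds | self.i_sw


@dataclass(frozen=True)
class EpisodeFlags:
    """Per-episode FoG index flags (aligned with the input episode list)."""

    episode: PhaseEpisode
    i_ds: bool = False
    short_swing: bool = False
    i_sw: bool = False


def calibrate(
    left: CombinedSignal, right: CombinedSignal, min_episodes: int = 8
) -> CalibrationProfile:
    """Baselines from a FoG-free walk (straight line plus turns).

    Boundary-truncated episodes are excluded: their durations underestimate
    the true phase durations and would bias the means downward.
    """
    episodes = segment_phases(left, right)
    ds = [ep.duration for ep in double_support_episodes(episodes) if not ep.truncated]
    sw_by_foot = {
        foot: [ep.duration for ep in swing_episodes(episodes, foot) if not ep.truncated]
        for foot in ("left", "right")
    }
    if len(ds) < min_episodes:
        raise InsufficientCalibrationError(
            f"only {len(ds)} double_support episodes; need at least {min_episodes}"
        )
    for foot, durs in sw_by_foot.items():
        if len(durs) < min_episodes:
            raise InsufficientCalibrationError(
                f"only {len(durs)} swing episodes for {foot} foot; need at least {min_episodes}"
            )
    pooled = sw_by_foot["left"] + sw_by_foot["right"]
    return CalibrationProfile.from_baselines(
        baseline_ds=float(np.mean(ds)),
        baseline_sw=float(np.mean(pooled)),
        n_ds=len(ds),
        n_sw=len(pooled),
    )


def fog_indices(
    episodes: Sequence[PhaseEpisode],
    profile: CalibrationProfile,
    thresholds: DetectionThresholds,
) -> list[EpisodeFlags]:
    """Per-episode FoG index flags.

    A double-support episode raises ``i_ds`` when its duration reaches
    ``k_ds * baseline_ds``.  A swing episode is short when its duration is at
    most ``baseline_sw / k_sw``; ``i_sw`` rises on the ``m_sw``-th (and any
    later) consecutive short swing of the same foot.  Truncated swings are
    skipped; truncated double-support episodes remain eligible since a
    crossing of an underestimated duration is still a crossing.
    """
    if profile is None:
        raise CalibrationRequiredError("fog_indices requires a calibration profile")
    ds_bound = thresholds.ds_bound(profile)
    sw_bound = thresholds.short_swing_bound(profile)
    counters = {"left": 0, "right": 0}
    out: list[EpisodeFlags] = []
    for ep in episodes:
        if ep.phase == "double_support":
            out.append(EpisodeFlags(ep, i_ds=ep.duration >= ds_bound - _EPS))
        elif ep.phase == "swing":
            if ep.truncated:
                out.append(EpisodeFlags(ep))
                continue
            short = ep.duration <= sw_bound + _EPS
            if short:
                counters[ep.foot] += 1
            else:
                counters[ep.foot] = 0
            out.append(
                EpisodeFlags(
                    ep, short_swing=short, i_sw=short and counters[ep.foot] >= thresholds.m_sw
                )
            )
        else:
            out.append(EpisodeFlags(ep))
    return out


def merge_events(events: Sequence[FogEvent], merge_gap: float) -> list[FogEvent]:
    """Merge events separated by gaps shorter than ``merge_gap``.

    A merged event keeps the kind of its first constituent, the union
    interval, and the earliest onset.
    """
    if not events:
        return []
    ordered = sorted(events, key=lambda e: (e.start_s, e.end_s))
    merged = [ordered[0]]
    for ev in ordered[1:]:
        cur = merged[-1]
        if ev.start_s - cur.end_s < merge_gap - _EPS:
            merged[-1] = FogEvent(
                kind=cur.kind,
                start_s=cur.start_s,
                end_s=max(cur.end_s, ev.end_s),
                onset_s=min(cur.onset_s, ev.onset_s),
            )
        else:
            merged.append(ev)
    return merged


def _onset_steps(ds_bound: float, dt: float) -> int:
    """Samples after double-support start at which the accumulator crosses."""
    return max(1, math.ceil(ds_bound / dt - _EPS))


def _raw_events_from_episodes(
    episodes: Sequence[PhaseEpisode],
    profile: CalibrationProfile,
    thresholds: DetectionThresholds,
    dt: float,
) -> list[FogEvent]:
    ds_bound = thresholds.ds_bound(profile)
    sw_bound = thresholds.short_swing_bound(profile)
    j = _onset_steps(ds_bound, dt)
    raw: list[FogEvent] = []
    for ep in double_support_episodes(episodes):
        if ep.duration >= ds_bound - _EPS:
            raw.append(
                FogEvent(kind="LDDS", start_s=ep.start_s, end_s=ep.end_s, onset_s=ep.start_s + j * dt)
            )
    for foot, kind in (("left", "SSW_L"), ("right", "SSW_R")):
        swings = [ep for ep in swing_episodes(episodes, foot) if not ep.truncated]
        run: list[PhaseEpisode] = []
        for ep in swings + [None]:  # sentinel closes the final run
            if ep is not None and ep.duration <= sw_bound + _EPS:
                run.append(ep)
                continue
            if len(run) >= thresholds.m_sw:
                raw.append(
                    FogEvent(
                        kind=kind,
                        start_s=run[0].start_s,
                        end_s=run[-1].end_s,
                        onset_s=run[thresholds.m_sw - 1].end_s,
                    )
                )
            run = []
    raw.sort(key=lambda e: (e.start_s, e.end_s))
    return raw


def _decision_from_raw(
    raw: Sequence[FogEvent], n_samples: int, sampling_rate: float, t0: float
) -> FogDecision:
    i_ds = np.zeros(n_samples, dtype=bool)
    i_sw = np.zeros(n_samples, dtype=bool)
    for ev in raw:
        lo = max(0, math.ceil((ev.start_s - t0) * sampling_rate - _EPS))
        hi = min(n_samples, math.ceil((ev.end_s - t0) * sampling_rate - _EPS))
        (i_ds if ev.kind == "LDDS" else i_sw)[lo:hi] = True
    return FogDecision(i_ds=i_ds, i_sw=i_sw)


@dataclass(frozen=True)
class OfflineDetection:
    """Result of offline FoG detection on one bilateral recording."""

    events: list[FogEvent]  # after gap merging
    raw_events: list[FogEvent]  # before merging
    decision: FogDecision
    episodes: list[PhaseEpisode]


def detect_fog_offline(
    left: CombinedSignal,
    right: CombinedSignal,
    profile: CalibrationProfile,
    thresholds: DetectionThresholds,
) -> OfflineDetection:
    """Episode-wise FoG detection over a full recording.

    Raw events: one LDDS event per flagged double-support episode (the event
    interval is the episode) and one SSW event per maximal run of at least
    ``m_sw`` consecutive short swings of one foot (first short-swing start to
    last short-swing end).  Events separated by less than ``merge_gap`` are
    merged.  Per-sample flags come from the raw events so that
    ``fog = i_ds | i_sw`` holds exactly.
    """
    if profile is None:
        raise CalibrationRequiredError("detect_fog_offline requires a calibration profile")
    check_aligned(left, right)
    episodes = segment_phases(left, right)
    raw = _raw_events_from_episodes(episodes, profile, thresholds, left.dt)
    decision = _decision_from_raw(raw, len(left), left.sampling_rate, left.t0)
    return OfflineDetection(
        events=merge_events(raw, thresholds.merge_gap),
        raw_events=raw,
        decision=decision,
        episodes=episodes,
    )


@dataclass(frozen=True)
class OnsetNotice:
    """Immediate notification that an online criterion just fired."""

    kind: str
    onset_s: float
    sample_index: int


class _FootState:
    __slots__ = ("bit", "swing_start", "short_count", "run_start", "run_last_end", "ssw_onset")

    def __init__(self) -> None:
        self.bit: Optional[int] = None
        self.swing_start: Optional[int] = None
        self.short_count = 0
        self.run_start: Optional[float] = None
        self.run_last_end: Optional[float] = None
        self.ssw_onset: Optional[float] = None


class OnlineFogDetector:
    """Causal, sample-by-sample FoG onset detector.

    Feed aligned bilateral contact bits in time order via :meth:`update`,
    which returns onset notices the moment a criterion fires, then call
    :meth:`finalize` at end of stream.  ``events`` holds the completed raw
    events, identical to the offline detector's raw events on the same
    stream.
    """

    def __init__(
        self,
        profile: CalibrationProfile,
        thresholds: DetectionThresholds,
        sampling_rate: float,
        t0: float = 0.0,
    ) -> None:
        if profile is None:
            raise CalibrationRequiredError("online detection requires a calibration profile")
        self.profile = profile
        self.thresholds = thresholds
        self.sampling_rate = sampling_rate
        self.t0 = t0
        self.dt = 1.0 / sampling_rate
        self._ds_bound = thresholds.ds_bound(profile)
        self._sw_bound = thresholds.short_swing_bound(profile)
        self._jdt = _onset_steps(self._ds_bound, self.dt) * self.dt
        self._n = -1
        self._feet = {"left": _FootState(), "right": _FootState()}
        self._ds_start: Optional[int] = None
        self._ds_fired = False
        self._ldds_onset: Optional[float] = None
        self._finalized = False
        self.events: list[FogEvent] = []

    def _time(self, n: int) -> float:
        return self.t0 + n * self.dt

    def _close_ssw(self, foot: str) -> None:
        st = self._feet[foot]
        if st.short_count >= self.thresholds.m_sw:
            kind = "SSW_L" if foot == "left" else "SSW_R"
            self.events.append(
                FogEvent(kind=kind, start_s=st.run_start, end_s=st.run_last_end, onset_s=st.ssw_onset)
            )
        st.short_count = 0
        st.run_start = None
        st.run_last_end = None
        st.ssw_onset = None

    def _close_ldds(self, end_s: float) -> None:
        if self._ds_fired:
            self.events.append(
                FogEvent(
                    kind="LDDS",
                    start_s=self._time(self._ds_start),
                    end_s=end_s,
                    onset_s=self._ldds_onset,
                )
            )
        self._ds_start = None
        self._ds_fired = False
        self._ldds_onset = None

    def update(self, c_left: int, c_right: int, t: Optional[float] = None) -> list[OnsetNotice]:
        if self._finalized:
            raise SequencingError("detector already finalized")
        n = self._n + 1
        if t is not None:
            expected = self._time(n)
            if abs(t - expected) > 1e-6:
                raise SequencingError(
                    f"sample {n} has timestamp {t}, expected {expected} (fixed-rate, in-order)"
                )
        notices: list[OnsetNotice] = []
        for foot, bit in (("left", int(c_left)), ("right", int(c_right))):
            st = self._feet[foot]
            prev = st.bit
            if prev is None:
                if bit == 0:
                    st.swing_start = n
            elif bit != prev:
                if bit == 1:  # foot strike: a swing [swing_start, n) just ended
                    if st.swing_start is not None and st.swing_start > 0:
                        dur = (n - st.swing_start) * self.dt
                        if dur <= self._sw_bound + _EPS:
                            st.short_count += 1
                            if st.short_count == 1:
                                st.run_start = self._time(st.swing_start)
                            st.run_last_end = self._time(n)
                            if st.short_count == self.thresholds.m_sw:
                                st.ssw_onset = self._time(n)
                                kind = "SSW_L" if foot == "left" else "SSW_R"
                                notices.append(OnsetNotice(kind, st.ssw_onset, n))
                        else:
                            self._close_ssw(foot)
                    st.swing_start = None
                else:  # foot off
                    st.swing_start = n
            st.bit = bit
        if c_left and c_right:
            if self._ds_start is None:
                self._ds_start = n
                self._ds_fired = False
            if not self._ds_fired:
                t_ds = (n - self._ds_start + 1) * self.dt
                if t_ds >= self._ds_bound - _EPS:
                    self._ds_fired = True
                    self._ldds_onset = self._time(self._ds_start) + self._jdt
                    notices.append(OnsetNotice("LDDS", self._ldds_onset, n))
        elif self._ds_start is not None:
            self._close_ldds(end_s=self._time(n))
        self._n = n
        return notices

    def finalize(self) -> list[FogEvent]:
        """Close open episodes at end of stream and return all raw events."""
        if not self._finalized:
            if self._ds_start is not None:
                self._close_ldds(end_s=self._time(self._n + 1))
            for foot in ("left", "right"):
                self._close_ssw(foot)
            self._finalized = True
        self.events.sort(key=lambda e: (e.start_s, e.end_s))
        return self.events

    def merged_events(self) -> list[FogEvent]:
        if not self._finalized:
            raise SequencingError("call finalize() before merged_events()")
        return merge_events(self.events, self.thresholds.merge_gap)


def detect_onset_online(
    state: OnlineFogDetector,
    sample: tuple[int, int],
    t: Optional[float] = None,
) -> list[OnsetNotice]:
    """Functional wrapper over :meth:`OnlineFogDetector.update`."""
    return state.update(sample[0], sample[1], t=t)
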