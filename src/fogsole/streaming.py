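"""Packetized transport model, streaming detection loop, cueing state
machine, and device-budget arithmetic.

The insole firmware batches samples into packets of eight before radio
transmission, so a sample captured at time t only reaches the detector when
its packet is complete: the first sample of each packet waits
``(packet_size - 1)/Fs`` seconds.  Packetization therefore delays decisions
by up to one packet period (0.25 s at the default 8 samples / 32 Hz) but
never changes them.

The cueing controller activates on the first delivered FoG onset and keeps
cueing until normal gait has been sustained for a continuous 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ParameterError, SequencingError
from .detect import (
    CalibrationProfile,
    DetectionThresholds,
    FogEvent,
    OnlineFogDetector,
    merge_events,
)
from .signals import InsoleStream, combine_signal

#: Days per month used for wear-life arithmetic (mean Gregorian month).
DAYS_PER_MONTH = 30.44

#: Continuous normal-gait seconds required before cueing deactivates.
CUE_HOLD_S = 30.0


@dataclass(frozen=True)
class Packet:
    """Consecutive bilateral samples delivered together.

    ``samples`` has shape (n, 2) with columns (left, right) combined bits;
    ``capture_times`` are the per-sample capture instants and
    ``delivery_time`` is when the whole packet reaches the detector.
    """

    samples: np.ndarray
    capture_times: np.ndarray
    delivery_time: float

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class CueState:
    """Cueing controller state: idle, or cueing with a deactivation timer."""

    mode: str = "idle"  # "idle" or "cueing"
    cueing_since: Optional[float] = None
    normal_since: Optional[float] = None
    modality: str = "both"  # auditory / visual / both (metadata only)
    last_t: float = float("-inf")


@dataclass(frozen=True)
class DeviceBudget:
    """Wear life of a pressure-sensing unit from its cycle rating."""

    cycle_rating: int
    steps_per_day: int

    @property
    def wear_life_days(self) -> float:
        return self.cycle_rating / self.steps_per_day

    @property
    def wear_life_months(self) -> float:
        return self.wear_life_days / DAYS_PER_MONTH


def packet_period(packet_size: int, sampling_rate: float) -> float:
    """Packet duration in seconds — the packaging-induced response-time span."""
    if packet_size < 1:
        raise ParameterError("packet_size must be at least 1")
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    return packet_size / sampling_rate


def packetize(
    left: InsoleStream,
    right: InsoleStream,
    packet_size: int = 8,
    transmission_delay: float = 0.0,
) -> list[Packet]:
    """Batch aligned bilateral streams into consecutive delivery packets.

    A trailing partial packet is flushed at end of stream so that finite
    recordings replay completely.  Sample availability delay
    (delivery - capture) lies in
    ``[transmission_delay, (packet_size - 1)/Fs + transmission_delay]``.
    """
    if packet_size < 1:
        raise ParameterError("packet_size must be at least 1")
    if transmission_delay < 0:
        raise ParameterError("transmission_delay must be non-negative")
    if len(left) != len(right) or left.sampling_rate != right.sampling_rate:
        raise AlignmentError("left/right streams must share length and sampling rate")
    if abs(left.t0 - right.t0) > 1e-9:
        raise AlignmentError("left/right streams must share t0")
    lbits = combine_signal(left).bits
    rbits = combine_signal(right).bits
    times = left.times()
    packets = []
    for start in range(0, len(left), packet_size):
        stop = min(start + packet_size, len(left))
        packets.append(
            Packet(
                samples=np.column_stack((lbits[start:stop], rbits[start:stop])),
                capture_times=times[start:stop],
                delivery_time=float(times[stop - 1]) + transmission_delay,
            )
        )
    return packets


def stream_detect(
    packets: Sequence[Packet],
    profile: CalibrationProfile,
    thresholds: DetectionThresholds,
    sampling_rate: float,
    t0: float = 0.0,
) -> list[tuple[FogEvent, float]]:
    """Replay packets through the online detector.

    Returns the merged FoG events together with each event's decision time:
    the later of the algorithmic onset and the delivery time of the packet
    carrying the triggering sample.  The event set is identical to offline
    detection on the same recording; only decision times shift.
    """
    detector = OnlineFogDetector(profile, thresholds, sampling_rate, t0=t0)
    onset_decisions: dict[tuple[str, float], float] = {}
    for packet in packets:
        for (cl, cr), t in zip(packet.samples, packet.capture_times):
            for notice in detector.update(int(cl), int(cr), t=float(t)):
                key = (notice.kind, notice.onset_s)
                decision = max(notice.onset_s, packet.delivery_time)
                onset_decisions.setdefault(key, decision)
    raw = detector.finalize()
    decorated = []
    for ev in raw:
        decorated.append((ev, onset_decisions[(ev.kind, ev.onset_s)]))
    # merge exactly as offline; a merged event keeps its earliest decision
    merged = merge_events([ev for ev, _ in decorated], thresholds.merge_gap)
    out: list[tuple[FogEvent, float]] = []
    for mev in merged:
        constituents = [d for ev, d in decorated if mev.start_s <= ev.start_s and ev.end_s <= mev.end_s]
        out.append((mev, min(constituents)))
    return out


def cueing_step(state: CueState, fog_active: bool, t: float) -> CueState:
    """Advance the cueing controller by one observation.

    Idle + FoG -> start cueing.  While cueing, any FoG clears the
    deactivation timer; sustained normal gait starts it, and after 30 s of
    continuous normal gait the controller returns to idle.
    """
    if t < state.last_t:
        raise SequencingError(f"time went backwards: {t} < {state.last_t}")
    state = replace(state, last_t=t)
    if state.mode == "idle":
        if fog_active:
            return replace(state, mode="cueing", cueing_since=t, normal_since=None)
        return state
    if fog_active:
        return replace(state, normal_since=None)
    if state.normal_since is None:
        return replace(state, normal_since=t)
    if t - state.normal_since >= CUE_HOLD_S:
        return replace(state, mode="idle", cueing_since=None, normal_since=None)
    return state


def wear_life(cycle_rating: int, steps_per_day: int) -> DeviceBudget:
    """Wear life of a PSU given its compression-cycle rating and daily steps."""
    if cycle_rating <= 0:
        raise ParameterError("cycle_rating must be positive")
    if steps_per_day <= 0:
        raise ParameterError("steps_per_day must be positive")
    return DeviceBudget(cycle_rating=cycle_rating, steps_per_day=steps_per_day)
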