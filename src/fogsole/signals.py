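"""Binary insole streams, the pressure-sensing-unit (PSU) contract, and the
combined per-foot contact signal.

A smart insole carries six PSUs, each a mechanical switch with a fixed
pressure threshold: its output is 1 while the applied plantar pressure
reaches or exceeds the threshold and 0 otherwise.  Sampling both insoles at
32 Hz yields two six-bit binary streams.  The *combined signal* of a foot is
the per-sample logical OR of its six sensor bits: 1 means the foot is loaded
(stance / single support), 0 means it is airborne (swing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, EmptyInputError, LayoutError, LengthError, ParameterError

SENSOR_IDS = ("S1", "S2", "S3", "S4", "S5", "S6")
SITES = ("heel", "metatarsal", "inversion", "eversion")

#: Default per-sensor thresholds in kPa: heel switch at ~50 kPa, the two
#: forefoot switches at 20 kPa, and the three metatarsal-head switches at the
#: mid-range (27.5 kPa) of the 20-35 kPa production versions.
DEFAULT_THRESHOLDS_KPA: Mapping[str, float] = {
    "S1": 50.0,
    "S2": 27.5,
    "S3": 27.5,
    "S4": 20.0,
    "S5": 20.0,
    "S6": 27.5,
}

_DEFAULT_SITES: Mapping[str, str] = {
    "S1": "heel",
    "S2": "metatarsal",
    "S3": "metatarsal",
    "S4": "inversion",
    "S5": "eversion",
    "S6": "metatarsal",
}


@dataclass(frozen=True)
class PsuSpec:
    """One pressure-sensing unit: identity, anatomical site, kPa threshold."""

    sensor_id: str
    site: str
    threshold_kpa: float

    def __post_init__(self) -> None:
        if self.sensor_id not in SENSOR_IDS:
            raise LayoutError(f"unknown sensor_id {self.sensor_id!r}; expected one of {SENSOR_IDS}")
        if self.site not in SITES:
            raise LayoutError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not self.threshold_kpa > 0:
            raise LayoutError(f"threshold must be positive, got {self.threshold_kpa}")


@dataclass(frozen=True)
class SensorLayout:
    """Ordered collection of exactly six PSUs for one insole.

    Exactly one sensor (S1) sits at the heel; the rest cover the forefoot.
    """

    specs: tuple[PsuSpec, ...]

    def __post_init__(self) -> None:
        if len(self.specs) != 6:
            raise LayoutError(f"a layout needs exactly 6 PSUs, got {len(self.specs)}")
        ids = [s.sensor_id for s in self.specs]
        if len(set(ids)) != 6:
            raise LayoutError(f"duplicate sensor ids in layout: {ids}")
        heels = [s for s in self.specs if s.site == "heel"]
        if len(heels) != 1 or heels[0].sensor_id != "S1":
            raise LayoutError("layout must have exactly one heel sensor and it must be S1")

    @classmethod
    def default(cls) -> "SensorLayout":
        specs = tuple(
            PsuSpec(sid, _DEFAULT_SITES[sid], DEFAULT_THRESHOLDS_KPA[sid]) for sid in SENSOR_IDS
        )
        return cls(specs)

    def thresholds(self) -> np.ndarray:
        """Thresholds in kPa ordered S1..S6."""
        by_id = {s.sensor_id: s.threshold_kpa for s in self.specs}
        return np.array([by_id[sid] for sid in SENSOR_IDS], dtype=float)


@dataclass(frozen=True)
class InsoleStream:
    """Time-indexed binary frames from the six PSUs of one foot.

    ``frames`` has shape (N, 6), dtype uint8, columns ordered S1..S6.
    Sample ``n`` covers the interval ``[t0 + n*dt, t0 + (n+1)*dt)`` with
    ``dt = 1/sampling_rate``.
    """

    foot: str
    sampling_rate: float
    frames: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ParameterError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        frames = np.asarray(self.frames, dtype=np.uint8)
        if frames.ndim != 2 or frames.shape[1] != 6:
            raise LengthError(f"frames must have shape (N, 6), got {frames.shape}")
        if frames.shape[0] < 1:
            raise EmptyInputError("a stream needs at least one frame")
        if frames.max(initial=0) > 1:
            raise ParameterError("frame values must be 0 or 1")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    def window(self, start_s: float, end_s: float) -> "InsoleStream":
        """Sub-stream covering samples whose start time lies in [start_s, end_s)."""
        n0 = max(0, int(np.ceil((start_s - self.t0) * self.sampling_rate - 1e-9)))
        n1 = min(len(self), int(np.ceil((end_s - self.t0) * self.sampling_rate - 1e-9)))
        if n1 <= n0:
            raise EmptyInputError(f"window [{start_s}, {end_s}) selects no samples")
        return replace(self, frames=self.frames[n0:n1], t0=self.t0 + n0 * self.dt)


@dataclass(frozen=True)
class CombinedSignal:
    """Per-sample OR of the six sensor bits of one foot (1 = foot loaded)."""

    foot: str
    sampling_rate: float
    bits: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise LengthError("bits must be one-dimensional")
        if bits.size < 1:
            raise EmptyInputError("a combined signal needs at least one sample")
        if bits.max(initial=0) > 1:
            raise ParameterError("bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


def binarize(
    pressure_traces: Mapping[str, Sequence[float]] | np.ndarray,
    layout: SensorLayout,
    sampling_rate: float,
    foot: str = "left",
    t0: float = 0.0,
) -> InsoleStream:
    """Threshold analog pressure traces into a binary insole stream.

    Parameters
    ----------
    pressure_traces
        Either a mapping sensor_id -> kPa series, or an (N, 6) array ordered
        S1..S6.  All traces must share one length.
    layout
        Per-sensor thresholds.  A bit is 1 iff pressure >= threshold
        (the switch closes when the load reaches or exceeds its rating).
    """
    if isinstance(pressure_traces, Mapping):
        unknown = set(pressure_traces) - set(SENSOR_IDS)
        if unknown:
            raise LayoutError(f"unknown sensor ids in traces: {sorted(unknown)}")
        missing = set(SENSOR_IDS) - set(pressure_traces)
        if missing:
            raise LayoutError(f"missing traces for sensors: {sorted(missing)}")
        cols = [np.asarray(pressure_traces[sid], dtype=float) for sid in SENSOR_IDS]
        lengths = {c.size for c in cols}
        if len(lengths) != 1:
            raise LengthError(f"traces have mismatched lengths: {sorted(lengths)}")
        arr = np.column_stack(cols)
    else:
        arr = np.asarray(pressure_traces, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise LengthError(f"pressure array must have shape (N, 6), got {arr.shape}")
    if np.any(arr < 0):
        raise ParameterError("pressures must be non-negative")
    bits = (arr >= layout.thresholds()[np.newaxis, :]).astype(np.uint8)
    return InsoleStream(foot=foot, sampling_rate=sampling_rate, frames=bits, t0=t0)


def combine_signal(stream: InsoleStream) -> CombinedSignal:
    """Logical OR of the six sensor bits at each sample (foot-contact signal)."""
    bits = (stream.frames.max(axis=1)).astype(np.uint8)
    return CombinedSignal(
        foot=stream.foot, sampling_rate=stream.sampling_rate, bits=bits, t0=stream.t0
    )


def check_aligned(left: CombinedSignal, right: CombinedSignal) -> None:
    """Raise AlignmentError unless the two signals share length, rate, t0."""
    if len(left) != len(right):
        raise AlignmentError(f"length mismatch: left {len(left)} vs right {len(right)}")
    if left.sampling_rate != right.sampling_rate:
        raise AlignmentError(
            f"sampling_rate mismatch: {left.sampling_rate} vs {right.sampling_rate}"
        )
    if abs(left.t0 - right.t0) > 1e-9:
        raise AlignmentError(f"t0 mismatch: {left.t0} vs {right.t0}")
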