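"""Synthetic labeled gait generator.

Emulates the temporal structure the detector consumes: bilateral alternating
stance/swing with double-support overlap, occasional wider double supports
at turns, and injected FoG episodes of the three manifestations —

* akinesia: both feet stay loaded (long double support);
* tremble: both heels stay loaded while one forefoot oscillates about its
  pressure threshold at 4-8 Hz; the combined signal never clears, so the
  episode also presents as long double support;
* shuffle: one foot takes rapid short steps (swings of 0.05-0.12 s between
  0.2 s stances) while the other stays loaded.

Episode durations follow a log-normal law (sigma 0.8) truncated by rejection
to the clinically observed 0.4-31.8 s range, with the location calibrated so
the truncated mean matches the observed 2.4 s.  Episode starts come from a
Poisson process; the first 30 s are kept clean so a calibration profile can
be taken from them.  All randomness flows from a single seed: equal configs
give bit-identical recordings.

Analog per-sensor pressures are synthesized (stylized heel-then-forefoot
loading within each stance) and passed through the same binarization
contract as real hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, InfeasibleTargetError, ParameterError
from .signals import SENSOR_IDS, InsoleStream, SensorLayout, binarize

_HEEL_PEAK_KPA = 120.0  # clears the 50 kPa heel threshold with margin
_FOREFOOT_PEAK_KPA = 80.0  # clears the 20-35 kPa forefoot thresholds


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic recording."""

    sampling_rate: float = 32.0
    duration_s: float = 180.0
    stance_mean: float = 0.65
    swing_mean: float = 0.45
    ds_mean: float = 0.15
    cv: float = 0.08
    fog_rate_per_min: float = 2.0
    #: proportions over (akinesia, shuffle, tremble)
    manifestation_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    episode_sigma: float = 0.8
    episode_range: tuple[float, float] = (0.4, 31.8)
    episode_mean: float = 2.4
    shuffle_swing_range: tuple[float, float] = (0.05, 0.12)
    shuffle_stance_s: float = 0.2
    tremble_freq_range: tuple[float, float] = (4.0, 8.0)
    turn_fraction: float = 0.10
    turn_ds_factor: float = 1.5
    clean_lead_s: float = 30.0
    min_gap_s: float = 2.0
    end_margin_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.manifestation_mix) - 1.0) > 1e-9:
            raise ConfigError("manifestation_mix must sum to 1")
        if not self.episode_range[0] < self.episode_range[1]:
            raise ConfigError("episode_range must satisfy low < high")
        for name in ("sampling_rate", "duration_s", "stance_mean", "swing_mean", "ds_mean"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.fog_rate_per_min < 0:
            raise ConfigError("fog_rate_per_min must be non-negative")


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth FoG intervals: (start_s, end_s, kind)."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        rows = tuple(sorted((float(s), float(e), str(k)) for s, e, k in self.intervals))
        for s, e, k in rows:
            if not s < e:
                raise ParameterError(f"truth interval [{s}, {e}) is empty")
            if k not in ("LDDS", "SSW_L", "SSW_R"):
                raise ParameterError(f"unknown truth kind {k!r}")
        for (s1, e1, _), (s2, e2, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ParameterError("truth intervals overlap")
        object.__setattr__(self, "intervals", rows)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class PlannedEpisode:
    start_s: float
    duration_s: float
    manifestation: str  # akinesia / shuffle / tremble


@dataclass(frozen=True)
class SimulatedRecording:
    left: InsoleStream
    right: InsoleStream
    pressures: dict[str, np.ndarray]  # foot -> (N, 6) kPa, columns S1..S6
    truth: TruthLabels
    plan: tuple[PlannedEpisode, ...]
    config: SimConfig


def _truncated_lognorm_mean(loc: float, sigma: float, low: float, high: float) -> float:
    """Mean of LogNormal(loc, sigma) conditioned on [low, high] (closed form)."""
    a = (math.log(low) - loc) / sigma
    b = (math.log(high) - loc) / sigma
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    if z <= 0:
        return float("nan")
    weight = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
    return math.exp(loc + 0.5 * sigma**2) * weight / z


def calibrate_episode_location(
    sigma: float,
    duration_range: tuple[float, float],
    target_mean: float,
    tol: float = 1e-3,
) -> float:
    """Log-normal location whose range-truncated mean hits ``target_mean``.

    The truncated mean is monotone in the location and spans (low, high), so
    the root is unique; it is bracketed and solved deterministically.
    """
    low, high = duration_range
    if not (low < target_mean < high):
        raise InfeasibleTargetError(
            f"target mean {target_mean} outside achievable range ({low}, {high})"
        )
    if sigma < 1e-6:
        return math.log(target_mean)

    def gap(loc: float) -> float:
        return _truncated_lognorm_mean(loc, sigma, low, high) - target_mean

    lo, hi = math.log(low) - 6 * sigma, math.log(high) + 6 * sigma
    loc = float(optimize.brentq(gap, lo, hi, xtol=1e-9))
    if abs(gap(loc)) > tol:
        raise InfeasibleTargetError("location solve did not reach the requested tolerance")
    return loc


def sample_episode_durations(
    n: int,
    rng: np.random.Generator,
    loc: float,
    sigma: float,
    duration_range: tuple[float, float],
) -> np.ndarray:
    """Rejection-sample n durations from the truncated log-normal law."""
    low, high = duration_range
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mean=loc, sigma=sigma, size=max(64, 2 * (n - out.size)))
        out = np.concatenate((out, draw[(draw >= low) & (draw <= high)]))
    return out[:n]


def plan_episodes(config: SimConfig) -> tuple[PlannedEpisode, ...]:
    """Poisson-placed FoG episodes with truncated log-normal durations.

    Arrivals before ``clean_lead_s`` (reserved calibration window), within
    ``min_gap_s`` of the previous episode, or extending past
    ``duration_s - end_margin_s`` are rejected.
    """
    if config.fog_rate_per_min <= 0:
        return ()
    rng = np.random.default_rng(config.seed)
    loc = calibrate_episode_location(
        config.episode_sigma, config.episode_range, config.episode_mean
    )
    rate = config.fog_rate_per_min / 60.0
    horizon = config.duration_s - config.end_margin_s
    plan: list[PlannedEpisode] = []
    t = config.clean_lead_s
    last_end = config.clean_lead_s
    manifestations = ("akinesia", "shuffle", "tremble")
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        dur = float(
            sample_episode_durations(1, rng, loc, config.episode_sigma, config.episode_range)[0]
        )
        kind = manifestations[rng.choice(3, p=config.manifestation_mix)]
        if t < last_end + config.min_gap_s or t + dur > horizon:
            continue
        plan.append(PlannedEpisode(start_s=t, duration_s=dur, manifestation=kind))
        last_end = t + dur
    return tuple(plan)


class _FootTimeline:
    """Per-foot list of loading segments on the continuous time axis."""

    def __init__(self) -> None:
        self.segments: list[tuple[float, float, str, float]] = []  # (start, end, kind, param)
        self.open_since: Optional[float] = 0.0  # both feet loaded at t = 0
        self.open_kind: str = "stance"
        self.open_param: float = 0.0

    def close(self, t: float) -> None:
        if self.open_since is not None and t > self.open_since:
            self.segments.append((self.open_since, t, self.open_kind, self.open_param))
        self.open_since = None

    def open(self, t: float, kind: str = "stance", param: float = 0.0) -> None:
        self.open_since = t
        self.open_kind = kind
        self.open_param = param


class _Walker:
    """Event-driven bilateral gait constructor."""

    def __init__(self, config: SimConfig, rng: np.random.Generator) -> None:
        self.cfg = config
        self.rng = rng
        self.feet = {"left": _FootTimeline(), "right": _FootTimeline()}
        self.next_lifter = "left"

    # -- duration samplers ------------------------------------------------
    def _swing(self) -> float:
        d = self.rng.normal(self.cfg.swing_mean, self.cfg.cv * self.cfg.swing_mean)
        return float(np.clip(d, 0.30, 0.65))

    def _ds(self) -> float:
        d = self.rng.normal(self.cfg.ds_mean, self.cfg.cv * self.cfg.ds_mean)
        if self.rng.random() < self.cfg.turn_fraction:
            d *= self.cfg.turn_ds_factor  # wider double support at turns
        return float(np.clip(d, 0.06, 0.32))

    @staticmethod
    def _other(foot: str) -> str:
        return "right" if foot == "left" else "left"

    # -- normal walking between seams -------------------------------------
    def walk_until(
        self, t_first_fo: float, seam: float
    ) -> tuple[str, Optional[str], Optional[float]]:
        """Alternate steps until ``seam``.

        Returns (seam_state, lander, deferred_fo): "landed" means one foot's
        swing was extended to land exactly at the seam (that foot is the
        lander); "both_loaded" means no foot lifts near the seam — both
        stances run through it, and ``deferred_fo`` is the foot-off that was
        scheduled but suppressed.
        """
        lifter = self.next_lifter
        t_fo = t_first_fo
        while True:
            if t_fo >= seam - 0.30:
                # lifting this close to the seam would create a short swing
                self.next_lifter = lifter
                return "both_loaded", None, t_fo
            t_fs = t_fo + self._swing()
            landed = False
            if t_fs >= seam - 0.25:
                t_fs = seam  # extend the swing to land exactly at the seam
                landed = True
            foot = self.feet[lifter]
            foot.close(t_fo)
            foot.open(t_fs, "stance")
            if landed:
                self.next_lifter = self._other(lifter)
                return "landed", lifter, None
            t_fo = t_fs + self._ds()
            lifter = self._other(lifter)

    # -- episode injection -------------------------------------------------
    def inject(
        self,
        ep: PlannedEpisode,
        seam_state: str,
        lander: Optional[str],
        deferred_fo: Optional[float],
    ) -> tuple[tuple[float, float, str], float]:
        """Realize one FoG episode; returns (truth_row, resume_fo_time)."""
        s, e = ep.start_s, ep.start_s + ep.duration_s
        left, right = self.feet["left"], self.feet["right"]
        if seam_state == "landed":
            moving = lander  # the foot that just landed keeps moving
        else:
            moving = self.next_lifter
        holding = self._other(moving)

        if ep.manifestation in ("akinesia", "tremble"):
            # both feet fully loaded through [truth_start, e)
            truth_start = s if seam_state == "landed" else max(
                left.open_since if left.open_since is not None else s,
                right.open_since if right.open_since is not None else s,
            )
            for name in ("left", "right"):
                foot = self.feet[name]
                foot.close(truth_start)
                if ep.manifestation == "tremble" and name == moving:
                    freq = float(self.rng.uniform(*self.cfg.tremble_freq_range))
                    foot.open(truth_start, "tremble", freq)
                else:
                    foot.open(truth_start, "hold")
            # at e the moving foot lifts and normal gait resumes
            self.feet[moving].close(e)
            self.next_lifter = self._other(moving)  # moving foot is airborne
            t_fs = e + self._swing()
            self.feet[moving].open(t_fs, "stance")
            resume_fo = t_fs + self._ds()
            return (truth_start, e, "LDDS"), resume_fo

        # shuffle: `moving` takes rapid short steps, `holding` stays loaded
        st = self.cfg.shuffle_stance_s
        lo, hi = self.cfg.shuffle_swing_range
        shuffler = self.feet[moving]
        if seam_state == "landed":
            # the lander's first shuffle stance starts at the seam
            truth_start = s
            shuffler.close(s)
            shuffler.open(s, "hold")
            t = s
        else:
            # the suppressed foot-off becomes the first shuffle lift; never
            # later than the seam so the preceding double support stays in
            # the normal range
            lift = min(deferred_fo, s)
            truth_start = lift
            shuffler.close(lift)
            t = lift + float(self.rng.uniform(lo, hi))  # first short swing
            shuffler.open(t, "hold")
        self.feet[holding].close(truth_start)
        self.feet[holding].open(truth_start, "hold")
        while True:
            t_off = t + st
            ssw = float(self.rng.uniform(lo, hi))
            if t_off + ssw > e - 0.01:
                break  # the final stance extends past the episode end
            shuffler.close(t_off)
            t = t_off + ssw
            shuffler.open(t, "hold")
        # at e the holding foot lifts first and normal gait resumes
        self.feet[holding].close(e)
        self.next_lifter = moving
        t_fs = e + self._swing()
        self.feet[holding].open(t_fs, "stance")
        resume_fo = t_fs + self._ds()
        kind = "SSW_L" if moving == "left" else "SSW_R"
        return (truth_start, e, kind), resume_fo

    def finish(self, t_end: float) -> None:
        for foot in self.feet.values():
            if foot.open_since is not None:
                foot.close(t_end)


def _rasterize_foot(
    timeline: _FootTimeline, layout: SensorLayout, n: int, fs: float
) -> np.ndarray:
    """Per-sensor kPa traces from a foot's loading segments."""
    pressures = np.zeros((n, 6))
    col = {sid: i for i, sid in enumerate(SENSOR_IDS)}
    heel = col["S1"]
    forefoot = [col[s] for s in ("S2", "S3", "S4", "S5", "S6")]

    def idx(a: float, b: float) -> slice:
        lo = max(0, math.ceil(a * fs - 1e-9))
        hi = min(n, math.ceil(b * fs - 1e-9))
        return slice(lo, hi)

    for a, b, kind, param in timeline.segments:
        if kind == "stance":
            d = b - a
            heel_sl = idx(a, a + 0.55 * d)
            fore_sl = idx(a + 0.35 * d, b)
            pressures[heel_sl, heel] = np.maximum(pressures[heel_sl, heel], _HEEL_PEAK_KPA)
            for c in forefoot:
                pressures[fore_sl, c] = np.maximum(pressures[fore_sl, c], _FOREFOOT_PEAK_KPA)
        elif kind == "hold":
            sl = idx(a, b)
            pressures[sl, heel] = np.maximum(pressures[sl, heel], _HEEL_PEAK_KPA)
            for c in forefoot:
                pressures[sl, c] = np.maximum(pressures[sl, c], _FOREFOOT_PEAK_KPA)
        elif kind == "tremble":
            sl = idx(a, b)
            pressures[sl, heel] = np.maximum(pressures[sl, heel], _HEEL_PEAK_KPA)
            t = np.arange(sl.start, sl.stop) / fs
            wave = 27.5 + 20.0 * np.sin(2 * math.pi * param * (t - a))
            for c in forefoot:
                pressures[sl, c] = np.maximum(pressures[sl, c], wave)
        else:  # pragma: no cover - internal invariant
            raise ConfigError(f"unknown segment kind {kind!r}")
    return pressures


def simulate_recording(
    config: SimConfig, layout: Optional[SensorLayout] = None
) -> SimulatedRecording:
    """Generate one labeled bilateral recording.

    Truth intervals record the *realized* episodes: for long-double-support
    manifestations the interval starts when both feet actually became loaded
    (at or slightly before the planned start, depending on the gait phase at
    the seam) and ends exactly at the planned episode end.
    """
    layout = layout or SensorLayout.default()
    if layout.thresholds().max() >= _HEEL_PEAK_KPA:
        raise ConfigError("layout thresholds exceed the synthesized pressure amplitudes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    plan = plan_episodes(config)
    walker = _Walker(config, rng)
    truth_rows: list[tuple[float, float, str]] = []
    t_fo = walker._ds()  # first foot-off after the both-loaded start
    for ep in plan:
        seam_state, lander, deferred = walker.walk_until(t_fo, ep.start_s)
        truth, t_fo = walker.inject(ep, seam_state, lander, deferred)
        truth_rows.append(truth)
    walker.walk_until(t_fo, config.duration_s)
    walker.finish(config.duration_s)

    n = int(round(config.duration_s * config.sampling_rate))
    pressures = {
        foot: _rasterize_foot(walker.feet[foot], layout, n, config.sampling_rate)
        for foot in ("left", "right")
    }
    streams = {
        foot: binarize(pressures[foot], layout, config.sampling_rate, foot=foot)
        for foot in ("left", "right")
    }
    return SimulatedRecording(
        left=streams["left"],
        right=streams["right"],
        pressures=pressures,
        truth=TruthLabels(tuple(truth_rows)),
        plan=plan,
        config=config,
    )
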