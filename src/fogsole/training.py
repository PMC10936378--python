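"""Fuzzy-zone threshold training and event-level evaluation.

Training operates on labeled *instances*: every double-support episode and
every maximal same-foot swing run becomes one instance whose dimensionless
ratio compares it against the calibration baseline (episode duration over
``baseline_ds`` for double support; ``baseline_sw`` over the shortest swing
of the run for swings).  With ground-truth FoG intervals, the ratio axis
splits into a normal-gait zone, a FoG zone, and a *fuzzy zone* in between —
bounded below by the largest normal ratio and above by the smallest FoG
ratio (stored sorted).  The working threshold ``k`` is the grid point inside
the fuzzy zone that maximizes sensitivity + specificity, the same criterion
used to obtain the shipped clinical defaults k_ds = 4.7 and k_sw = 4.5.

Evaluation is event-framed: predictions are greedily matched one-to-one to
truth intervals (truth expanded by a tolerance absorbing annotation jitter),
giving sensitivity/specificity/accuracy plus the correct/over/under
detection percentages used in the clinical accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateZoneError, EmptyInputError, ParameterError
from .detect import CalibrationProfile, DetectionThresholds, FogEvent
from .events import PhaseEpisode, double_support_episodes, swing_episodes

_EPS = 1e-9


@dataclass(frozen=True)
class LabeledInstance:
    """One training/evaluation instance on the dimensionless ratio axis."""

    kind: str  # "ds_episode" or "swing_run"
    ratio: float
    label: str  # "fog" or "normal"
    start_s: float
    end_s: float
    foot: str = "both"

    def __post_init__(self) -> None:
        if self.kind not in ("ds_episode", "swing_run"):
            raise ParameterError(f"unknown instance kind {self.kind!r}")
        if self.label not in ("fog", "normal"):
            raise ParameterError(f"unknown label {self.label!r}")
        if not self.ratio > 0:
            raise ParameterError("instance ratio must be positive")


@dataclass(frozen=True)
class FuzzyZone:
    """Ratio interval between the largest normal and smallest FoG values."""

    low: float
    high: float


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


@dataclass(frozen=True)
class DetectionAccounting:
    """Correct/over/under detection percentages from event counts.

    Follows the clinical accounting of triggered reminders versus
    human-verified events: ``n_matched`` counts *predictions* that coincide
    with true FoG (several reminders during one long freeze are each
    verified), while ``n_matched_true`` counts distinct *truth* episodes
    that were found.  correct_pct + over_pct = 100 whenever n_pred > 0.
    """

    n_pred: int
    n_true: int
    n_matched: int
    n_matched_true: int

    @property
    def correct_pct(self) -> float:
        return 100.0 * self.n_matched / self.n_pred if self.n_pred else float("nan")

    @property
    def over_pct(self) -> float:
        return 100.0 * (self.n_pred - self.n_matched) / self.n_pred if self.n_pred else float("nan")

    @property
    def under_pct(self) -> float:
        if not self.n_true:
            return float("nan")
        return 100.0 * (self.n_true - self.n_matched_true) / self.n_true


@dataclass(frozen=True)
class LatencySummary:
    """Detection latency (onset minus truth start) statistics per event kind."""

    mean: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class TrainingResult:
    """Outcome of a fuzzy-zone grid search for one instance kind."""

    k: float
    sensitivity: float
    specificity: float
    zone: FuzzyZone
    grid: np.ndarray
    scores: np.ndarray


def _overlaps_truth(start_s: float, end_s: float, intervals) -> bool:
    return any(start_s < e and s < end_s for s, e, *_ in intervals)


def build_instances(
    episodes: Sequence[PhaseEpisode],
    truth: Sequence[tuple],
    profile: CalibrationProfile,
    kind_aware: bool = True,
) -> list[LabeledInstance]:
    """Turn segmented episodes plus truth intervals into labeled instances.

    Truth rows are ``(start_s, end_s, kind)`` tuples (or TruthLabels rows).
    With ``kind_aware`` (default), double-support episodes are labeled fog
    only by LDDS truth and swing runs only by same-foot SSW truth — the two
    indices respond to different FoG manifestations and are trained
    independently.  Swing runs are maximal sequences of consecutive
    same-label swings of one foot; the run ratio uses the shortest swing in
    the run.  Truncated episodes are excluded.
    """
    truth = [(float(s), float(e), str(k)) for s, e, k in truth]
    ldds = [t for t in truth if t[2] == "LDDS"]
    ssw = {
        "left": [t for t in truth if t[2] == "SSW_L"],
        "right": [t for t in truth if t[2] == "SSW_R"],
    }
    instances: list[LabeledInstance] = []
    for ep in double_support_episodes(episodes):
        if ep.truncated:
            continue
        pool = ldds if kind_aware else truth
        label = "fog" if _overlaps_truth(ep.start_s, ep.end_s, pool) else "normal"
        instances.append(
            LabeledInstance(
                kind="ds_episode",
                ratio=ep.duration / profile.baseline_ds,
                label=label,
                start_s=ep.start_s,
                end_s=ep.end_s,
            )
        )
    for foot in ("left", "right"):
        swings = [ep for ep in swing_episodes(episodes, foot) if not ep.truncated]
        pool = ssw[foot] if kind_aware else truth
        labels = [
            "fog" if _overlaps_truth(ep.start_s, ep.end_s, pool) else "normal" for ep in swings
        ]
        i = 0
        while i < len(swings):
            j = i
            while j + 1 < len(swings) and labels[j + 1] == labels[i]:
                j += 1
            run = swings[i : j + 1]
            instances.append(
                LabeledInstance(
                    kind="swing_run",
                    ratio=profile.baseline_sw / min(ep.duration for ep in run),
                    label=labels[i],
                    start_s=run[0].start_s,
                    end_s=run[-1].end_s,
                    foot=foot,
                )
            )
            i = j + 1
    instances.sort(key=lambda x: (x.start_s, x.end_s))
    return instances


def compute_fuzzy_zone(instances: Sequence[LabeledInstance]) -> FuzzyZone:
    """Zone bounded by the smallest fog ratio and the largest normal ratio."""
    fog = [x.ratio for x in instances if x.label == "fog"]
    normal = [x.ratio for x in instances if x.label == "normal"]
    if not fog or not normal:
        raise DegenerateZoneError(
            f"need both classes to bound a fuzzy zone (fog: {len(fog)}, normal: {len(normal)})"
        )
    lo, hi = min(fog), max(normal)
    return FuzzyZone(low=min(lo, hi), high=max(lo, hi))


def _scores_on_grid(
    ratios: np.ndarray, labels_fog: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity for the classifier fog <=> ratio >= k."""
    pred = ratios[np.newaxis, :] >= grid[:, np.newaxis] - _EPS
    fog = labels_fog[np.newaxis, :]
    tp = (pred & fog).sum(axis=1)
    fn = (~pred & fog).sum(axis=1)
    tn = (~pred & ~fog).sum(axis=1)
    fp = (pred & ~fog).sum(axis=1)
    return tp / (tp + fn), tn / (tn + fp)


def train_thresholds(
    instances: Sequence[LabeledInstance], grid_step: float = 0.1
) -> TrainingResult:
    """Grid search over the fuzzy zone maximizing sensitivity + specificity.

    Candidates are ``{low, low + step, ...}`` up to ``high``.  Ties are
    broken by the midpoint of the longest maximal-scoring contiguous grid
    interval, rounding to the lower grid point on an exact half.  The grid
    step matches the reported precision of the clinical defaults.
    """
    if grid_step <= 0:
        raise ParameterError("grid_step must be positive")
    zone = compute_fuzzy_zone(instances)
    n_pts = int(math.floor((zone.high - zone.low) / grid_step + _EPS)) + 1
    grid = zone.low + grid_step * np.arange(n_pts)
    ratios = np.array([x.ratio for x in instances])
    fog = np.array([x.label == "fog" for x in instances])
    sens, spec = _scores_on_grid(ratios, fog, grid)
    # threshold classifiers are monotone along the grid by construction
    assert np.all(np.diff(sens) <= _EPS), "sensitivity must be non-increasing in k"
    assert np.all(np.diff(spec) >= -_EPS), "specificity must be non-decreasing in k"
    scores = sens + spec
    best = scores.max()
    is_best = scores >= best - _EPS
    # longest contiguous run of maximizers (first such run on ties)
    best_run, cur_start = None, None
    for i, flag in enumerate(list(is_best) + [False]):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if best_run is None or (i - cur_start) > (best_run[1] - best_run[0] + 1):
                best_run = (cur_start, i - 1)
            cur_start = None
    i0, i1 = best_run
    pick = (i0 + i1) // 2  # midpoint; floor resolves the exact-half case downward
    return TrainingResult(
        k=float(grid[pick]),
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        zone=zone,
        grid=grid,
        scores=scores,
    )


def train_detection_thresholds(
    instances: Sequence[LabeledInstance],
    grid_step: float = 0.1,
    m_sw: int = 2,
    merge_gap: float = 0.5,
) -> DetectionThresholds:
    """Train k_ds on double-support instances and k_sw on swing-run instances."""
    ds = [x for x in instances if x.kind == "ds_episode"]
    sw = [x for x in instances if x.kind == "swing_run"]
    return DetectionThresholds(
        k_ds=train_thresholds(ds, grid_step).k,
        k_sw=train_thresholds(sw, grid_step).k,
        m_sw=m_sw,
        merge_gap=merge_gap,
    )


def match_events(
    predicted: Sequence[FogEvent],
    truth: Sequence[tuple],
    tol: float = 0.5,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of predictions to truth, in time order.

    Truth intervals are expanded by ``tol`` on both sides; a prediction
    matches a truth interval iff they overlap.  Returns (pred_idx,
    truth_idx) pairs.
    """
    if tol < 0:
        raise ParameterError("tol must be non-negative")
    truth = [(float(s), float(e), str(k)) for s, e, k in truth]
    pred_order = sorted(range(len(predicted)), key=lambda i: predicted[i].start_s)
    truth_order = sorted(range(len(truth)), key=lambda i: truth[i][0])
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi in pred_order:
        ev = predicted[pi]
        for ti in truth_order:
            if ti in matched_truth:
                continue
            s, e, _ = truth[ti]
            if ev.overlaps(s - tol, e + tol):
                matched_truth.add(ti)
                pairs.append((pi, ti))
                break
    return pairs


def evaluate_events(
    predicted: Sequence[FogEvent],
    truth: Sequence[tuple],
    tol: float = 0.5,
    instances: Optional[Sequence[LabeledInstance]] = None,
    thresholds: Optional[DetectionThresholds] = None,
) -> tuple[EvalMetrics, DetectionAccounting]:
    """Event-level metrics plus correct/over/under detection accounting.

    TP/FN count matched/unmatched truth episodes and FP unmatched
    predictions.  TN counts normal-labeled instances that the thresholds do
    not flag; pass the instance list (and the thresholds applied to it) to
    populate it, otherwise TN = 0.
    """
    pairs = match_events(predicted, truth, tol)
    n_matched_true = len(pairs)
    tp = n_matched_true
    fn = len(truth) - n_matched_true
    fp = len(predicted) - n_matched_true
    # a prediction is "correct" (verified) if it coincides with any true
    # episode, independent of the one-to-one pairing above
    expanded = [(float(s) - tol, float(e) + tol) for s, e, *_ in truth]
    n_matched = sum(1 for ev in predicted if any(ev.overlaps(s, e) for s, e in expanded))
    tn = 0
    if instances is not None:
        if thresholds is None:
            raise ParameterError("thresholds are required to count unflagged normal instances")
        for x in instances:
            if x.label != "normal":
                continue
            k = thresholds.k_ds if x.kind == "ds_episode" else thresholds.k_sw
            if x.ratio < k - _EPS:
                tn += 1
    metrics = EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
    accounting = DetectionAccounting(
        n_pred=len(predicted),
        n_true=len(truth),
        n_matched=n_matched,
        n_matched_true=n_matched_true,
    )
    return metrics, accounting


def latency_stats(
    predicted: Sequence[FogEvent],
    truth: Sequence[tuple],
    tol: float = 0.5,
) -> dict[str, LatencySummary]:
    """Per-kind detection latency (onset_s minus truth start) over matches."""
    pairs = match_events(predicted, truth, tol)
    if not pairs:
        return {}
    truth = [(float(s), float(e), str(k)) for s, e, k in truth]
    by_kind: dict[str, list[float]] = {}
    for pi, ti in pairs:
        lat = predicted[pi].onset_s - truth[ti][0]
        by_kind.setdefault(truth[ti][2], []).append(lat)
    return {
        kind: LatencySummary(
            mean=float(np.mean(v)), min=float(np.min(v)), max=float(np.max(v)), n=len(v)
        )
        for kind, v in sorted(by_kind.items())
    }
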