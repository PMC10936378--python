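"""End-to-end synthetic cohort protocol.

Mirrors the two-phase clinical workflow on generated data: each recording
starts with a clean 30 s walk used for per-user calibration; thresholds are
trained on one group of recordings (fuzzy-zone grid search, pooled
instances) and evaluated on a held-out group, both offline and through the
packetized streaming detector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .detect import (
    CalibrationProfile,
    DetectionThresholds,
    FogEvent,
    detect_fog_offline,
)
from .events import segment_phases
from .signals import CombinedSignal, combine_signal
from .simulate import SimConfig, SimulatedRecording, simulate_recording
from .streaming import packetize, stream_detect
from .training import (
    DetectionAccounting,
    EvalMetrics,
    LabeledInstance,
    build_instances,
    evaluate_events,
    match_events,
    train_detection_thresholds,
)


@dataclass(frozen=True)
class RecordingBundle:
    """One simulated recording with its combined signals and calibration."""

    recording: SimulatedRecording
    left: CombinedSignal
    right: CombinedSignal
    profile: CalibrationProfile


@dataclass(frozen=True)
class CohortResult:
    """Aggregated outcome of a train/test cohort run."""

    thresholds: DetectionThresholds
    offline_metrics: EvalMetrics
    offline_accounting: DetectionAccounting
    stream_accounting: DetectionAccounting
    latencies_s: tuple[float, ...]  # matched offline onset latencies


def prepare_recording(seed: int, config: Optional[SimConfig] = None) -> RecordingBundle:
    """Simulate one recording and calibrate on its clean lead-in window."""
    config = replace(config or SimConfig(), seed=seed)
    rec = simulate_recording(config)
    left = combine_signal(rec.left)
    right = combine_signal(rec.right)
    cal_left = combine_signal(rec.left.window(0.0, config.clean_lead_s))
    cal_right = combine_signal(rec.right.window(0.0, config.clean_lead_s))
    profile = calibrate_bundle(cal_left, cal_right)
    return RecordingBundle(recording=rec, left=left, right=right, profile=profile)


def calibrate_bundle(cal_left: CombinedSignal, cal_right: CombinedSignal) -> CalibrationProfile:
    from .detect import calibrate

    return calibrate(cal_left, cal_right)


def train_on_recordings(
    bundles: Sequence[RecordingBundle], grid_step: float = 0.1
) -> DetectionThresholds:
    """Pool labeled instances across recordings and train k_ds / k_sw."""
    instances: list[LabeledInstance] = []
    for b in bundles:
        episodes = segment_phases(b.left, b.right)
        instances.extend(build_instances(episodes, b.recording.truth, b.profile))
    return train_detection_thresholds(instances, grid_step=grid_step)


def run_cohort(
    train_seeds: Sequence[int],
    test_seeds: Sequence[int],
    config: Optional[SimConfig] = None,
    packet_size: int = 8,
    tol: float = 0.5,
) -> CohortResult:
    """Train on one recording group, evaluate offline + streaming on another."""
    train = [prepare_recording(s, config) for s in train_seeds]
    thresholds = train_on_recordings(train)

    tp = fp = tn = fn = 0
    n_pred = n_true = n_matched = n_matched_true = 0
    s_pred = s_true = s_matched = s_matched_true = 0
    latencies: list[float] = []
    for seed in test_seeds:
        b = prepare_recording(seed, config)
        truth = b.recording.truth.intervals
        det = detect_fog_offline(b.left, b.right, b.profile, thresholds)
        instances = build_instances(det.episodes, truth, b.profile)
        metrics, accounting = evaluate_events(
            det.events, truth, tol=tol, instances=instances, thresholds=thresholds
        )
        tp += metrics.tp
        fp += metrics.fp
        tn += metrics.tn
        fn += metrics.fn
        n_pred += accounting.n_pred
        n_true += accounting.n_true
        n_matched += accounting.n_matched
        n_matched_true += accounting.n_matched_true
        for pi, ti in match_events(det.events, truth, tol=tol):
            latencies.append(det.events[pi].onset_s - truth[ti][0])

        packets = packetize(b.recording.left, b.recording.right, packet_size=packet_size)
        streamed: list[FogEvent] = [
            ev
            for ev, _decision in stream_detect(
                packets, b.profile, thresholds, b.left.sampling_rate, t0=b.left.t0
            )
        ]
        _, s_acc = evaluate_events(streamed, truth, tol=tol)
        s_pred += s_acc.n_pred
        s_true += s_acc.n_true
        s_matched += s_acc.n_matched
        s_matched_true += s_acc.n_matched_true

    return CohortResult(
        thresholds=thresholds,
        offline_metrics=EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn),
        offline_accounting=DetectionAccounting(
            n_pred=n_pred, n_true=n_true, n_matched=n_matched, n_matched_true=n_matched_true
        ),
        stream_accounting=DetectionAccounting(
            n_pred=s_pred, n_true=s_true, n_matched=s_matched, n_matched_true=s_matched_true
        ),
        latencies_s=tuple(latencies),
    )
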