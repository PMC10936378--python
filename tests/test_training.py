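import numpy as np
import pytest

from fogsole.detect import CalibrationProfile, DetectionThresholds, FogEvent
from fogsole.errors import DegenerateZoneError, ParameterError
from fogsole.events import PhaseEpisode
from fogsole.training import (
    DetectionAccounting,
    LabeledInstance,
    build_instances,
    compute_fuzzy_zone,
    evaluate_events,
    latency_stats,
    match_events,
    train_thresholds,
)


def inst(ratio, label, kind="ds_episode", start=0.0, end=1.0):
    return LabeledInstance(kind=kind, ratio=ratio, label=label, start_s=start, end_s=end)


def instance_set(normal, fog, kind="ds_episode"):
    out = []
    for i, r in enumerate(normal):
        out.append(inst(r, "normal", kind, start=float(i), end=float(i) + 0.5))
    for i, r in enumerate(fog):
        out.append(inst(r, "fog", kind, start=100.0 + i, end=100.5 + i))
    return out


def brute_force_train(instances, grid_step=0.1):
    """Independent exhaustive grid evaluation with the same tie-break rule."""
    fog = sorted(x.ratio for x in instances if x.label == "fog")
    normal = sorted(x.ratio for x in instances if x.label == "normal")
    lo, hi = sorted((fog[0], normal[-1]))
    grid, k = [], lo
    while k <= hi + 1e-9:
        grid.append(k)
        k += grid_step
    scores = []
    for k in grid:
        tp = sum(1 for r in fog if r >= k - 1e-9)
        tn = sum(1 for r in normal if r < k - 1e-9)
        scores.append(tp / len(fog) + tn / len(normal))
    best = max(scores)
    runs, start = [], None
    for i, s in enumerate(scores + [-1]):
        if s >= best - 1e-9 and start is None:
            start = i
        elif s < best - 1e-9 and start is not None:
            runs.append((start, i - 1))
            start = None
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    return grid[(i0 + i1) // 2]


class TestFuzzyZone:
    def test_separated_classes(self):
        zone = compute_fuzzy_zone(instance_set([1.0, 1.5, 2.0], [6.0, 7.0]))
        assert (zone.low, zone.high) == (2.0, 6.0)

    def test_overlapping_classes_sort_the_boundaries(self):
        zone = compute_fuzzy_zone(instance_set([1, 2, 3], [2.5, 4, 5]))
        assert (zone.low, zone.high) == (2.5, 3.0)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateZoneError):
            compute_fuzzy_zone(instance_set([], [6.0, 7.0]))


class TestTrainThresholds:
    def test_unique_maximizer_in_overlapping_zone(self):
        res = train_thresholds(instance_set([1, 2, 3], [2.5, 4, 5]))
        assert res.k == pytest.approx(2.5)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(2 / 3)

    def test_separable_zone_tie_breaks_to_midpoint_rounded_down(self):
        res = train_thresholds(instance_set([1.0, 1.5, 2.0], [6.0, 7.0]))
        assert res.k == pytest.approx(4.0)  # midpoint of {2.1..6.0} is 4.05
        assert res.sensitivity + res.specificity == pytest.approx(2.0)

    def test_perfect_recovery_on_separable_instances(self, rng):
        # normal ratios fill (0.5, 2], fog ratios [6, 12): the trained k must
        # fall in the gap and classify perfectly
        for _ in range(20):
            normal = list(rng.uniform(0.5, 2.0, size=rng.integers(3, 15))) + [2.0]
            fog = [6.0] + list(rng.uniform(6.0, 12.0, size=rng.integers(2, 10)))
            res = train_thresholds(instance_set(normal, fog))
            assert 2.0 < res.k <= 6.0
            assert res.sensitivity + res.specificity == pytest.approx(2.0)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n_n = int(rng.integers(2, 25))
            n_f = int(rng.integers(2, 25))
            normal = np.round(rng.uniform(0.5, 5.0, n_n), 3)
            fog = np.round(rng.uniform(1.0, 9.0, n_f), 3)
            instances = instance_set(list(normal), list(fog))
            assert train_thresholds(instances).k == pytest.approx(
                brute_force_train(instances)
            )

    def test_sensitivity_and_specificity_are_monotone_over_the_grid(self, rng):
        instances = instance_set(list(rng.uniform(0.5, 4, 20)), list(rng.uniform(2, 9, 20)))
        res = train_thresholds(instances)
        ratios = np.array([x.ratio for x in instances])
        fog = np.array([x.label == "fog" for x in instances])
        sens = [( (ratios >= k - 1e-9) & fog).sum() / fog.sum() for k in res.grid]
        spec = [(~(ratios >= k - 1e-9) & ~fog).sum() / (~fog).sum() for k in res.grid]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestBuildInstances:
    PROFILE = CalibrationProfile.from_baselines(0.15, 0.5)

    def test_ds_episode_overlapping_ldds_truth_is_fog(self):
        episodes = [PhaseEpisode("double_support", "both", 1.0, 3.0, False)]
        out = build_instances(episodes, [(0.5, 4.0, "LDDS")], self.PROFILE)
        assert len(out) == 1
        assert out[0].label == "fog"

    def test_ratio_arithmetic(self):
        episodes = [PhaseEpisode("double_support", "both", 0.0, 0.45, False)]
        out = build_instances(episodes, [], self.PROFILE)
        assert out[0].ratio == pytest.approx(3.0)

    def test_no_truth_means_all_normal(self):
        episodes = [
            PhaseEpisode("double_support", "both", 0.0, 0.2, False),
            PhaseEpisode("swing", "left", 0.3, 0.8, False),
        ]
        out = build_instances(episodes, [], self.PROFILE)
        assert all(x.label == "normal" for x in out)

    def test_swing_runs_group_by_label_and_use_min_duration(self):
        episodes = [
            PhaseEpisode("swing", "left", 0.0, 0.5, False),
            PhaseEpisode("swing", "left", 1.0, 1.4, False),
            PhaseEpisode("swing", "left", 10.0, 10.1, False),
            PhaseEpisode("swing", "left", 10.5, 10.58, False),
        ]
        out = build_instances(episodes, [(9.9, 11.0, "SSW_L")], self.PROFILE)
        runs = [x for x in out if x.kind == "swing_run"]
        assert [x.label for x in runs] == ["normal", "fog"]
        assert runs[0].ratio == pytest.approx(0.5 / 0.4)
        assert runs[1].ratio == pytest.approx(0.5 / 0.08)

    def test_kind_aware_labeling_ignores_cross_kind_truth(self):
        # a short double support inside a shuffling episode is not long-DS fog
        episodes = [PhaseEpisode("double_support", "both", 10.0, 10.2, False)]
        out = build_instances(episodes, [(9.9, 11.0, "SSW_L")], self.PROFILE)
        assert out[0].label == "normal"


class TestEvaluateEvents:
    def test_perfect_predictions(self):
        truth = [(1.0, 3.0, "LDDS"), (5.0, 6.0, "SSW_L")]
        predicted = [FogEvent("LDDS", 1.0, 3.0, 1.5), FogEvent("SSW_L", 5.0, 6.0, 5.5)]
        metrics, acc = evaluate_events(predicted, truth)
        assert (metrics.sensitivity, metrics.accuracy) == (1.0, 1.0)
        assert acc.correct_pct == 100.0 and acc.over_pct == 0.0 and acc.under_pct == 0.0

    def test_clinical_accounting_from_printed_counts(self):
        acc = DetectionAccounting(n_pred=662, n_true=623, n_matched=623, n_matched_true=623)
        assert round(acc.correct_pct, 1) == 94.1
        assert round(acc.over_pct, 1) == 5.9
        assert acc.under_pct == 0.0

    def test_unmatched_prediction_is_a_false_positive(self):
        truth = [(float(k), float(k) + 0.5, "LDDS") for k in range(0, 40, 4)]
        predicted = [FogEvent("LDDS", s, e, s) for s, e, _ in truth]
        predicted.append(FogEvent("LDDS", 100.0, 101.0, 100.0))
        metrics, acc = evaluate_events(predicted, truth)
        assert (metrics.fp, metrics.fn) == (1, 0)
        assert acc.n_matched == 10

    def test_correct_plus_over_is_always_100(self, rng):
        for _ in range(20):
            truth = [(float(k), k + 1.0, "LDDS") for k in range(0, 60, 6)]
            predicted = [
                FogEvent("LDDS", float(rng.uniform(0, 70)), float(rng.uniform(0, 70)) + 0.5, 0.0)
                for _ in range(int(rng.integers(1, 8)))
            ]
            _, acc = evaluate_events(predicted, truth)
            assert acc.correct_pct + acc.over_pct == pytest.approx(100.0)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            match_events([], [], tol=-0.1)


class TestLatencyStats:
    def test_single_pair(self):
        truth = [(10.0, 12.0, "LDDS")]
        predicted = [FogEvent("LDDS", 10.0, 12.0, 10.71875)]
        stats = latency_stats(predicted, truth)
        assert stats["LDDS"].mean == stats["LDDS"].min == stats["LDDS"].max == pytest.approx(0.71875)

    def test_zero_latency_when_onsets_hit_truth_starts(self):
        truth = [(1.0, 2.0, "LDDS"), (5.0, 6.0, "SSW_R")]
        predicted = [FogEvent("LDDS", 1.0, 2.0, 1.0), FogEvent("SSW_R", 5.0, 6.0, 5.0)]
        stats = latency_stats(predicted, truth)
        assert stats["LDDS"].mean == 0.0 and stats["SSW_R"].mean == 0.0

    def test_mean_min_max(self):
        truth = [(1.0, 2.0, "LDDS"), (5.0, 6.0, "LDDS")]
        predicted = [FogEvent("LDDS", 1.0, 2.0, 1.2), FogEvent("LDDS", 5.0, 6.0, 5.4)]
        s = latency_stats(predicted, truth)["LDDS"]
        assert (s.mean, s.min, s.max) == (pytest.approx(0.3), pytest.approx(0.2), pytest.approx(0.4))

    def test_no_matches_gives_empty_summary(self):
        assert latency_stats([], [(0.0, 1.0, "LDDS")]) == {}
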