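import math

import numpy as np
import pytest

from fogsole.detect import (
    CalibrationProfile,
    DetectionThresholds,
    OnlineFogDetector,
    calibrate,
    detect_fog_offline,
    fog_indices,
    merge_events,
)
from fogsole.errors import (
    InsufficientCalibrationError,
    ParameterError,
    SequencingError,
)
from fogsole.events import PhaseEpisode, segment_phases

from conftest import bits_from_stances, comb, random_pair

FS = 32.0
DT = 1.0 / FS


def ds_ep(start, dur, truncated=False):
    return PhaseEpisode("double_support", "both", start, start + dur, truncated)


def sw_ep(start, dur, foot="left", truncated=False):
    return PhaseEpisode("swing", foot, start, start + dur, truncated)


def random_profile(rng):
    return CalibrationProfile.from_baselines(
        baseline_ds=float(rng.uniform(0.08, 0.3)), baseline_sw=float(rng.uniform(0.2, 0.6))
    )


def run_online(left, right, profile, thresholds):
    det = OnlineFogDetector(profile, thresholds, left.sampling_rate, t0=left.t0)
    notices = []
    for cl, cr in zip(left.bits, right.bits):
        notices.extend(det.update(int(cl), int(cr)))
    det.finalize()
    return det, notices


class TestCalibrate:
    def test_baseline_arithmetic(self):
        profile = CalibrationProfile.from_baselines(0.15, 0.5)
        assert profile.baseline_sw_recip == pytest.approx(2.0)

    def test_means_exclude_truncated_and_pool_both_feet(self):
        fs = 10.0
        # right loads briefly twice inside long left stances: DS = {0.1, 0.2}
        left = comb(bits_from_stances(10.0, fs, [(0, 1.5), (1.9, 3.0), (3.4, 10)]), "left", fs)
        right = comb(bits_from_stances(10.0, fs, [(0.5, 0.6), (2.0, 2.2)]), "right", fs)
        profile = calibrate(left, right, min_episodes=1)
        assert profile.baseline_ds == pytest.approx(0.15)
        # pooled non-truncated swings: left {0.4, 0.4}, right {1.4}
        assert profile.baseline_sw == pytest.approx((0.4 + 0.4 + 1.4) / 3)
        assert profile.n_ds == 2 and profile.n_sw == 3

    def test_too_few_episodes_names_the_deficient_phase(self):
        fs = 10.0
        left = comb(bits_from_stances(10.0, fs, [(0, 1.5), (1.9, 3.0), (3.4, 10)]), "left", fs)
        right = comb(bits_from_stances(10.0, fs, [(0.5, 0.6), (2.0, 2.2)]), "right", fs)
        with pytest.raises(InsufficientCalibrationError, match="double_support"):
            calibrate(left, right, min_episodes=8)


class TestFogIndices:
    PROFILE = CalibrationProfile.from_baselines(0.15, 0.5)
    THR = DetectionThresholds(k_ds=4.7, k_sw=4.5)

    def test_long_double_support_boundary(self):
        flags = fog_indices([ds_ep(0, 0.70), ds_ep(2, 0.71)], self.PROFILE, self.THR)
        assert [f.i_ds for f in flags] == [False, True]  # bound 4.7 * 0.15 = 0.705

    def test_second_consecutive_short_swing_flags(self):
        # short-swing bound 0.5 / 4.5 = 0.111...
        episodes = [sw_ep(0, 0.10), sw_ep(1, 0.10)]
        flags = fog_indices(episodes, self.PROFILE, self.THR)
        assert [f.short_swing for f in flags] == [True, True]
        assert [f.i_sw for f in flags] == [False, True]

    def test_other_foot_run_does_not_interleave(self):
        episodes = [sw_ep(0, 0.10, "left"), sw_ep(1, 0.10, "right"), sw_ep(2, 0.10, "left")]
        flags = fog_indices(episodes, self.PROFILE, self.THR)
        assert [f.i_sw for f in flags] == [False, False, True]

    def test_baseline_gait_never_flags(self):
        episodes = [ds_ep(0, 0.15), sw_ep(1, 0.5), sw_ep(2, 0.5), ds_ep(3, 0.15)]
        flags = fog_indices(episodes, self.PROFILE, self.THR)
        assert not any(f.i_ds or f.i_sw for f in flags)


class TestOfflineDetection:
    PROFILE = CalibrationProfile.from_baselines(0.15, 0.5)
    THR = DetectionThresholds(k_ds=4.7, k_sw=4.5)

    def test_injected_akinesia_block_yields_one_ldds_event(self):
        left = comb(np.ones(int(12 * FS), dtype=np.uint8), "left", FS)
        right = comb(
            bits_from_stances(12.0, FS, [(k, k + 0.25) for k in range(5)] + [(6.0, 8.0)]
                              + [(k + 0.5, k + 0.75) for k in range(9, 11)]),
            "right",
            FS,
        )
        det = detect_fog_offline(left, right, self.PROFILE, self.THR)
        assert [ev.kind for ev in det.events] == ["LDDS"]
        assert det.events[0].start_s == pytest.approx(6.0)
        assert det.events[0].end_s == pytest.approx(8.0)

    def test_normal_gait_yields_no_events(self):
        left = comb(bits_from_stances(8.0, FS, [(k, k + 0.6) for k in range(8)]), "left", FS)
        right = comb(
            bits_from_stances(8.0, FS, [(k + 0.5, k + 1.1) for k in range(7)]), "right", FS
        )
        det = detect_fog_offline(left, right, self.PROFILE, self.THR)
        assert det.events == []
        assert not det.decision.fog.any()

    def test_nearby_events_merge_keeping_first_kind_and_earliest_onset(self):
        from fogsole.detect import FogEvent

        merged = merge_events(
            [FogEvent("LDDS", 1.0, 2.0, 1.7), FogEvent("LDDS", 2.3, 3.0, 2.9)], merge_gap=0.5
        )
        assert len(merged) == 1
        assert (merged[0].start_s, merged[0].end_s, merged[0].onset_s, merged[0].kind) == (
            1.0,
            3.0,
            1.7,
            "LDDS",
        )

    def test_gap_at_or_above_merge_gap_stays_separate(self):
        from fogsole.detect import FogEvent

        kept = merge_events(
            [FogEvent("LDDS", 1.0, 2.0, 1.7), FogEvent("SSW_L", 2.5, 3.0, 2.9)], merge_gap=0.5
        )
        assert len(kept) == 2

    def test_eq5_identity_fog_is_ds_or_sw(self, rng):
        for _ in range(50):
            left, right = random_pair(rng, 200)
            det = detect_fog_offline(left, right, random_profile(rng), self.THR)
            assert np.array_equal(det.decision.fog, det.decision.i_ds | det.decision.i_sw)

    def test_raising_thresholds_never_adds_flags(self, rng):
        # the flagged episode set and the per-sample decision support are
        # non-increasing in k_ds and k_sw
        for _ in range(30):
            left, right = random_pair(rng, 300)
            profile = random_profile(rng)
            episodes = segment_phases(left, right)
            prev_flags = None
            prev_decision = None
            for k in (1.5, 2.0, 3.0, 4.5):
                thr = DetectionThresholds(k_ds=k, k_sw=k)
                flags = {
                    (f.episode.start_s, f.episode.phase)
                    for f in fog_indices(episodes, profile, thr)
                    if f.i_ds or f.i_sw
                }
                decision = detect_fog_offline(left, right, profile, thr).decision
                if prev_flags is not None:
                    assert flags <= prev_flags
                    assert not (decision.fog & ~prev_decision.fog).any()
                prev_flags, prev_decision = flags, decision


class TestOnlineDetection:
    PROFILE = CalibrationProfile.from_baselines(0.15, 0.5)
    THR = DetectionThresholds(k_ds=4.7, k_sw=4.5)

    def test_ldds_onset_fires_at_the_accumulator_crossing(self):
        # bound 0.705 s; ceil(0.705 * 32) = 23 samples -> onset 0.71875 s
        # after the double support begins
        start = 2.0
        left = comb(np.ones(int(6 * FS), dtype=np.uint8), "left", FS)
        right = comb(bits_from_stances(6.0, FS, [(start, 5.0)]), "right", FS)
        _, notices = run_online(left, right, self.PROFILE, self.THR)
        assert len(notices) == 1
        assert notices[0].kind == "LDDS"
        assert notices[0].onset_s - start == pytest.approx(23 * DT) == pytest.approx(0.71875)

    def test_normal_stream_never_fires(self):
        left = comb(bits_from_stances(8.0, FS, [(k, k + 0.6) for k in range(8)]), "left", FS)
        right = comb(
            bits_from_stances(8.0, FS, [(k + 0.5, k + 1.1) for k in range(7)]), "right", FS
        )
        _, notices = run_online(left, right, self.PROFILE, self.THR)
        assert notices == []

    def test_out_of_order_timestamps_rejected(self):
        det = OnlineFogDetector(self.PROFILE, self.THR, FS)
        det.update(1, 1, t=0.0)
        with pytest.raises(SequencingError):
            det.update(1, 1, t=0.0)

    @pytest.mark.parametrize("n", [64, 200, 333])
    def test_online_equals_offline_on_randomized_streams(self, rng, n):
        for _ in range(100):
            left, right = random_pair(rng, n)
            profile = random_profile(rng)
            thr = DetectionThresholds(
                k_ds=float(rng.uniform(1.5, 5.0)), k_sw=float(rng.uniform(1.5, 5.0))
            )
            offline = detect_fog_offline(left, right, profile, thr)
            det, notices = run_online(left, right, profile, thr)
            assert det.events == offline.raw_events
            assert det.merged_events() == offline.events
            # every completed event announced its onset exactly once
            assert sorted(n.onset_s for n in notices) == sorted(
                e.onset_s for e in offline.raw_events
            )


class TestThresholdValidation:
    def test_k_must_exceed_one(self):
        with pytest.raises(ParameterError):
            DetectionThresholds(k_ds=1.0)

    def test_json_round_trip(self):
        thr = DetectionThresholds(k_ds=2.6, k_sw=3.1, m_sw=3, merge_gap=0.25)
        assert DetectionThresholds.from_json(thr.to_json()) == thr
        profile = CalibrationProfile.from_baselines(0.17, 0.44, 10, 20)
        assert CalibrationProfile.from_json(profile.to_json()) == profile
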