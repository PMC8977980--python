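import numpy as np
import pytest

import afdm
from afdm.burden import LOG_ENERGY_EPS, extract_activity_features
from afdm.simulate import synthesize_bursty_channel


class TestFeatures:
    def test_all_zero_channel_is_log_eps(self):
        f = extract_activity_features(np.zeros(1000), 1000.0)
        assert np.allclose(f.frame_values, np.log(LOG_ENERGY_EPS))

    def test_constant_sinusoid_is_flat(self):
        t = np.arange(5000) / 1000.0
        f = extract_activity_features(np.sin(2 * np.pi * 50 * t), 1000.0)
        assert np.ptp(f.frame_values) < 0.1

    def test_doubling_amplitude_adds_log4(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, 4000)
        f1 = extract_activity_features(x, 1000.0)
        f2 = extract_activity_features(2 * x, 1000.0)
        assert np.allclose(f2.frame_values - f1.frame_values, np.log(4.0), atol=1e-9)

    def test_short_channel_single_frame_fallback(self):
        f = extract_activity_features(np.ones(20), 1000.0)
        assert len(f) == 1

    def test_frame_count_formula(self):
        f = extract_activity_features(np.zeros(1000), 1000.0, frame_ms=50, hop_ms=25)
        assert len(f) == (1000 - 50) // 25 + 1


class TestBurdenScore:
    def test_silence_scores_near_zero(self):
        sig, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=0.0, seed=0)
        assert afdm.score_channel(sig, 1000.0, seed=0).score <= 0.05

    def test_continuous_activity_scores_near_one(self):
        sig, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=1.0, seed=0)
        assert afdm.score_channel(sig, 1000.0, seed=0).score >= 0.95

    def test_duty_cycle_recovered_against_mask_oracle(self):
        for seed in range(3):
            sig, mask = synthesize_bursty_channel(duration_s=10, duty_cycle=0.3, seed=seed)
            r = afdm.score_channel(sig, 1000.0, seed=seed)
            assert r.score == pytest.approx(mask.mean(), abs=0.05)

    def test_score_invariant_to_amplitude_rescaling(self):
        sig, _ = synthesize_bursty_channel(duration_s=10, duty_cycle=0.4, seed=2)
        r1 = afdm.score_channel(sig, 1000.0, seed=5)
        r2 = afdm.score_channel(100.0 * sig, 1000.0, seed=5)
        assert r1.score == pytest.approx(r2.score, abs=1e-12)

    def test_identical_seed_identical_result(self):
        sig, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=0.5, seed=3)
        r1 = afdm.score_channel(sig, 1000.0, seed=7)
        r2 = afdm.score_channel(sig, 1000.0, seed=7)
        assert r1.score == r2.score
        assert np.array_equal(r1.state_path, r2.state_path)
        assert np.array_equal(r1.means, r2.means)

    def test_score_bounded(self):
        sig, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=0.7, seed=4)
        r = afdm.score_channel(sig, 1000.0, seed=1)
        assert 0.0 <= r.score <= 1.0
        assert r.score == pytest.approx(r.state_path.mean())

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            afdm.fit_burden_hmm(extract_activity_features(np.zeros(100), 1000.0))


class TestAcquisitionBurden:
    def test_mixed_channels_average(self, geometry):
        silent, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=0.0, seed=0)
        busy, _ = synthesize_bursty_channel(duration_s=8, duty_cycle=1.0, seed=1)
        rng = np.random.default_rng(9)
        uni = rng.normal(0, 0.05, (len(silent), 20))
        uni[:, 0] = silent  # bipole (1,2) -> silent
        uni[:, 4] = busy  # bipole (5,6) -> busy
        bip = np.column_stack([uni[:, a - 1] - uni[:, b - 1] for a, b in geometry.bipole_pairs])
        acq = afdm.Acquisition(uni, bip, 1000.0, geometry, np.zeros(3))
        mean, scores, n_failed = afdm.burden_per_acquisition(acq, seed=0)
        assert n_failed == 0
        assert scores[0] <= 0.05 and scores[1] >= 0.95
        assert mean == pytest.approx(np.mean(scores))

    def test_channelwise_oracle_mean(self, geometry):
        duties = [0.2, 0.8, 0.5, 0.0, 1.0, 0.3, 0.6, 0.4, 0.9, 0.1]
        chans, masks = [], []
        for j, d in enumerate(duties):
            s, m = synthesize_bursty_channel(duration_s=10, duty_cycle=d, seed=j)
            chans.append(s)
            masks.append(m)
        rng = np.random.default_rng(9)
        uni = rng.normal(0, 0.01, (len(chans[0]), 20))
        for j, (a, b) in enumerate(geometry.bipole_pairs):
            uni[:, a - 1] += chans[j]  # bipolar = difference picks up the burst
        bip = np.column_stack([uni[:, a - 1] - uni[:, b - 1] for a, b in geometry.bipole_pairs])
        acq = afdm.Acquisition(uni, bip, 1000.0, geometry, np.zeros(3))
        mean, scores, _ = afdm.burden_per_acquisition(acq, seed=3)
        oracle = np.mean([m.mean() for m in masks])
        assert mean == pytest.approx(oracle, abs=0.07)


def test_monotone_in_duty_cycle():
    """Mean score never decreases as the generator's duty cycle grows."""
    means = []
    for duty in (0.1, 0.3, 0.5, 0.7, 0.9):
        scores = [
            afdm.score_channel(
                synthesize_bursty_channel(duration_s=8, duty_cycle=duty, seed=s)[0],
                1000.0,
                seed=s,
            ).score
            for s in range(5)
        ]
        means.append(np.mean(scores))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
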