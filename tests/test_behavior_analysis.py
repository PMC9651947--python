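"""Walking amplitude, Li thresholding, behaving classification, saccades."""

import numpy as np
import pytest
from scipy import stats

from glomcode import behavior_analysis as ba
from glomcode import synthetic_population as sp


def li_criterion_naive(values, threshold):
    """Independently coded Li cross-entropy (plain loop over the definition)."""
    lo = [v for v in values if v <= threshold]
    hi = [v for v in values if v > threshold]
    total = 0.0
    if lo and np.mean(lo) > 0:
        total += sum(lo) * np.log(np.mean(lo))
    if hi and np.mean(hi) > 0:
        total += sum(hi) * np.log(np.mean(hi))
    return -total


def li_exhaustive(values):
    u = np.unique(values)
    cands = (u[:-1] + u[1:]) / 2.0
    scores = [li_criterion_naive(values, c) for c in cands]
    return cands[int(np.argmin(scores))]


class TestWalkingAmplitude:
    def test_zero_and_pythagorean(self):
        assert ba.walking_amplitude([0.0], [0.0], [0.0])[0] == 0.0
        assert ba.walking_amplitude([3.0], [4.0], [0.0])[0] == 5.0

    def test_elementwise_norm_oracle(self):
        rng = np.random.default_rng(0)
        x, y, z = rng.normal(size=(3, 100))
        amp = ba.walking_amplitude(x, y, z)
        for i in range(100):
            assert np.isclose(amp[i], np.sqrt(x[i] ** 2 + y[i] ** 2 + z[i] ** 2))

    def test_sign_flip_and_axis_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x, y, z = rng.normal(size=(3, 50))
        a = ba.walking_amplitude(x, y, z)
        np.testing.assert_allclose(a, ba.walking_amplitude(-x, y, -z))
        np.testing.assert_allclose(a, ba.walking_amplitude(z, x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ba.walking_amplitude([1.0, 2.0], [1.0], [1.0])


class TestLiThreshold:
    def test_bimodal_sample_threshold_separates_modes(self):
        vals = np.concatenate([np.full(100, 0.1), np.full(100, 10.0)])
        thr = ba.li_threshold(vals)
        assert 0.1 < thr < 10.0

    def test_equals_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = np.concatenate([
                rng.gamma(2.0, 1.0, 80), rng.gamma(9.0, 2.0, 80)
            ])
            assert np.isclose(ba.li_threshold(vals), li_exhaustive(vals))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.gamma(2, 1, 100), rng.gamma(8, 2, 100)])
        thr = ba.li_threshold(vals)
        for c in (0.5, 3.0, 17.0):
            assert np.isclose(ba.li_threshold(c * vals), c * thr, rtol=1e-9)

    def test_agrees_with_skimage_reference(self):
        """Cross-check against the scikit-image iterative implementation."""
        from skimage.filters import threshold_li

        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.gamma(2, 1, 500), rng.gamma(9, 2, 500)])
        ours = ba.li_threshold(vals)
        ref = threshold_li(vals)
        assert abs(ours - ref) < 0.1 * vals.std()

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ba.li_threshold(np.full(10, 3.0))


class TestClassifyBehaving:
    def test_single_active_trial_flagged(self):
        time = np.arange(0, 30, 0.02)
        amp = np.full(len(time), 0.01)
        amp[(time >= 10) & (time < 14)] = 20.0
        wins = [(t, t + 4.0) for t in (0.0, 5.0, 10.0, 15.0, 20.0)]
        cls = ba.classify_behaving(amp, time, wins)
        np.testing.assert_array_equal(cls.behaving, [False, False, True, False, False])

    def test_boundary_fraction_inclusive(self):
        time = np.arange(0, 8, 0.02)
        amp = np.full(len(time), 0.01)
        amp[(time >= 4.0) & (time < 5.0)] = 50.0  # exactly 25% of a 4 s trial
        cls = ba.classify_behaving(amp, time, [(0.0, 4.0), (4.0, 8.0)])
        assert not cls.behaving[0] and cls.behaving[1]
        assert np.isclose(cls.fraction_above[1], 0.25)

    def test_recovers_generated_walking_bouts(self, walking_session):
        trace, traj, _ = walking_session
        wins = [(t, t + 4.0) for t in np.arange(0.0, 296.0, 6.0)]
        cls = ba.classify_behaving(trace.amplitude, trace.time, wins)
        bout_frac = np.array([
            np.mean(traj.forward_velocity[(traj.time >= a) & (traj.time < b)] > 0)
            for a, b in wins
        ])
        clear = (bout_frac <= 0.1) | (bout_frac >= 0.4)
        agreement = np.mean(cls.behaving[clear] == (bout_frac[clear] >= 0.25))
        assert agreement >= 0.95

    def test_empty_window_rejected(self):
        time = np.arange(0, 10, 0.02)
        with pytest.raises(ValueError):
            ba.classify_behaving(np.ones(len(time)), time, [(20.0, 24.0)])


class TestDetectSaccades:
    def test_three_pulses_three_events(self):
        time = np.arange(0, 10, 0.01)
        v = np.zeros(len(time))
        for onset in (2.0, 5.0, 8.0):
            v[(time >= onset) & (time < onset + 0.2)] = 300.0
        ev = ba.detect_saccades(v, time)
        assert len(ev) == 3
        np.testing.assert_allclose(ev.onset_times, [2.0, 5.0, 8.0], atol=0.011)
        np.testing.assert_allclose(ev.peak_speeds, 300.0)

    def test_subthreshold_trace_gives_empty_list(self):
        time = np.arange(0, 5, 0.01)
        ev = ba.detect_saccades(np.full(len(time), 100.0), time)
        assert len(ev) == 0

    def test_negative_velocity_excursions_detected(self):
        time = np.arange(0, 4, 0.01)
        v = np.zeros(len(time))
        v[(time >= 1.0) & (time < 1.2)] = -300.0
        ev = ba.detect_saccades(v, time)
        assert len(ev) == 1

    def test_invariant_to_subthreshold_noise(self):
        rng = np.random.default_rng(0)
        time = np.arange(0, 10, 0.01)
        v = np.zeros(len(time))
        for onset in (2.0, 6.0):
            v[(time >= onset) & (time < onset + 0.2)] = 300.0
        noisy = v + rng.uniform(-39.0, 39.0, len(time))  # < threshold/4
        a = ba.detect_saccades(v, time)
        b = ba.detect_saccades(noisy, time)
        assert len(a) == len(b)
        np.testing.assert_allclose(a.onset_times, b.onset_times, atol=0.05)

    def test_generator_onsets_recovered(self, walking_session):
        _, traj, onsets = walking_session
        ev = ba.detect_saccades(traj.angular_velocity, traj.time)
        matched = np.mean([
            np.min(np.abs(ev.onset_times - t)) <= 0.05 for t in onsets
        ])
        false = np.mean([
            np.min(np.abs(onsets - t)) > 0.05 for t in ev.onset_times
        ])
        assert matched >= 0.95
        assert false <= 0.05

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ba.detect_saccades(np.zeros(10), np.arange(10) * 0.1, speed_threshold=0.0)


class TestSaccadeCycleStats:
    def test_regular_events_give_constant_iti(self):
        onsets = np.arange(1.0, 9.0, 1.0)
        ev = ba.SaccadeEventList(onsets, np.full(len(onsets), 300.0))
        time = np.arange(0, 10, 0.02)
        out = ba.saccade_cycle_stats(ev, np.zeros(len(time)), np.zeros(len(time)), time)
        np.testing.assert_allclose(out["iti"], 1.0)

    def test_peri_angular_speed_exceeds_intersaccade(self, walking_session):
        _, traj, _ = walking_session
        ev = ba.detect_saccades(traj.angular_velocity, traj.time)
        out = ba.saccade_cycle_stats(ev, traj.angular_velocity, traj.forward_velocity,
                                     traj.time)
        assert np.median(out["angular_speed"]["peri"]) > np.median(
            out["angular_speed"]["inter"]
        )

    def test_forward_velocity_independent_of_saccade_timing(self):
        ok = 0
        for seed in range(10):
            _, traj, _ = sp.generate_walking(duration_s=120.0, seed=seed)
            ev = ba.detect_saccades(traj.angular_velocity, traj.time)
            out = ba.saccade_cycle_stats(ev, traj.angular_velocity,
                                         traj.forward_velocity, traj.time)
            ok += out["forward_velocity_ks"]["p"] > 0.05
        assert ok >= 8

    def test_few_detected_itis_below_refractory(self, walking_session):
        _, traj, _ = walking_session
        ev = ba.detect_saccades(traj.angular_velocity, traj.time)
        iti = ev.inter_turn_intervals
        assert np.mean(iti < 0.5) < 0.02

    def test_single_event_flags_empty_iti(self):
        ev = ba.SaccadeEventList(np.array([1.0]), np.array([300.0]))
        time = np.arange(0, 5, 0.02)
        out = ba.saccade_cycle_stats(ev, np.zeros(len(time)), np.zeros(len(time)), time)
        assert out["iti_flagged_empty"]


def test_fictrac_csv_roundtrip(tmp_path):
    import pandas as pd

    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "time": np.arange(100) * 0.02,
        "rot_x": rng.normal(size=100),
        "rot_y": rng.normal(size=100),
        "rot_z": rng.normal(size=100),
    })
    path = tmp_path / "fictrac.csv"
    df.to_csv(path, index=False)
    out = ba.read_fictrac_csv(path)
    np.testing.assert_allclose(
        out["amplitude"],
        ba.walking_amplitude(df.rot_x, df.rot_y, df.rot_z),
    )
    with pytest.raises(ValueError, match="missing columns"):
        ba.read_fictrac_csv(path, columns=("rot_x", "rot_y", "nope"))
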