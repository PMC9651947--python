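"""dF/F, amplitudes, correlations, clustering, shared gain, decoding."""

import numpy as np
import pytest
from scipy import stats

from glomcode import synthetic_population as sp
from glomcode.population_analysis import (
    AmplitudeMatrix,
    behavior_correlation,
    behavior_correlation_test,
    cluster_tuning,
    compute_dff,
    decode,
    peak_amplitudes,
    shared_gain,
    shuffle_trials,
    trial_correlations,
)


def holm_oracle(pvals, alpha=0.05):
    """Hand-stepped Holm procedure: sort ascending, compare p_(i) <= alpha/(m-i+1),
    stop at the first failure."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        time = np.linspace(-1.0, 2.0, 30)
        raw = np.full((2, 3, 30), 5.0)
        dff = compute_dff(raw, time, (-1.0, 0.0))
        np.testing.assert_allclose(dff, 0.0)

    def test_doubling_gives_one(self):
        time = np.linspace(-1.0, 2.0, 30)
        raw = np.full((1, 1, 30), 2.0)
        raw[0, 0, time > 0] = 4.0
        dff = compute_dff(raw, time, (-1.0, 0.0))
        assert np.allclose(dff[0, 0, time > 0], 1.0)

    def test_matches_direct_formula_on_random_traces(self):
        rng = np.random.default_rng(0)
        time = np.linspace(-1.5, 3.0, 40)
        raw = rng.random((3, 5, 40)) + 1.0
        dff = compute_dff(raw, time, (-1.5, 0.0))
        pre = time <= 0.0
        for g in range(3):
            for t in range(5):
                f0 = raw[g, t, pre].mean()
                np.testing.assert_allclose(dff[g, t], (raw[g, t] - f0) / f0)

    def test_nonpositive_baseline_names_offender(self):
        time = np.linspace(-1.0, 1.0, 20)
        raw = np.ones((2, 2, 20))
        raw[1, 0] = 0.0
        with pytest.raises(ValueError, match="glomerulus 1, trial 0"):
            compute_dff(raw, time, (-1.0, 0.0))


class TestPeakAmplitudes:
    def test_monotone_trace_peaks_at_window_end(self, tuning):
        tensor, _ = sp.generate_trials(tuning, gain_sd=0.0, behavior_coupling=0.0,
                                       noise_sd=0.0, n_trials_per_stim=2, seed=0)
        ramp = np.linspace(0.0, 1.0, len(tensor.time))
        tensor.dff[:] = ramp[None, None, :]
        amps = peak_amplitudes(tensor, response_window=(0.0, 2.0))
        in_window = (tensor.time >= 0) & (tensor.time <= 2.0)
        assert np.allclose(amps.values, ramp[in_window][-1])

    def test_zero_tensor_gives_zero_matrix(self, tuning):
        tensor, _ = sp.generate_trials(tuning, n_trials_per_stim=2, seed=0)
        tensor.dff[:] = 0.0
        amps = peak_amplitudes(tensor)
        np.testing.assert_array_equal(amps.values, 0.0)

    def test_empty_window_rejected(self, trial_data):
        tensor, _ = trial_data
        with pytest.raises(ValueError):
            peak_amplitudes(tensor, response_window=(100.0, 101.0))


class TestTrialCorrelations:
    def test_duplicated_glomerulus_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        col = rng.random(30)
        amps = AmplitudeMatrix(np.column_stack([col, col]), np.zeros(30, dtype=int))
        corr = trial_correlations(amps)
        assert np.isclose(corr.values[0, 1], 1.0)

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(1)
        amps = AmplitudeMatrix(rng.random((30, 8)), np.zeros(30, dtype=int))
        corr = trial_correlations(amps)
        off = corr.values[~np.eye(8, dtype=bool)]
        assert np.mean(np.abs(off) < 0.35) > 0.8

    def test_symmetry_and_unit_diagonal(self, amplitudes):
        corr = trial_correlations(amplitudes)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        assert np.nanmax(np.abs(corr.values)) <= 1.0 + 1e-12


class TestClusterTuning:
    def test_two_separated_templates_recovered(self):
        rng = np.random.default_rng(0)
        a = np.tile([1.0, 0.1, 0.1, 1.0], (4, 1)) + rng.normal(0, 0.02, (4, 4))
        b = np.tile([0.1, 1.0, 1.0, 0.1], (4, 1)) + rng.normal(0, 0.02, (4, 4))
        t = sp.TuningMatrix(np.abs(np.vstack([a, b])),
                            [f"g{i}" for i in range(8)],
                            [f"s{i}" for i in range(4)],
                            np.repeat([0, 1], 4))
        labels, _ = cluster_tuning(t, n_clusters=2)
        assert len(np.unique(labels[:4])) == 1
        assert len(np.unique(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_singleton_limit(self, tuning):
        labels, _ = cluster_tuning(tuning, n_clusters=tuning.n_glomeruli)
        assert len(np.unique(labels)) == tuning.n_glomeruli

    def test_permutation_invariance(self, tuning):
        labels, _ = cluster_tuning(tuning, 4)
        perm = np.random.default_rng(0).permutation(tuning.n_glomeruli)
        t2 = sp.TuningMatrix(tuning.values[perm],
                             [tuning.glomerulus_names[i] for i in perm],
                             tuning.stimulus_names, tuning.group_labels[perm])
        labels2, _ = cluster_tuning(t2, 4)
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels2) == 1.0


class TestSharedGain:
    def test_rank_one_data_recovered(self):
        rng = np.random.default_rng(0)
        gain = np.exp(rng.normal(0, 0.4, 200))
        loadings = rng.uniform(0.5, 1.5, 10)
        amps = AmplitudeMatrix(np.outer(gain, loadings), np.zeros(200, dtype=int))
        score, load, var = shared_gain(amps)
        assert var > 0.99
        assert np.corrcoef(score, gain)[0, 1] > 0.99

    def test_isotropic_noise_variance_explained_near_1_over_g(self):
        rng = np.random.default_rng(1)
        G = 10
        vars_ = []
        for _ in range(20):
            amps = AmplitudeMatrix(rng.normal(size=(100, G)), np.zeros(100, dtype=int))
            vars_.append(shared_gain(amps)[2])
        assert 1.0 / G < np.mean(vars_) < 2.5 / G

    def test_sign_convention_loadings_positive_mean(self, amplitudes):
        _, load, _ = shared_gain(amplitudes)
        assert load.mean() > 0
        flipped = AmplitudeMatrix(-amplitudes.values, amplitudes.labels)
        _, load_f, _ = shared_gain(flipped)
        assert load_f.mean() > 0  # orientation rule, not data sign, fixes it

    def test_recovers_generator_gain(self):
        tuning = sp.generate_tuning(n_stimuli=1, n_groups=1, seed=0)
        tensor, truth = sp.generate_trials(
            tuning, behavior_coupling=0.0, noise_sd=0.2 * tuning.values.mean(),
            n_trials_per_stim=100, seed=0,
        )
        score, _, _ = shared_gain(peak_amplitudes(tensor))
        assert np.corrcoef(score, truth.gain)[0, 1] > 0.9

    def test_too_few_glomeruli_rejected(self):
        amps = AmplitudeMatrix(np.random.default_rng(0).random((10, 1)),
                               np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            shared_gain(amps)


class TestBehaviorCorrelation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        behavior = rng.random(50)
        amps = AmplitudeMatrix((1.0 - behavior)[:, None] + 1.0, np.zeros(50, dtype=int))
        rho = behavior_correlation(amps, behavior)
        assert np.isclose(rho[0], -1.0)

    def test_constant_behavior_rejected(self, amplitudes):
        with pytest.raises(ValueError):
            behavior_correlation(amplitudes, np.ones(amplitudes.n_trials))

    def test_holm_matches_hand_stepped_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(6) * 0.2
            reject, _, _, _ = multipletests(p, alpha=0.05, method="holm")
            np.testing.assert_array_equal(reject, holm_oracle(p))
        # the worked example: only the smallest survives
        np.testing.assert_array_equal(
            holm_oracle(np.array([0.01, 0.03, 0.04])), [True, False, False]
        )

    def test_modulated_glomeruli_flagged_across_flies(self):
        rhos, modulated = [], None
        for f in range(8):
            tuning = sp.generate_tuning(seed=f)
            tensor, truth = sp.generate_trials(tuning, seed=f + 50)
            amps = peak_amplitudes(tensor)
            rhos.append(behavior_correlation(amps, tensor.behavior_amplitude))
            modulated = truth.modulated
        res = behavior_correlation_test(np.stack(rhos))
        assert res["significant"][modulated].all()
        assert not res["significant"][~modulated].any()


class TestDecode:
    def test_one_hot_noiseless_tuning_is_perfect(self):
        X = np.repeat(np.eye(4), 10, axis=0)
        amps = AmplitudeMatrix(X, np.repeat(np.arange(4), 10))
        res = decode(amps, n_iterations=5, seed=0)
        assert res.overall_accuracy == 1.0

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(0)
        X = rng.random((120, 6))
        labels = rng.permutation(np.repeat(np.arange(4), 30))
        res = decode(AmplitudeMatrix(X, labels), n_iterations=30, seed=1)
        assert abs(res.overall_accuracy - 0.25) < 0.12

    def test_confusion_rows_sum_to_one(self, amplitudes):
        res = decode(amplitudes, n_iterations=10, seed=0)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0)
        assert 0.0 <= res.overall_accuracy <= 1.0

    def test_subset_never_beats_full_population(self, amplitudes):
        full = decode(amplitudes, n_iterations=20, seed=3)
        sub = AmplitudeMatrix(amplitudes.values[:, :4], amplitudes.labels)
        part = decode(sub, n_iterations=20, seed=3)
        assert part.overall_accuracy <= full.overall_accuracy + 0.05

    def test_deterministic_given_seed(self, amplitudes):
        a = decode(amplitudes, n_iterations=5, seed=7)
        b = decode(amplitudes, n_iterations=5, seed=7)
        assert a.overall_accuracy == b.overall_accuracy
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_single_trial_class_rejected(self):
        X = np.random.default_rng(0).random((5, 3))
        labels = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            decode(AmplitudeMatrix(X, labels))


class TestShuffleTrials:
    def test_single_glomerulus_multiset_unchanged(self):
        rng = np.random.default_rng(0)
        amps = AmplitudeMatrix(rng.random((20, 1)), np.repeat([0, 1], 10))
        sh = shuffle_trials(amps, seed=1)
        for s in (0, 1):
            sel = amps.labels == s
            np.testing.assert_array_equal(
                np.sort(sh.values[sel, 0]), np.sort(amps.values[sel, 0])
            )

    def test_moments_exactly_preserved(self, amplitudes):
        sh = shuffle_trials(amplitudes, seed=2)
        for s in np.unique(amplitudes.labels):
            sel = amplitudes.labels == s
            np.testing.assert_allclose(sh.values[sel].mean(axis=0),
                                       amplitudes.values[sel].mean(axis=0), rtol=1e-12)
            np.testing.assert_allclose(sh.values[sel].var(axis=0),
                                       amplitudes.values[sel].var(axis=0), rtol=1e-12)

    def test_correlated_columns_decorrelated(self):
        rng = np.random.default_rng(3)
        col = rng.random(30)
        amps = AmplitudeMatrix(np.column_stack([col, col]), np.zeros(30, dtype=int))
        sh = shuffle_trials(amps, seed=4)
        assert abs(np.corrcoef(sh.values.T)[0, 1]) < 0.35

    def test_shuffled_decoding_not_better_on_gain_data(self, amplitudes):
        intact = decode(amplitudes, n_iterations=30, seed=5)
        sh = decode(shuffle_trials(amplitudes, seed=6), n_iterations=30, seed=5)
        assert sh.overall_accuracy <= intact.overall_accuracy
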