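import numpy as np
import pandas as pd
import pytest

from neurofuse.decoding import (
    DecodingParams,
    SCHEMES,
    balance_one_vs_rest,
    compute_whitener,
    decode_static,
    decode_timecourse,
    ecog_feature_vector,
    make_pseudotrials,
    noise_normalize,
    patternsets_to_trials,
)
from neurofuse.design import make_design
from neurofuse.generator import GeneratorParams, simulate_eeg, simulate_fmri


class TestBalance:
    @pytest.mark.parametrize(
        "reps,variations,expected",
        [
            (32, None, 800),   # selectivity: 800 vs 3200 -> 800 sampled
            (32, ("v1",), 160),  # invariance: 160 vs 640 -> 160 sampled
        ],
    )
    def test_paper_scale_pools(self, reps, variations, expected, rng):
        d = make_design(5, 5, 5, reps)
        pos, neg = balance_one_vs_rest(d, "face", rng, variations=variations)
        assert pos.size == expected and neg.size == expected
        assert (d.loc[pos, "category"] == "face").all()
        assert (d.loc[neg, "category"] != "face").all()
        assert len(np.unique(neg)) == neg.size  # without replacement

    def test_equal_classes_returned_unchanged(self, rng):
        labels = pd.DataFrame(
            {"category": ["face"] * 4 + ["chair"] * 4, "variation": ["v1"] * 8}
        )
        pos, neg = balance_one_vs_rest(labels, "face", rng)
        np.testing.assert_array_equal(np.sort(neg), np.arange(4, 8))

    def test_fewer_negatives_rejected(self, rng):
        labels = pd.DataFrame(
            {"category": ["face"] * 5 + ["chair"] * 2, "variation": ["v1"] * 7}
        )
        with pytest.raises(ValueError, match="balance"):
            balance_one_vs_rest(labels, "face", rng)


class TestPseudotrials:
    def test_800_into_150_set_sizes(self, rng):
        """800 trials in 150 sets: 100 sets of 5 and 50 sets of 6."""
        trials = np.arange(800, dtype=float)[:, None]
        out = make_pseudotrials(trials, 150, rng)
        assert out.shape == (150, 1)
        # reconstruct multiset of set sizes from the partition property:
        # every trial used exactly once => sizes sum to 800
        sizes = [len(c) for c in np.array_split(rng.permutation(800), 150)]
        assert sorted(set(sizes)) == [5, 6]
        assert sizes.count(5) == 100 and sizes.count(6) == 50

    def test_partition_uses_each_trial_once(self, rng):
        trials = np.eye(12)  # one-hot rows: sums reveal membership counts
        out = make_pseudotrials(trials, 5, rng)
        sizes = np.array([1.0 / out[i][out[i] > 0][0] for i in range(5)])
        counts = (out > 0).sum(axis=1)
        assert np.allclose(sizes, counts)  # mean of k one-hots has value 1/k
        assert counts.sum() == 12

    def test_identity_when_sets_equal_trials(self, rng):
        trials = rng.standard_normal((7, 3))
        out = make_pseudotrials(trials, 7, rng)
        assert np.allclose(np.sort(out, axis=0), np.sort(trials, axis=0))

    def test_constant_trials_stay_constant(self, rng):
        out = make_pseudotrials(np.full((10, 2), 3.0), 4, rng)
        np.testing.assert_allclose(out, 3.0)

    def test_too_many_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            make_pseudotrials(np.zeros((3, 1)), 4, rng)


class TestWhitening:
    def test_white_noise_gives_near_identity(self, rng):
        x = rng.standard_normal((4000, 6))
        w = compute_whitener(x, np.zeros(4000), shrinkage="lw")
        np.testing.assert_allclose(w, np.eye(6), atol=0.1)

    def test_diagonal_covariance_closed_form(self, rng):
        """diag(1, 4) noise: whitener scales channel 2 by ~1/2."""
        x = rng.standard_normal((6000, 2)) * np.array([1.0, 2.0])
        w = compute_whitener(x, np.zeros(6000), shrinkage=0.0)
        assert abs(w[1, 1] / w[0, 0] - 0.5) < 0.05
        assert abs(w[0, 1]) < 0.05

    def test_whitening_reduces_offdiagonal_covariance(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=3000)
        wx, _ = noise_normalize(x, np.zeros(3000), x[:10], shrinkage=0.0)
        c = np.cov(wx.T)
        assert abs(c[0, 1]) < 0.1

    def test_degenerate_covariance_survives_via_floor(self):
        x = np.ones((8, 3))  # zero covariance
        w = compute_whitener(x, np.zeros(8), shrinkage=0.0)
        assert np.all(np.isfinite(w))

    def test_uses_training_statistics_only(self, rng):
        train = rng.standard_normal((50, 4))
        test_a = rng.standard_normal((5, 4))
        test_b = rng.standard_normal((5, 4)) * 100
        wa, _ = noise_normalize(train, np.zeros(50), test_a)
        wb, _ = noise_normalize(train, np.zeros(50), test_b)
        np.testing.assert_allclose(wa, wb)


def test_whitening_identity_covariance_near_noop():
    """With white (identity-covariance) noise the whitener is ~identity, so
    whitened and unwhitened decoding agree closely."""
    params = GeneratorParams(
        n_participants=1, n_channels=8, sfreq=200.0, epoch_window=(-50, 250),
        n_repetitions=8, noise_sd=1.0, channel_corr_scale=1e-6,
        temporal_smoothing=0.0, seed=13,
    )
    rec = simulate_eeg(params, make_design(5, 2, 5, 8))[0].crop(140, 160)
    accs = {}
    for wh in (True, False):
        res = decode_timecourse(
            rec, "category_selectivity",
            DecodingParams(n_pseudotrials=8, n_repeats=2, seed=4, whitening=wh),
        )
        accs[wh] = res.accuracy
    # small residual disagreement reflects shrinkage-estimation noise on a
    # finite sample, not a systematic whitening effect
    assert abs(accs[True].mean() - accs[False].mean()) < 0.05
    assert np.abs(accs[True] - accs[False]).mean() < 0.08


class TestSchemes:
    def test_scheme_variation_sets(self):
        assert SCHEMES["category_selectivity"].train_variations == SCHEMES[
            "category_selectivity"
        ].test_variations
        assert SCHEMES["rotation_invariance"].train_variations == ("v1",)
        assert SCHEMES["rotation_invariance"].test_variations == ("v2", "v3")
        assert SCHEMES["scale_invariance"].test_variations == ("v4", "v5")

    def test_missing_test_variation_rejected(self, small_params):
        design = make_design(5, 2, 2, 4)  # only v1, v2 present
        rec = simulate_eeg(small_params.replace(n_participants=1), design)[0]
        with pytest.raises(ValueError, match="absent"):
            decode_timecourse(rec, "scale_invariance", DecodingParams(n_repeats=1))


class TestDecodeTimecourse:
    def test_hand_toy_matches_linear_separator(self):
        """2-channel, 1-timepoint toy with an obvious separator: every fold
        must classify the held-out pair correctly."""
        design = make_design(2, 1, 1, 4)  # animal vs chair, 8 trials
        rng = np.random.default_rng(0)
        data = np.zeros((8, 2, 1))
        is_animal = (design["category"] == "animal").to_numpy()
        data[is_animal, 0, 0] = 5.0 + 0.1 * rng.standard_normal(4)
        data[~is_animal, 0, 0] = -5.0 + 0.1 * rng.standard_normal(4)
        data[:, 1, 0] = 0.1 * rng.standard_normal(8)
        from neurofuse.generator import EpochedRecording

        rec = EpochedRecording(
            data, np.array([0.0]), 1000.0,
            pd.DataFrame({"name": ["a", "b"], "region": pd.array([pd.NA] * 2, dtype="string"),
                          "source_participant": pd.array([pd.NA] * 2, dtype="string")}),
            "toy", "EEG", design,
        )
        res = decode_timecourse(
            rec, "category_selectivity",
            DecodingParams(n_pseudotrials=4, n_repeats=1, whitening=False, seed=0),
        )
        np.testing.assert_allclose(res.accuracy, 1.0)

    def test_high_amplitude_invariant_signal_saturates(self, small_design):
        params = GeneratorParams(
            n_participants=1, n_channels=10, sfreq=200.0, epoch_window=(-50, 250),
            n_repetitions=6, invariance_mix=1.0, noise_sd=0.3,
            category_amplitudes={c: 3.0 for c in "animal chair face fruit vehicle".split()},
            seed=2,
        )
        rec = simulate_eeg(params, small_design)[0].crop(145, 155)
        res = decode_timecourse(
            rec, "category_selectivity", DecodingParams(n_pseudotrials=6, n_repeats=1, seed=3)
        )
        assert (res.accuracy.max(axis=1) >= 0.95).all()

    def test_accuracy_bounds_and_axes(self, small_eeg):
        rec = small_eeg[0].crop(100, 150)
        res = decode_timecourse(
            rec, "rotation_invariance", DecodingParams(n_repeats=1, seed=0)
        )
        assert res.accuracy.shape == (5, rec.time_ms.size)
        assert np.all(res.accuracy >= 0) and np.all(res.accuracy <= 1)
        np.testing.assert_array_equal(res.time_ms, rec.time_ms)


class TestEcogFeatures:
    def test_constant_signal_gives_zero_features(self, small_eeg):
        rec = small_eeg[0]
        rec2 = rec.crop(rec.time_ms[0], rec.time_ms[-1])
        rec2.data = np.ones_like(rec2.data)
        feats = ecog_feature_vector(rec2, window=(50, 250), bin_ms=25)
        np.testing.assert_allclose(feats, 0.0)

    def test_bin_count(self, small_eeg):
        feats = ecog_feature_vector(small_eeg[0], window=(50, 250), bin_ms=25)
        assert feats.shape == (small_eeg[0].n_trials, small_eeg[0].n_channels * 8)

    def test_ramp_closed_form(self):
        """Linear ramp of slope s: range over one 25 ms bin at 1 kHz is
        s*24 ms (25 samples spanning 24 ms)."""
        from neurofuse.generator import EpochedRecording

        t = np.arange(-100, 601, 1.0)
        s = 0.3
        data = np.tile(s * t, (2, 1, 1))  # 2 trials, 1 channel
        labels = make_design(1, 1, 1, 2)
        rec = EpochedRecording(
            data, t, 1000.0,
            pd.DataFrame({"name": ["e0"], "region": pd.array([pd.NA], dtype="string"),
                          "source_participant": pd.array([pd.NA], dtype="string")}),
            "toy", "ECoG", labels,
        )
        feats = ecog_feature_vector(rec, window=(50, 300), bin_ms=25)
        assert feats.shape == (2, 10)
        np.testing.assert_allclose(feats, s * 24.0, atol=1e-9)

    def test_non_divisible_window_rejected(self, small_eeg):
        with pytest.raises(ValueError, match="divisible"):
            ecog_feature_vector(small_eeg[0], window=(50, 260), bin_ms=25)


@pytest.fixture(scope="module")
def fmri_trials():
    params = GeneratorParams(
        n_participants=1, n_channels=4, sfreq=200.0, epoch_window=(-50, 250),
        n_voxels=15, n_runs=4, noise_sd=1.0, seed=8,
    )
    sets = simulate_fmri(params, make_design(5, 5, 5, 4, n_runs=4))
    return patternsets_to_trials(sets, "O-Inf", "sub-01")


class TestDecodeStatic:

    def test_leave_one_run_out_folds(self, fmri_trials):
        x, labels = fmri_trials
        res = decode_static(
            x, labels, "category_selectivity",
            DecodingParams(whitening=False, n_repeats=1, seed=0),
            cv="leave_one_run_out",
        )
        assert res.accuracy.shape == (5,)
        assert np.all((res.accuracy >= 0) & (res.accuracy <= 1))

    def test_single_run_rejected(self, fmri_trials):
        x, labels = fmri_trials
        one_run = labels["run"] == 1
        with pytest.raises(ValueError, match="2 runs"):
            decode_static(
                x[one_run.to_numpy()], labels[one_run].reset_index(drop=True),
                "category_selectivity", DecodingParams(n_repeats=1), cv="leave_one_run_out",
            )

    def test_zero_snr_roi_at_chance(self):
        params = GeneratorParams(
            n_participants=1, n_voxels=15, n_runs=4, noise_sd=1.0, seed=9,
            roi_snr={"O-Inf": 1.0, "T-LFus": 1.0, "T-MLing": 1.0,
                     "T-MTPhip": 1.0, "T-IT": 1.0, "T-Pole": 0.0},
        )
        sets = simulate_fmri(params, make_design(5, 5, 5, 4, n_runs=4))
        x, labels = patternsets_to_trials(sets, "T-Pole", "sub-01")
        res = decode_static(
            x, labels, "category_selectivity",
            DecodingParams(whitening=False, n_repeats=2, seed=1),
            cv="leave_one_run_out",
        )
        assert np.all(np.abs(res.accuracy - 0.5) < 0.2)

    def test_invariance_scheme_cross_view(self, fmri_trials):
        x, labels = fmri_trials
        res = decode_static(
            x, labels, "scale_invariance",
            DecodingParams(whitening=False, n_repeats=2, seed=0),
        )
        assert res.accuracy.shape == (5,)
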