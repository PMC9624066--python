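import numpy as np
import pytest
import scipy.stats

from neurofuse.generator import GeneratorParams, simulate_ecog, simulate_eeg, simulate_fmri
from neurofuse.design import make_design
from neurofuse.rsa import (
    RDM,
    compute_rdm,
    condition_means,
    mean_rdm,
    noise_ceiling_upper,
    rdm_timecourse,
    regional_rdms,
    spearman,
    upper_triangle,
)


def _brute_spearman(a, b):
    """Rank-difference formula oracle (mid-ranks for ties)."""
    ra = scipy.stats.rankdata(a)
    rb = scipy.stats.rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]


class TestConditionMeans:
    def test_identity_with_one_trial_per_condition(self, rng):
        labels = make_design(2, 1, 2, 1)
        data = rng.standard_normal((4, 3))
        means, order = condition_means(data, labels)
        np.testing.assert_allclose(means, data)
        np.testing.assert_array_equal(order, labels["condition_id"].to_numpy())

    def test_order_invariance(self, rng):
        labels = make_design(2, 1, 2, 3)
        data = rng.standard_normal((12, 4))
        perm = rng.permutation(12)
        m1, _ = condition_means(data, labels)
        m2, _ = condition_means(data[perm], labels.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(m1, m2)

    def test_averaging_concentrates_at_clt_rate(self, rng):
        """32 noisy repetitions of a constant: mean within ~noise/sqrt(32)."""
        labels = make_design(1, 1, 1, 32)
        const = np.array([1.0, -2.0, 0.5])
        errs = []
        for _ in range(50):
            data = const + rng.standard_normal((32, 3))
            means, _ = condition_means(data, labels)
            errs.append(np.abs(means[0] - const).mean())
        assert np.mean(errs) < 3.0 / np.sqrt(32)

    def test_missing_condition_reported(self, rng):
        labels = make_design(2, 1, 2, 1)
        full_order = labels["condition_id"].to_numpy()
        with pytest.raises(ValueError, match=r"condition ids: \[2\]"):
            condition_means(
                rng.standard_normal((3, 3)),
                labels.iloc[[0, 2, 3]].reset_index(drop=True),
                condition_order=full_order,
            )


class TestComputeRdm:
    def test_identical_and_reversed_patterns(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        pats = np.stack([base, base * 2 + 1, base[::-1]])
        rdm = compute_rdm(pats)
        assert rdm.values[0, 1] == pytest.approx(0.0)  # monotone transform
        assert rdm.values[0, 2] == pytest.approx(2.0)  # reversed ranks
        assert np.isnan(rdm.values[0, 0])

    def test_matches_brute_force_rank_oracle(self, rng):
        pats = rng.integers(0, 10, size=(3, 4)).astype(float)
        rdm = compute_rdm(pats)
        for i in range(3):
            for j in range(i + 1, 3):
                assert rdm.values[i, j] == pytest.approx(
                    1.0 - _brute_spearman(pats[i], pats[j]), abs=1e-12
                )

    def test_constant_pattern_flagged_undefined(self, rng):
        pats = np.vstack([np.ones(5), rng.standard_normal((2, 5))])
        with pytest.warns(RuntimeWarning, match="constant"):
            rdm = compute_rdm(pats)
        assert np.isnan(rdm.values[0, 1]) and np.isnan(rdm.values[0, 2])
        assert np.isfinite(rdm.values[1, 2])

    def test_invariants_enforced(self, rng):
        vals = rng.uniform(0, 2, (4, 4))
        with pytest.raises(ValueError, match="asymmetric"):
            RDM(vals, np.arange(4))


class TestRdmTimecourse:
    def test_one_rdm_per_timepoint(self, small_eeg):
        rdms = rdm_timecourse(small_eeg[0])
        assert len(rdms) == small_eeg[0].time_ms.size
        assert rdms[0].n_conditions == 50  # 5 cats x 2 ids x 5 vars

    def test_null_pre_onset_entries_near_one(self, small_params, small_design):
        """Independent noise patterns: expected rank correlation 0, so
        dissimilarities fluctuate around 1."""
        rec = simulate_eeg(small_params, small_design)[0]
        pre = rec.crop(rec.time_ms[0], 0.0)
        rdms = rdm_timecourse(pre)
        vals = np.concatenate([upper_triangle(r.values) for r in rdms])
        assert 0.9 < np.nanmean(vals) < 1.1

    def test_identical_participants_average_to_themselves(self, small_eeg):
        rdms = rdm_timecourse(small_eeg[0].crop(100, 120))
        group = mean_rdm([rdms[0], rdms[0]])
        np.testing.assert_allclose(group.values, rdms[0].values)


class TestRegionalRdms:
    def test_single_region_equals_pooled(self, small_params, small_design):
        ecog = simulate_ecog(
            small_params.replace(n_electrodes_per_region=4,
                                 region_latency_offsets={"O-Inf": 0.0}),
            small_design,
        )
        short = ecog.crop(100, 120)
        pooled = rdm_timecourse(short)
        regional = regional_rdms(short)
        assert list(regional) == ["O-Inf"]
        for a, b in zip(regional["O-Inf"], pooled):
            np.testing.assert_array_equal(a.values, b.values)

    def test_split_half_agreement(self, small_params, small_design):
        """Two regions with identical latency/statistics produce RDMs that
        agree within sampling error (split-half oracle)."""
        ecog = simulate_ecog(
            small_params.replace(
                n_electrodes_per_region=10, noise_sd=0.3, invariance_mix=0.7,
                region_latency_offsets={"O-Inf": 0.0, "T-LFus": 0.0},
            ),
            small_design,
        )
        short = ecog.crop(145, 155)
        regional = regional_rdms(short)
        rhos = [
            spearman(upper_triangle(a.values), upper_triangle(b.values))
            for a, b in zip(regional["O-Inf"], regional["T-LFus"])
        ]
        # positive shared structure at the signal peak; pre-onset timepoints
        # of the same recording are the no-structure baseline
        pre = regional_rdms(ecog.crop(-50, -20))
        base = [
            spearman(upper_triangle(a.values), upper_triangle(b.values))
            for a, b in zip(pre["O-Inf"], pre["T-LFus"])
        ]
        assert np.mean(rhos) > 0.1
        assert np.mean(rhos) > np.mean(base) + 0.1

    def test_empty_region_skipped_with_warning(self, small_eeg):
        with pytest.warns(RuntimeWarning, match="no electrodes"):
            out = regional_rdms(small_eeg[0].crop(0, 20), region_map={"T-Pole": []})
        assert out == {}


class TestNoiseCeiling:
    def test_identical_participants_ceiling_one(self, rng):
        pats = rng.standard_normal((6, 8))
        rdm = compute_rdm(pats)
        assert noise_ceiling_upper([rdm, rdm, rdm]) == pytest.approx(1.0)

    def test_rank_reversed_pair_gives_zero(self):
        """Two participants with rank-reversed RDMs: correlations with the
        group mean cancel by symmetry."""
        base = np.array(
            [[np.nan, 0.1, 0.5, 0.9],
             [0.1, np.nan, 0.3, 0.7],
             [0.5, 0.3, np.nan, 0.2],
             [0.9, 0.7, 0.2, np.nan]]
        )
        flipped = 1.0 - base  # reverses all ranks of the off-diagonal entries
        a = RDM(base, np.arange(4))
        b = RDM(flipped, np.arange(4))
        assert noise_ceiling_upper([a, b]) == pytest.approx(0.0, abs=1e-12)

    def test_self_inclusion_bias_exceeds_leave_one_out(self, rng):
        """Independent random RDMs: the with-self ceiling is biased above 0
        and strictly exceeds a leave-one-out variant."""
        n_part, k = 6, 12
        with_self, loo = [], []
        for _ in range(50):
            rdms = [compute_rdm(rng.standard_normal((k, 20))) for _ in range(n_part)]
            with_self.append(noise_ceiling_upper(rdms))
            accs = []
            for i in range(n_part):
                others = mean_rdm([r for j, r in enumerate(rdms) if j != i])
                accs.append(
                    spearman(upper_triangle(rdms[i].values), upper_triangle(others.values))
                )
            loo.append(np.mean(accs))
        assert np.mean(with_self) > 0.05
        assert np.mean(with_self) > np.mean(loo)

    def test_ceiling_monotone_in_snr(self):
        """Upper ceiling increases with generator SNR (3 levels)."""
        means = []
        for snr in (0.3, 1.0, 3.0):
            vals = []
            for seed in range(5):
                params = GeneratorParams(
                    n_participants=4, n_voxels=12, n_runs=3, noise_sd=1.0, seed=seed,
                    roi_snr={r: snr for r in
                             ("O-Inf", "T-LFus", "T-MLing", "T-MTPhip", "T-IT", "T-Pole")},
                )
                sets = simulate_fmri(params, make_design(5, 2, 5, 3, n_runs=3))
                rdms = []
                for pid in sorted({ps.participant_id for ps in sets}):
                    runs = [ps for ps in sets if ps.roi == "O-Inf" and ps.participant_id == pid]
                    betas = np.mean([ps.betas for ps in runs], axis=0)
                    rdms.append(compute_rdm(betas))
                vals.append(noise_ceiling_upper(rdms))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_two_participant_minimum(self, rng):
        rdm = compute_rdm(rng.standard_normal((5, 6)))
        with pytest.raises(ValueError, match="2 participants"):
            noise_ceiling_upper([rdm])
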