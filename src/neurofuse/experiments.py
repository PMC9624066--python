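"""Validation experiments: calibration and ground-truth recovery.

Each function runs one self-contained experiment on the synthetic generator
and returns a dict of summary numbers. They serve two audiences: the test
suite asserts their scientific expectations (null calibration, latency
recovery, scheme ordering, whitening benefit, SNR-correspondence), and the
acceptance script reports their outputs.

Problem sizes are chosen for desk-scale runtime while keeping each
experiment well powered; docs/methods.md discusses the choices. All
randomness derives from the ``seed`` argument; sub-seeds stay below 2**31.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .decoding import (
    DecodingParams,
    balance_one_vs_rest,
    decode_static,
    decode_timecourse,
    ecog_feature_vector,
    make_pseudotrials,
    patternsets_to_trials,
)
from .design import ROIS, make_design
from .fusion import snr_vs_correspondence
from .generator import GeneratorParams, simulate_ecog, simulate_eeg, simulate_fmri
from .inference import fdr_correct, onset_latency, peak_latency, wilcoxon_above_chance
from .rsa import compute_rdm, condition_means

__all__ = [
    "design_arithmetic",
    "null_decoding_calibration",
    "null_inference_calibration",
    "latency_recovery",
    "invariance_ordering",
    "whitening_benefit",
    "snr_correspondence",
]

def _sub(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def design_arithmetic() -> dict:
    """Exact class-balance and pseudo-trial counts implied by the design.

    Runs the actual balancing / pseudo-trial / RDM code on the full-size
    design rather than restating the arithmetic.
    """
    rng = np.random.default_rng(0)
    eeg = make_design(5, 5, 5, 32)
    pos, neg = balance_one_vs_rest(eeg, "face", rng)
    v1_pos, v1_neg = balance_one_vs_rest(eeg, "face", rng, variations=("v1",))
    pseudo = make_pseudotrials(np.ones((pos.size, 1)), 150, rng)
    sizes = {len(c) for c in np.array_split(rng.permutation(pos.size), 150)}
    fmri = make_design(5, 5, 5, 8, n_runs=8)
    train = fmri[fmri["run"] != 8].reset_index(drop=True)
    f_pos, f_neg = balance_one_vs_rest(train, "face", rng)
    fi_pos, fi_neg = balance_one_vs_rest(fmri, "face", rng, variations=("v1",))
    rdm = compute_rdm(np.random.default_rng(1).standard_normal((125, 8)))
    return {
        "eeg_selectivity_pool": int(pos.size),
        "eeg_selectivity_negatives": int(neg.size),
        "eeg_invariance_pool": int(v1_pos.size),
        "eeg_invariance_negatives": int(v1_neg.size),
        "n_pseudotrials": int(pseudo.shape[0]),
        "pseudotrial_sizes": sorted(int(s) for s in sizes),
        "fmri_selectivity_training_pool": int(f_pos.size),
        "fmri_invariance_pool": int(fi_pos.size),
        "rdm_dimension": int(rdm.n_conditions),
    }


def null_decoding_calibration(seed: int = 0, n_datasets: int = 10) -> dict:
    """Label-shuffled decoding: pooled accuracy vs the exact binomial band.

    Each dataset is one simulated participant whose category labels are
    randomly permuted before decoding; pooled over datasets, the mean
    accuracy must fall inside the central 99 % binomial interval around
    0.5. The two test patterns of one cross-validation fold share their
    classifier and are therefore not independent decisions; the band is
    computed for one decision per fold, which bounds that dependence.
    """
    n_sets = 6
    correct = 0.0
    n_folds = 0
    n_decisions = 0
    for d in range(n_datasets):
        s = _sub(seed, 100 + d)
        params = GeneratorParams(
            n_participants=1, n_channels=10, sfreq=50.0, epoch_window=(-40, 240),
            n_repetitions=6, noise_sd=1.0, temporal_smoothing=0.0, seed=s,
        )
        rec = simulate_eeg(params, make_design(5, 2, 5, 6))[0].crop(100, 200)
        rng = np.random.default_rng(s + 1)
        rec.labels = rec.labels.copy()
        rec.labels["category"] = rng.permutation(rec.labels["category"].to_numpy())
        res = decode_timecourse(
            rec, "category_selectivity",
            DecodingParams(n_pseudotrials=n_sets, n_repeats=1, seed=s + 2),
        )
        correct += res.accuracy.sum() * n_sets  # fold-pair units
        n_folds += n_sets * res.accuracy.size
        n_decisions += 2 * n_sets * res.accuracy.size
    mean_acc = correct / n_folds
    lo, hi = scipy.stats.binom.interval(0.99, n_folds, 0.5)
    return {
        "mean_accuracy": float(mean_acc),
        "n_decisions": int(n_decisions),
        "n_independent_units": int(n_folds),
        "band": (float(lo / n_folds), float(hi / n_folds)),
    }


def null_inference_calibration(seed: int = 0, n_families: int = 200) -> dict:
    """FDR and onset calibration on null accuracy curves.

    Families are participants x timepoints accuracy matrices with no true
    effect (binomial fluctuation around chance); reports the mean FDR
    discovery fraction and the fraction of families with no onset.
    """
    rng = np.random.default_rng(_sub(seed, 200))
    n_part, n_t, n_dec = 12, 80, 24
    time_ms = np.arange(n_t) * 4.0
    discovery = []
    onset_undef = 0
    for _ in range(n_families):
        acc = rng.binomial(n_dec, 0.5, size=(n_part, n_t)) / n_dec
        sig = fdr_correct(wilcoxon_above_chance(acc), q=0.05)
        discovery.append(sig.mask.mean())
        if onset_latency(sig, time_ms, min_run=15) is None:
            onset_undef += 1
    return {
        "fdr_discovery_fraction": float(np.mean(discovery)),
        "onset_undefined_fraction": onset_undef / n_families,
        "n_families": n_families,
    }


# Latency-recovery study conditions: ground truth onset 80 ms / peak 150 ms,
# 21 simulated participants; amplitudes doubled relative to the generator
# default so the onset is detectable close to the 5 %-of-peak envelope foot.
_LATENCY_AMPS = {"animal": 2.0, "chair": 1.8, "face": 3.0, "fruit": 1.6, "vehicle": 2.2}


def latency_recovery(seed: int = 0, n_meta: int = 10) -> dict:
    """Recover group onset/peak latency from time-resolved decoding."""
    onsets, peaks = [], []
    for m in range(n_meta):
        s = _sub(seed, 300 + m)
        params = GeneratorParams(
            n_participants=21, n_channels=24, sfreq=250.0, epoch_window=(-52, 320),
            n_repetitions=8, signal_onset=80.0, signal_peak=150.0,
            category_amplitudes=_LATENCY_AMPS, noise_sd=1.0, seed=s,
        )
        recs = simulate_eeg(params, make_design(5, 2, 5, 8))
        curves = []
        for i, rec in enumerate(recs):
            res = decode_timecourse(
                rec, "category_selectivity",
                DecodingParams(n_pseudotrials=10, n_repeats=2, seed=_sub(s, i)),
                categories=("animal", "face"),
            )
            curves.append(res.accuracy.mean(axis=0))
        acc = np.asarray(curves)
        t = recs[0].time_ms
        sig = fdr_correct(wilcoxon_above_chance(acc), q=0.05)
        onset = onset_latency(sig, t, min_run=15)
        onsets.append(np.nan if onset is None else onset)
        peaks.append(peak_latency(acc.mean(axis=0), t))
    onsets = np.asarray(onsets, dtype=float)
    return {
        "true_onset_ms": 80.0,
        "true_peak_ms": 150.0,
        "mean_onset_ms": float(np.nanmean(onsets)),
        "mean_peak_ms": float(np.mean(peaks)),
        "onsets_ms": onsets.tolist(),
        "peaks_ms": list(map(float, peaks)),
    }


def invariance_ordering(seed: int = 0, n_seeds: int = 20) -> dict:
    """Category-selectivity vs cross-view decoding at invariance mix 0.5.

    Paired over seeds; reports the win count and a one-sided sign-test p.
    """
    wins = 0
    sel_all, inv_all = [], []
    for k in range(n_seeds):
        s = _sub(seed, 400 + k)
        params = GeneratorParams(
            n_participants=1, n_channels=16, sfreq=200.0, epoch_window=(-50, 250),
            n_repetitions=8, invariance_mix=0.5, noise_sd=1.0, seed=s,
        )
        rec = simulate_eeg(params, make_design(5, 2, 5, 8))[0].crop(130, 170)
        sel = decode_timecourse(
            rec, "category_selectivity",
            DecodingParams(n_pseudotrials=8, n_repeats=1, seed=s + 1),
        ).accuracy.mean()
        inv = decode_timecourse(
            rec, "rotation_invariance", DecodingParams(n_repeats=1, seed=s + 1)
        ).accuracy.mean()
        sel_all.append(sel)
        inv_all.append(inv)
        wins += int(sel >= inv)
    p = scipy.stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
    return {
        "n_selectivity_wins": wins,
        "n_seeds": n_seeds,
        "sign_test_p": float(p),
        "mean_selectivity_accuracy": float(np.mean(sel_all)),
        "mean_invariance_accuracy": float(np.mean(inv_all)),
    }


def whitening_benefit(seed: int = 0, n_seeds: int = 20) -> dict:
    """Multivariate noise normalisation vs none under correlated noise."""
    wins = 0
    w_all, p_all = [], []
    amps = {"animal": 0.7, "chair": 0.63, "face": 1.05, "fruit": 0.56, "vehicle": 0.77}
    for k in range(n_seeds):
        s = _sub(seed, 500 + k)
        params = GeneratorParams(
            n_participants=1, n_channels=16, sfreq=200.0, epoch_window=(-50, 250),
            n_repetitions=8, noise_sd=1.0, channel_corr_scale=6.0,
            category_amplitudes=amps, seed=s,
        )
        rec = simulate_eeg(params, make_design(5, 2, 5, 8))[0].crop(140, 160)
        accs = {}
        for wh in (True, False):
            accs[wh] = decode_timecourse(
                rec, "category_selectivity",
                DecodingParams(n_pseudotrials=8, n_repeats=1, seed=s + 1, whitening=wh),
            ).accuracy.mean()
        wins += int(accs[True] >= accs[False])
        w_all.append(accs[True])
        p_all.append(accs[False])
    return {
        "n_whitening_wins": wins,
        "n_seeds": n_seeds,
        "mean_whitened_accuracy": float(np.mean(w_all)),
        "mean_unwhitened_accuracy": float(np.mean(p_all)),
    }


# SNR-correspondence study conditions: an ROI-graded fMRI SNR profile
# (occipital high, temporal pole low) with category amplitudes shared
# between the fMRI and ECoG generators.
_SNR_AMPS = {"animal": 1.0, "chair": 0.7, "face": 1.6, "fruit": 0.5, "vehicle": 1.3}
_SNR_GRADIENT = {
    "O-Inf": 2.2, "T-LFus": 1.6, "T-MLing": 1.2,
    "T-MTPhip": 0.5, "T-IT": 0.25, "T-Pole": 0.1,
}


def _snr_one(seed: int) -> float:
    params = GeneratorParams(
        n_participants=10, n_channels=8, sfreq=200.0, epoch_window=(-50, 300),
        noise_sd=1.0, category_amplitudes=_SNR_AMPS, n_voxels=12, n_runs=4,
        roi_snr=_SNR_GRADIENT, n_electrodes_per_region=12, ecog_power_scale=3.0,
        invariance_mix=0.7, seed=seed,
    )
    fmri = simulate_fmri(params, make_design(5, 5, 5, 4, n_runs=4))
    participants = sorted({ps.participant_id for ps in fmri})
    rng = np.random.default_rng(seed + 1)
    fmri_acc, fmri_rdms = {}, {}
    for roi in ROIS:
        accs, rdms = [], []
        for pid in participants:
            x, labels = patternsets_to_trials(fmri, roi, pid)
            dp = DecodingParams(
                whitening=False, n_repeats=2, seed=int(rng.integers(2**31 - 1))
            )
            accs.append(
                decode_static(x, labels, "category_selectivity", dp,
                              cv="leave_one_run_out", participant_id=pid).accuracy
            )
            means, order = condition_means(x, labels)
            rdms.append(compute_rdm(means, order, meta={"roi": roi, "participant": pid}))
        fmri_acc[roi] = np.mean(accs, axis=0)
        fmri_rdms[roi] = rdms
    # ECoG: four independent pooled pseudo-patient cohorts with the same
    # category amplitude profile; sessions are grouped into pseudo-runs so
    # the run-wise cross-validation applies, and accuracies are averaged
    # over cohorts
    ecog_vecs: dict[str, list] = {roi: [] for roi in ROIS}
    for cohort in range(4):
        ep = params.replace(noise_sd=0.5, seed=_sub(seed, 600 + cohort))
        ecog = simulate_ecog(ep, make_design(5, 5, 5, 4, n_runs=4))
        for roi in ROIS:
            mask = (ecog.channels["region"] == roi).to_numpy()
            feats = ecog_feature_vector(ecog, window=(50, 300), bin_ms=25, electrodes=mask)
            dp = DecodingParams(
                whitening=False, n_repeats=2, seed=int(rng.integers(2**31 - 1))
            )
            ecog_vecs[roi].append(
                decode_static(feats, ecog.labels, "category_selectivity", dp,
                              cv="leave_one_run_out").accuracy
            )
    ecog_acc = {roi: np.mean(v, axis=0) for roi, v in ecog_vecs.items()}
    return snr_vs_correspondence(fmri_acc, ecog_acc, fmri_rdms).summary_rho


def snr_correspondence(seed: int = 0, n_seeds: int = 20) -> dict:
    """ROI-graded fMRI SNR vs ECoG-fMRI decoding correspondence."""
    rhos = np.array([_snr_one(_sub(seed, 700 + k)) for k in range(n_seeds)])
    return {
        "n_positive": int(np.sum(rhos > 0)),
        "n_seeds": n_seeds,
        "mean_summary_rho": float(np.nanmean(rhos)),
        "summary_rhos": rhos.tolist(),
    }
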