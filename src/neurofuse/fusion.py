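"""Cross-modal comparison: timecourse correlation and RDM fusion.

Two complementary routes relate modalities:

* classification-performance based — Spearman correlation between decoding
  accuracy timecourses (overall, and per timepoint across the five
  category accuracies);
* representation based — Spearman correlation between RDMs, either a
  static RDM (fMRI) broadcast against a time-resolved RDM stack (EEG or
  ECoG), or two stacks timepoint by timepoint, with condition-label
  permutation significance and FDR correction over time.

The SNR analysis asks whether per-region fMRI-to-ECoG correspondence in
category decoding tracks the region's fMRI signal-to-noise (the upper
noise ceiling of its participant RDMs).

Temporal alignment: a millisecond-resolved accuracy curve is compared to a
25 ms-binned one by averaging the fine curve within each bin and comparing
at bin centers — resolution is never fabricated by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ROIS
from .inference import SignificanceMask, fdr_correct, permutation_rdm_test
from .rsa import RDM, noise_ceiling_upper, spearman, upper_triangle

__all__ = [
    "FusionTimecourse",
    "RegionCorrespondence",
    "bin_average",
    "correlate_timecourses",
    "timewise_category_correlation",
    "fuse_rdm_timecourse",
    "snr_vs_correspondence",
]


@dataclass
class FusionTimecourse:
    rho: np.ndarray
    time_ms: np.ndarray
    significance: SignificanceMask | None = None
    pair: tuple[str, str, str] = ("a", "b", "all")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("rho out of [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time_ms, "rho": self.rho})
        if self.significance is not None:
            df["p"] = self.significance.p_values
            df["p_adj"] = self.significance.p_adjusted
            df["significant"] = self.significance.mask
        return df


@dataclass
class RegionCorrespondence:
    """Per-region ECoG-fMRI correspondence vs fMRI SNR."""

    table: pd.DataFrame  # columns: roi, rho, snr
    summary_rho: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.summary_rho)


def bin_average(
    curve: np.ndarray, time_ms: np.ndarray, bin_ms: float, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Average a fine-grained curve in consecutive bins tiling ``window``.

    Returns (bin_centers_ms, means). Bins are [lo, lo+bin) style.
    """
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_ms))
    if abs(n_bins * bin_ms - (hi - lo)) > 1e-9:
        raise ValueError("window length must be divisible by bin width")
    centers = lo + bin_ms * (np.arange(n_bins) + 0.5)
    means = np.empty(n_bins)
    for b in range(n_bins):
        m = (time_ms >= lo + b * bin_ms - 1e-9) & (time_ms < lo + (b + 1) * bin_ms - 1e-9)
        if not m.any():
            raise ValueError(f"no samples in bin starting {lo + b * bin_ms} ms")
        means[b] = np.asarray(curve)[m].mean()
    return centers, means


def correlate_timecourses(tc_a: np.ndarray, tc_b: np.ndarray) -> float:
    """Single Spearman rho between two accuracy timecourses already on a
    common grid (see :func:`bin_average` for alignment)."""
    tc_a, tc_b = np.asarray(tc_a, float), np.asarray(tc_b, float)
    if tc_a.shape != tc_b.shape:
        raise ValueError("timecourses must share a time grid")
    if tc_a.size < 3:
        raise ValueError("need at least 3 common timepoints")
    return spearman(tc_a, tc_b)


def timewise_category_correlation(
    acc_a: np.ndarray, acc_b: np.ndarray, time_ms: np.ndarray, pair=("a", "b", "all")
) -> FusionTimecourse:
    """Per-timepoint Spearman over the 5 category accuracies.

    ``acc_a``/``acc_b`` are timepoints x categories in the same category
    order. Constant (fully tied) vectors give NaN at that timepoint.
    """
    acc_a, acc_b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if acc_a.shape != acc_b.shape:
        raise ValueError("accuracy arrays must match (time x category)")
    rho = np.empty(acc_a.shape[0])
    for t in range(acc_a.shape[0]):
        a, b = acc_a[t], acc_b[t]
        if np.all(a == a[0]) or np.all(b == b[0]):
            rho[t] = np.nan
        else:
            rho[t] = spearman(a, b)
    return FusionTimecourse(rho, np.asarray(time_ms, float), pair=pair)


def fuse_rdm_timecourse(
    rdm_a: RDM | list[RDM],
    rdm_stack_b: list[RDM],
    time_ms: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    q: float = 0.05,
    pair=("a", "b", "all"),
) -> FusionTimecourse:
    """Fuse a static RDM (or a time-resolved stack) with a time-resolved
    RDM stack: per-timepoint Spearman over upper-triangle vectors, a
    condition-label permutation p per timepoint, and FDR over time.

    A static ``rdm_a`` is broadcast across time. Undefined correlations
    (constant vectors) propagate as NaN and are excluded from the FDR
    family.
    """
    n_t = len(rdm_stack_b)
    if len(time_ms) != n_t:
        raise ValueError("time axis must match the RDM stack length")
    stack_a = [rdm_a] * n_t if isinstance(rdm_a, RDM) else list(rdm_a)
    if len(stack_a) != n_t:
        raise ValueError("time-resolved members must have equal length")
    rho = np.empty(n_t)
    p = np.empty(n_t)
    rng = np.random.default_rng(seed)
    for t in range(n_t):
        r, pv = permutation_rdm_test(
            stack_a[t], rdm_stack_b[t], n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rho[t], p[t] = r, (pv if np.isfinite(r) else np.nan)
    sig = fdr_correct(p, q)
    return FusionTimecourse(rho, np.asarray(time_ms, float), significance=sig, pair=pair)


def snr_vs_correspondence(
    fmri_acc_by_roi: dict[str, np.ndarray],
    ecog_acc_by_roi: dict[str, np.ndarray],
    fmri_rdms_by_roi: dict[str, list[RDM]],
    rois: tuple[str, ...] = ROIS,
) -> RegionCorrespondence:
    """Relate per-region fMRI SNR to ECoG-fMRI decoding correspondence.

    Inputs per ROI: the participant-mean fMRI per-category accuracies (one
    value per category, category-selectivity scheme), the ECoG per-category
    accuracies, and the per-participant fMRI RDMs. Per region the
    correspondence is Spearman's rho across the 5 category accuracies; the
    region's SNR is the upper noise ceiling of its participant RDMs; the
    summary is Spearman between the per-region rhos and SNRs (a 1 x 6
    vector each). Constant vectors give NaN, flagged via ``degenerate``.
    """
    missing = [r for r in rois if r not in fmri_acc_by_roi or r not in ecog_acc_by_roi
               or r not in fmri_rdms_by_roi]
    if missing:
        raise ValueError(f"missing ROIs: {missing}")
    rows = []
    for roi in rois:
        a = np.asarray(fmri_acc_by_roi[roi], float)
        b = np.asarray(ecog_acc_by_roi[roi], float)
        if a.shape != b.shape:
            raise ValueError(f"category accuracy vectors differ in length for {roi!r}")
        rho = np.nan if (np.all(a == a[0]) or np.all(b == b[0])) else spearman(a, b)
        snr = noise_ceiling_upper(fmri_rdms_by_roi[roi])
        rows.append((roi, rho, snr))
    table = pd.DataFrame(rows, columns=["roi", "rho", "snr"])
    rhos, snrs = table["rho"].to_numpy(), table["snr"].to_numpy()
    if np.all(np.isfinite(rhos)) and rhos.std() > 0 and snrs.std() > 0:
        summary = spearman(rhos, snrs)
    else:
        summary = float("nan")
    return RegionCorrespondence(table, float(summary))
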