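"""Representational similarity analysis: RDMs and the noise ceiling.

A representational dissimilarity matrix (RDM) summarises a modality's
geometry over the 125 experimental conditions: entry (i, j) is
1 - Spearman's rank correlation between the condition-mean activation
patterns of conditions i and j, so values range over [0, 2], the matrix is
symmetric and the diagonal is undefined (stored as NaN). Because every
modality's RDM is indexed by the same condition order, RDMs are the common
currency for comparing EEG, ECoG and fMRI.

The upper noise ceiling — the mean Spearman correlation of each
participant's RDM with the group-mean RDM (participant included) — serves
as a per-ROI SNR proxy for fMRI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .generator import EpochedRecording

__all__ = [
    "RDM",
    "condition_means",
    "compute_rdm",
    "rdm_timecourse",
    "regional_rdms",
    "mean_rdm",
    "noise_ceiling_upper",
    "upper_triangle",
    "spearman",
]


@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity matrix (NaN diagonal)."""

    values: np.ndarray
    condition_order: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.condition_order = np.asarray(self.condition_order)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("RDM must be square")
        if self.condition_order.size != k:
            raise ValueError("condition_order length must match RDM size")
        if len(np.unique(self.condition_order)) != k:
            raise ValueError("condition_order has duplicates")
        off = ~np.eye(k, dtype=bool)
        vals = self.values[off]
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("off-diagonal dissimilarities must lie in [0, 2]")
        asym = np.nanmax(np.abs(self.values - self.values.T)) if k else 0.0
        if asym > 1e-12:
            raise ValueError(f"RDM asymmetric by {asym}")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Canonical vectorisation: row < col entries, diagonal excluded."""
    i, j = np.triu_indices(values.shape[0], k=1)
    return values[i, j]


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with pairwise NaN exclusion; NaN when
    either vector is constant or fewer than 3 valid pairs remain."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = scipy.stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)


def condition_means(
    data: np.ndarray, labels: pd.DataFrame, condition_order: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Average trials within condition; rows follow the canonical order.

    ``data`` is trials x features (or trials x channels x timepoints).
    Returns ``(means, condition_order)``. Missing conditions are reported
    by id.
    """
    cids = labels["condition_id"].to_numpy()
    if condition_order is None:
        condition_order = np.sort(np.unique(cids))
    means = np.empty((condition_order.size,) + data.shape[1:])
    missing = []
    for i, cid in enumerate(condition_order):
        m = cids == cid
        if not m.any():
            missing.append(int(cid))
            continue
        means[i] = data[m].mean(axis=0)
    if missing:
        raise ValueError(f"no trials for condition ids: {missing}")
    return means, condition_order


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, axis=1)


def compute_rdm(
    patterns: np.ndarray,
    condition_order: np.ndarray | None = None,
    meta: dict | None = None,
) -> RDM:
    """RDM from condition x feature patterns: 1 - Spearman per pair.

    Computed as Pearson correlation of mid-ranked rows (equivalent to
    Spearman with average ranks for ties). A constant row has no rank
    variance; its dissimilarities are undefined (NaN) and a warning is
    emitted.
    """
    patterns = np.asarray(patterns, dtype=float)
    k, n_feat = patterns.shape
    if n_feat < 3:
        raise ValueError("need at least 3 features per condition for rank correlation")
    if condition_order is None:
        condition_order = np.arange(1, k + 1)
    ranks = _rank_rows(patterns)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant pattern(s): dissimilarities set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    corr = (centered @ centered.T) / np.outer(sd_safe, sd_safe)
    corr = np.clip(corr, -1.0, 1.0)
    values = 1.0 - corr
    values[degenerate, :] = np.nan
    values[:, degenerate] = np.nan
    np.fill_diagonal(values, np.nan)
    values = 0.5 * (values + values.T)  # kill float asymmetry from the product
    return RDM(values, condition_order, dict(meta or {}))


def rdm_timecourse(epochs: EpochedRecording, channel_mask: np.ndarray | None = None) -> list[RDM]:
    """One RDM per timepoint from channel-space condition means."""
    data = epochs.data if channel_mask is None else epochs.data[:, channel_mask, :]
    means, order = condition_means(data, epochs.labels)
    out = []
    for t in range(epochs.time_ms.size):
        out.append(
            compute_rdm(
                means[:, :, t],
                order,
                meta={
                    "modality": epochs.modality,
                    "participant": epochs.participant_id,
                    "time_ms": float(epochs.time_ms[t]),
                },
            )
        )
    return out


def regional_rdms(
    ecog: EpochedRecording, region_map: dict[str, list[str]] | None = None
) -> dict[str, list[RDM]]:
    """Per-region RDM timecourses from a pooled region-labelled recording.

    ``region_map`` maps region name -> electrode names; by default the
    channel table's ``region`` column defines the partition. Regions with
    no electrodes are skipped with a warning; fewer than 3 electrodes warns
    (rank correlations over so few features are fragile) but proceeds.
    """
    if region_map is None:
        regions = ecog.channels["region"].dropna().unique()
        region_map = {
            r: list(ecog.channels.loc[ecog.channels["region"] == r, "name"]) for r in regions
        }
    names = list(ecog.channels["name"])
    out: dict[str, list[RDM]] = {}
    for region, elecs in region_map.items():
        mask = np.zeros(ecog.n_channels, dtype=bool)
        for e in elecs:
            mask[names.index(e)] = True
        if not mask.any():
            warnings.warn(f"region {region!r} has no electrodes; skipped", RuntimeWarning)
            continue
        if mask.sum() < 3:
            warnings.warn(
                f"region {region!r} has only {int(mask.sum())} electrodes", RuntimeWarning
            )
        rdms = rdm_timecourse(ecog, channel_mask=mask)
        for r in rdms:
            r.meta["roi"] = region
        out[region] = rdms
    return out


def mean_rdm(rdms: list[RDM]) -> RDM:
    """Elementwise mean over same-order RDMs (dissimilarities averaged
    directly, not rank-transformed). Undefined entries propagate: a cell is
    NaN in the mean iff it is NaN in any input."""
    order = rdms[0].condition_order
    for r in rdms[1:]:
        if not np.array_equal(r.condition_order, order):
            raise ValueError("condition orders differ; refusing to average")
    stack = np.stack([r.values for r in rdms])
    return RDM(stack.mean(axis=0), order, {"n_averaged": len(rdms)})


def noise_ceiling_upper(participant_rdms: list[RDM]) -> float:
    """Upper noise ceiling: mean Spearman correlation of each participant's
    RDM (upper triangle) with the group-mean RDM including that participant."""
    if len(participant_rdms) < 2:
        raise ValueError("need at least 2 participants")
    group = mean_rdm(participant_rdms)
    gvec = upper_triangle(group.values)
    finite = gvec[np.isfinite(gvec)]
    if finite.size < 3:
        raise ValueError("fewer than 3 valid RDM entry pairs")
    if np.ptp(finite) == 0:
        # perfectly cancelling participants (e.g. mirror-image RDMs) leave a
        # constant group RDM: no shared structure, ceiling 0 by convention
        return 0.0
    rhos = []
    for r in participant_rdms:
        rho = spearman(upper_triangle(r.values), gvec)
        if np.isnan(rho):
            raise ValueError("fewer than 3 valid RDM entry pairs for a participant")
        rhos.append(rho)
    return float(np.mean(rhos))
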