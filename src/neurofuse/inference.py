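"""Nonparametric inference: signed-rank tests, FDR, latencies, resampling.

Per-timepoint significance of decoding accuracy uses the one-sided Wilcoxon
signed-rank test across participants against chance, corrected over the time
axis with Benjamini-Hochberg FDR. Onset latency is the first timepoint
opening a sustained run of significant samples; peak latency the time of the
accuracy maximum. Uncertainty over participants comes from bootstrap
resampling; RDM-to-RDM correlations are tested by permuting condition
labels.

The signed-rank null is computed exactly (dynamic programming over the
mid-rank distribution, which handles tied accuracies) for n <= 25
participants and by a tie-corrected normal approximation with continuity
correction above that.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .rsa import RDM, spearman, upper_triangle

__all__ = [
    "SignificanceMask",
    "LatencyEstimate",
    "BootstrapResult",
    "signed_rank_p",
    "wilcoxon_above_chance",
    "fdr_correct",
    "onset_latency",
    "peak_latency",
    "bootstrap_participants",
    "permutation_rdm_test",
]

EXACT_N_MAX = 25


@dataclass
class SignificanceMask:
    p_values: np.ndarray
    p_adjusted: np.ndarray
    mask: np.ndarray
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (len(self.p_values) == len(self.p_adjusted) == len(self.mask)):
            raise ValueError("p, adjusted p and mask must share length")


@dataclass
class LatencyEstimate:
    peak_ms: float
    onset_ms: float | None = None
    bootstrap_ci: tuple[float, float] | None = None
    n_boot: int = 0


@dataclass
class BootstrapResult:
    distribution: np.ndarray
    ci: tuple[float, float]
    p: float
    n_undefined: int = 0
    meta: dict = field(default_factory=dict)


def signed_rank_p(diffs: np.ndarray, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for median(diffs) vs 0.

    Zero differences are dropped (Wilcoxon convention); ties among the
    absolute differences receive average (mid) ranks. For n <= 25 the null
    distribution of the positive-rank sum is built exactly by dynamic
    programming over doubled ranks (mid-ranks are half-integers); larger n
    uses the tie-corrected normal approximation with continuity correction.
    If every difference is zero, p = 1 by convention.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if alternative == "less":
        d = -d
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        # exact: DP over doubled ranks (integers); count sign patterns with
        # positive-rank sum >= observed
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        w2 = int(np.rint(2 * w_pos))
        return float(counts[w2:].sum() / 2.0**n)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return 1.0 if w_pos <= mean else 0.0
    z = (w_pos - mean - 0.5) / math.sqrt(var)
    return float(scipy.stats.norm.sf(z))


def wilcoxon_above_chance(acc: np.ndarray, chance: float = 0.5) -> np.ndarray:
    """One-sided signed-rank p per timepoint for participants x timepoints
    accuracies exceeding chance."""
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    n_part, n_t = acc.shape
    if n_part < 5:
        raise ValueError("need at least 5 participants for the signed-rank test")
    return np.array([signed_rank_p(acc[:, t] - chance) for t in range(n_t)])


def fdr_correct(p: np.ndarray, q: float = 0.05) -> SignificanceMask:
    """Benjamini-Hochberg step-up over one curve's timepoints.

    NaN p-values (e.g. undefined correlations) are excluded from the family
    and never significant.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = np.isfinite(p)
    mask = np.zeros(p.size, dtype=bool)
    p_adj = np.full(p.size, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        mask[ok] = rej
        p_adj[ok] = adj
    return SignificanceMask(p, p_adj, mask, q)


def onset_latency(
    mask: SignificanceMask | np.ndarray,
    time_ms: np.ndarray,
    min_run: int = 15,
    t_start: float = 0.0,
) -> float | None:
    """Earliest time opening a run of >= min_run consecutive significant
    samples, searched from ``t_start`` (stimulus onset) onward; ``None``
    when no such run exists."""
    m = mask.mask if isinstance(mask, SignificanceMask) else np.asarray(mask, dtype=bool)
    time_ms = np.asarray(time_ms, dtype=float)
    if m.size != time_ms.size:
        raise ValueError("mask and time axis lengths differ")
    keep = time_ms >= t_start
    mm, tt = m[keep], time_ms[keep]
    run = 0
    for i, flag in enumerate(mm):
        run = run + 1 if flag else 0
        if run >= min_run:
            return float(tt[i - min_run + 1])
    return None


def peak_latency(
    curve: np.ndarray,
    time_ms: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Time of the global accuracy maximum (earliest sample on ties).

    ``window`` restricts the search (default: all post-stimulus times).
    """
    curve = np.asarray(curve, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    if window is None:
        keep = time_ms >= 0.0
        if not keep.any():
            keep = np.ones_like(time_ms, dtype=bool)
    else:
        keep = (time_ms >= window[0]) & (time_ms <= window[1])
        if not keep.any():
            raise ValueError(f"no samples in window {window}")
    c, t = curve[keep], time_ms[keep]
    return float(t[int(np.argmax(c))])


def bootstrap_participants(
    stat_fn,
    per_participant_data: np.ndarray | list,
    n_boot: int = 10000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Bootstrap over participants (resampled with replacement).

    ``stat_fn`` maps a participant sample (same container type, first axis
    participants) to a scalar; undefined outcomes may be returned as NaN
    or None. The p-value treats the statistic as a difference:
    p = 2 * min(P(stat* <= 0), P(stat* >= 0)) with +1 smoothing. Aborts if
    more than half the resamples are undefined.
    """
    data = per_participant_data
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    is_array = isinstance(data, np.ndarray)
    dist = np.empty(n_boot)
    n_undef = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data[idx] if is_array else [data[i] for i in idx]
        val = stat_fn(sample)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            n_undef += 1
            dist[b] = np.nan
        else:
            dist[b] = float(val)
    if n_undef > n_boot / 2:
        raise RuntimeError(
            f"statistic undefined on {n_undef}/{n_boot} resamples; aborting"
        )
    valid = dist[np.isfinite(dist)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(valid, [100 * alpha, 100 * (1 - alpha)])
    b = valid.size
    p_le = (1 + np.sum(valid <= 0)) / (1 + b)
    p_ge = (1 + np.sum(valid >= 0)) / (1 + b)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return BootstrapResult(dist, (float(lo), float(hi)), float(p), n_undef)


def _pair_index_matrix(k: int) -> np.ndarray:
    m = np.zeros((k, k), dtype=np.int64)
    i, j = np.triu_indices(k, 1)
    m[i, j] = np.arange(i.size)
    m[j, i] = m[i, j]
    return m


def permutation_rdm_test(
    rdm_a: RDM,
    rdm_b: RDM,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
    return_null: bool = False,
):
    """Spearman correlation between two RDMs with a condition-label
    permutation null.

    The observed statistic is Spearman's rho over the upper-triangle
    vectors. The null jointly permutes rows and columns of ``rdm_b`` —
    i.e. relabels its conditions — ``n_perm`` times (or exhaustively over
    all K! relabelings when ``exhaustive``). One-sided
    p = (1 + #{rho* >= rho_obs}) / (1 + n_perm). Condition orders must
    match exactly; nothing is silently realigned.
    """
    if not np.array_equal(rdm_a.condition_order, rdm_b.condition_order):
        raise ValueError("condition orders differ between RDMs")
    k = rdm_a.n_conditions
    va, vb = upper_triangle(rdm_a.values), upper_triangle(rdm_b.values)
    rho_obs = spearman(va, vb)
    finite = np.isfinite(va).all() and np.isfinite(vb).all()
    pairs = _pair_index_matrix(k)
    iu, ju = np.triu_indices(k, 1)

    if finite:
        ra = scipy.stats.rankdata(va)
        rb = scipy.stats.rankdata(vb)
        ra_c = ra - ra.mean()
        denom_a = math.sqrt((ra_c**2).sum())

        def corr_for(perm: np.ndarray) -> float:
            # relabeling conditions permutes the pair vector; ranks permute
            # with it, so rank once and gather
            rbp = rb[pairs[perm[iu], perm[ju]]]
            rb_c = rbp - rbp.mean()
            db = math.sqrt((rb_c**2).sum())
            if denom_a == 0 or db == 0:
                return float("nan")
            return float((ra_c @ rb_c) / (denom_a * db))
    else:

        def corr_for(perm: np.ndarray) -> float:
            vbp = rdm_b.values[np.ix_(perm, perm)][iu, ju]
            return spearman(va, vbp)

    if exhaustive:
        null = np.array([corr_for(np.array(p)) for p in itertools.permutations(range(k))])
    else:
        rng = np.random.default_rng(seed)
        null = np.array([corr_for(rng.permutation(k)) for _ in range(n_perm)])
    valid = null[np.isfinite(null)]
    p = (1 + np.sum(valid >= rho_obs)) / (1 + valid.size)
    if return_null:
        return float(rho_obs), float(p), null
    return float(rho_obs), float(p)
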