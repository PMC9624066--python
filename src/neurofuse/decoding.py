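"""One-vs-rest category decoding in three generalisation schemes.

Decoding follows the time-resolved MVPA recipe standard in visual
neuroscience: one linear support-vector machine per timepoint, one-vs-rest
per category with the majority class subsampled to balance, trial averaging
into pseudo-trials to raise SNR, and multivariate noise normalisation
(whitening by a shrinkage-regularised channel noise covariance estimated
from training data only). Chance level is 0.5 throughout.

Three schemes probe increasingly tolerant representations:

* ``category_selectivity`` — train and test on all viewing conditions;
  leave-one-pseudo-trial-(per-class)-out cross-validation.
* ``rotation_invariance`` — train on the canonical view (v1), test on the
  rotated views (v2, v3); the two test views are decoded separately and
  averaged.
* ``scale_invariance`` — train on v1, test on the rescaled views (v4, v5).

Static decoders cover fMRI beta patterns (leave-one-run-out) and ECoG
range features (max - min per electrode in 25 ms bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .design import CATEGORIES, VARIATIONS
from .generator import EpochedRecording, PatternSet
from .svm import svm_fit_predict

__all__ = [
    "Scheme",
    "SCHEMES",
    "DecodingParams",
    "DecodingResult",
    "balance_one_vs_rest",
    "make_pseudotrials",
    "compute_whitener",
    "noise_normalize",
    "decode_timecourse",
    "ecog_feature_vector",
    "patternsets_to_trials",
    "decode_static",
]


@dataclass(frozen=True)
class Scheme:
    name: str
    train_variations: tuple[str, ...]
    test_variations: tuple[str, ...]

    @property
    def is_cross(self) -> bool:
        return set(self.train_variations) != set(self.test_variations)


SCHEMES: dict[str, Scheme] = {
    "category_selectivity": Scheme("category_selectivity", VARIATIONS, VARIATIONS),
    "rotation_invariance": Scheme("rotation_invariance", ("v1",), ("v2", "v3")),
    "scale_invariance": Scheme("scale_invariance", ("v1",), ("v4", "v5")),
}


def get_scheme(scheme: str | Scheme) -> Scheme:
    if isinstance(scheme, Scheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}") from None


@dataclass(frozen=True)
class DecodingParams:
    """Tunables of the decoding procedure.

    ``n_repeats=None`` resolves to the scheme default (300 for the
    selectivity scheme, 150 for the invariance schemes). ``shrinkage``
    is either ``"lw"`` (Ledoit-Wolf) or a fixed coefficient in [0, 1].
    """

    n_pseudotrials: int = 150
    n_repeats: int | None = None
    C: float = 1.0
    whitening: bool = True
    shrinkage: str | float = "lw"
    seed: int = 0

    def resolve_repeats(self, scheme: Scheme) -> int:
        if self.n_repeats is not None:
            return self.n_repeats
        return 300 if not scheme.is_cross else 150


@dataclass
class DecodingResult:
    """Per-participant decoding accuracies.

    ``accuracy`` has shape (n_categories, n_timepoints) for time-resolved
    decoding or (n_categories,) for static decoding; values in [0, 1].
    """

    accuracy: np.ndarray
    categories: tuple[str, ...]
    scheme: str
    participant_id: str
    time_ms: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        if np.any((self.accuracy < -1e-12) | (self.accuracy > 1 + 1e-12)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: participant, scheme, category, time_ms, accuracy."""
        rows = []
        acc = np.atleast_2d(self.accuracy)
        times = self.time_ms if self.time_ms is not None else [np.nan]
        for ci, cat in enumerate(self.categories):
            for ti, t in enumerate(np.atleast_1d(times)):
                a = acc[ci, ti] if acc.ndim == 2 else acc[ci]
                rows.append((self.participant_id, self.scheme, cat, float(t), float(a)))
        return pd.DataFrame(
            rows, columns=["participant", "scheme", "category", "time_ms", "accuracy"]
        )


def stack_accuracies(results: list[DecodingResult]) -> np.ndarray:
    """Stack per-participant accuracies into participants x categories x [time]."""
    return np.stack([r.accuracy for r in results])


def balance_one_vs_rest(
    labels: pd.DataFrame,
    target_category: str,
    rng: np.random.Generator,
    variations: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of all target-category trials and an equal-size random
    subsample of the remaining trials (uniform, without replacement)."""
    mask = np.ones(len(labels), dtype=bool)
    if variations is not None:
        mask = labels["variation"].isin(variations).to_numpy()
    is_pos = (labels["category"] == target_category).to_numpy() & mask
    is_neg = (labels["category"] != target_category).to_numpy() & mask
    pos = np.flatnonzero(is_pos)
    neg = np.flatnonzero(is_neg)
    if pos.size == 0:
        raise ValueError(f"no trials for category {target_category!r}")
    if neg.size < pos.size:
        raise ValueError(
            f"cannot balance: {neg.size} negatives for {pos.size} positives"
        )
    if neg.size == pos.size:
        return pos, neg
    return pos, np.sort(rng.choice(neg, size=pos.size, replace=False))


def make_pseudotrials(
    trials: np.ndarray, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly partition trials into ``n_sets`` sets (sizes differing by at
    most one) and average within each set.

    800 trials into 150 sets gives 50 sets of 6 and 100 sets of 5 trials.
    """
    n = trials.shape[0]
    if n_sets < 1 or n_sets > n:
        raise ValueError(f"n_sets={n_sets} must be in 1..{n}")
    perm = rng.permutation(n)
    out = np.empty((n_sets,) + trials.shape[1:], dtype=np.float64)
    for i, chunk in enumerate(np.array_split(perm, n_sets)):
        out[i] = trials[chunk].mean(axis=0)
    return out


def _shrink(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    mu = np.trace(cov) / cov.shape[0]
    return (1.0 - shrinkage) * cov + shrinkage * mu * np.eye(cov.shape[0])


def compute_whitener(
    train: np.ndarray, classes: np.ndarray, shrinkage: str | float = "lw"
) -> np.ndarray:
    """Whitening matrix W = Sigma^(-1/2) from training data only.

    ``train`` is trials x channels x timepoints (or trials x channels for
    static patterns). Residuals are computed per class and per timepoint
    (pattern minus its class mean at that timepoint); their pooled
    covariance — equivalently, the per-class per-timepoint covariances
    averaged — is shrunk toward a scaled identity (Ledoit-Wolf by default)
    and inverted through an eigendecomposition with a floor on the
    eigenvalues, so degenerate covariances still whiten.
    """
    x = train[..., None] if train.ndim == 2 else train
    n, n_ch, n_t = x.shape
    residuals = np.empty_like(x)
    for c in np.unique(classes):
        m = classes == c
        residuals[m] = x[m] - x[m].mean(axis=0, keepdims=True)
    flat = residuals.transpose(0, 2, 1).reshape(n * n_t, n_ch)
    if shrinkage == "lw":
        lw = LedoitWolf(assume_centered=True).fit(flat)
        cov = lw.covariance_
    else:
        cov = flat.T @ flat / max(flat.shape[0], 1)
        cov = _shrink(cov, float(shrinkage))
    vals, vecs = np.linalg.eigh(cov)
    floor = max(vals.max(), 1e-30) * 1e-10
    vals = np.maximum(vals, floor)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def noise_normalize(
    train: np.ndarray,
    classes: np.ndarray,
    test: np.ndarray,
    shrinkage: str | float = "lw",
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate noise normalisation: whiten train and test patterns by
    the training-estimated channel noise covariance."""
    w = compute_whitener(train, classes, shrinkage)
    return apply_whitener(train, w), apply_whitener(test, w)


def apply_whitener(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    if x.ndim == 2:
        return x @ w.T
    return np.einsum("ij,njt->nit", w, x)


def _fit_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    C: float,
) -> np.ndarray:
    """Linear max-margin classifier; score ties resolve to the negative class.

    Uses the package's dual coordinate-descent solver (:mod:`neurofuse.svm`),
    whose solution coincides with ``sklearn.svm.LinearSVC`` at the same C.
    """
    return svm_fit_predict(train_x, train_y, test_x, C)


def decode_timecourse(
    epochs: EpochedRecording,
    scheme: str | Scheme,
    params: DecodingParams = DecodingParams(),
    categories: tuple[str, ...] | None = None,
) -> DecodingResult:
    """Time-resolved one-vs-rest decoding for one participant.

    Selectivity scheme: per repeat — balance classes, average trials into
    pseudo-trials per class, whiten, then leave-one-pseudo-trial-per-class
    out: each fold trains on (n-1)+(n-1) pseudo-trials and tests the held
    out pair at every timepoint. Invariance schemes: per repeat — train on
    all canonical-view (v1) trials of the category vs an equal random
    sample of v1 trials of other categories, whiten, and test every trial
    of each unseen test view against a balanced negative sample; the two
    test views are averaged. Accuracies are averaged over folds then
    repeats.
    """
    scheme = get_scheme(scheme)
    if categories is None:
        categories = tuple(c for c in CATEGORIES if (epochs.labels["category"] == c).any())
    if scheme.is_cross:
        # selectivity uses whatever views are present; cross-decoding needs
        # its specific train and test views
        present = set(epochs.labels["variation"].unique())
        missing = (set(scheme.train_variations) | set(scheme.test_variations)) - present
        if missing:
            raise ValueError(
                f"scheme {scheme.name!r} needs variations absent from data: {sorted(missing)}"
            )
    rng = np.random.default_rng(params.seed)
    n_rep = params.resolve_repeats(scheme)
    n_t = epochs.time_ms.size
    acc = np.zeros((len(categories), n_t))
    for ci, cat in enumerate(categories):
        total = np.zeros(n_t)
        for _ in range(n_rep):
            if not scheme.is_cross:
                total += _selectivity_repeat(epochs, cat, params, rng)
            else:
                total += _cross_repeat(epochs, cat, scheme, params, rng)
        acc[ci] = total / n_rep
    return DecodingResult(
        accuracy=acc,
        categories=categories,
        scheme=scheme.name,
        participant_id=epochs.participant_id,
        time_ms=epochs.time_ms.copy(),
        provenance={"params": params, "n_repeats": n_rep},
    )


def _selectivity_repeat(
    epochs: EpochedRecording, cat: str, params: DecodingParams, rng: np.random.Generator
) -> np.ndarray:
    pos, neg = balance_one_vs_rest(epochs.labels, cat, rng)
    n_sets = min(params.n_pseudotrials, pos.size)
    xp = make_pseudotrials(epochs.data[pos], n_sets, rng)
    xn = make_pseudotrials(epochs.data[neg], n_sets, rng)
    n_t = epochs.time_ms.size
    correct = np.zeros(n_t)
    idx = np.arange(n_sets)
    for k in range(n_sets):
        tr_p, tr_n = xp[idx != k], xn[idx != k]
        te = np.stack([xp[k], xn[k]])
        train = np.concatenate([tr_p, tr_n])
        y = np.concatenate([np.ones(n_sets - 1, int), np.zeros(n_sets - 1, int)])
        if params.whitening:
            w = compute_whitener(train, y, params.shrinkage)
            train, te = apply_whitener(train, w), apply_whitener(te, w)
        for t in range(n_t):
            pred = _fit_predict(train[:, :, t], y, te[:, :, t], params.C)
            correct[t] += int(pred[0] == 1) + int(pred[1] == 0)
    return correct / (2 * n_sets)


def _cross_repeat(
    epochs: EpochedRecording,
    cat: str,
    scheme: Scheme,
    params: DecodingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    pos, neg = balance_one_vs_rest(epochs.labels, cat, rng, variations=scheme.train_variations)
    train = np.concatenate([epochs.data[pos], epochs.data[neg]])
    y = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    n_t = epochs.time_ms.size
    if params.whitening:
        w = compute_whitener(train, y, params.shrinkage)
        train = apply_whitener(train, w)
    else:
        w = None
    acc_views = []
    for tv in scheme.test_variations:
        tpos, tneg = balance_one_vs_rest(epochs.labels, cat, rng, variations=(tv,))
        te = np.concatenate([epochs.data[tpos], epochs.data[tneg]])
        ty = np.concatenate([np.ones(tpos.size, int), np.zeros(tneg.size, int)])
        if w is not None:
            te = apply_whitener(te, w)
        a = np.empty(n_t)
        for t in range(n_t):
            pred = _fit_predict(train[:, :, t], y, te[:, :, t], params.C)
            a[t] = np.mean(pred == ty)
        acc_views.append(a)
    return np.mean(acc_views, axis=0)


def ecog_feature_vector(
    epochs: EpochedRecording,
    window: tuple[float, float] = (50.0, 300.0),
    bin_ms: float = 25.0,
    electrodes: np.ndarray | list[str] | str | None = None,
) -> np.ndarray:
    """Range features: max(x) - min(x) per electrode in consecutive bins.

    Bins tile [window[0], window[1]) in steps of ``bin_ms``; the window
    length must be divisible by the bin width. ``electrodes`` selects a
    subset by name, boolean mask, or the string ``"selective"`` (uses the
    channel table's selectivity flag). Returns trials x (electrode * bin).
    """
    lo, hi = window
    n_bins = (hi - lo) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"window length {hi - lo} ms not divisible by bin {bin_ms} ms")
    n_bins = int(round(n_bins))
    if electrodes is None:
        sel = np.ones(epochs.n_channels, dtype=bool)
    elif isinstance(electrodes, str) and electrodes == "selective":
        if "selective" not in epochs.channels.columns:
            raise ValueError("channel table has no 'selective' column")
        sel = epochs.channels["selective"].to_numpy(dtype=bool)
    elif isinstance(electrodes, (list, tuple)) and electrodes and isinstance(electrodes[0], str):
        names = list(epochs.channels["name"])
        sel = np.zeros(epochs.n_channels, dtype=bool)
        for e in electrodes:
            sel[names.index(e)] = True
    else:
        sel = np.asarray(electrodes, dtype=bool)
    data = epochs.data[:, sel, :]
    feats = np.empty((epochs.n_trials, int(sel.sum()), n_bins))
    for b in range(n_bins):
        t0, t1 = lo + b * bin_ms, lo + (b + 1) * bin_ms
        m = (epochs.time_ms >= t0 - 1e-9) & (epochs.time_ms < t1 - 1e-9)
        if not m.any():
            raise ValueError(f"no samples in bin [{t0}, {t1}) ms")
        seg = data[:, :, m]
        feats[:, :, b] = seg.max(axis=2) - seg.min(axis=2)
    return feats.reshape(epochs.n_trials, -1)


def patternsets_to_trials(
    patternsets: list[PatternSet], roi: str, participant_id: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack one participant's runs for one ROI into trials x voxels."""
    sel = [
        ps
        for ps in patternsets
        if ps.roi == roi and ps.participant_id == participant_id
    ]
    if not sel:
        raise ValueError(f"no pattern sets for roi={roi!r}, participant={participant_id!r}")
    sel.sort(key=lambda ps: (ps.run if ps.run is not None else 0))
    x = np.concatenate([ps.betas for ps in sel])
    labels = pd.concat([ps.labels for ps in sel], ignore_index=True)
    return x, labels


def decode_static(
    x: np.ndarray,
    labels: pd.DataFrame,
    scheme: str | Scheme,
    params: DecodingParams = DecodingParams(whitening=False),
    cv: str = "leave_one_run_out",
    categories: tuple[str, ...] | None = None,
    participant_id: str = "unknown",
) -> DecodingResult:
    """Static one-vs-rest decoding of trial x feature patterns.

    Selectivity scheme with ``cv="leave_one_run_out"``: folds over runs;
    per repeat the training negatives are subsampled to balance, and the
    held-out run's negatives are likewise subsampled so that chance is
    exactly 0.5. With ``cv="leave_one_trial_out"``: leave-one-out over the
    balanced trial set. Invariance schemes train on the canonical view and
    test every trial of the unseen views against balanced negatives,
    repeated over negative samples and averaged.
    """
    scheme = get_scheme(scheme)
    if categories is None:
        categories = tuple(c for c in CATEGORIES if (labels["category"] == c).any())
    rng = np.random.default_rng(params.seed)
    n_rep = params.resolve_repeats(scheme)
    acc = np.zeros(len(categories))
    for ci, cat in enumerate(categories):
        if scheme.is_cross:
            acc[ci] = np.mean(
                [_static_cross_repeat(x, labels, cat, scheme, params, rng) for _ in range(n_rep)]
            )
        elif cv == "leave_one_run_out":
            acc[ci] = _static_loro(x, labels, cat, params, rng, n_rep)
        elif cv == "leave_one_trial_out":
            acc[ci] = np.mean(
                [_static_loo_repeat(x, labels, cat, params, rng) for _ in range(n_rep)]
            )
        else:
            raise ValueError(f"unknown cv {cv!r}")
    return DecodingResult(
        accuracy=acc,
        categories=categories,
        scheme=scheme.name,
        participant_id=participant_id,
        time_ms=None,
        provenance={"params": params, "cv": cv, "n_repeats": n_rep},
    )


def _maybe_whiten(train, y, test, params):
    if params.whitening:
        return noise_normalize(train, y, test, params.shrinkage)
    return train, test


def _static_loro(x, labels, cat, params, rng, n_rep):
    runs = labels["run"].dropna().unique()
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    fold_accs = []
    for run in sorted(runs):
        te_mask = (labels["run"] == run).to_numpy()
        tr_lab = labels[~te_mask].reset_index(drop=True)
        te_lab = labels[te_mask].reset_index(drop=True)
        xtr_all, xte_all = x[~te_mask], x[te_mask]
        rep_accs = []
        for _ in range(n_rep):
            pos, neg = balance_one_vs_rest(tr_lab, cat, rng)
            tpos, tneg = balance_one_vs_rest(te_lab, cat, rng)
            train = np.concatenate([xtr_all[pos], xtr_all[neg]])
            y = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
            test = np.concatenate([xte_all[tpos], xte_all[tneg]])
            ty = np.concatenate([np.ones(tpos.size, int), np.zeros(tneg.size, int)])
            train, test = _maybe_whiten(train, y, test, params)
            pred = _fit_predict(train, y, test, params.C)
            rep_accs.append(np.mean(pred == ty))
        fold_accs.append(np.mean(rep_accs))
    return float(np.mean(fold_accs))


def _static_loo_repeat(x, labels, cat, params, rng):
    pos, neg = balance_one_vs_rest(labels, cat, rng)
    idx = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    xx = x[idx]
    correct = 0
    for k in range(idx.size):
        m = np.arange(idx.size) != k
        train, test = xx[m], xx[k : k + 1]
        train, test = _maybe_whiten(train, y[m], test, params)
        pred = _fit_predict(train, y[m], test, params.C)
        correct += int(pred[0] == y[k])
    return correct / idx.size


def _static_cross_repeat(x, labels, cat, scheme, params, rng):
    pos, neg = balance_one_vs_rest(labels, cat, rng, variations=scheme.train_variations)
    train = np.concatenate([x[pos], x[neg]])
    y = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    accs = []
    for tv in scheme.test_variations:
        tpos, tneg = balance_one_vs_rest(labels, cat, rng, variations=(tv,))
        test = np.concatenate([x[tpos], x[tneg]])
        ty = np.concatenate([np.ones(tpos.size, int), np.zeros(tneg.size, int)])
        tr, te = _maybe_whiten(train, y, test, params)
        pred = _fit_predict(tr, y, te, params.C)
        accs.append(np.mean(pred == ty))
    return float(np.mean(accs))
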