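"""Synthetic EEG / ECoG / fMRI generator with known ground truth.

The generator emulates the study design the rest of the package analyses:
125 conditions (5 categories x 5 identities x 5 viewing conditions), epoched
multichannel electrophysiology for EEG and ECoG, and condition x voxel beta
patterns for six ventral-stream ROIs in fMRI. Every structural parameter the
analyses are meant to recover — category effect size, the degree to which
category patterns generalise across viewing conditions, per-region response
latency, per-ROI signal-to-noise — is an explicit dial, so recovery can be
tested against ground truth.

Signal model
------------
Each trial of category c under viewing condition v carries the spatial
pattern

    a_c * [ rho * P_c  +  (1 - rho) * P_{c,v} ]

where ``P_c`` is a category pattern shared across viewing conditions,
``P_{c,v}`` is a condition-specific pattern, ``rho`` (``invariance_mix``)
interpolates between fully view-specific (0) and fully view-invariant (1)
codes, and ``a_c`` is the category amplitude. The pattern is modulated by a
Gaussian temporal envelope truncated at 5 % of its peak (so pre-onset
samples are exactly signal-free), and buried in spatially correlated,
temporally smoothed Gaussian noise.

Determinism: all randomness flows from ``GeneratorParams.seed`` through one
``numpy.random.SeedSequence``; participant ``i`` uses spawn key ``i``, so
identical parameters give bit-identical output and participants are
independent streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CATEGORIES, ROIS, VARIATIONS, make_design

__all__ = [
    "GeneratorParams",
    "EpochedRecording",
    "PatternSet",
    "gaussian_envelope",
    "simulate_eeg",
    "simulate_ecog",
    "simulate_fmri",
    "to_continuous",
]

# Fraction of the peak at which the (truncated) envelope switches on; the
# onset time is defined as this crossing.
ONSET_FRACTION = 0.05

_DEFAULT_AMPLITUDES = {"animal": 1.0, "chair": 0.9, "face": 1.5, "fruit": 0.8, "vehicle": 1.1}
# Regional response-latency offsets (ms): early visual regions first,
# temporal pole last.
_DEFAULT_REGION_OFFSETS = {
    "O-Inf": 0.0,
    "T-MLing": 5.0,
    "T-LFus": 20.0,
    "T-MTPhip": 45.0,
    "T-IT": 70.0,
    "T-Pole": 100.0,
}
# Per-ROI fMRI SNR scale: high occipital, degraded temporal.
_DEFAULT_ROI_SNR = {
    "O-Inf": 1.0,
    "T-LFus": 0.8,
    "T-MLing": 0.7,
    "T-MTPhip": 0.4,
    "T-IT": 0.3,
    "T-Pole": 0.15,
}


@dataclass(frozen=True)
class GeneratorParams:
    """All dials of the synthetic generator (see module docstring).

    ``signal_width`` is the Gaussian envelope sigma in ms; when ``None`` it
    is derived from ``signal_onset``/``signal_peak`` so that the envelope
    first exceeds 5 % of its peak exactly at ``signal_onset``. When an
    explicit width is given it wins, and the effective onset is the 5 %
    crossing implied by that width.
    """

    n_participants: int = 21
    n_channels: int = 64
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-100.0, 600.0)
    n_repetitions: int = 32
    signal_onset: float = 80.0
    signal_peak: float = 150.0
    signal_width: float | None = None
    category_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    invariance_mix: float = 0.5
    noise_sd: float = 1.0
    channel_corr_scale: float = 2.0
    temporal_smoothing: float = 0.3
    region_latency_offsets: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_OFFSETS)
    )
    n_electrodes_per_region: int = 8
    selective_fraction: float = 1.0
    ecog_power_scale: float = 1.0
    roi_snr: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ROI_SNR))
    n_voxels: int = 60
    n_runs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invariance_mix <= 1.0:
            raise ValueError("invariance_mix must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.temporal_smoothing < 1.0:
            raise ValueError("temporal_smoothing must be in [0, 1)")
        if not 0.0 <= self.selective_fraction <= 1.0:
            raise ValueError("selective_fraction must be in [0, 1]")
        if self.signal_onset >= self.signal_peak:
            raise ValueError("signal_onset must precede signal_peak")
        lo, hi = self.epoch_window
        if not (lo <= self.signal_onset and self.signal_peak <= hi):
            raise ValueError(
                f"epoch_window {self.epoch_window} must contain the envelope "
                f"support {self.signal_onset}..{self.signal_peak} ms"
            )

    @property
    def envelope_sigma(self) -> float:
        """Gaussian envelope sigma in ms."""
        if self.signal_width is not None:
            return float(self.signal_width)
        # exp(-d^2 / 2 sigma^2) = ONSET_FRACTION at d = peak - onset
        return (self.signal_peak - self.signal_onset) / math.sqrt(
            -2.0 * math.log(ONSET_FRACTION)
        )

    @property
    def effective_onset(self) -> float:
        """Time (ms) at which the truncated envelope switches on."""
        return self.signal_peak - self.envelope_sigma * math.sqrt(
            -2.0 * math.log(ONSET_FRACTION)
        )

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass
class EpochedRecording:
    """Epoched multichannel data: trials x channels x timepoints.

    ``channels`` is a table with columns ``name``, ``region`` (NA for EEG)
    and ``source_participant`` (provenance of pooled ECoG electrodes).
    ``labels`` holds one condition-table row per trial.
    """

    data: np.ndarray
    time_ms: np.ndarray
    sfreq: float
    channels: pd.DataFrame
    participant_id: str
    modality: str
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length must match data's third dimension")
        if self.time_ms.size > 1:
            steps = np.diff(self.time_ms)
            if not np.all(steps > 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.sfreq, atol=1e-6):
                raise ValueError("time axis step must equal 1000/sfreq")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels row count must equal trial count")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel table must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def crop(self, tmin: float, tmax: float) -> "EpochedRecording":
        """Restrict to time_ms in [tmin, tmax] (inclusive)."""
        keep = (self.time_ms >= tmin - 1e-9) & (self.time_ms <= tmax + 1e-9)
        if not keep.any():
            raise ValueError(f"no samples in [{tmin}, {tmax}] ms")
        return EpochedRecording(
            self.data[:, :, keep],
            self.time_ms[keep],
            self.sfreq,
            self.channels,
            self.participant_id,
            self.modality,
            self.labels,
        )


@dataclass
class PatternSet:
    """fMRI-style beta patterns: one row per condition for one run."""

    betas: np.ndarray
    labels: pd.DataFrame
    roi: str
    participant_id: str
    run: int | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.betas.ndim != 2:
            raise ValueError("betas must be conditions x voxels")
        if len(self.labels) != self.betas.shape[0]:
            raise ValueError("labels must have one row per beta row")
        key = self.labels["condition_id"]
        if key.duplicated().any():
            raise ValueError("duplicate condition rows within one run")


def gaussian_envelope(
    time_ms: np.ndarray, peak: float, sigma: float, offset: float = 0.0
) -> np.ndarray:
    """Truncated Gaussian bump: zero wherever below 5 % of its maximum."""
    env = np.exp(-0.5 * ((time_ms - peak - offset) / sigma) ** 2)
    env[env < ONSET_FRACTION] = 0.0
    return env


def _time_axis(params: GeneratorParams) -> np.ndarray:
    lo, hi = params.epoch_window
    step = 1000.0 / params.sfreq
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _category_amplitude(params: GeneratorParams, category: str) -> float:
    try:
        return float(params.category_amplitudes[category])
    except KeyError:
        raise KeyError(f"category_amplitudes missing category {category!r}") from None


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _condition_patterns(
    rng: np.random.Generator, n_features: int, categories, variations, rho: float
):
    """Per-(category, variation) unit spatial patterns mixed by rho."""
    shared = {c: _unit(rng.standard_normal(n_features)) for c in categories}
    specific = {
        (c, v): _unit(rng.standard_normal(n_features)) for c in categories for v in variations
    }
    return {
        (c, v): rho * shared[c] + (1.0 - rho) * specific[(c, v)]
        for c in categories
        for v in variations
    }


def _correlated_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_channels: int,
    n_times: int,
    params: GeneratorParams,
) -> np.ndarray:
    """Spatially correlated (exponential-decay covariance), AR(1)-smoothed noise."""
    idx = np.arange(n_channels)
    cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / params.channel_corr_scale)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_channels))
    e = rng.standard_normal((n_trials, n_channels, n_times))
    a = params.temporal_smoothing
    if a > 0:
        # stationary AR(1) with unit marginal variance
        s = math.sqrt(1.0 - a * a)
        x = np.empty_like(e)
        x[..., 0] = e[..., 0]
        for t in range(1, n_times):
            x[..., t] = a * x[..., t - 1] + s * e[..., t]
        e = x
    noise = np.einsum("ij,njt->nit", chol, e)
    return params.noise_sd * noise


def _participant_rngs(params: GeneratorParams, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(n)]


def simulate_eeg(
    params: GeneratorParams, design: pd.DataFrame | None = None
) -> list[EpochedRecording]:
    """Simulate one epoched EEG recording per participant."""
    if design is None:
        design = make_design(n_repetitions=params.n_repetitions)
    time_ms = _time_axis(params)
    env = gaussian_envelope(time_ms, params.signal_peak, params.envelope_sigma)
    cats = sorted(design["category"].unique())
    vars_ = sorted(design["variation"].unique())
    channels = pd.DataFrame(
        {
            "name": [f"EEG{i:03d}" for i in range(params.n_channels)],
            "region": pd.array([pd.NA] * params.n_channels, dtype="string"),
            "source_participant": pd.array([pd.NA] * params.n_channels, dtype="string"),
        }
    )
    out = []
    for p, rng in enumerate(_participant_rngs(params, params.n_participants)):
        patterns = _condition_patterns(rng, params.n_channels, cats, vars_, params.invariance_mix)
        data = _correlated_noise(rng, len(design), params.n_channels, time_ms.size, params)
        for i, row in enumerate(design.itertuples(index=False)):
            amp = _category_amplitude(params, row.category)
            if amp != 0.0:
                data[i] += amp * np.outer(patterns[(row.category, row.variation)], env)
        out.append(
            EpochedRecording(
                data,
                time_ms,
                params.sfreq,
                channels,
                participant_id=f"sub-{p + 1:02d}",
                modality="EEG",
                labels=design.reset_index(drop=True),
            )
        )
    return out


def simulate_ecog(
    params: GeneratorParams, design: pd.DataFrame | None = None
) -> EpochedRecording:
    """Simulate a pooled ("super-subject") region-labelled ECoG recording.

    Electrodes come in region blocks; each region's temporal envelope is
    shifted by ``region_latency_offsets[region]``, and a
    ``1 - selective_fraction`` share of each region's electrodes carries
    noise only. Electrode provenance across pseudo-participants is kept in
    the channel table.
    """
    if design is None:
        design = make_design(n_repetitions=params.n_repetitions)
    for region in params.region_latency_offsets:
        if region not in ROIS:
            raise ValueError(f"unknown region label {region!r}; expected one of {ROIS}")
    regions = [r for r in ROIS if r in params.region_latency_offsets]
    if not regions:
        raise ValueError("region_latency_offsets is empty")
    time_ms = _time_axis(params)
    cats = sorted(design["category"].unique())
    vars_ = sorted(design["variation"].unique())
    n_per = params.n_electrodes_per_region
    n_elec = n_per * len(regions)

    rng = _participant_rngs(params, 1)[0]
    rows = []
    for r_i, region in enumerate(regions):
        for e_i in range(n_per):
            rows.append(
                (f"{region}-{e_i:02d}", region, f"patient-{(r_i * n_per + e_i) % 5 + 1:02d}")
            )
    channels = pd.DataFrame(rows, columns=["name", "region", "source_participant"]).astype(
        {"region": "string", "source_participant": "string"}
    )

    noise_params = params.replace(n_channels=n_elec)
    data = _correlated_noise(rng, len(design), n_elec, time_ms.size, noise_params)
    patterns = _condition_patterns(rng, n_elec, cats, vars_, params.invariance_mix)
    # selectivity mask drawn once per region
    selective = np.zeros(n_elec, dtype=bool)
    for r_i in range(len(regions)):
        block = slice(r_i * n_per, (r_i + 1) * n_per)
        n_sel = int(round(params.selective_fraction * n_per))
        chosen = rng.choice(n_per, size=n_sel, replace=False)
        sel = np.zeros(n_per, dtype=bool)
        sel[chosen] = True
        selective[block] = sel
    channels["selective"] = selective

    envs = np.zeros((n_elec, time_ms.size))
    for r_i, region in enumerate(regions):
        block = slice(r_i * n_per, (r_i + 1) * n_per)
        env = gaussian_envelope(
            time_ms, params.signal_peak, params.envelope_sigma,
            offset=params.region_latency_offsets[region],
        )
        envs[block] = env[None, :]
    envs[~selective] = 0.0

    # intracranial field potentials carry category information both as a
    # slow evoked deflection and as a broadband (power) increase; the
    # latter is what range/power features in short bins pick up, so the
    # selective electrodes also get envelope-modulated fast variability
    for i, row in enumerate(design.itertuples(index=False)):
        amp = _category_amplitude(params, row.category)
        if amp != 0.0:
            pat = patterns[(row.category, row.variation)]
            data[i] += amp * pat[:, None] * envs
            if params.ecog_power_scale > 0.0:
                fast = rng.standard_normal((n_elec, time_ms.size))
                data[i] += (
                    params.ecog_power_scale * amp * np.abs(pat)[:, None] * envs * fast
                )
    return EpochedRecording(
        data,
        time_ms,
        params.sfreq,
        channels,
        participant_id="super-subject",
        modality="ECoG",
        labels=design.reset_index(drop=True),
    )


def simulate_fmri(
    params: GeneratorParams, design: pd.DataFrame | None = None
) -> list[PatternSet]:
    """Simulate condition x voxel beta patterns per participant x ROI x run.

    Each ROI's category/variation pattern is scaled by ``roi_snr[roi]``;
    voxel noise is unit-free Gaussian with sd ``noise_sd``, drawn
    independently per run. Returns a flat list of :class:`PatternSet`.
    """
    for roi in ROIS:
        if roi not in params.roi_snr:
            raise ValueError(f"roi_snr missing ROI {roi!r}")
    if design is None:
        design = make_design(n_repetitions=params.n_runs, n_runs=params.n_runs)
    vocab = design[["condition_id", "category", "identity", "variation"]].drop_duplicates(
        subset="condition_id"
    ).sort_values("condition_id").reset_index(drop=True)
    runs = sorted(design["run"].dropna().unique()) if design["run"].notna().any() else [1]
    cats = sorted(vocab["category"].unique())
    vars_ = sorted(vocab["variation"].unique())
    out = []
    for p, rng in enumerate(_participant_rngs(params, params.n_participants)):
        for roi in ROIS:
            snr = float(params.roi_snr[roi])
            patterns = _condition_patterns(rng, params.n_voxels, cats, vars_, params.invariance_mix)
            signal = np.zeros((len(vocab), params.n_voxels))
            for i, row in enumerate(vocab.itertuples(index=False)):
                amp = _category_amplitude(params, row.category)
                signal[i] = snr * amp * patterns[(row.category, row.variation)]
            for run in runs:
                betas = signal + params.noise_sd * rng.standard_normal(signal.shape)
                labels = vocab.copy()
                labels["repetition"] = int(run)
                labels["run"] = pd.array([int(run)] * len(vocab), dtype="Int64")
                out.append(
                    PatternSet(
                        betas,
                        labels,
                        roi=roi,
                        participant_id=f"sub-{p + 1:02d}",
                        run=int(run),
                    )
                )
    return out


def to_continuous(rec: EpochedRecording, gap_ms: float = 0.0):
    """Lay epochs end-to-end into a continuous recording with event markers.

    Returns a :class:`~neurofuse.preprocessing.ContinuousRecording` whose
    events mark each epoch's 0 ms sample, so that re-epoching recovers the
    original tensors. Used to exercise the preprocessing chain end-to-end.
    """
    from .preprocessing import ContinuousRecording

    n_gap = int(round(gap_ms * rec.sfreq / 1000.0))
    n_t = rec.time_ms.size
    zero_idx = int(np.argmin(np.abs(rec.time_ms)))
    total = rec.n_trials * (n_t + n_gap)
    data = np.zeros((rec.n_channels, total))
    events = []
    for i in range(rec.n_trials):
        start = i * (n_t + n_gap)
        data[:, start : start + n_t] = rec.data[i]
        events.append((start + zero_idx, int(rec.labels["condition_id"].iloc[i])))
    return ContinuousRecording(
        data=data,
        sfreq=rec.sfreq,
        channels=list(rec.channels["name"]),
        events=events,
    )
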