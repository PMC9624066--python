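"""Signal conditioning: FIR low-pass, resampling, re-referencing, epoching.

The chain mirrors a minimal event-related EEG pipeline: a linear-phase FIR
low-pass (applied zero-phase by compensating the group delay), polyphase
resampling, subtraction re-referencing to a named electrode, and fixed-window
epoching around event markers. No high-pass filtering and no baseline
correction are applied anywhere: high-pass filtering is known to smear
multivariate patterns into activity-silent periods, and the decoders
downstream are insensitive to a per-channel constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .generator import EpochedRecording

__all__ = [
    "ContinuousRecording",
    "fir_lowpass",
    "resample",
    "rereference",
    "epoch",
]


@dataclass
class ContinuousRecording:
    """Continuous multichannel data with event markers.

    ``events`` is a list of ``(sample_index, condition_id)`` pairs; indices
    must lie strictly within the recording.
    """

    data: np.ndarray
    sfreq: float
    channels: list[str]
    events: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n = self.data.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def design_lowpass(cutoff: float, order: int, sfreq: float) -> np.ndarray:
    """Design the linear-phase FIR low-pass taps (Hamming window)."""
    if cutoff >= sfreq / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {sfreq / 2} Hz")
    if order % 2:
        raise ValueError("order must be even (type-I linear phase)")
    return scipy.signal.firwin(order + 1, cutoff, fs=sfreq)


def fir_lowpass(x: ContinuousRecording, cutoff: float = 40.0, order: int = 396) -> ContinuousRecording:
    """Zero-phase FIR low-pass.

    The filter is applied in a single forward pass and the constant group
    delay of ``order/2`` samples is compensated by shifting, so the
    magnitude response is exactly that of the designed filter (a
    forward-backward pass would square it) and latencies are unbiased.
    DC gain is 1 by construction of the window design.
    """
    taps = design_lowpass(cutoff, order, x.sfreq)
    delay = order // 2
    full = scipy.signal.fftconvolve(x.data, taps[None, :], mode="full", axes=1)
    out = full[:, delay : delay + x.n_samples]
    return ContinuousRecording(out, x.sfreq, list(x.channels), list(x.events))


def resample(x: ContinuousRecording, new_sfreq: float) -> ContinuousRecording:
    """Polyphase rational resampling; event indices are remapped proportionally.

    The ratio ``new_sfreq / sfreq`` must be representable as a fraction with
    denominator <= 1000 to within 1e-9 relative error (1100 -> 1000 Hz is
    10/11); anything else is rejected rather than silently approximated.
    Anti-aliasing is built into the polyphase filter; for the intended use
    the signal is already band-limited by the preceding low-pass.
    """
    if new_sfreq <= 0:
        raise ValueError("new_sfreq must be positive")
    ratio = new_sfreq / x.sfreq
    frac = Fraction(ratio).limit_denominator(1000)
    if abs(float(frac) - ratio) > 1e-9 * ratio:
        raise ValueError(
            f"resampling ratio {ratio} is not rational with denominator <= 1000"
        )
    if frac == 1:
        return ContinuousRecording(x.data.copy(), new_sfreq, list(x.channels), list(x.events))
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(x.data, up, down, axis=1)
    events = [(int(round(idx * up / down)), cid) for idx, cid in x.events]
    events = [(min(i, out.shape[1] - 1), c) for i, c in events]
    return ContinuousRecording(out, new_sfreq, list(x.channels), events)


def rereference(epochs: EpochedRecording, ref_channel: str) -> EpochedRecording:
    """Subtract the named reference channel from every channel.

    The reference channel itself becomes identically zero; applying the same
    reference twice is a no-op.
    """
    names = list(epochs.channels["name"])
    if ref_channel not in names:
        raise ValueError(f"reference channel {ref_channel!r} not found")
    ref_idx = names.index(ref_channel)
    data = epochs.data - epochs.data[:, ref_idx : ref_idx + 1, :]
    return EpochedRecording(
        data,
        epochs.time_ms,
        epochs.sfreq,
        epochs.channels,
        epochs.participant_id,
        epochs.modality,
        epochs.labels,
    )


def epoch(
    x: ContinuousRecording,
    tmin: float,
    tmax: float,
    condition_table: pd.DataFrame | None = None,
    participant_id: str = "unknown",
    modality: str = "EEG",
) -> EpochedRecording:
    """Slice fixed windows [tmin, tmax] ms (both ends inclusive) around events.

    0 ms is the event sample itself; the window is closed on the sample
    grid. Events whose window leaves the recording are reported by index.
    ``condition_table`` (one row per condition_id with category / identity /
    variation) is joined onto the per-trial labels when provided; the
    ``repetition`` counter is the running occurrence count per condition.
    """
    if tmin > tmax:
        raise ValueError("tmin must be <= tmax")
    step = 1000.0 / x.sfreq
    i0 = int(round(tmin / step))
    i1 = int(round(tmax / step))
    bad = [
        k
        for k, (idx, _) in enumerate(x.events)
        if idx + i0 < 0 or idx + i1 >= x.n_samples
    ]
    if bad:
        raise ValueError(f"events out of bounds for window [{tmin}, {tmax}] ms: indices {bad}")
    sl = np.arange(i0, i1 + 1)
    data = np.stack([x.data[:, idx + sl] for idx, _ in x.events]) if x.events else np.empty(
        (0, len(x.channels), sl.size)
    )
    time_ms = sl * step
    cids = [cid for _, cid in x.events]
    labels = pd.DataFrame({"condition_id": cids})
    if condition_table is not None:
        meta = condition_table.drop_duplicates(subset="condition_id")
        labels = labels.merge(
            meta[["condition_id", "category", "identity", "variation"]],
            on="condition_id",
            how="left",
        )
    labels["repetition"] = labels.groupby("condition_id").cumcount() + 1
    labels["run"] = pd.array([pd.NA] * len(labels), dtype="Int64")
    channels = pd.DataFrame(
        {
            "name": list(x.channels),
            "region": pd.array([pd.NA] * len(x.channels), dtype="string"),
            "source_participant": pd.array([pd.NA] * len(x.channels), dtype="string"),
        }
    )
    return EpochedRecording(
        data, time_ms, x.sfreq, channels, participant_id, modality, labels
    )
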