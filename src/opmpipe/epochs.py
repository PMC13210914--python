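"""Event-locked segmentation, baseline correction, rejection, averaging.

Epoch windows follow the two MNS protocols: −0.2…+0.5 s (short) and
−1.2…+5.2 s (long), with sample 0 of the epoch clock aligned to the event
sample and both window endpoints included at sample resolution.  Visual
artifact screening is replaced by an automated any-channel peak-to-peak
threshold (default 5 pT on preprocessed data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from opmpipe.simulate import RawSession


@dataclass
class EpochSet:
    data: np.ndarray  # (n_epochs, n_channels, n_samples) [T]
    tmin: float
    tmax: float
    sample_rate: float
    channel_names: list[str]
    baseline_window: tuple[float, float] | None = None
    kept: np.ndarray = field(default=None)  # original epoch indices
    rejected: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        n_expected = int(round((self.tmax - self.tmin) * self.sample_rate)) + 1
        if self.data.shape[2] != n_expected:
            raise ValueError("epoch length inconsistent with tmin/tmax")
        if self.kept is None:
            self.kept = np.arange(self.data.shape[0])

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.sample_rate

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        return mask

    def copy_with(self, **kw) -> "EpochSet":
        out = EpochSet(self.data.copy(), self.tmin, self.tmax,
                       self.sample_rate, list(self.channel_names),
                       self.baseline_window, self.kept.copy(),
                       self.rejected.copy())
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class Evoked:
    data: np.ndarray  # (n_channels, n_samples)
    tmin: float
    tmax: float
    sample_rate: float
    channel_names: list[str]
    n_epochs: int

    def __post_init__(self):
        if self.n_epochs < 1:
            raise ValueError("an evoked must average at least one epoch")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.sample_rate


def make_epochs(session: RawSession, tmin: float, tmax: float) -> EpochSet:
    """One epoch per event; epoch sample 0 aligned to the event sample.

    Events whose window would exceed the recording are dropped with a
    warning.
    """
    fs = session.sample_rate
    i0, i1 = int(round(tmin * fs)), int(round(tmax * fs))
    n_samp = i1 - i0 + 1
    chunks, kept = [], []
    for k, ev in enumerate(session.events):
        lo, hi = ev + i0, ev + i1 + 1
        if lo < 0 or hi > session.n_samples:
            warnings.warn(f"event {k} window exceeds recording; dropped",
                          RuntimeWarning, stacklevel=2)
            continue
        chunks.append(session.data[:, lo:hi])
        kept.append(k)
    if not chunks:
        raise ValueError("no event window fits inside the recording")
    data = np.stack(chunks)
    assert data.shape[2] == n_samp
    return EpochSet(data, i0 / fs, i1 / fs, fs,
                    list(session.array.names), kept=np.array(kept))


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract each epoch's per-channel baseline-window mean everywhere."""
    mask = epochs.window_slice(window)
    out = epochs.copy_with(baseline_window=tuple(window))
    out.data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_epochs(epochs: EpochSet, ptp_threshold: float = 5e-12) -> EpochSet:
    """Drop epochs whose any-channel peak-to-peak exceeds the threshold."""
    if ptp_threshold <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    bad = (ptp > ptp_threshold).any(axis=1)
    if bad.all():
        raise ValueError("all epochs exceed the rejection threshold")
    out = epochs.copy_with()
    out.data = epochs.data[~bad]
    out.kept = epochs.kept[~bad]
    out.rejected = np.concatenate([epochs.rejected, epochs.kept[bad]])
    return out


def rejection_fraction(epochs: EpochSet) -> float:
    total = epochs.n_epochs + len(epochs.rejected)
    return len(epochs.rejected) / total


def average_evoked(epochs: EpochSet) -> Evoked:
    """Inter-trial average across kept epochs."""
    if epochs.n_epochs < 1:
        raise ValueError("no epochs to average")
    return Evoked(epochs.data.mean(axis=0), epochs.tmin, epochs.tmax,
                  epochs.sample_rate, list(epochs.channel_names),
                  epochs.n_epochs)


def subtract_evoked(epochs: EpochSet) -> EpochSet:
    """Remove the inter-trial average from every epoch (induced activity)."""
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs to subtract the evoked")
    out = epochs.copy_with()
    out.data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return out
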