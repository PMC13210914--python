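"""Morlet wavelet time-frequency analysis with log-ratio baselining.

Power is computed per epoch by complex Morlet convolution over 3–40 Hz in
1 Hz steps with the number of cycles equal to one third of the center
frequency (a constant-duration wavelet: temporal SD = cycles/(2πf) =
1/(6π) s at every frequency).  The first and last 0.2 s are trimmed to
remove edge artifacts.  Baseline correction is log10(power / mean
baseline power) per frequency, and band time courses average the mu
(8–15 Hz) and beta (15–30 Hz) rows with inclusive endpoints (15 Hz
belongs to both bands, as the printed ranges overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU_BAND = (8.0, 15.0)
BETA_BAND = (15.0, 30.0)
DEFAULT_FREQS = np.arange(3.0, 41.0, 1.0)
EDGE_TRIM = 0.2  # [s]


@dataclass
class TfrArray:
    """Power (or log-ratio) array: (..., n_freqs, n_samples)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # [s], edge-trimmed epoch clock
    baseline_window: tuple[float, float] | None = None
    is_log_ratio: bool = False
    log_base: float = 10.0

    def __post_init__(self):
        self.power = np.asarray(self.power, float)
        self.freqs = np.asarray(self.freqs, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape[-2] != len(self.freqs):
            raise ValueError("power/freqs mismatch")
        if self.power.shape[-1] != len(self.times):
            raise ValueError("power/times mismatch")

    def mean_over_epochs(self) -> "TfrArray":
        if self.power.ndim < 3:
            return self
        return TfrArray(self.power.mean(axis=0), self.freqs, self.times,
                        self.baseline_window, self.is_log_ratio, self.log_base)


def morlet_wavelet(freq: float, sample_rate: float, n_cycles: float) -> np.ndarray:
    """L2-normalized complex Morlet wavelet; Gaussian SD = n_cycles/(2πf)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    data: np.ndarray,
    times: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray = DEFAULT_FREQS,
    cycles_factor: float = 1.0 / 3.0,
    edge_trim: float = EDGE_TRIM,
    average_epochs: bool = False,
) -> TfrArray:
    """Morlet power of ``data`` (..., n_samples).

    ``cycles(f) = cycles_factor × f`` (default f/3).  The first and last
    ``edge_trim`` seconds of the epoch clock are removed from the output.
    Raises if any wavelet is longer than the epoch.  With
    ``average_epochs`` the per-epoch power is averaged over the leading
    axis on the fly (the participant-level TFR), which keeps memory flat
    for large epoch stacks.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    flat = data.reshape(-1, n)
    wavelets = [morlet_wavelet(f, sample_rate, cycles_factor * f) for f in freqs]
    for f, w in zip(freqs, wavelets):
        if len(w) > n:
            raise ValueError(f"wavelet at {f} Hz is longer than the epoch")
    # one FFT of the data, reused for every frequency
    max_w = max(len(w) for w in wavelets)
    nfft = int(2 ** np.ceil(np.log2(n + max_w - 1)))
    F = np.fft.fft(flat, nfft, axis=-1)
    trim = int(round(edge_trim * sample_rate))
    sl = slice(trim, n - trim) if trim > 0 else slice(None)
    n_out = len(np.arange(n)[sl])
    if average_epochs:
        if data.ndim < 2:
            raise ValueError("average_epochs requires an epoch axis")
        out_shape = data.shape[1:-1]
        power = np.zeros((*out_shape, len(freqs), n_out))
    else:
        power = np.empty((flat.shape[0], len(freqs), n_out))
    for fi, w in enumerate(wavelets):
        W = np.fft.fft(w, nfft)
        full = np.fft.ifft(F * W, axis=-1)
        start = (len(w) - 1) // 2  # 'same' alignment
        p = np.abs(full[:, start:start + n][:, sl]) ** 2
        if average_epochs:
            power[..., fi, :] = p.reshape(*data.shape[:-1], n_out).mean(axis=0)
        else:
            power[:, fi, :] = p
    if not average_epochs:
        power = power.reshape(*data.shape[:-1], len(freqs), n_out)
    return TfrArray(power, freqs, np.asarray(times)[sl])


def baseline_log_ratio(tfr: TfrArray, window: tuple[float, float]) -> TfrArray:
    """log10 of power relative to the mean baseline power per frequency."""
    t = tfr.times
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside the trimmed time axis")
    base = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power must be strictly positive")
    return TfrArray(np.log10(tfr.power / base), tfr.freqs, tfr.times,
                    tuple(window), is_log_ratio=True)


def band_timecourse(tfr: TfrArray, band: tuple[float, float]) -> np.ndarray:
    """Mean over band frequencies (inclusive endpoints) at each time point."""
    sel = (tfr.freqs >= band[0] - 1e-9) & (tfr.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} contains no analysis frequencies")
    return tfr.power[..., sel, :].mean(axis=-2)
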