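"""Synthetic multi-subject OPM sessions with planted sensorimotor responses.

Each session emulates a median-nerve-stimulation (MNS) recording from the
16-channel partial-coverage array: a somatosensory-evoked-field (SEF)
dipole in the postcentral gyrus with N20m/P35m/P60m lobes, mu and beta
rhythms in the central sulcus with post-stimulus event-related
desynchronization (ERD), a beta-rebound (ERS) source in the precentral
gyrus, homogeneous ambient interference with a small first-order gradient
remainder, 60/120/180 Hz line fields, white sensor noise, and a broadband
stimulus artifact centered on each event.  Two protocols are shipped:
``short_mns`` (300 events, ISI 1–1.4 s, for evoked analysis) and
``long_mns`` (80 events, ISI 5.6–7.6 s, for oscillatory analysis).

Everything is reproducible from ``(seed, subject_id, protocol)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import signal

from opmpipe.forward import (
    LeadField,
    SensorArray,
    SourceGrid,
    SphereHeadModel,
    build_default_array,
    build_default_grid,
    compute_lead_field,
)


@dataclass(frozen=True)
class ProtocolSpec:
    name: str
    n_events: int
    isi_range: tuple[float, float]
    sample_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-0.2, 0.5)
    baseline_window: tuple[float, float] = (-0.2, -0.1)
    #: apply ERD/ERS envelope modulation (requires ISIs long enough that
    #: successive post-event windows do not overlap)
    modulate_rhythms: bool = True

    def __post_init__(self):
        if not self.isi_range[0] < self.isi_range[1]:
            raise ValueError("isi_range must be increasing")


SHORT_MNS = ProtocolSpec(
    "short_mns", n_events=300, isi_range=(1.0, 1.4),
    epoch_window=(-0.2, 0.5), baseline_window=(-0.2, -0.1),
    modulate_rhythms=False,
)
LONG_MNS = ProtocolSpec(
    "long_mns", n_events=80, isi_range=(5.6, 7.6),
    epoch_window=(-1.2, 5.2), baseline_window=(-1.0, -0.5),
    modulate_rhythms=True,
)


@dataclass(frozen=True)
class SefPeak:
    latency: float  # [s]
    width: float  # Gaussian SD [s]
    amplitude: float  # signed [A·m]

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")


#: Default SEF complex: N20m (negative), P35m, P60m.  The amplitude scale
#: is a generator default calibrated so that sensor-level N20m SNR on the
#: default cohort falls in the single-digit-to-low-twenties band typical
#: of compact partial-coverage systems.
DEFAULT_SEF_PEAKS = (
    SefPeak(0.020, 0.005, -4e-9),
    SefPeak(0.035, 0.008, +2e-9),
    SefPeak(0.060, 0.012, +4e-9),
)


@dataclass(frozen=True)
class OscillatorySource:
    vertex: int
    center_freq: float  # [Hz]
    baseline_amplitude: float  # carrier RMS [A·m]
    erd_window: tuple[float, float] = (0.2, 0.4)
    erd_depth: float = 0.0  # fractional amplitude reduction in erd_window
    ers_window: tuple[float, float] = (0.5, 1.0)
    ers_gain: float = 0.0  # fractional amplitude increase in ers_window
    bandwidth: float = 2.0  # carrier bandwidth [Hz]

    def __post_init__(self):
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must be in [0, 1)")
        if self.ers_gain < 0.0:
            raise ValueError("ers_gain must be non-negative")


@dataclass(frozen=True)
class SourceScenario:
    """Planted sources.  Vertex ids refer to the default 6×20 source grid:
    the SEF dipole sits in the postcentral-gyrus strip beneath C3/C5, the
    mu and beta-ERD sources in the central sulcus, and the beta-ERS
    (rebound) source in the precentral gyrus."""

    sef_vertex: int = 68
    sef_peaks: tuple[SefPeak, ...] = DEFAULT_SEF_PEAKS
    #: sign applied to the planted dipole's tangential orientation; the
    #: default makes the negative N20m lobe of the field fall over the
    #: medial peri-rolandic sensors (C1–C5), matching the component naming
    sef_polarity: float = -1.0
    mu_source: OscillatorySource = OscillatorySource(
        vertex=52, center_freq=10.0, baseline_amplitude=8e-9,
        erd_window=(0.2, 0.4), erd_depth=0.5, ers_gain=0.0,
    )
    beta_erd_source: OscillatorySource = OscillatorySource(
        vertex=52, center_freq=21.0, baseline_amplitude=6e-9,
        erd_window=(0.2, 0.4), erd_depth=0.3, ers_gain=0.0,
    )
    beta_ers_source: OscillatorySource = OscillatorySource(
        vertex=32, center_freq=21.0, baseline_amplitude=6e-9,
        erd_depth=0.0, ers_window=(0.5, 1.0), ers_gain=0.3,
    )
    latency_jitter_sd: float = 0.001  # per-subject [s]
    amplitude_jitter_sd: float = 0.2  # per-subject, fractional

    @property
    def oscillatory_sources(self) -> tuple[OscillatorySource, ...]:
        return (self.mu_source, self.beta_erd_source, self.beta_ers_source)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise terms.  The sensor noise floor (10 fT/√Hz, within the
    magnetometers' <20 fT/√Hz rating), interference level, gradient
    remainder and line amplitudes are generator defaults typical of a
    compact passively shielded environment."""

    sensor_noise_density: float = 10e-15  # [T/√Hz]
    interference_rms: float = 30e-12  # per cardinal component [T]
    interference_bandwidth: float = 4.0  # [Hz]
    gradient_fraction: float = 0.05  # first-order remainder HFC cannot remove
    line_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    line_amplitudes: tuple[float, ...] = (1e-12, 0.5e-12, 0.3e-12)
    artifact_amplitude: float | None = None  # default: 10 × sensor-noise RMS
    artifact_duration: float = 0.010  # [s]

    def __post_init__(self):
        vals = [self.sensor_noise_density, self.interference_rms,
                self.interference_bandwidth, self.gradient_fraction,
                self.artifact_duration, *self.line_amplitudes]
        if self.artifact_amplitude is not None:
            vals.append(self.artifact_amplitude)
        if any(v < 0 for v in vals):
            raise ValueError("noise parameters must be non-negative")

    def sensor_noise_rms(self, sample_rate: float) -> float:
        return self.sensor_noise_density * np.sqrt(sample_rate / 2.0)

    def artifact_rms(self, sample_rate: float) -> float:
        if self.artifact_amplitude is not None:
            return self.artifact_amplitude
        return 10.0 * self.sensor_noise_rms(sample_rate)


@dataclass
class RawSession:
    """A recorded (here: simulated) session: channels × samples in tesla."""

    data: np.ndarray
    sample_rate: float
    events: np.ndarray  # sample indices
    array: SensorArray
    subject_id: str
    seed: int
    protocol: ProtocolSpec | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.events = np.asarray(self.events, int)
        if np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("session data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, **kw) -> "RawSession":
        out = RawSession(
            self.data.copy(), self.sample_rate, self.events.copy(),
            self.array, self.subject_id, self.seed, self.protocol,
        )
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def _session_rng(seed: int, subject_id: str, protocol_name: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed), zlib.crc32(subject_id.encode()), zlib.crc32(protocol_name.encode())]
    )


def sef_moment_timecourse(times: np.ndarray, peaks=DEFAULT_SEF_PEAKS) -> np.ndarray:
    """Sum of Gaussian-windowed lobes, one per SEF peak [A·m]."""
    times = np.asarray(times, float)
    out = np.zeros_like(times)
    for p in peaks:
        if p.width <= 0:
            raise ValueError("peak width must be positive")
        out += p.amplitude * np.exp(-0.5 * ((times - p.latency) / p.width) ** 2)
    return out


def _narrowband_carrier(n: int, fs: float, f0: float, bw: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS random-phase carrier of bandwidth ``bw`` around ``f0``."""
    white = rng.standard_normal(n)
    sos = signal.butter(2, [f0 - bw / 2.0, f0 + bw / 2.0], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / np.sqrt(np.mean(x**2))


def _modulation_envelope(n: int, fs: float, events_s: np.ndarray,
                         src: OscillatorySource, smooth: float = 0.1) -> np.ndarray:
    """Amplitude envelope: baseline, scaled by (1−depth) in each event's ERD
    window and (1+gain) in each ERS window; transitions smoothed over
    ``smooth`` seconds.  Raises if successive events' windows overlap."""
    windows = []
    if src.erd_depth > 0:
        windows.append(src.erd_window)
    if src.ers_gain > 0:
        windows.append(src.ers_window)
    if windows and len(events_s) > 1:
        span = (min(w[0] for w in windows), max(w[1] for w in windows))
        min_isi = np.min(np.diff(events_s))
        if span[1] - span[0] > 0 and span[1] + smooth / 2 - span[0] > min_isi:
            raise ValueError(
                "ERD/ERS windows of successive events overlap: ISI too short "
                "for the modulated scenario"
            )
    env = np.ones(n)
    for ev in events_s:
        if src.erd_depth > 0:
            i0, i1 = (int(round((ev + t) * fs)) for t in src.erd_window)
            env[max(i0, 0):min(i1, n)] *= 1.0 - src.erd_depth
        if src.ers_gain > 0:
            i0, i1 = (int(round((ev + t) * fs)) for t in src.ers_window)
            env[max(i0, 0):min(i1, n)] *= 1.0 + src.ers_gain
    m = max(int(round(smooth * fs)), 1)
    kernel = np.hanning(m + 2)[1:-1]
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def oscillatory_moment(times: np.ndarray, events_s: np.ndarray,
                       src: OscillatorySource, rng: np.random.Generator,
                       modulate: bool = True) -> np.ndarray:
    """Narrowband source moment [A·m]: random-phase carrier × ERD/ERS envelope."""
    n = len(times)
    fs = 1.0 / (times[1] - times[0])
    carrier = _narrowband_carrier(n, fs, src.center_freq, src.bandwidth, rng)
    if modulate:
        env = _modulation_envelope(n, fs, np.asarray(events_s, float), src)
    else:
        env = np.ones(n)
    return src.baseline_amplitude * carrier * env


def _filtered_walk(n: int, fs: float, bandwidth: float,
                   rng: np.random.Generator, n_comp: int) -> np.ndarray:
    """(n_comp, n) low-pass-filtered Gaussian random-walk components, each
    normalized to unit RMS."""
    steps = rng.standard_normal((n_comp, n))
    walk = np.cumsum(steps, axis=1)
    sos = signal.butter(4, bandwidth, btype="lowpass", fs=fs, output="sos")
    walk = signal.sosfiltfilt(sos, walk, axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(walk**2, axis=1, keepdims=True))
    return walk / rms


def interference_timecourse(n_samples: int, spec: NoiseSpec, seed,
                            sample_rate: float = 1000.0):
    """Homogeneous ambient field b(t) plus a projection rule.

    Returns ``(b, project)`` where ``b`` is 3 × n_samples [T] (each cardinal
    component a low-pass-filtered random walk at the stated RMS) and
    ``project(positions, orientations)`` yields per-channel interference:
    ``o·b(t)`` plus ``gradient_fraction`` times a fixed first-order
    spatial-gradient term, so that homogeneous-field correction is
    imperfect whenever ``gradient_fraction > 0``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = spec.interference_rms * _filtered_walk(
        n_samples, sample_rate, spec.interference_bandwidth, rng, 3
    )
    g_time = _filtered_walk(n_samples, sample_rate, spec.interference_bandwidth, rng, 1)[0]
    # fixed symmetric traceless gradient tensor (source-free field), unit scale
    A = rng.standard_normal((3, 3))
    G0 = 0.5 * (A + A.T)
    G0 -= np.eye(3) * np.trace(G0) / 3.0
    G0 /= np.linalg.norm(G0)

    def project(positions: np.ndarray, orientations: np.ndarray) -> np.ndarray:
        homog = orientations @ b
        # per-channel static gradient gain o·(G0 p), normalized to unit RMS
        # at a 10 cm reference distance so the scalp-level gradient term has
        # RMS ≈ gradient_fraction × interference_rms
        gains = np.einsum("ij,jk,ik->i", orientations, G0, positions) / 0.1
        grad = spec.gradient_fraction * spec.interference_rms * np.outer(gains, g_time)
        return homog + grad

    return b, project


def generate_session(
    protocol: ProtocolSpec,
    scenario: SourceScenario,
    noise: NoiseSpec,
    array: SensorArray,
    head: SphereHeadModel,
    subject_id: str = "sub-01",
    seed: int = 0,
    grid: SourceGrid | None = None,
    lead: LeadField | None = None,
) -> RawSession:
    """Simulate one raw session for one subject under one protocol.

    Channel data = lead-field-projected source moments + ambient
    interference + line sinusoids + white sensor noise + a broadband
    artifact burst around each event.  Per-subject latency and amplitude
    jitter come from a subject-seeded stream, so the same ``(seed,
    subject_id)`` always yields byte-identical data.
    """
    fs = protocol.sample_rate
    rng = _session_rng(seed, subject_id, protocol.name)
    subj_rng = np.random.default_rng([int(seed), zlib.crc32(subject_id.encode())])
    lat_offset = subj_rng.normal(0.0, scenario.latency_jitter_sd)
    amp_factor = max(1.0 + subj_rng.normal(0.0, scenario.amplitude_jitter_sd), 0.1)

    if grid is None:
        grid = build_default_grid(head)
    if lead is None:
        lead = compute_lead_field(array, grid, head)

    isis = rng.uniform(*protocol.isi_range, size=protocol.n_events)
    pre_pad = max(-protocol.epoch_window[0] + 0.5, 1.0)
    event_times = pre_pad + np.cumsum(isis) - isis[0] + 0.0
    post_pad = protocol.epoch_window[1] + 0.5
    n = int(round((event_times[-1] + post_pad) * fs))
    events = np.round(event_times * fs).astype(int)
    times = np.arange(n) / fs

    n_ch = array.n_channels
    scalp_idx = np.where(~array.is_reference)[0]
    data = np.zeros((n_ch, n))

    # --- SEF source -------------------------------------------------------
    peaks = tuple(
        SefPeak(p.latency + lat_offset, p.width, p.amplitude * amp_factor)
        for p in scenario.sef_peaks
    )
    tmpl_t = np.arange(int(round(-0.05 * fs)), int(round(0.25 * fs))) / fs
    tmpl = sef_moment_timecourse(tmpl_t, peaks)
    sef_moment = np.zeros(n)
    off = int(round(-0.05 * fs))
    for ev in events:
        lo, hi = ev + off, ev + off + len(tmpl)
        s0, s1 = max(lo, 0), min(hi, n)
        sef_moment[s0:s1] += tmpl[s0 - lo:s1 - lo]
    data[scalp_idx] += np.outer(
        scenario.sef_polarity * lead.matrix[:, scenario.sef_vertex], sef_moment
    )

    # --- oscillatory sources ---------------------------------------------
    for src in scenario.oscillatory_sources:
        moment = oscillatory_moment(
            times, events / fs, src, rng, modulate=protocol.modulate_rhythms
        ) * amp_factor
        data[scalp_idx] += np.outer(lead.matrix[:, src.vertex], moment)

    # --- ambient interference --------------------------------------------
    if noise.interference_rms > 0:
        _, project = interference_timecourse(n, noise, rng, fs)
        data += project(array.positions, array.orientations)

    # --- line noise (homogeneous AC fields) -------------------------------
    for f, a in zip(noise.line_freqs, noise.line_amplitudes):
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        gains = array.orientations @ direction
        data += a * np.outer(gains, np.sin(2 * np.pi * f * times + phase))

    # --- sensor noise -----------------------------------------------------
    sigma = noise.sensor_noise_rms(fs)
    if sigma > 0:
        data += sigma * rng.standard_normal((n_ch, n))

    # --- stimulus artifact ------------------------------------------------
    a_rms = noise.artifact_rms(fs)
    half = int(round(noise.artifact_duration * fs / 2.0))
    if a_rms > 0 and half > 0:
        for ev in events:
            s0, s1 = max(ev - half, 0), min(ev + half, n)
            data[:, s0:s1] += a_rms * rng.standard_normal((n_ch, s1 - s0))

    if events[-1] + int(round(protocol.epoch_window[1] * fs)) >= n:
        raise ValueError("session too short for the last epoch window")
    return RawSession(data, fs, events, array, subject_id, int(seed), protocol)


def default_subject_ids(n_subjects: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n_subjects)]


def generate_cohort(
    n_subjects: int = 12,
    scenario: SourceScenario | None = None,
    noise: NoiseSpec | None = None,
    head: SphereHeadModel | None = None,
    array: SensorArray | None = None,
    seed: int = 0,
    protocols: tuple[ProtocolSpec, ...] = (SHORT_MNS, LONG_MNS),
) -> list[dict[str, RawSession]]:
    """One short-MNS and one long-MNS session per subject (default 12)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for paired statistics")
    scenario = scenario or SourceScenario()
    noise = noise or NoiseSpec()
    head = head or SphereHeadModel()
    array = array or build_default_array(head)
    grid = build_default_grid(head)
    lead = compute_lead_field(array, grid, head)
    cohort = []
    for sid in default_subject_ids(n_subjects):
        sessions = {
            proto.name: generate_session(
                proto, scenario, noise, array, head, sid, seed,
                grid=grid, lead=lead,
            )
            for proto in protocols
        }
        cohort.append(sessions)
    return cohort
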