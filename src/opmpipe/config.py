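"""Run configuration: YAML-serializable settings for the full pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from opmpipe.simulate import (
    LONG_MNS,
    SHORT_MNS,
    NoiseSpec,
    ProtocolSpec,
    SourceScenario,
)

SCHEMA_ID = "opmpipe-config-1"


@dataclass(frozen=True)
class PreprocessingConfig:
    hfc: bool = True
    compare_hfc: bool = False  # also run the HFC-omitted arm
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    band: tuple[float, float] = (3.0, 150.0)
    bad_threshold: float = 2.0
    ptp_threshold: float = 5e-12  # epoch rejection, any-channel peak-to-peak [T]


@dataclass(frozen=True)
class InverseConfig:
    snr: float = 3.0  # λ² = 1/snr²
    loading: float = 0.1  # diagonal loading of the noise covariance


@dataclass(frozen=True)
class RunConfig:
    schema: str = SCHEMA_ID
    seed: int = 0
    n_subjects: int = 12
    output_dir: str = "results"
    short_mns: ProtocolSpec = SHORT_MNS
    long_mns: ProtocolSpec = LONG_MNS
    scenario: SourceScenario = field(default_factory=SourceScenario)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    representative_sensor: str = "C3"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _override(obj, overrides: dict):
    if not overrides:
        return obj
    kw = {}
    for k, v in overrides.items():
        cur = getattr(obj, k)
        if isinstance(cur, tuple) and isinstance(v, list):
            v = tuple(v)
        kw[k] = v
    return replace(obj, **kw)


def load_config(path) -> RunConfig:
    """Load a YAML config; unspecified keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if raw.get("schema", SCHEMA_ID) != SCHEMA_ID:
        raise ValueError(f"unsupported config schema {raw.get('schema')!r}")
    cfg = RunConfig()
    simple = {k: raw[k] for k in
              ("seed", "n_subjects", "output_dir", "representative_sensor")
              if k in raw}
    cfg = replace(cfg, **simple)
    cfg = replace(
        cfg,
        short_mns=_override(cfg.short_mns, raw.get("short_mns", {})),
        long_mns=_override(cfg.long_mns, raw.get("long_mns", {})),
        noise=_override(cfg.noise, raw.get("noise", {})),
        preprocessing=_override(cfg.preprocessing, raw.get("preprocessing", {})),
        inverse=_override(cfg.inverse, raw.get("inverse", {})),
    )
    scen = raw.get("scenario", {})
    scalar_keys = {k: v for k, v in scen.items()
                   if k in ("sef_vertex", "latency_jitter_sd", "amplitude_jitter_sd")}
    cfg = replace(cfg, scenario=_override(cfg.scenario, scalar_keys))
    return cfg


DEFAULT_CONFIG_YAML = """\
# Default pipeline configuration (schema opmpipe-config-1).
# Values marked [generator default] are simulation choices not fixed by any
# measurement protocol; everything else mirrors the study parameters.
schema: opmpipe-config-1
seed: 0
n_subjects: 12                 # cohort size
output_dir: results
representative_sensor: C3

short_mns:                     # evoked (SEF) protocol
  n_events: 300                # stimulations
  isi_range: [1.0, 1.4]        # s
long_mns:                      # oscillatory protocol
  n_events: 80
  isi_range: [5.6, 7.6]

scenario:
  sef_vertex: 67               # postcentral-gyrus vertex [generator default]
  latency_jitter_sd: 0.001     # per-subject, s [generator default]
  amplitude_jitter_sd: 0.2     # per-subject, fractional [generator default]

noise:
  sensor_noise_density: 1.0e-14   # T/√Hz [generator default, within <20 fT/√Hz]
  interference_rms: 3.0e-11       # T per cardinal axis [generator default]
  interference_bandwidth: 4.0     # Hz [generator default]
  gradient_fraction: 0.05         # first-order remainder [generator default]
  line_freqs: [60.0, 120.0, 180.0]
  line_amplitudes: [1.0e-12, 5.0e-13, 3.0e-13]   # [generator default]
  artifact_duration: 0.010        # s [generator default]

preprocessing:
  hfc: true
  compare_hfc: false           # also run the HFC-omitted arm
  notch_freqs: [60.0, 120.0, 180.0]
  band: [3.0, 150.0]
  bad_threshold: 2.0           # z-score on 120–145 Hz spectral amplitude
  ptp_threshold: 5.0e-12       # T, epoch rejection [generator default]

inverse:
  snr: 3.0                     # λ² = 1/9 [generator default]
  loading: 0.1                 # covariance diagonal loading [generator default]
"""


def write_default_config(path) -> None:
    Path(path).write_text(DEFAULT_CONFIG_YAML)
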