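"""Run configuration and deterministic per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic stage seed from the global seed and a stage label.

    Stable across processes (CRC32-based, not Python's salted hash); the
    result fits in 31 bits.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Fully serializable configuration of the end-to-end demo pipeline."""

    seed: int = 0
    # stimulus
    duration: float = 60.0
    fmin: float = 2_000.0
    fmax: float = 90_000.0
    speed_cutoff: float = 10.0
    n_channels: int = 45
    spectrogram_dt: float = 5e-3
    ridge_width: float = 0.125
    trajectory_dt: float = 5e-4
    # encoder population
    n_poisson: int = 4
    poisson_rates: tuple = (2.0, 40.0)
    n_lnp: int = 4
    lnp_gain: float = 60.0
    lnp_baseline: float = 2.0
    lnp_bandwidth: float = 0.5
    lnp_latency: float = 0.015
    # decoder
    code_kinds: tuple = ("temporal", "rate")
    k: int = 100
    window_length: float = 0.100
    stride: float = 0.010
    eval_stride: float = 0.050
    lags: tuple = (-0.010, 0.0)
    # null calibration
    calib_trains: int = 20
    calib_percentile: float = 95.0
    # outputs
    out_dir: str = "ncr_demo_out"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("poisson_rates", "code_kinds", "lags"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seed(self, label: str) -> int:
        return derive_seed(self.seed, label)
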