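"""YAML run configuration for the end-to-end benchmark.

The configuration is a nested dataclass tree that round-trips through YAML
bit-exactly; unknown keys anywhere in the file are rejected so that typos
surface immediately.
"""

from __future__ import annotations

import dataclasses
import typing
from dataclasses import dataclass, field

import yaml


def _from_dict(cls, raw: dict, path: str = ""):
    """Strict dataclass construction: every key must match a field."""
    if not isinstance(raw, dict):
        raise ValueError(f"expected a mapping at {path or 'top level'}")
    hints = typing.get_type_hints(cls)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = raw.keys() - fields
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        ftype = hints.get(name)
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            kwargs[name] = _from_dict(ftype, value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _to_dict(obj):
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = _to_dict(v)
        elif isinstance(v, tuple):
            out[f.name] = [list(x) if isinstance(x, tuple) else x for x in v]
        else:
            out[f.name] = v
    return out


@dataclass
class PhantomConfig:
    grid_shape: tuple = (96, 192, 256)  # (nz, ny, nx)
    voxel_size: tuple = (1.5, 1.5, 1.5)  # mm
    texture_scale: float = 1.0
    prior_noise_std_hu: float = 10.0


@dataclass
class ApplicatorConfig:
    channel_polyline: tuple = ((-60.0, 0.0, 0.0), (30.0, 0.0, 0.0))
    radius_mm: float = 3.0
    hu_value: float = 2500.0


@dataclass
class GeometryConfig:
    source_axis_distance: float = 1000.0
    source_detector_distance: float = 1500.0
    detector_pixels: tuple = (384, 192)  # (nu, nv)
    pixel_pitch: float = 1.552
    n_views: int = 360
    I0: float = 1.0


@dataclass
class ScatterConfig:
    spr: float = 0.06
    blur_sigma_mm: float = 150.0
    plateau_frac: float = 0.9
    photons_per_I0: float = 1.0e6


@dataclass
class CorrectionSettings:
    mu_w: float = 0.020
    percentile_rule: float = 0.90
    object_mask_rule: float = 0.90
    softcut_eps: float = 0.05
    segmentation_source: str = "prior"
    filter_name: str = "hann"
    eps_floor: float = 1.0e-4
    mask_percentile: float = 0.80
    filtration_sigma_mm: float = 12.0
    applicator_threshold_hu: float = 1000.0


@dataclass
class DoseConfig:
    n_dwells: int = 10
    step_mm: float = 5.0
    dwell_time_s: float = 30.0
    source_strength: float = 7.5  # Gy*mm^2/s
    grid_voxel_mm: tuple = (1.0, 2.5, 2.5)  # (dz, dy, dx)
    grid_extent_mm: tuple = ((-85.0, 55.0), (-80.0, 80.0), (-95.0, 95.0))
    gamma_criteria: tuple = ((1.0, 1.0), (2.0, 1.0), (2.0, 2.0))  # (dd %, dta mm)
    gamma_thresholds_gy: tuple = (3.0, 6.0, 9.0, 12.0)


@dataclass
class RunConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    applicator: ApplicatorConfig = field(default_factory=ApplicatorConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    scatter: ScatterConfig = field(default_factory=ScatterConfig)
    correction: CorrectionSettings = field(default_factory=CorrectionSettings)
    dose: DoseConfig = field(default_factory=DoseConfig)
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return _from_dict(cls, raw)

    def to_dict(self) -> dict:
        return _to_dict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
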