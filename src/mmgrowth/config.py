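"""Pipeline configuration: schema-validated YAML round-tripping.

The configuration mirrors the dataclasses of the library modules.  Validation
is strict: unknown keys are rejected and type mismatches are reported with
dotted field paths, so a typo in a YAML document fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, get_args, get_origin

import yaml

from .measure import MeasurementConfig

__all__ = [
    "ConfigError",
    "SceneConfig",
    "GrowthLawConfig",
    "TransportConfig",
    "MechanicsConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
    "dataclass_from_mapping",
    "dataclass_to_mapping",
]


class ConfigError(ValueError):
    """A configuration document failed validation."""


def dataclass_from_mapping(cls, data: dict, path: str = "") -> Any:
    """Instantiate a (possibly nested) dataclass from a plain mapping.

    Missing fields take their defaults; unknown keys and type mismatches
    raise :class:`ConfigError` naming the offending dotted field path.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = f"{path}." if path else ""
        raise ConfigError(f"unknown key(s): {', '.join(sorted(where + k for k in unknown))}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        here = f"{path}.{name}" if path else name
        kwargs[name] = _coerce(f.type, value, here)
    try:
        return cls(**kwargs)
    except ValueError as err:
        raise ConfigError(f"{path or cls.__name__}: {err}") from None


def _coerce(ftype, value, path: str):
    if isinstance(ftype, str):  # from __future__ annotations
        ftype = eval(ftype, _TYPE_NAMESPACE)  # noqa: S307 - controlled namespace
    origin = get_origin(ftype)
    if dataclasses.is_dataclass(ftype):
        return dataclass_from_mapping(ftype, value, path)
    if ftype is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        return float(value)
    if ftype is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        return value
    if ftype is bool:
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
        return value
    if ftype is str:
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
        return value
    if origin in (list, tuple):
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{path}: expected a sequence, got {value!r}")
        args = get_args(ftype)
        elem = args[0] if args else float
        seq = [_coerce(elem, v, f"{path}[{i}]") for i, v in enumerate(value)]
        return tuple(seq) if origin is tuple else seq
    return value


def dataclass_to_mapping(obj) -> dict:
    """Plain-YAML-serializable dict of a nested dataclass."""
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = dataclass_to_mapping(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


@dataclass
class SceneConfig:
    """Synthetic-scene stage: geometry, optics, noise and colony layout."""

    n_replicates: int = 3
    n_cells: int = 10
    channel_width: float = 0.9     # μm
    channel_height: float = 1.15   # μm
    mean_length: float = 2.12      # μm
    mean_width: float = 0.78       # μm
    length_sd: float = 0.12
    width_sd: float = 0.02
    gap_um: float = 0.35
    pixel_size: float = 0.065      # μm/px
    psf_sigma: float = 0.10        # μm
    background_level: float = 100.0
    peak_signal: float = 400.0
    read_noise_sd: float = 2.0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_cells < 1:
            raise ValueError("n_replicates and n_cells must be ≥ 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class GrowthLawConfig:
    """Growth-law stage: generator truth and fit input."""

    v_i: float = 0.79              # μm³
    cd_period: float = 103.0       # min
    n_samples: int = 30
    td_min: float = 100.0          # min, lower end of sampled doubling times
    td_max: float = 220.0
    noise_cv: float = 0.03


@dataclass
class TransportConfig:
    """Transport stage: parameters of the three channel models."""

    channel_length: float = 50.0   # μm
    cell_radius: float = 0.4       # μm
    diffusion_nutrient: float = 700.0   # μm²/s (glucose)
    k_abs: float = 1.0             # μm/s (parametric; no measured value exists)
    imax: float = 2e5              # molecules/(cell·s)
    mean_cell_length: float = 2.12  # μm
    c0_mM: float = 22.0            # glucose at the entrance
    diffusion_bsa: float = 70.0    # μm²/s
    water_flux: float = 7e-6       # kg/(m² s)
    water_density: float = 1000.0  # kg/m³
    td_min_minutes: float = 23.0   # min, saturating growth
    td_liquid_minutes: float = 25.0
    n_profile_points: int = 200


@dataclass
class MechanicsConfig:
    youngs_modulus_MPa_low: float = 50.0
    youngs_modulus_MPa_high: float = 150.0
    envelope_thickness_nm: float = 4.0
    cell_diameter_um: float = 0.8
    axial_strain: float = 0.25


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; round-trips losslessly via YAML."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    growth_law: GrowthLawConfig = field(default_factory=GrowthLawConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    rng_seed: int = 0
    log_level: str = "INFO"


def load_config(source) -> PipelineConfig:
    """Validate a YAML document (path or mapping) into a PipelineConfig."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    return dataclass_from_mapping(PipelineConfig, data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclass_to_mapping(config), fh, sort_keys=False)


_TYPE_NAMESPACE: dict[str, Any] = {
    "float": float,
    "int": int,
    "bool": bool,
    "str": str,
    "list": list,
    "tuple": tuple,
    "MeasurementConfig": MeasurementConfig,
    "SceneConfig": SceneConfig,
    "GrowthLawConfig": GrowthLawConfig,
    "TransportConfig": TransportConfig,
    "MechanicsConfig": MechanicsConfig,
    "PipelineConfig": PipelineConfig,
}
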