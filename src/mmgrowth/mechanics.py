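"""Elastic estimate of the growth-opposing force on a compressed cell.

A rod-shaped cell jammed in a dead-end channel behaves, upon pressure
release, like a compressed elastic rod.  Treating the load-bearing envelope
as a thin cylindrical shell of diameter ``d`` and wall thickness ``t`` with
Young's modulus ``E``, the axial force at uniform compressive strain ``ε``
is

    F = E · ε · (π d t),

π·d·t being the wall cross-sectional area.  With E = 50–150 MPa, t = 4 nm,
d = 0.8 μm and ε = 0.25 this gives 0.13–0.38 μN — an estimate of the stall
force for envelope synthesis.  The module also provides the linear friction
model: when wall friction opposes growth, the excess doubling time scales
with the opposing force and hence linearly with channel length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .growthlaw import LinearFit, pearson_and_line

__all__ = [
    "ShellMechanics",
    "FrictionModel",
    "stall_force",
    "friction_doubling_model",
    "strain_from_release",
]


@dataclass(frozen=True)
class ShellMechanics:
    """Thin-shell parameters: E in MPa, thickness t in nm, diameter d in μm, strain ε."""

    youngs_modulus_MPa: float
    envelope_thickness_nm: float = 4.0
    cell_diameter_um: float = 0.8
    axial_strain: float = 0.25

    def __post_init__(self) -> None:
        if min(self.youngs_modulus_MPa, self.envelope_thickness_nm, self.cell_diameter_um) <= 0:
            raise ValueError("modulus, thickness and diameter must be positive")
        if not (0 <= self.axial_strain < 1):
            raise ValueError("axial strain must lie in [0, 1)")


@dataclass
class FrictionModel:
    base_doubling_time_min: float  # extrapolated T_d at L = 0
    slope_min_per_um: float
    fit: LinearFit


def stall_force(shell: ShellMechanics) -> float:
    """Axial force F = E ε π d t carried by the envelope wall, in μN.

    Unit bookkeeping: MPa·μm·nm = 1e6 N/m² · 1e-6 m · 1e-9 m = 1e-9 N = 1e-3 μN.
    """
    return (
        shell.youngs_modulus_MPa
        * shell.axial_strain
        * math.pi
        * shell.cell_diameter_um
        * shell.envelope_thickness_nm
        * 1e-3
    )


def friction_doubling_model(lengths_um, doubling_times_min) -> FrictionModel:
    """Straight-line fit of doubling time on channel length.

    Under the friction hypothesis the force opposing growth, and with it the
    excess doubling time T_d − T_d,liquid, grows linearly with channel length;
    the intercept extrapolates to the friction-free doubling time.
    """
    fit = pearson_and_line(np.asarray(lengths_um, float), np.asarray(doubling_times_min, float))
    return FrictionModel(
        base_doubling_time_min=fit.intercept,
        slope_min_per_um=fit.slope,
        fit=fit,
    )


def strain_from_release(length_before_um: float, length_after_um: float) -> float:
    """Compressive strain ε = (ℓ_after − ℓ_before)/ℓ_after from a pressure-release event.

    The strain is referred to the relaxed (post-release) length, so a cell
    that elongates by a third on release was compressed by ε = 0.25.
    """
    if length_before_um <= 0 or length_after_um <= 0:
        raise ValueError("lengths must be positive")
    if length_after_um < length_before_um:
        raise ValueError("relaxed length must not be shorter than the compressed length")
    return (length_after_um - length_before_um) / length_after_um
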