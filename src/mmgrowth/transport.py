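"""1D mass-transport models for dead-end mother-machine channels.

Three steady-state models are implemented in closed form, each validated
against a finite-difference oracle:

* **Nutrient screening** — a single growth-limiting compound diffusing into a
  channel uniformly filled with absorbing cells (first-order uptake, far from
  saturation).  The concentration decays over a screening length ``λ`` and the
  profile is a ratio of hyperbolic cosines.
* **Kinetically limited depletion** — uptake saturated at a fixed rate per
  cell; the concentration drop grows quadratically with channel length.
* **Permeation-driven accumulation** — water permeating into the PDMS walls of
  an *empty* channel drags non-permeating solutes (e.g. BSA) toward the dead
  end; the profile is Gaussian in the distance from the dead end with an
  accumulation length ``σ`` set by the channel cross-section only.

Internal unit system: micrometres, seconds, molecules/μm³.  Millimolar
concentrations, kg-based water fluxes and densities are converted at the
interface (see :func:`concentration_units`).  The coordinate ``x`` runs from 0
at the channel entrance to ``L`` at the dead end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "ChannelGeometry",
    "AbsorbingColonyParams",
    "GrowthKinetics",
    "KineticUptakeParams",
    "PermeationParams",
    "TransportResult",
    "KineticDepletionResult",
    "screening_length",
    "nutrient_profile",
    "doubling_time_profile",
    "mother_cell_doubling_time",
    "kinetic_depletion",
    "accumulation_length",
    "accumulation_profile",
    "concentration_units",
    "solve_transport_numerically",
]

#: molecules per μm³ in a 1 mM solution: 1e-3 mol/L * N_A / 1e15 μm³/L
MOLECULES_PER_UM3_PER_MM = 6.02214076e23 * 1e-3 / 1e15  # = 6.02214076e5


@dataclass(frozen=True)
class ChannelGeometry:
    """Dead-end channel: width ``W`` and height ``H`` (cross-section), length ``L``, all μm."""

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.length > 0):
            raise ValueError("channel W, H, L must all be positive")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area W·H in μm²."""
        return self.width * self.height


@dataclass(frozen=True)
class AbsorbingColonyParams:
    """Continuum colony of absorbing cells.

    ``k_abs`` is the uptake coefficient per unit cell surface area (μm/s);
    ``cell_radius`` the rod radius R_c (μm); ``diffusion`` in μm²/s;
    ``c0`` the entrance concentration (any fixed unit — profiles scale with it).
    """

    cell_radius: float
    diffusion: float
    k_abs: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        if self.diffusion <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.k_abs < 0:
            raise ValueError("k_abs must be non-negative")
        if self.cell_radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.c0 <= 0:
            raise ValueError("entrance concentration must be positive")


@dataclass(frozen=True)
class GrowthKinetics:
    """Michaelis–Menten coupling of doubling time to nutrient concentration.

    ``td_min`` is the doubling time when the compound is saturating,
    ``td_liquid`` the doubling time in dilute liquid culture at entrance
    concentration ``c0``; the saturation constant follows from
    ``td_liquid = td_min * (1 + K/c0)``.
    """

    td_min: float
    td_liquid: float

    def __post_init__(self) -> None:
        if self.td_min <= 0:
            raise ValueError("td_min must be positive")
        if self.td_liquid < self.td_min:
            raise ValueError("td_liquid must be >= td_min")

    def saturation_constant(self, c0: float) -> float:
        """K such that td_liquid = td_min (1 + K/c0)."""
        return c0 * (self.td_liquid / self.td_min - 1.0)


@dataclass(frozen=True)
class KineticUptakeParams:
    """Saturated (kinetically limited) uptake: I_max molecules/(cell·s)."""

    imax: float
    mean_cell_length: float
    diffusion: float
    c0_mM: float

    def __post_init__(self) -> None:
        if min(self.imax, self.mean_cell_length, self.diffusion, self.c0_mM) <= 0:
            raise ValueError("all kinetic-uptake parameters must be positive")


@dataclass(frozen=True)
class PermeationParams:
    """Water permeation into PDMS walls concentrating a non-permeating solute.

    ``water_flux`` J in kg/(m²·s), ``water_density`` ρ in kg/m³,
    ``diffusion`` of the solute in μm²/s, ``c0`` entrance concentration.
    """

    water_flux: float
    diffusion: float
    water_density: float = 1000.0
    c0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.water_flux, self.diffusion, self.water_density, self.c0) <= 0:
            raise ValueError("all permeation parameters must be positive")

    @property
    def permeation_velocity(self) -> float:
        """J/ρ converted to μm/s."""
        return self.water_flux / self.water_density * 1e6


@dataclass
class TransportResult:
    """A 1D profile along the channel with its characteristic length."""

    x: np.ndarray
    values: np.ndarray
    characteristic_length: float
    model: str
    meta: dict = field(default_factory=dict)


@dataclass
class KineticDepletionResult:
    delta_c_mM: float
    c_end_mM: float
    valid: bool  # False when the predicted drop exceeds the entrance concentration


# ---------------------------------------------------------------------------
# nutrient screening (absorption-limited)
# ---------------------------------------------------------------------------

def _free_cross_section(geom: ChannelGeometry, cell_radius: float) -> float:
    free = geom.cross_section - np.pi * cell_radius**2
    if free <= 0:
        raise ValueError(
            f"cells of radius {cell_radius} μm do not fit the "
            f"{geom.width}×{geom.height} μm cross-section"
        )
    return free


def screening_length(geom: ChannelGeometry, params: AbsorbingColonyParams) -> float:
    """Nutrient screening length λ = sqrt((WH − πR_c²) D / (2π R_c k_abs)), μm.

    ``k_abs = 0`` yields an infinite screening length (no absorption).
    """
    free = _free_cross_section(geom, params.cell_radius)
    if params.k_abs == 0:
        return np.inf
    return float(np.sqrt(free * params.diffusion / (2 * np.pi * params.cell_radius * params.k_abs)))


def nutrient_profile(
    geom: ChannelGeometry, params: AbsorbingColonyParams, x: np.ndarray
) -> TransportResult:
    """c(x) = c0 cosh((x−L)/λ) / cosh(L/λ): entrance Dirichlet, dead-end zero flux."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > geom.length):
        raise ValueError("positions must lie within [0, L]")
    lam = screening_length(geom, params)
    if np.isinf(lam):
        c = np.full_like(x, params.c0)
    else:
        # cosh ratio written via exponentials for stability at L >> λ
        c = params.c0 * _cosh_ratio(x - geom.length, geom.length, lam)
    return TransportResult(x, c, lam, "screening", {"c0": params.c0})


def _cosh_ratio(num_arg: np.ndarray, L: float, lam: float) -> np.ndarray:
    """cosh(num_arg/λ)/cosh(L/λ), overflow-safe for large L/λ."""
    a = np.asarray(num_arg, dtype=float) / lam
    b = L / lam
    # cosh(a)/cosh(b) = [exp(a-b) + exp(-a-b)] / [1 + exp(-2b)]
    return (np.exp(np.abs(a) - b) + np.exp(-np.abs(a) - b)) / (1.0 + np.exp(-2.0 * b))


def doubling_time_profile(
    geom: ChannelGeometry,
    params: AbsorbingColonyParams,
    kinetics: GrowthKinetics,
    x: np.ndarray,
) -> TransportResult:
    """T_d(x) = td_min + (td_liquid − td_min) cosh(L/λ) / cosh((x−L)/λ), minutes."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > geom.length):
        raise ValueError("positions must lie within [0, L]")
    lam = screening_length(geom, params)
    if np.isinf(lam):
        td = np.full_like(x, kinetics.td_liquid)
    else:
        td = kinetics.td_min + (kinetics.td_liquid - kinetics.td_min) / _cosh_ratio(
            x - geom.length, geom.length, lam
        )
    return TransportResult(x, td, lam, "doubling_time", {"td_liquid": kinetics.td_liquid})


def mother_cell_doubling_time(
    geom: ChannelGeometry, params: AbsorbingColonyParams, kinetics: GrowthKinetics
) -> float:
    """Doubling time of the mother cell at the dead end (x ≈ L), minutes.

    T_d = td_min + (td_liquid − td_min)·cosh(L/λ): equals td_liquid for L ≪ λ
    and grows exponentially ∝ exp(L/λ) for L ≫ λ.
    """
    lam = screening_length(geom, params)
    if np.isinf(lam):
        return kinetics.td_liquid
    return float(
        kinetics.td_min + (kinetics.td_liquid - kinetics.td_min) * np.cosh(geom.length / lam)
    )


# ---------------------------------------------------------------------------
# kinetically limited depletion
# ---------------------------------------------------------------------------

def kinetic_depletion(
    geom: ChannelGeometry, params: KineticUptakeParams, cell_radius: float
) -> KineticDepletionResult:
    """Concentration drop Δc = L² I_max / (2 (WH − πR_c²) L_c D) over a full channel.

    The channel is assumed completely filled with cells of mean length ``L_c``
    (one uptake site per cell length along the channel).  Returned in mM; the
    result is flagged invalid when the drop would exceed the entrance
    concentration (the constant-rate model then no longer applies).
    """
    free = _free_cross_section(geom, cell_radius)
    delta_molec = geom.length**2 * params.imax / (
        2.0 * free * params.mean_cell_length * params.diffusion
    )  # molecules/μm³
    delta_mM = concentration_units(delta_molec, "molecules/um3", "mM")
    return KineticDepletionResult(
        delta_c_mM=delta_mM,
        c_end_mM=params.c0_mM - delta_mM,
        valid=delta_mM < params.c0_mM,
    )


# ---------------------------------------------------------------------------
# permeation-driven accumulation
# ---------------------------------------------------------------------------

def accumulation_length(geom: ChannelGeometry, params: PermeationParams) -> float:
    """Accumulation length σ = sqrt((ρ D / J) · WH/(2H+W)), μm.

    ``2H + W`` is the permeating wall perimeter (two side walls and the top;
    the floor is glass).  σ depends on the cross-section only, not on L.
    """
    wetted = 2.0 * geom.height + geom.width  # μm of PDMS perimeter
    ratio = params.diffusion / params.permeation_velocity  # μm
    return float(np.sqrt(ratio * geom.cross_section / wetted))


def accumulation_profile(
    geom: ChannelGeometry, params: PermeationParams, x: np.ndarray
) -> TransportResult:
    """c(x) = c0 exp(L²/2σ²) exp(−(L−x)²/2σ²) for an empty channel at steady state."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > geom.length):
        raise ValueError("positions must lie within [0, L]")
    sigma = accumulation_length(geom, params)
    L = geom.length
    c = params.c0 * np.exp((L**2 - (L - x) ** 2) / (2.0 * sigma**2))
    return TransportResult(x, c, sigma, "accumulation", {"c0": params.c0})


def dead_end_fold_increase(geom: ChannelGeometry, params: PermeationParams) -> float:
    """Fold increase of the solute at the dead end: exp(L²/(2σ²))."""
    sigma = accumulation_length(geom, params)
    return float(np.exp(geom.length**2 / (2.0 * sigma**2)))


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

_UNIT_ALIASES = {
    "mm": "mM",
    "mM": "mM",
    "molecules/um3": "molecules/um3",
    "molecules/μm3": "molecules/um3",
    "molecules/um^3": "molecules/um3",
}


def concentration_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between mM and molecules/μm³ (1 mM = 6.02214076e5 molecules/μm³)."""
    try:
        f = _UNIT_ALIASES[from_unit if from_unit == "mM" else from_unit.lower()]
        t = _UNIT_ALIASES[to_unit if to_unit == "mM" else to_unit.lower()]
    except KeyError as err:
        raise ValueError(f"unknown concentration unit: {err.args[0]!r}") from None
    if f == t:
        return float(value)
    if f == "mM":
        return float(value) * MOLECULES_PER_UM3_PER_MM
    return float(value) / MOLECULES_PER_UM3_PER_MM


# ---------------------------------------------------------------------------
# finite-difference oracle
# ---------------------------------------------------------------------------

def solve_transport_numerically(
    model: Literal["screening", "accumulation"],
    geom: ChannelGeometry,
    params,
    n_points: int = 10_000,
) -> TransportResult:
    """Second-order finite-difference solution of the steady transport BVPs.

    ``"screening"``: (WH − πR_c²) D c'' = 2π R_c k_abs c with c(0)=c0 and
    zero flux at x=L (ghost-node Neumann).  ``"accumulation"``: the first-order
    flux balance W H D c' = (J/ρ)(2H+W)(L−x) c with c(0)=c0, discretized with
    central differences (second-order one-sided closure at x=L).

    These solvers share no code with the closed forms; they exist to verify
    them.  Grid refinement halving the spacing shrinks the deviation from the
    closed form ≈4×, confirming second-order convergence.
    """
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    L = geom.length
    x = np.linspace(0.0, L, n_points)
    h = x[1] - x[0]
    n = n_points

    if model == "screening":
        free = _free_cross_section(geom, params.cell_radius)
        kappa = 2.0 * np.pi * params.cell_radius * params.k_abs / (free * params.diffusion)
        main = np.full(n, -2.0 / h**2 - kappa)
        lower = np.full(n - 1, 1.0 / h**2)
        upper = np.full(n - 1, 1.0 / h**2)
        rhs = np.zeros(n)
        # Dirichlet entrance
        main[0], upper[0], rhs[0] = 1.0, 0.0, params.c0
        # Neumann dead end via ghost node: c_{N+1} = c_{N-1}
        lower[-1] = 2.0 / h**2
        A = scipy.sparse.diags([lower, main, upper], [-1, 0, 1], format="csc")
        c = scipy.sparse.linalg.spsolve(A, rhs)
        lam = screening_length(geom, params)
        residual = float(np.max(np.abs(A @ c - rhs)))
        if not np.all(np.isfinite(c)):
            raise RuntimeError(f"screening FD solve failed on {n} points (residual {residual})")
        return TransportResult(x, c, lam, "screening_fd", {"n": n, "residual": residual})

    if model == "accumulation":
        sigma = accumulation_length(geom, params)
        g = (L - x) / sigma**2  # c'(x) = g(x) c(x)
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        rhs = np.zeros(n)
        main[0], rhs[0] = 1.0, params.c0
        # interior: (c_{i+1} - c_{i-1})/(2h) - g_i c_i = 0
        main[1:-1] = -g[1:-1]
        upper[1:] = 1.0 / (2.0 * h)
        lower[:-1] = -1.0 / (2.0 * h)
        # x = L: second-order backward difference (3c_N - 4c_{N-1} + c_{N-2})/(2h) = g_N c_N
        A = scipy.sparse.lil_matrix((n, n))
        A.setdiag(main)
        A.setdiag(upper, 1)
        A.setdiag(lower, -1)
        A[n - 1, n - 1] = 3.0 / (2.0 * h) - g[-1]
        A[n - 1, n - 2] = -4.0 / (2.0 * h)
        A[n - 1, n - 3] = 1.0 / (2.0 * h)
        A = A.tocsc()
        c = scipy.sparse.linalg.spsolve(A, rhs)
        residual = float(np.max(np.abs(A @ c - rhs)))
        if not np.all(np.isfinite(c)):
            raise RuntimeError(f"accumulation FD solve failed on {n} points (residual {residual})")
        return TransportResult(x, c, sigma, "accumulation_fd", {"n": n, "residual": residual})

    raise ValueError(f"unknown transport model {model!r}")
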