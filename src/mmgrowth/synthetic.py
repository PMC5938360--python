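"""Synthetic inputs: rendered channel scenes and growth-law datasets.

No raw mother-machine images are publicly deposited for this system, so every
downstream stage is exercised on synthetic data with known ground truth:

* :func:`render_scene` draws spherocylindrical cells of known length/width
  into a narrow dead-end channel, blurs them with an isotropic Gaussian PSF
  and corrupts them with photon shot noise and Gaussian read noise.  The
  rendered silhouette is the *cytoplasmic* fluorophore distribution: a capsule
  of pole-to-pole length L_c whose diameter is the outer diameter W_c minus
  the diffraction (0.04 μm) and envelope (0.04 μm) corrections that the
  measurement stage later adds back.
* :func:`generate_growth_law_dataset` samples (birth volume, doubling time)
  pairs from the universal growth law V_b = ½ V_i 2^((C+D)/T_d) with
  multiplicative lognormal noise of chosen coefficient of variation.
* :func:`generate_measurement_table` assembles per-cell measurements into the
  replicate-tagged tidy table the replicate statistics operate on.

Coordinates: x runs along the channel axis (image columns), y across it
(rows); both in μm with the origin at the channel entrance corner.  Pixel
(0, 0) is the top-left of the image, which extends ``margin_um`` beyond the
channel footprint on every side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .transport import ChannelGeometry

__all__ = [
    "GroundTruthCell",
    "SceneSpec",
    "GrowthLawSample",
    "render_scene",
    "render_silhouette",
    "generate_growth_law_dataset",
    "generate_measurement_table",
    "typical_scene",
    "write_scene",
]

#: total silhouette shrinkage of the cytoplasmic label relative to the outer
#: diameter: diffraction correction + envelope (periplasm + outer membrane)
CYTOPLASM_SHRINK_UM = 0.08

_SUPERSAMPLE = 8  # sub-pixel samples per axis for area-coverage rendering


@dataclass(frozen=True)
class GroundTruthCell:
    """One rod cell: center (x, y) μm, axis angle in degrees from the channel axis,
    pole-to-pole length L_c and outer diameter W_c in μm."""

    center: tuple[float, float]
    length: float
    width: float
    axis_angle: float = 0.0
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.length >= self.width):
            raise ValueError("need length ≥ width > 0")
        if self.width <= CYTOPLASM_SHRINK_UM:
            raise ValueError(f"width must exceed {CYTOPLASM_SHRINK_UM} μm to leave a cytoplasm")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")

    @property
    def cytoplasm_diameter(self) -> float:
        return self.width - CYTOPLASM_SHRINK_UM

    def footprint_area(self) -> float:
        """Analytic area of the rendered 2D capsule silhouette, μm²."""
        w = self.cytoplasm_diameter
        return (self.length - w) * w + math.pi * (w / 2.0) ** 2

    def footprint_perimeter(self) -> float:
        w = self.cytoplasm_diameter
        return 2.0 * (self.length - w) + math.pi * w

    def _axis(self) -> tuple[np.ndarray, float, float]:
        """(unit axis vector, core half-length, cap radius) in μm."""
        theta = math.radians(self.axis_angle)
        u = np.array([math.cos(theta), math.sin(theta)])
        r = self.cytoplasm_diameter / 2.0
        return u, self.length / 2.0 - r, r

    def x_extent(self) -> tuple[float, float]:
        """Projection of the silhouette onto the channel axis, μm."""
        u, a, r = self._axis()
        half = a * abs(u[0]) + r
        return self.center[0] - half, self.center[0] + half

    def y_extent(self) -> tuple[float, float]:
        u, a, r = self._axis()
        half = a * abs(u[1]) + r
        return self.center[1] - half, self.center[1] + half


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic channel scene."""

    channel: ChannelGeometry
    cells: tuple[GroundTruthCell, ...]
    pixel_size: float = 0.065        # μm/px
    psf_sigma: float = 0.10          # μm
    background_level: float = 100.0  # photons
    peak_signal: float = 400.0       # photons above background
    read_noise_sd: float = 2.0       # photons
    rng_seed: int = 0
    margin_um: float = 1.0
    allow_squeeze: bool = False      # permit width > channel W (wall-squeezed cells)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma and read_noise_sd must be non-negative")
        if self.background_level < 0 or self.peak_signal < 0:
            raise ValueError("background and peak signal must be non-negative")
        object.__setattr__(self, "cells", tuple(self.cells))
        self._validate_cells()

    def _validate_cells(self) -> None:
        geom = self.channel
        intervals = []
        for i, cell in enumerate(self.cells):
            if cell.width > geom.width and not self.allow_squeeze:
                raise ValueError(
                    f"cell {i} is wider ({cell.width} μm) than the channel "
                    f"({geom.width} μm); set allow_squeeze for wall-squeezing scenes"
                )
            x0, x1 = cell.x_extent()
            y0, y1 = cell.y_extent()
            # squeezed cells press into the walls; only the axial bound applies
            y_ok = self.allow_squeeze or (y0 >= 0 and y1 <= geom.width)
            if x0 < 0 or x1 > geom.length or not y_ok:
                raise ValueError(
                    f"cell {i} at ({cell.center[0]:.2f}, {cell.center[1]:.2f}) μm "
                    f"extends outside the channel footprint "
                    f"[0, {geom.length}] × [0, {geom.width}] μm"
                )
            intervals.append((x0, x1, i))
        intervals.sort()
        for (a0, a1, i), (b0, b1, j) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError(f"cells {i} and {j} overlap along the channel axis")

    @property
    def shape(self) -> tuple[int, int]:
        rows = int(round((self.channel.width + 2 * self.margin_um) / self.pixel_size))
        cols = int(round((self.channel.length + 2 * self.margin_um) / self.pixel_size))
        return rows, cols

    def ground_truth(self) -> pd.DataFrame:
        rows = [
            {
                "id": i,
                "x_um": c.center[0],
                "y_um": c.center[1],
                "angle_deg": c.axis_angle,
                "length_um": c.length,
                "width_um": c.width,
                "width_cyt_render_um": c.cytoplasm_diameter,
            }
            for i, c in enumerate(self.cells)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id", "x_um", "y_um", "angle_deg",
                "length_um", "width_um", "width_cyt_render_um",
            ],
        )


def _pixel_centers(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """(y_um of row centers, x_um of column centers) in channel coordinates."""
    rows, cols = spec.shape
    y = (np.arange(rows) + 0.5) * spec.pixel_size - spec.margin_um
    x = (np.arange(cols) + 0.5) * spec.pixel_size - spec.margin_um
    return y, x


def _capsule_coverage(cell: GroundTruthCell, spec: SceneSpec) -> np.ndarray:
    """Per-pixel coverage fraction of the cell silhouette (supersampled)."""
    rows, cols = spec.shape
    px = spec.pixel_size
    u, a, r = cell._axis()
    cx, cy = cell.center
    # bounding box in pixels, padded by one pixel
    x0, x1 = cell.x_extent()
    y0, y1 = cell.y_extent()
    c0 = max(int((x0 + spec.margin_um) / px) - 1, 0)
    c1 = min(int((x1 + spec.margin_um) / px) + 2, cols)
    r0 = max(int((y0 + spec.margin_um) / px) - 1, 0)
    r1 = min(int((y1 + spec.margin_um) / px) + 2, rows)

    if spec.psf_sigma == 0:
        # discrete limit: pixel-center membership gives an exactly binary image
        yy = (np.arange(r0, r1) + 0.5) * px - spec.margin_um
        xx = (np.arange(c0, c1) + 0.5) * px - spec.margin_um
        sub = 1
    else:
        s = _SUPERSAMPLE
        yy = (np.arange(r0 * s, r1 * s) + 0.5) * (px / s) - spec.margin_um
        xx = (np.arange(c0 * s, c1 * s) + 0.5) * (px / s) - spec.margin_um
        sub = s
    X, Y = np.meshgrid(xx - cx, yy - cy)
    t = np.clip(X * u[0] + Y * u[1], -a, a)  # position along the core segment
    d2 = (X - t * u[0]) ** 2 + (Y - t * u[1]) ** 2
    inside = (d2 <= r * r).astype(float)
    if sub > 1:
        inside = inside.reshape(r1 - r0, sub, c1 - c0, sub).mean(axis=(1, 3))
    out = np.zeros((rows, cols))
    out[r0:r1, c0:c1] = inside
    return out


def render_silhouette(spec: SceneSpec) -> np.ndarray:
    """Noise-free, unblurred signal image (photons above background)."""
    img = np.zeros(spec.shape)
    for cell in spec.cells:
        img += spec.peak_signal * cell.intensity_scale * _capsule_coverage(cell, spec)
    return img


def render_scene(
    spec: SceneSpec, *, noiseless: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to a float photon image plus its ground-truth table.

    The silhouette is convolved with an isotropic Gaussian PSF (``psf_sigma``),
    the background is added, and — unless ``noiseless`` — Poisson shot noise is
    applied to (background + signal) and Gaussian read noise added on top.
    Rendering is deterministic for a fixed ``rng_seed``.
    """
    from scipy.ndimage import gaussian_filter

    signal = render_silhouette(spec)
    if spec.psf_sigma > 0:
        signal = gaussian_filter(signal, sigma=spec.psf_sigma / spec.pixel_size)
    expected = signal + spec.background_level
    if noiseless:
        return expected, spec.ground_truth()
    rng = np.random.default_rng(spec.rng_seed)
    img = rng.poisson(expected).astype(float)
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return img, spec.ground_truth()


def write_scene(spec: SceneSpec, image: np.ndarray, tiff_path, truth_path=None) -> None:
    """Write a rendered image as 16-bit TIFF (and the ground truth as CSV)."""
    tifffile.imwrite(
        str(tiff_path),
        np.clip(np.round(image), 0, 65535).astype(np.uint16),
        metadata={"pixel_size_um": spec.pixel_size, "rng_seed": spec.rng_seed},
    )
    if truth_path is not None:
        spec.ground_truth().to_csv(truth_path, index=False)


# ---------------------------------------------------------------------------
# growth-law datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthLawSample:
    birth_volume: float  # μm³
    doubling_time: float  # min

    def __post_init__(self) -> None:
        if self.birth_volume <= 0 or self.doubling_time <= 0:
            raise ValueError("birth volume and doubling time must be positive")


def generate_growth_law_dataset(
    v_i: float,
    cd_period: float,
    n: int,
    td_range: tuple[float, float] = (100.0, 220.0),
    noise_cv: float = 0.03,
    rng_seed: int = 0,
) -> list[GrowthLawSample]:
    """Sample (V_b, T_d) pairs from V_b = ½ V_i 2^((C+D)/T_d).

    Doubling times are uniform over ``td_range`` (minutes); birth volumes are
    multiplied by mean-one lognormal noise with coefficient of variation
    ``noise_cv``.  At least 3 samples are required (the downstream fit needs
    them).
    """
    if v_i <= 0 or cd_period < 0:
        raise ValueError("v_i must be positive and cd_period non-negative")
    if n < 3:
        raise ValueError("need n ≥ 3 samples for a downstream fit")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    lo, hi = td_range
    if not (0 < lo <= hi):
        raise ValueError("td_range must be positive and ordered")
    rng = np.random.default_rng(rng_seed)
    td = rng.uniform(lo, hi, size=n)
    vb = 0.5 * v_i * 2.0 ** (cd_period / td)
    if noise_cv > 0:
        s2 = math.log(1.0 + noise_cv**2)
        vb = vb * rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n)
    return [GrowthLawSample(float(v), float(t)) for v, t in zip(vb, td)]


def samples_to_frame(samples: list[GrowthLawSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "v_b_um3": [s.birth_volume for s in samples],
            "t_d_min": [s.doubling_time for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# replicate tables
# ---------------------------------------------------------------------------

def generate_measurement_table(replicates: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-replicate measurement tables into one tidy table.

    ``replicates`` maps a replicate id to a per-cell table (any columns); a
    plain list is numbered 1..n.  The result carries a ``replicate`` column
    and feeds :func:`mmgrowth.growthlaw.replicate_statistics`.
    """
    if isinstance(replicates, list):
        replicates = {str(i + 1): t for i, t in enumerate(replicates)}
    if not replicates:
        raise ValueError("need at least one replicate group")
    parts = []
    for rep_id, tab in replicates.items():
        part = tab.copy()
        part.insert(0, "replicate", str(rep_id))
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# canonical study scene
# ---------------------------------------------------------------------------

def typical_scene(
    rng_seed: int = 0,
    n_cells: int = 10,
    channel: ChannelGeometry | None = None,
    mean_length: float = 2.12,
    mean_width: float = 0.78,
    length_sd: float = 0.12,
    width_sd: float = 0.02,
    gap_um: float = 0.35,
    angle_jitter_deg: float = 0.0,
    **overrides,
) -> SceneSpec:
    """A single-row colony at the study's cell scale (L_c ≈ 2.12, W_c ≈ 0.78 μm).

    Cells are placed end to end along a 0.9 μm wide channel with inter-cell
    gaps of ``gap_um`` so that segmentation has ground truth to count; sizes
    vary normally around the means (clipped to stay valid).  ``overrides``
    pass through to :class:`SceneSpec` (psf_sigma, noise levels, ...).
    """
    rng = np.random.default_rng(rng_seed)
    cells = []
    x = 0.6  # leave room at the entrance
    for _ in range(n_cells):
        length = float(np.clip(rng.normal(mean_length, length_sd), 1.2, 4.0))
        width = float(np.clip(rng.normal(mean_width, width_sd), 0.6, 0.88))
        angle = float(rng.normal(0.0, angle_jitter_deg)) if angle_jitter_deg else 0.0
        x_center = x + length / 2.0
        cells.append(GroundTruthCell((x_center, 0.45), length, width, angle))
        x = x_center + length / 2.0 + gap_um
    if channel is None:
        channel = ChannelGeometry(width=0.9, height=1.15, length=max(x + 0.6, 15.0))
    return SceneSpec(channel=channel, cells=tuple(cells), rng_seed=rng_seed, **overrides)
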