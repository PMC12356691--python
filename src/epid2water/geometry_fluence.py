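"""Incident energy-fluence modeling for a flattened linac photon beam.

The linac head is represented by a two-source model: a focal source (the
bremsstrahlung target, giving the sharp field edges) and a broad extra-focal
source (flattening-filter and collimator scatter, giving the low-intensity
tails outside the field edge).  The focal component carries the radial
"horn" profile of a flattened beam and a Gaussian penumbra; steering
mis-adjustments are represented as a linear off-axis intensity tilt.

All lateral coordinates are millimetres in the plane of the grid, with the
beam central axis (CAX) at (0, 0).  Crossplane is the x axis (second array
index), inplane is the y axis (first array index).  Jaw positions are given
in centimetres at the isocenter plane (100 cm from the source) and projected
to other planes by similar triangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

ISO_DISTANCE_CM = 100.0


def radial_poly(r_cm: np.ndarray | float, coeffs: Sequence[float]) -> np.ndarray | float:
    """Evaluate 1 + sum_k c_k r**(k+1) with r in cm.

    ``coeffs[0]`` multiplies r, ``coeffs[1]`` multiplies r**2, and so on.
    Used both for the flattened-beam horn profile and for the a-Si off-axis
    response polynomial.
    """
    out = np.ones_like(np.asarray(r_cm, dtype=float))
    rp = np.asarray(r_cm, dtype=float)
    for c in coeffs:
        out = out + c * rp
        rp = rp * np.asarray(r_cm, dtype=float)
    return out


@dataclass(frozen=True)
class FieldSpec:
    """Rectangular jaw-collimated field, positions in cm at isocenter."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError("degenerate field: require x1 < x2 and y1 < y2")

    @classmethod
    def square(cls, side_cm: float) -> "FieldSpec":
        h = side_cm / 2.0
        return cls(-h, h, -h, h)

    @property
    def width_x_cm(self) -> float:
        return self.x2 - self.x1

    @property
    def width_y_cm(self) -> float:
        return self.y2 - self.y1

    @property
    def equivalent_square_cm(self) -> float:
        """Side of the equivalent square, 2XY/(X+Y)."""
        return 2.0 * self.width_x_cm * self.width_y_cm / (self.width_x_cm + self.width_y_cm)


@dataclass(frozen=True)
class BeamConfig:
    """Full description of one delivery.

    ``tilt_crossplane`` / ``tilt_inplane`` are fractional intensity change
    per cm off-axis at isocenter scale (a de-steered beam); ``horn_coeffs``
    follow the :func:`radial_poly` convention; ``source_sigma_mm`` is the
    effective penumbra sigma at isocenter scale.
    """

    field: FieldSpec
    mu: float
    sdd_cm: float = 100.0
    ssd_cm: float = 100.0
    energy_label: str = "6MV-flattened"
    tilt_crossplane: float = 0.0
    tilt_inplane: float = 0.0
    horn_coeffs: Tuple[float, ...] = (0.0, 2.5e-4)
    source_sigma_mm: float = 3.0
    extrafocal_fraction: float = 0.05
    extrafocal_sigma_mm: float = 20.0
    jaw_transmission: float = 0.002

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0.0 <= self.extrafocal_fraction < 0.5):
            raise ValueError("extrafocal_fraction must be in [0, 0.5)")
        if self.sdd_cm <= 0 or self.ssd_cm <= 0:
            raise ValueError("sdd_cm and ssd_cm must be positive")

    def untilted(self) -> "BeamConfig":
        """Nominal (plan) configuration with no steering detune."""
        return replace(self, tilt_crossplane=0.0, tilt_inplane=0.0)


@dataclass(frozen=True)
class GridSpec:
    """Square, odd-sized, CAX-centered sampling grid at a stated plane."""

    spacing_mm: float
    half_extent_mm: float
    plane_distance_cm: float

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or self.half_extent_mm <= 0:
            raise ValueError("spacing and half extent must be positive")
        if self.plane_distance_cm <= 0:
            raise ValueError("plane distance must be positive")

    @property
    def n(self) -> int:
        # odd by construction so one sample sits exactly on the CAX
        return 2 * int(round(self.half_extent_mm / self.spacing_mm)) + 1

    @property
    def coords_mm(self) -> np.ndarray:
        n = self.n
        return (np.arange(n) - n // 2) * self.spacing_mm

    @property
    def magnification(self) -> float:
        return self.plane_distance_cm / ISO_DISTANCE_CM

    def iso_coords_cm(self) -> np.ndarray:
        """Axis coordinates back-projected to the isocenter plane, in cm."""
        return self.coords_mm / self.magnification / 10.0

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.coords_mm
        return np.meshgrid(c, c, indexing="xy")  # (X, Y); rows = y, cols = x

    @classmethod
    def at_isocenter(cls, spacing_mm: float = 1.0, half_extent_mm: float = 160.0) -> "GridSpec":
        return cls(spacing_mm, half_extent_mm, ISO_DISTANCE_CM)


@dataclass
class FluenceMap:
    """Relative energy fluence x MU on a :class:`GridSpec` (rows=y, cols=x)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match grid ({n}, {n})")
        if np.any(self.values < 0):
            raise ValueError("fluence values must be non-negative")

    @property
    def cax_value(self) -> float:
        c = self.grid.n // 2
        return float(self.values[c, c])

    def integral(self) -> float:
        """Integrated fluence, value x mm^2."""
        return float(self.values.sum()) * self.grid.spacing_mm**2

    def value_at(self, x_mm: float, y_mm: float) -> float:
        """Bilinear sample at a lateral position in the grid plane."""
        from scipy.interpolate import RegularGridInterpolator

        c = self.grid.coords_mm
        interp = RegularGridInterpolator((c, c), self.values, bounds_error=False, fill_value=0.0)
        return float(interp((y_mm, x_mm)))


def resample_to_grid(f: FluenceMap, grid: GridSpec) -> FluenceMap:
    """Bilinear resample onto another grid at the *same* plane (fill 0 outside)."""
    if abs(f.grid.plane_distance_cm - grid.plane_distance_cm) > 1e-6:
        raise ValueError(
            "resample_to_grid requires equal plane distances; use transport_fluence first"
        )
    if (
        f.grid.spacing_mm == grid.spacing_mm
        and f.grid.half_extent_mm == grid.half_extent_mm
    ):
        return FluenceMap(f.values.copy(), grid)
    from scipy.interpolate import RegularGridInterpolator

    c = f.grid.coords_mm
    interp = RegularGridInterpolator((c, c), f.values, bounds_error=False, fill_value=0.0)
    X, Y = grid.meshgrid_mm()
    vals = interp(np.stack([Y.ravel(), X.ravel()], axis=-1)).reshape(grid.n, grid.n)
    return FluenceMap(np.clip(vals, 0.0, None), grid)


def build_aperture_mask(
    field_spec: FieldSpec, grid: GridSpec, transmission: float = 0.002
) -> FluenceMap:
    """Jaw aperture projected to the grid plane by similar triangles.

    Inside the field the mask is 1, outside it is the jaw transmission;
    pixels straddling an edge get the fractional in-field coverage, so the
    discrete edge sits at the geometrically projected jaw position.
    """
    m = grid.magnification
    edges_x = (field_spec.x1 * 10.0 * m, field_spec.x2 * 10.0 * m)
    edges_y = (field_spec.y1 * 10.0 * m, field_spec.y2 * 10.0 * m)
    c = grid.coords_mm
    h = grid.spacing_mm / 2.0

    def coverage(lo: float, hi: float) -> np.ndarray:
        return np.clip((np.minimum(c + h, hi) - np.maximum(c - h, lo)) / grid.spacing_mm, 0.0, 1.0)

    cov = np.outer(coverage(*edges_y), coverage(*edges_x))
    vals = transmission + (1.0 - transmission) * cov
    return FluenceMap(vals, grid)


def _horn_profile(config: BeamConfig, grid: GridSpec) -> np.ndarray:
    r_iso = np.hypot(*np.meshgrid(grid.iso_coords_cm(), grid.iso_coords_cm(), indexing="xy"))
    return np.asarray(radial_poly(r_iso, config.horn_coeffs))


def focal_fluence(config: BeamConfig, grid: GridSpec) -> FluenceMap:
    """Focal-source fluence: aperture x horn, Gaussian penumbra blur, x MU."""
    mask = build_aperture_mask(config.field, grid, config.jaw_transmission)
    horn = _horn_profile(config, grid)
    infield = mask.values > 0.5
    if np.any(horn[infield] <= 0.0):
        raise ValueError("horn profile is non-positive inside the field (unphysical)")
    vals = mask.values * horn
    sigma_px = config.source_sigma_mm * grid.magnification / grid.spacing_mm
    if sigma_px > 0:
        vals = gaussian_filter(vals, sigma_px, mode="nearest")
    return FluenceMap(np.clip(vals, 0.0, None) * config.mu, grid)


def extrafocal_fluence(config: BeamConfig, grid: GridSpec) -> FluenceMap:
    """Broad extra-focal (collimator/flattening-filter scatter) component."""
    if config.extrafocal_fraction == 0.0:
        return FluenceMap(np.zeros((grid.n, grid.n)), grid)
    mask = build_aperture_mask(config.field, grid, 0.0)
    sigma_px = config.extrafocal_sigma_mm * grid.magnification / grid.spacing_mm
    vals = gaussian_filter(mask.values, sigma_px, mode="constant", cval=0.0)
    return FluenceMap(
        np.clip(vals, 0.0, None) * config.extrafocal_fraction * config.mu, grid
    )


def total_head_fluence(config: BeamConfig, grid: GridSpec) -> FluenceMap:
    """Two-source head fluence with the steering-tilt modulation applied."""
    focal = focal_fluence(config, grid)
    vals = (1.0 - config.extrafocal_fraction) * focal.values
    if config.extrafocal_fraction > 0.0:
        vals = vals + extrafocal_fluence(config, grid).values
    if config.tilt_crossplane != 0.0 or config.tilt_inplane != 0.0:
        x_cm = grid.iso_coords_cm()
        X, Y = np.meshgrid(x_cm, x_cm, indexing="xy")
        modulation = 1.0 + config.tilt_crossplane * X + config.tilt_inplane * Y
        mask = build_aperture_mask(config.field, grid, 0.0)
        if np.any(modulation[mask.values > 0.5] <= 0.0):
            raise ValueError("steering tilt drives fluence negative inside the field")
        vals = vals * modulation
    return FluenceMap(np.clip(vals, 0.0, None), grid)


def transport_fluence(f: FluenceMap, to_distance_cm: float) -> FluenceMap:
    """Transport a fluence map along the diverging beam to another plane.

    The grid magnifies with distance and per-point fluence scales with the
    inverse square of distance, so the integrated fluence is conserved
    exactly; no resampling is involved.
    """
    if to_distance_cm <= 0:
        raise ValueError("target plane distance must be positive")
    d0 = f.grid.plane_distance_cm
    k = to_distance_cm / d0
    grid = GridSpec(f.grid.spacing_mm * k, f.grid.half_extent_mm * k, to_distance_cm)
    return FluenceMap(f.values / k**2, grid)
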