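"""Beam QA metrics: PDD and profile extraction, flatness and symmetry.

Flatness and symmetry are evaluated over the central 80% of the field
width (FWHM of the CAX-normalized profile), centered on the CAX:

    flatness = 100 (M - m) / (M + m)
    symmetry = 100 (D_left - D_right) / D_center   at the CAX-equidistant
                                                   pair maximizing the
                                                   absolute difference

where M, m are the extrema within the evaluation region and left is the
negative-coordinate side.  Symmetry is signed (sign of D_left - D_right);
both metrics are invariant under uniform dose rescaling.  Pairs are
evaluated on a 1 mm interpolated grid; ties go to the smallest off-axis
distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .water_dose import ArrayImage, DoseGrid3D


@dataclass
class Profile:
    """1D dose trace; lateral profiles must contain a sample exactly at 0."""

    positions_mm: np.ndarray
    values: np.ndarray
    axis_label: str = "crossplane"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.ndim != 1 or self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis_label != "depth" and not np.any(np.isclose(self.positions_mm, 0.0)):
            raise ValueError("lateral profiles need a CAX sample at position 0")

    @property
    def cax_value(self) -> float:
        i = int(np.argmin(np.abs(self.positions_mm)))
        return float(self.values[i])

    def resample_1mm(self) -> "Profile":
        lo = float(np.ceil(self.positions_mm[0]))
        hi = float(np.floor(self.positions_mm[-1]))
        pos = np.arange(lo, hi + 0.5)
        return Profile(pos, np.interp(pos, self.positions_mm, self.values), self.axis_label)

    def mirrored(self) -> "Profile":
        return Profile(-self.positions_mm[::-1], self.values[::-1], self.axis_label)

    def scaled(self, k: float) -> "Profile":
        return Profile(self.positions_mm, self.values * k, self.axis_label)


@dataclass(frozen=True)
class QAMetrics:
    flatness_pct: float
    symmetry_pct: float
    field_width_mm: float
    eval_region_mm: Tuple[float, float]
    axis_label: str = "crossplane"


@dataclass(frozen=True)
class MetricDiff:
    flatness_pct: float
    symmetry_pct: float
    field_width_mm: float
    axis_label: str


def extract_pdd(d: DoseGrid3D) -> Profile:
    """CAX dose versus depth, normalized to 100 at its maximum."""
    if d.values.size == 0:
        raise ValueError("empty dose grid")
    c = d.tank.n_lateral // 2
    cax = d.values[:, c, c]
    peak = cax.max()
    if peak <= 0:
        raise ValueError("no dose on the central axis")
    return Profile(d.tank.z_coords_mm, 100.0 * cax / peak, "depth")


def extract_profile(d: DoseGrid3D, depth_cm: float, axis: str) -> Profile:
    """Lateral CAX trace at a depth, interpolated to 1 mm steps.

    The slice is linearly interpolated between the two bracketing depth
    planes, so any depth inside the tank is available.
    """
    z_mm = depth_cm * 10.0
    zc = d.tank.z_coords_mm
    if not (zc[0] <= z_mm <= zc[-1]):
        raise ValueError("depth outside the tank")
    i = int(np.searchsorted(zc, z_mm, side="right") - 1)
    i = min(i, len(zc) - 2)
    t = (z_mm - zc[i]) / (zc[i + 1] - zc[i])
    slice_ = (1.0 - t) * d.values[i] + t * d.values[i + 1]
    c = d.tank.n_lateral // 2
    if axis == "crossplane":
        trace = slice_[c, :]
    elif axis == "inplane":
        trace = slice_[:, c]
    else:
        raise ValueError("axis must be 'crossplane' or 'inplane'")
    return Profile(d.tank.lateral_coords_mm, trace, axis).resample_1mm()


def array_profile(img: ArrayImage, axis: str) -> Profile:
    """Chamber row/column through the CAX as a lateral profile."""
    c = img.array.n_chambers // 2
    if axis == "crossplane":
        trace = img.values[c, :]
    elif axis == "inplane":
        trace = img.values[:, c]
    else:
        raise ValueError("axis must be 'crossplane' or 'inplane'")
    return Profile(img.array.positions_mm, trace, axis)


def epid_profile(image, axis: str) -> Profile:
    """Pixel row/column through the CAX of an EPID image (raw-EPID metrics)."""
    c = image.detector.n_pixels // 2
    trace = image.pixels[c, :] if axis == "crossplane" else image.pixels[:, c]
    return Profile(image.detector.grid.coords_mm, trace, axis)


def field_width(p: Profile) -> Tuple[float, Tuple[float, float]]:
    """FWHM of the CAX-normalized profile and its central-80% region.

    The evaluation region is centered on the CAX (not the beam center),
    because the symmetry pairs are defined as equidistant from the CAX.
    """
    q = p.resample_1mm()
    cax = q.cax_value
    if cax <= 0:
        raise ValueError("non-positive CAX value")
    half = cax / 2.0
    v, x = q.values, q.positions_mm
    i0 = int(np.argmin(np.abs(x)))

    def crossing(direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(v) and v[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(v):
            raise ValueError("no 50% falloff found on one side of the profile")
        t = (half - v[i]) / (v[j] - v[i])
        return float(x[i] + t * (x[j] - x[i]))

    left, right = crossing(-1), crossing(+1)
    width = right - left
    half_region = 0.4 * width
    return width, (-half_region, half_region)


def _eval_region_samples(p: Profile) -> Tuple[np.ndarray, np.ndarray, float]:
    q = p.resample_1mm()
    _, (lo, hi) = field_width(p)
    sel = (q.positions_mm >= lo) & (q.positions_mm <= hi)
    return q.positions_mm[sel], q.values[sel], q.cax_value


def flatness(p: Profile) -> float:
    """100 (M - m) / (M + m) over the central-80% evaluation region."""
    _, vals, _ = _eval_region_samples(p)
    if np.any(vals <= 0):
        raise ValueError("non-positive dose inside the evaluation region")
    M, m = float(vals.max()), float(vals.min())
    return 100.0 * (M - m) / (M + m)


def symmetry(p: Profile) -> float:
    """Signed symmetry at the CAX-equidistant pair with the largest difference."""
    pos, vals, cax = _eval_region_samples(p)
    if cax <= 0:
        raise ValueError("CAX value must be positive")
    left = {-int(round(x)): v for x, v in zip(pos, vals) if x < 0}
    best_diff, best_d = 0.0, None
    for x, v in zip(pos, vals):
        d = int(round(x))
        if d <= 0 or d not in left:
            continue
        diff = left[d] - v  # D_left - D_right
        if abs(diff) > abs(best_diff) or (
            abs(diff) == abs(best_diff) and (best_d is None or d < best_d)
        ):
            best_diff, best_d = diff, d
    return 100.0 * best_diff / cax


def compute_qa_metrics(p: Profile) -> QAMetrics:
    width, region = field_width(p)
    return QAMetrics(flatness(p), symmetry(p), width, region, p.axis_label)


def compare_metrics(a: QAMetrics, b: QAMetrics) -> MetricDiff:
    """Elementwise differences a - b (e.g. EPID-reconstructed minus reference)."""
    if a.axis_label != b.axis_label:
        raise ValueError("cannot compare metrics from different axes")
    return MetricDiff(
        a.flatness_pct - b.flatness_pct,
        a.symmetry_pct - b.symmetry_pct,
        a.field_width_mm - b.field_width_mm,
        a.axis_label,
    )
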