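"""Forward model of an amorphous-silicon (a-Si) portal imager.

The detector dose image is predicted by convolving the incident energy
fluence at the detector plane with a radially symmetric dose-deposition
kernel (a sum of Gaussians: a sharp core plus a long low-energy-scatter
tail — the tail is what makes the panel non-water-equivalent) and applying
the panel's characterized radial off-axis over-response.  The same model,
perturbed (kernel-width mismatch, residual uncorrected over-response,
noise, dark/gain structure), generates synthetic "measured" images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry_fluence import (
    FluenceMap,
    GridSpec,
    radial_poly,
    resample_to_grid,
)


@dataclass(frozen=True)
class Kernel:
    """Radially symmetric dose-deposition kernel as weighted Gaussian terms."""

    components: Tuple[Tuple[float, float], ...]  # (weight, sigma_mm)
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("kernel needs at least one component")
        if any(w <= 0 or s < 0 for w, s in self.components):
            raise ValueError("kernel weights must be > 0 and sigmas >= 0")

    def normalize(self) -> "Kernel":
        total = sum(w for w, _ in self.components)
        comps = tuple((w / total, s) for w, s in self.components)
        return Kernel(comps, normalized=True)

    def weight_sum(self) -> float:
        return sum(w for w, _ in self.components)

    def scaled_sigmas(self, factor: float) -> "Kernel":
        return Kernel(tuple((w, s * factor) for w, s in self.components), self.normalized)

    def apply(self, image: np.ndarray, pitch_mm: float) -> np.ndarray:
        """Convolve a pixel image with the kernel (zero padding outside)."""
        out = np.zeros_like(image)
        for w, sigma in self.components:
            if sigma == 0:
                out += w * image
            else:
                out += w * gaussian_filter(image, sigma / pitch_mm, mode="constant", cval=0.0)
        return out

    def radial_profile(self, r_mm: np.ndarray) -> np.ndarray:
        """Analytic 2D kernel density at radius r (per mm^2)."""
        r = np.asarray(r_mm, dtype=float)
        out = np.zeros_like(r)
        for w, sigma in self.components:
            if sigma == 0:
                continue
            out += w / (2.0 * np.pi * sigma**2) * np.exp(-(r**2) / (2.0 * sigma**2))
        return out


#: Default a-Si panel kernel: sharp core, mid-range scatter, long glare tail.
DEFAULT_EPID_KERNEL = Kernel(((0.80, 0.8), (0.14, 6.0), (0.06, 25.0))).normalize()


@dataclass(frozen=True)
class DetectorSpec:
    """Geometry and response of the portal-imager panel.

    ``offaxis_response_coeffs`` describe the characterized radial
    over-response of the a-Si panel relative to water (r in cm at the
    detector plane, :func:`radial_poly` convention).  Being characterized,
    it is part of the forward model used for image prediction — this is
    what lets the reconstruction undo it, while raw images keep it.
    """

    pixel_pitch_mm: float = 1.0
    n_pixels: int = 321
    sdd_cm: float = 100.0
    epid_kernel: Kernel = DEFAULT_EPID_KERNEL
    offaxis_response_coeffs: Tuple[float, ...] = (0.0, 2.5e-4)
    dark_field: Optional[np.ndarray] = None
    pixel_sensitivity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_pixels % 2 == 0:
            raise ValueError("n_pixels must be odd so a CAX pixel exists")
        if self.pixel_sensitivity is not None and np.any(np.asarray(self.pixel_sensitivity) <= 0):
            raise ValueError("pixel_sensitivity must be positive everywhere")

    @property
    def grid(self) -> GridSpec:
        half = (self.n_pixels // 2) * self.pixel_pitch_mm
        return GridSpec(self.pixel_pitch_mm, half, self.sdd_cm)

    def response_map(self) -> np.ndarray:
        c = self.grid.coords_mm / 10.0  # cm at the detector plane
        X, Y = np.meshgrid(c, c, indexing="xy")
        return np.asarray(radial_poly(np.hypot(X, Y), self.offaxis_response_coeffs))

    @classmethod
    def as1200(cls, **overrides) -> "DetectorSpec":
        """aS1200-like panel: 0.34 mm pitch, ~43 cm square active area."""
        kw = dict(pixel_pitch_mm=0.34, n_pixels=1265)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class CorrectionFlags:
    dark: bool = False
    sensitivity: bool = False
    flood: bool = False


@dataclass
class EPIDImage:
    """2D detector-dose image with its panel spec and correction state."""

    pixels: np.ndarray
    detector: DetectorSpec
    corrections_applied: CorrectionFlags = field(default_factory=CorrectionFlags)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        n = self.detector.n_pixels
        if self.pixels.shape != (n, n):
            raise ValueError("pixel array does not match detector geometry")

    @property
    def cax_value(self) -> float:
        c = self.detector.n_pixels // 2
        return float(self.pixels[c, c])


@dataclass(frozen=True)
class PerturbSpec:
    """Mismatch between the simulated physical panel and the forward model.

    ``kernel_sigma_scale`` widens the true deposition kernel relative to the
    modeled one; ``overresponse_coeffs`` is the *residual* (uncharacterized)
    radial over-response on top of the panel's known response;
    ``noise_frac`` is the Gaussian noise sigma as a fraction of the CAX
    signal.
    """

    kernel_sigma_scale: float = 1.0
    overresponse_coeffs: Tuple[float, ...] = ()
    noise_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be non-negative")
        if self.kernel_sigma_scale <= 0:
            raise ValueError("kernel sigma scale must be positive")


def _forward_image(f: FluenceMap, det: DetectorSpec, kernel: Kernel) -> np.ndarray:
    if abs(f.grid.plane_distance_cm - det.sdd_cm) > 1e-6:
        raise ValueError(
            f"fluence plane {f.grid.plane_distance_cm} cm does not match detector "
            f"SDD {det.sdd_cm} cm; transport it first"
        )
    fr = resample_to_grid(f, det.grid)
    img = kernel.apply(fr.values, det.pixel_pitch_mm)
    return img * det.response_map()


def predict_epid_image(f: FluenceMap, det: DetectorSpec) -> EPIDImage:
    """Deterministic model prediction of the panel dose image."""
    kernel = det.epid_kernel if det.epid_kernel.normalized else det.epid_kernel.normalize()
    img = _forward_image(f, det, kernel)
    return EPIDImage(img, det, CorrectionFlags(dark=True, sensitivity=True, flood=False))


def simulate_measured_epid(
    f: FluenceMap, det: DetectorSpec, perturb: PerturbSpec, seed: int
) -> EPIDImage:
    """Synthetic raw measurement: perturbed physics plus panel artifacts.

    The returned image is *uncorrected* (dark offset and pixel gain still
    present); pass it through :func:`apply_pixel_corrections` before
    reconstruction, as with a real acquisition.
    """
    kernel = det.epid_kernel if det.epid_kernel.normalized else det.epid_kernel.normalize()
    kernel = kernel.scaled_sigmas(perturb.kernel_sigma_scale)
    img = _forward_image(f, det, kernel)
    if perturb.overresponse_coeffs:
        c = det.grid.coords_mm / 10.0
        X, Y = np.meshgrid(c, c, indexing="xy")
        img = img * np.asarray(radial_poly(np.hypot(X, Y), perturb.overresponse_coeffs))
    if det.pixel_sensitivity is not None:
        img = img * np.asarray(det.pixel_sensitivity, dtype=float)
    if det.dark_field is not None:
        img = img + np.asarray(det.dark_field, dtype=float)
    if perturb.noise_frac > 0:
        rng = np.random.default_rng(seed)
        c0 = det.n_pixels // 2
        sigma = perturb.noise_frac * float(img[c0, c0])
        img = img + rng.normal(0.0, sigma, img.shape)
    return EPIDImage(img, det, CorrectionFlags(dark=False, sensitivity=False, flood=False))


def apply_pixel_corrections(raw: EPIDImage) -> EPIDImage:
    """Dark-field and pixel-sensitivity corrections (never flood-field).

    Flood-field correction would flatten out the very incident-fluence
    profile the reconstruction needs, so it is deliberately never applied.
    """
    if raw.corrections_applied.dark or raw.corrections_applied.sensitivity:
        raise ValueError("image already corrected; refusing double correction")
    det = raw.detector
    pix = raw.pixels.copy()
    if det.dark_field is not None:
        pix = pix - np.asarray(det.dark_field, dtype=float)
    if det.pixel_sensitivity is not None:
        pix = pix / np.asarray(det.pixel_sensitivity, dtype=float)
    return EPIDImage(pix, det, CorrectionFlags(dark=True, sensitivity=True, flood=False))
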