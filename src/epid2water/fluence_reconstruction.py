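"""Iterative estimation of incident fluence from a measured EPID image.

The predicted fluence is corrected by a multiplicative, positivity-
preserving fixed-point iteration (Richardson-Lucy flavored):

    f_{k+1} = f_k * smooth( measured / predict(f_k) )

with the correction ratio clamped, forced to 1 outside the in-field
region, and lightly smoothed — the deconvolution is ill-posed and the
smoothing prevents noise amplification.  Iteration stops when the
predicted image matches the measurement within tolerance (maximum
in-field deviation relative to the CAX signal) or at the iteration cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .epid_forward import EPIDImage, predict_epid_image
from .geometry_fluence import BeamConfig, FluenceMap, GridSpec, resample_to_grid, total_head_fluence, transport_fluence

logger = logging.getLogger(__name__)

RATIO_CLAMP = (0.2, 5.0)


@dataclass(frozen=True)
class ReconOptions:
    max_iter: int = 25
    tol: float = 0.002
    smoothing_sigma_mm: float = 1.0
    infield_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ConvergenceReport:
    iterations_used: int
    deviations: List[float] = field(default_factory=list)
    converged: bool = False

    def as_dict(self) -> dict:
        return {
            "iterations_used": self.iterations_used,
            "deviations": list(self.deviations),
            "converged": self.converged,
        }


def image_deviation(measured: EPIDImage, predicted: EPIDImage, threshold: float = 0.05) -> float:
    """Max in-field |measured - predicted| relative to the measured CAX signal."""
    if measured.pixels.shape != predicted.pixels.shape:
        raise ValueError("images must share the same pixel grid")
    cax = measured.cax_value
    if cax <= 0:
        raise ValueError("non-positive CAX signal in measured image")
    infield = measured.pixels >= threshold * cax
    if not np.any(infield):
        raise ValueError("empty in-field region at this threshold")
    return float(np.max(np.abs(measured.pixels[infield] - predicted.pixels[infield])) / cax)


def initial_fluence_estimate(config: BeamConfig, measured: EPIDImage) -> FluenceMap:
    """Model-predicted head fluence, transported and resampled to the pixel grid."""
    det = measured.detector
    iso_half = det.grid.half_extent_mm * 100.0 / det.sdd_cm
    iso_grid = GridSpec(min(1.0, det.pixel_pitch_mm), iso_half, 100.0)
    f = total_head_fluence(config, iso_grid)
    f = transport_fluence(f, det.sdd_cm)
    return resample_to_grid(f, det.grid)


def reconstruct_incident_fluence(
    measured: EPIDImage, config: BeamConfig, opts: ReconOptions = ReconOptions()
) -> Tuple[FluenceMap, ConvergenceReport]:
    """Invert a corrected EPID measurement to incident fluence at the EPID plane.

    The measurement must have dark/sensitivity corrections applied and must
    *not* be flood-corrected.  The forward model inside the loop uses the
    nominal (characterized) kernel and off-axis response even when the
    measurement came from a perturbed panel — mirroring reality, where the
    true detector state is never exactly known.
    """
    flags = measured.corrections_applied
    if flags.flood:
        raise ValueError("flood-corrected images carry no fluence profile; cannot reconstruct")
    if not (flags.dark and flags.sensitivity):
        raise ValueError("apply dark/sensitivity corrections before reconstruction")

    det = measured.detector
    f = initial_fluence_estimate(config, measured)
    cax = measured.cax_value
    infield = measured.pixels >= opts.infield_threshold * cax
    sigma_px = opts.smoothing_sigma_mm / det.pixel_pitch_mm

    report = ConvergenceReport(iterations_used=0)
    for it in range(1, opts.max_iter + 1):
        predicted = predict_epid_image(f, det)
        dev = image_deviation(measured, predicted, opts.infield_threshold)
        report.deviations.append(dev)
        report.iterations_used = it
        if dev < opts.tol:
            report.converged = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(predicted.pixels > 0, measured.pixels / predicted.pixels, 1.0)
        ratio = np.where(infield, ratio, 1.0)
        ratio = np.clip(ratio, *RATIO_CLAMP)
        if sigma_px > 0:
            ratio = gaussian_filter(ratio, sigma_px, mode="nearest")
        f = FluenceMap(np.clip(f.values * ratio, 0.0, None), f.grid)

    if not report.converged:
        logger.warning(
            "fluence reconstruction did not reach tol=%.2e in %d iterations "
            "(final deviation %.2e)",
            opts.tol,
            opts.max_iter,
            report.deviations[-1],
        )
    return f, report
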