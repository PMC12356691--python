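"""Synthetic QA scenarios: baselines, composite asymmetric fields, detuned beams.

Three experiment families exercise the full measure-reconstruct-convert
loop:

* symmetric open-field baselines (10x10 and 20x20 cm2, water-tank runs);
* incrementally asymmetric composite fields — a 500 MU 20x20 open field
  plus an extra 5/10/15/20 MU delivered through a half-blocked 10x20 field
  whose blocking edge sits on the CAX, on either side, giving symmetry
  distortions of roughly 0, +/-1, +/-2, +/-3, +/-4 %;
* steering-detuned beams — a linear off-axis intensity tilt in the
  crossplane and/or inplane direction, the lowest-order effect of a
  steering-angle change, sized to give water symmetry in the 2-3.5% range.

The physical two-exposure composite acquisition is modeled as fluence
addition (the panel integrates dose linearly).  Each scenario yields a
ground-truth fluence, a ground-truth water/array dose (with the
electron-contamination surface term, which the reconstruction-side engine
deliberately lacks), and a simulated raw EPID measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple, Union

from .epid_forward import (
    DetectorSpec,
    EPIDImage,
    PerturbSpec,
    simulate_measured_epid,
)
from .geometry_fluence import (
    BeamConfig,
    FieldSpec,
    FluenceMap,
    GridSpec,
    total_head_fluence,
    transport_fluence,
)
from .water_dose import (
    ArrayImage,
    ArraySpec,
    DoseGrid3D,
    TankGrid,
    WaterModel,
    compute_array_dose,
    compute_watertank_dose,
)

#: Default panel perturbations for closed-loop runs: 5% kernel-width
#: mismatch, residual (uncharacterized) off-axis over-response of +0.25%
#: at 10 cm, and 0.3% Gaussian noise.
DEFAULT_PERTURB = PerturbSpec(
    kernel_sigma_scale=1.05, overresponse_coeffs=(0.0, 2.5e-5), noise_frac=0.003
)

#: Steering tilt magnitude (fractional intensity change per cm off-axis)
#: sized so the ground-truth water symmetry of a detuned 20x20 beam falls
#: in the 2-3.5% range.
DEFAULT_TILT = 0.002

DEFAULT_SCENARIO_GRID = GridSpec.at_isocenter(1.0, 160.0)


def study_config(field_spec: Optional[FieldSpec] = None, mu: float = 500.0) -> BeamConfig:
    """Flattened 6 MV open-field delivery at 100 cm SDD/SSD."""
    return BeamConfig(field=field_spec or FieldSpec.square(20.0), mu=mu)


def ideal_edges(config: BeamConfig) -> BeamConfig:
    """Idealized variant: step edges, flat beam, no scatter or transmission."""
    return replace(
        config,
        source_sigma_mm=0.0,
        horn_coeffs=(),
        extrafocal_fraction=0.0,
        jaw_transmission=0.0,
    )


def half_blocked_field(base: FieldSpec, side: str, axis: str) -> FieldSpec:
    """Half of ``base`` with the blocking edge on the CAX."""
    if side not in ("negative", "positive"):
        raise ValueError("side must be 'negative' or 'positive'")
    if axis == "crossplane":
        return (
            FieldSpec(base.x1, 0.0, base.y1, base.y2)
            if side == "negative"
            else FieldSpec(0.0, base.x2, base.y1, base.y2)
        )
    if axis == "inplane":
        return (
            FieldSpec(base.x1, base.x2, base.y1, 0.0)
            if side == "negative"
            else FieldSpec(base.x1, base.x2, 0.0, base.y2)
        )
    raise ValueError("axis must be 'crossplane' or 'inplane'")


@dataclass(frozen=True)
class Scenario:
    """One delivery of the study: segments delivered cumulatively."""

    name: str
    config: BeamConfig
    segments: Tuple[Tuple[FieldSpec, float], ...]
    perturb: PerturbSpec = PerturbSpec()
    seed: int = 0

    @property
    def total_mu(self) -> float:
        return sum(mu for _, mu in self.segments)

    @property
    def nominal_config(self) -> BeamConfig:
        """Plan-level configuration the reconstruction is allowed to know:
        the base segment, with no knowledge of the detune or extra segments."""
        f0, mu0 = self.segments[0]
        return replace(self.config, field=f0, mu=mu0).untilted()


def ground_truth_fluence(s: Scenario, grid: GridSpec = DEFAULT_SCENARIO_GRID) -> FluenceMap:
    """Segment-summed head fluence, steering tilt included."""
    total = None
    for fld, mu in s.segments:
        f = total_head_fluence(replace(s.config, field=fld, mu=mu), grid)
        total = f if total is None else FluenceMap(total.values + f.values, grid)
    assert total is not None
    return total


def compose_asymmetric_field(
    base_mu: float,
    extra_mu: float,
    side: str,
    axis: str,
    config: BeamConfig,
    grid: GridSpec = DEFAULT_SCENARIO_GRID,
) -> FluenceMap:
    """Open field at ``base_mu`` plus a half-blocked boost at ``extra_mu``."""
    if extra_mu < 0:
        raise ValueError("extra_mu must be >= 0")
    segments: List[Tuple[FieldSpec, float]] = [(config.field, base_mu)]
    if extra_mu > 0:
        segments.append((half_blocked_field(config.field, side, axis), extra_mu))
    s = Scenario("composite", config, tuple(segments))
    return ground_truth_fluence(s, grid)


def build_asymmetry_series(
    axis: str,
    config: Optional[BeamConfig] = None,
    base_mu: float = 500.0,
    extra_levels: Tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    perturb: PerturbSpec = DEFAULT_PERTURB,
    seed: int = 0,
) -> List[Scenario]:
    """Nine scenarios skewing symmetry to each side: -4% ... 0 ... +4%.

    A positive boost on the negative-coordinate (left) side raises D_left,
    giving positive symmetry.
    """
    if axis not in ("crossplane", "inplane"):
        raise ValueError("axis must be 'crossplane' or 'inplane'")
    cfg = config or study_config()
    signed = [-mu for mu in reversed(extra_levels)] + [0.0] + list(extra_levels)
    out: List[Scenario] = []
    for i, mu in enumerate(signed):
        segments: List[Tuple[FieldSpec, float]] = [(cfg.field, base_mu)]
        if mu != 0.0:
            side = "negative" if mu > 0 else "positive"
            segments.append((half_blocked_field(cfg.field, side, axis), abs(mu)))
        name = f"asym_{axis}_{mu:+.0f}MU" if mu else f"asym_{axis}_baseline"
        out.append(Scenario(name, cfg, tuple(segments), perturb, seed + i))
    return out


def build_steering_series(
    config: Optional[BeamConfig] = None,
    tilt_magnitude: float = DEFAULT_TILT,
    perturb: PerturbSpec = DEFAULT_PERTURB,
    seed: int = 100,
) -> List[Scenario]:
    """Six scenarios: baseline, +/- crossplane, +/- inplane, and both."""
    cfg = config or study_config()
    t = tilt_magnitude
    detunes = [
        ("steer_baseline", 0.0, 0.0),
        ("steer_crossplane_pos", +t, 0.0),
        ("steer_crossplane_neg", -t, 0.0),
        ("steer_inplane_neg", 0.0, -t),
        ("steer_inplane_pos", 0.0, +t),
        ("steer_both", +t, +t),
    ]
    out: List[Scenario] = []
    for i, (name, tcp, tip) in enumerate(detunes):
        c = replace(cfg, tilt_crossplane=tcp, tilt_inplane=tip)
        out.append(Scenario(name, c, ((cfg.field, cfg.mu),), perturb, seed + i))
    return out


def build_watertank_scenarios(
    mu: float = 100.0,
    perturb: PerturbSpec = DEFAULT_PERTURB,
    seed: int = 200,
) -> List[Scenario]:
    """Symmetric 10x10 and 20x20 open fields for the PDD/profile loop."""
    out = []
    for i, side in enumerate((10.0, 20.0)):
        cfg = study_config(FieldSpec.square(side), mu=mu)
        out.append(
            Scenario(f"watertank_{side:.0f}x{side:.0f}", cfg, ((cfg.field, mu),), perturb, seed + i)
        )
    return out


def build_full_scenario_suite(
    config: Optional[BeamConfig] = None,
    perturb: PerturbSpec = DEFAULT_PERTURB,
    seed: int = 0,
) -> List[Scenario]:
    """The complete closed-loop metrics suite: 9 + 9 asymmetry + 6 steering."""
    cfg = config or study_config()
    return (
        build_asymmetry_series("crossplane", cfg, perturb=perturb, seed=seed)
        + build_asymmetry_series("inplane", cfg, perturb=perturb, seed=seed + 50)
        + build_steering_series(cfg, perturb=perturb, seed=seed + 100)
    )


@dataclass
class ScenarioRealization:
    truth_fluence: FluenceMap  # at isocenter plane
    truth_dose: Union[ArrayImage, DoseGrid3D]
    measured: EPIDImage  # raw (uncorrected) simulated measurement


def realize_scenario(
    s: Scenario,
    detector: Optional[DetectorSpec] = None,
    water_model: Optional[WaterModel] = None,
    kind: str = "array",
    array_spec: Optional[ArraySpec] = None,
    tank: Optional[TankGrid] = None,
    grid: GridSpec = DEFAULT_SCENARIO_GRID,
) -> ScenarioRealization:
    """Ground-truth fluence and dose plus a simulated raw EPID measurement."""
    det = detector or DetectorSpec()
    wm = water_model or WaterModel()
    truth = ground_truth_fluence(s, grid)
    base_field = s.segments[0][0]
    if kind == "array":
        dose: Union[ArrayImage, DoseGrid3D] = compute_array_dose(
            truth, wm, array_spec or ArraySpec(), include_contaminants=True, field=base_field
        )
    elif kind == "tank":
        dose = compute_watertank_dose(
            truth,
            wm,
            ssd_cm=s.config.ssd_cm,
            include_contaminants=True,
            field=base_field,
            tank=tank or TankGrid(),
        )
    else:
        raise ValueError("kind must be 'array' or 'tank'")
    at_epid = transport_fluence(truth, det.sdd_cm)
    measured = simulate_measured_epid(at_epid, det, s.perturb, s.seed)
    return ScenarioRealization(truth, dose, measured)
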