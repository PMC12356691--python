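"""End-to-end QA pipeline and report generation.

For every scenario the pipeline computes three sets of flatness/symmetry
metrics per axis, mirroring the three comparison methods of the study
design:

* ``raw``   — straight from the corrected (dark/sensitivity, never flood)
              EPID pixels;
* ``we``    — from the water-equivalent dose reconstructed out of the same
              measurement (virtual chamber array);
* ``truth`` — from the ground-truth water-equivalent dose of the known
              incident fluence (the synthetic stand-in for the reference
              chamber-array measurement).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .detuning_sim import Scenario, ScenarioRealization, realize_scenario
from .epid_forward import DetectorSpec, apply_pixel_corrections
from .fluence_reconstruction import ReconOptions, reconstruct_incident_fluence
from .qa_metrics import (
    QAMetrics,
    array_profile,
    compare_metrics,
    compute_qa_metrics,
    epid_profile,
)
from .water_dose import ArraySpec, TankGrid, WaterModel, compute_array_dose, compute_watertank_dose

logger = logging.getLogger(__name__)


@dataclass
class QAReport:
    rows: List[Dict] = field(default_factory=list)
    errors: List[Dict] = field(default_factory=list)
    provenance: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "rows": self.rows, "errors": self.errors},
            indent=2,
            sort_keys=True,
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def max_abs(self, column: str) -> float:
        return max(abs(r[column]) for r in self.rows)


def _scenario_fingerprint(scenarios: Sequence[Scenario]) -> str:
    payload = []
    for s in scenarios:
        d = dataclasses.asdict(s)
        payload.append(d)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(
    scenarios: Sequence[Scenario],
    detector: Optional[DetectorSpec] = None,
    water_model: Optional[WaterModel] = None,
    array_spec: Optional[ArraySpec] = None,
    recon_opts: ReconOptions = ReconOptions(),
    axes: Tuple[str, ...] = ("crossplane", "inplane"),
) -> QAReport:
    """Simulate, correct, reconstruct, convert and score every scenario."""
    det = detector or DetectorSpec()
    wm = water_model or WaterModel()
    arr = array_spec or ArraySpec()
    report = QAReport(
        provenance={
            "version": __version__,
            "n_scenarios": len(scenarios),
            "seeds": [s.seed for s in scenarios],
            "scenario_hash": _scenario_fingerprint(scenarios),
        }
    )
    for s in scenarios:
        t0 = time.perf_counter()
        try:
            rows = _run_one(s, det, wm, arr, recon_opts, axes)
        except Exception as exc:  # keep going; record the failure
            logger.exception("scenario %s failed", s.name)
            report.errors.append({"scenario": s.name, "error": f"{type(exc).__name__}: {exc}"})
            continue
        report.rows.extend(rows)
        logger.info("scenario %s done in %.2f s", s.name, time.perf_counter() - t0)
    return report


def _run_one(
    s: Scenario,
    det: DetectorSpec,
    wm: WaterModel,
    arr: ArraySpec,
    recon_opts: ReconOptions,
    axes: Tuple[str, ...],
) -> List[Dict]:
    real: ScenarioRealization = realize_scenario(s, det, wm, kind="array", array_spec=arr)
    corrected = apply_pixel_corrections(real.measured)
    recon_fluence, conv = reconstruct_incident_fluence(corrected, s.nominal_config, recon_opts)
    we_dose = compute_array_dose(
        recon_fluence, wm, arr, include_contaminants=False, field=s.segments[0][0]
    )
    rows = []
    for axis in axes:
        truth = compute_qa_metrics(array_profile(real.truth_dose, axis))
        we = compute_qa_metrics(array_profile(we_dose, axis))
        raw = compute_qa_metrics(epid_profile(corrected, axis))
        d_we = compare_metrics(we, truth)
        d_raw = compare_metrics(raw, truth)
        rows.append(
            {
                "scenario": s.name,
                "axis": axis,
                "depth_cm": arr.depth_cm,
                "flatness_truth": truth.flatness_pct,
                "flatness_we": we.flatness_pct,
                "flatness_raw": raw.flatness_pct,
                "symmetry_truth": truth.symmetry_pct,
                "symmetry_we": we.symmetry_pct,
                "symmetry_raw": raw.symmetry_pct,
                "dflatness_we": d_we.flatness_pct,
                "dsymmetry_we": d_we.symmetry_pct,
                "dflatness_raw": d_raw.flatness_pct,
                "dsymmetry_raw": d_raw.symmetry_pct,
                "recon_converged": conv.converged,
                "recon_iterations": conv.iterations_used,
                "recon_final_deviation": conv.deviations[-1],
            }
        )
    return rows


@dataclass
class TankComparison:
    """Closed-loop water-tank run: ground truth versus reconstruction."""

    scenario: str
    truth_dose: "object"
    recon_dose: "object"
    recon_converged: bool


def closed_loop_tank(
    s: Scenario,
    detector: Optional[DetectorSpec] = None,
    water_model: Optional[WaterModel] = None,
    tank: Optional[TankGrid] = None,
    recon_opts: ReconOptions = ReconOptions(),
) -> TankComparison:
    """Simulate a measurement and reconstruct the 3D virtual-tank dose.

    The ground-truth dose includes the electron-contamination surface
    term; the reconstruction-side engine omits it (the model does not
    transport contaminant electrons), so the comparison exhibits the
    expected buildup-region discrepancy.
    """
    det = detector or DetectorSpec()
    wm = water_model or WaterModel()
    tg = tank or TankGrid()
    real = realize_scenario(s, det, wm, kind="tank", tank=tg)
    corrected = apply_pixel_corrections(real.measured)
    recon_fluence, conv = reconstruct_incident_fluence(corrected, s.nominal_config, recon_opts)
    recon_dose = compute_watertank_dose(
        recon_fluence,
        wm,
        ssd_cm=s.config.ssd_cm,
        include_contaminants=False,
        field=s.segments[0][0],
        tank=tg,
    )
    return TankComparison(s.name, real.truth_dose, recon_dose, conv.converged)
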