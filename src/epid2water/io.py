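"""Plain-text file formats and configuration (de)serialization.

Grids (EPID images, fluence maps, array images) are stored as a plain
numeric matrix preceded by a ``# key: value`` metadata header — lossless,
diff-able, and free of proprietary formats.  Beam configurations round-trip
through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Tuple

import numpy as np
import yaml

from .epid_forward import CorrectionFlags, DetectorSpec, EPIDImage, PerturbSpec
from .geometry_fluence import BeamConfig, FieldSpec, FluenceMap, GridSpec
from .qa_metrics import Profile


class GridFormatError(ValueError):
    pass


def write_grid(path, values: np.ndarray, meta: Dict[str, Any]) -> None:
    """Matrix with a ``# key: value`` header; floats at full precision."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        np.savetxt(fh, np.asarray(values), fmt="%.10g")


def read_grid(path) -> Tuple[np.ndarray, Dict[str, Any]]:
    path = Path(path)
    meta: Dict[str, Any] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            data_start = lineno - 1
            break
        body = line[1:].strip()
        if ":" not in body:
            raise GridFormatError(f"{path}:{lineno}: malformed header line {line.strip()!r}")
        key, _, val = body.partition(":")
        try:
            meta[key.strip()] = json.loads(val.strip())
        except json.JSONDecodeError as exc:
            raise GridFormatError(f"{path}:{lineno}: unparseable value {val.strip()!r}") from exc
    else:
        raise GridFormatError(f"{path}: no data rows found")
    values = np.loadtxt(lines[data_start:], ndmin=2)
    return values, meta


def require_keys(meta: Dict[str, Any], keys, path="grid") -> None:
    missing = [k for k in keys if k not in meta]
    if missing:
        raise GridFormatError(f"{path}: missing required metadata keys {missing}")


def write_fluence(path, f: FluenceMap) -> None:
    write_grid(
        path,
        f.values,
        {
            "kind": "fluence",
            "spacing_mm": f.grid.spacing_mm,
            "half_extent_mm": f.grid.half_extent_mm,
            "plane_distance_cm": f.grid.plane_distance_cm,
        },
    )


def read_fluence(path) -> FluenceMap:
    values, meta = read_grid(path)
    require_keys(meta, ["spacing_mm", "half_extent_mm", "plane_distance_cm"], path)
    grid = GridSpec(meta["spacing_mm"], meta["half_extent_mm"], meta["plane_distance_cm"])
    return FluenceMap(values, grid)


def write_epid_image(path, img: EPIDImage) -> None:
    det = img.detector
    flags = img.corrections_applied
    write_grid(
        path,
        img.pixels,
        {
            "kind": "epid_image",
            "pixel_pitch_mm": det.pixel_pitch_mm,
            "n_pixels": det.n_pixels,
            "sdd_cm": det.sdd_cm,
            "corrected_dark": flags.dark,
            "corrected_sensitivity": flags.sensitivity,
            "corrected_flood": flags.flood,
        },
    )


def read_epid_image(path, detector: DetectorSpec | None = None) -> EPIDImage:
    """Read an EPID image; kernel/response come from ``detector`` (default spec)."""
    values, meta = read_grid(path)
    require_keys(meta, ["pixel_pitch_mm", "n_pixels", "sdd_cm"], path)
    base = detector or DetectorSpec(
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        n_pixels=int(meta["n_pixels"]),
        sdd_cm=meta["sdd_cm"],
    )
    flags = CorrectionFlags(
        dark=bool(meta.get("corrected_dark", False)),
        sensitivity=bool(meta.get("corrected_sensitivity", False)),
        flood=bool(meta.get("corrected_flood", False)),
    )
    return EPIDImage(values, base, flags)


def profile_to_csv(path, p: Profile) -> None:
    import pandas as pd

    pd.DataFrame({"position_mm": p.positions_mm, "value": p.values}).to_csv(path, index=False)


def profile_from_csv(path, axis_label: str = "crossplane") -> Profile:
    import pandas as pd

    df = pd.read_csv(path)
    return Profile(df["position_mm"].to_numpy(), df["value"].to_numpy(), axis_label)


# --- beam configuration ----------------------------------------------------

def config_to_dict(config: BeamConfig) -> Dict[str, Any]:
    d = dataclasses.asdict(config)
    d["field"] = dataclasses.asdict(config.field)
    d["horn_coeffs"] = list(config.horn_coeffs)
    return d


def config_from_dict(d: Dict[str, Any]) -> BeamConfig:
    d = dict(d)
    fld = d.pop("field")
    return BeamConfig(field=FieldSpec(**fld), **{**d, "horn_coeffs": tuple(d.pop("horn_coeffs", ()))})


def write_beam_config(path, config: BeamConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_beam_config(path) -> BeamConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def perturb_to_dict(p: PerturbSpec) -> Dict[str, Any]:
    d = dataclasses.asdict(p)
    d["overresponse_coeffs"] = list(p.overresponse_coeffs)
    return d


def perturb_from_dict(d: Dict[str, Any]) -> PerturbSpec:
    d = dict(d)
    return PerturbSpec(
        kernel_sigma_scale=d.get("kernel_sigma_scale", 1.0),
        overresponse_coeffs=tuple(d.get("overresponse_coeffs", ())),
        noise_frac=d.get("noise_frac", 0.0),
    )
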