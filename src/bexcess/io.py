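"""Observation CSV dialect, design JSON, and calibration report output.

CSV dialect: comma-separated UTF-8 with a header row; columns
``study_id, subject_id, exposure_id, pco2_mmhg, ph, hco3_mmol_l`` (the
last optional/blank -> derived from pH and PCO2).  Units are suffixed in
the column names so a file can never be mis-read in kPa.

Reports are schema-versioned JSON with a config echo (seed, grid, level)
and a plain-text summary; both are byte-stable for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_CONSTANTS, AcidBaseConstants, hco3_from_ph_pco2
from .simulate import OBSERVATION_COLUMNS, StudyDesign, TitrationDataset

__all__ = [
    "SchemaError",
    "read_observations",
    "write_observations",
    "read_designs",
    "write_designs",
    "write_report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["study_id", "subject_id", "exposure_id", "pco2_mmhg", "ph"]
REPORT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """The input file does not match the observation CSV dialect."""


def read_observations(
    path: str | Path,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> TitrationDataset:
    """Load and validate an observation CSV.

    Rows outside the plausibility bounds (pH, PCO2, or non-positive HCO3)
    are rejected with one WARNING log line each plus a summary count.
    Missing bicarbonate is derived via Henderson-Hasselbalch; a measured
    value disagreeing with the derived one by more than the consistency
    tolerance is kept but logged.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise SchemaError(f"{path}: no observation rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "hco3_mmol_l" not in frame.columns:
        frame["hco3_mmol_l"] = np.nan

    ph = frame["ph"].to_numpy(dtype=float)
    pco2 = frame["pco2_mmhg"].to_numpy(dtype=float)
    hco3 = frame["hco3_mmol_l"].to_numpy(dtype=float)
    ph_lo, ph_hi = constants.ph_bounds
    p_lo, p_hi = constants.pco2_bounds
    ok = (
        np.isfinite(ph)
        & np.isfinite(pco2)
        & (ph >= ph_lo)
        & (ph <= ph_hi)
        & (pco2 >= p_lo)
        & (pco2 <= p_hi)
        & (np.isnan(hco3) | (hco3 > 0))
    )
    for i in np.flatnonzero(~ok):
        logger.warning(
            "%s row %d rejected: ph=%s pco2=%s hco3=%s outside plausibility "
            "bounds",
            path.name,
            i,
            frame["ph"].iloc[i],
            frame["pco2_mmhg"].iloc[i],
            frame["hco3_mmol_l"].iloc[i],
        )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path.name, n_rejected, len(ok))
    frame = frame.loc[ok].reset_index(drop=True)
    if frame.empty:
        raise SchemaError(f"{path}: all rows rejected by plausibility bounds")

    absent = frame["hco3_mmol_l"].isna()
    if absent.any():
        frame.loc[absent, "hco3_mmol_l"] = hco3_from_ph_pco2(
            frame.loc[absent, "ph"].to_numpy(dtype=float),
            frame.loc[absent, "pco2_mmhg"].to_numpy(dtype=float),
            constants,
        )
    present = ~absent
    if present.any():
        derived = hco3_from_ph_pco2(
            frame.loc[present, "ph"].to_numpy(dtype=float),
            frame.loc[present, "pco2_mmhg"].to_numpy(dtype=float),
            constants,
        )
        gap = np.abs(frame.loc[present, "hco3_mmol_l"].to_numpy(dtype=float) - derived)
        n_inconsistent = int((gap > constants.hco3_consistency_tol).sum())
        if n_inconsistent:
            logger.warning(
                "%s: %d measured hco3 values differ from pH/PCO2-derived by "
                "> %.1f mmol/L; measured values kept",
                path.name,
                n_inconsistent,
                constants.hco3_consistency_tol,
            )
    for col in ("study_id", "subject_id", "exposure_id"):
        frame[col] = frame[col].astype(str)
    frame = frame[OBSERVATION_COLUMNS]
    return TitrationDataset(frame, constants=constants)


def write_observations(dataset: TitrationDataset, path: str | Path) -> None:
    """Write the observation table in the package CSV dialect.

    Uses repr-precision floats so a CSV -> dataset -> CSV round trip
    preserves every value exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.frame[OBSERVATION_COLUMNS].to_csv(path, index=False, float_format=None)
    if dataset.designs:
        write_designs(dataset.designs, path.with_suffix(".designs.json"),
                      seed=dataset.seed)


def write_designs(
    designs: Sequence[StudyDesign], path: str | Path, seed: int | None = None
) -> None:
    """Provenance sidecar: the generating designs and master seed as JSON."""
    payload = {
        "seed": seed,
        "designs": [dataclasses.asdict(d) for d in designs],
    }
    Path(path).write_text(_dumps(payload))


def read_designs(path: str | Path) -> list[StudyDesign]:
    raw = json.loads(Path(path).read_text())
    items = raw["designs"] if isinstance(raw, dict) else raw
    designs = []
    for item in items:
        if "pco2_levels" in item:
            item = {**item, "pco2_levels": tuple(item["pco2_levels"])}
        designs.append(StudyDesign(**item))
    return designs


def _sanitize(obj: Any) -> Any:
    """Make numpy/dataclass content JSON-serializable, NaN -> None."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _sanitize(obj.to_dict())
        return _sanitize(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _sanitize(obj.to_dict(orient="records"))
    return obj


def _dumps(payload: Any) -> str:
    return json.dumps(_sanitize(payload), indent=2, sort_keys=True) + "\n"


def _fmt_ci(lo, hi) -> str:
    if lo is None or hi is None or not np.all(np.isfinite([lo, hi])):
        return "(CI degenerate)"
    return f"(95% CI {lo:.3f} to {hi:.3f})"


def write_report(results: dict, path: str | Path) -> Path:
    """Write the calibration report JSON plus a plain-text summary.

    ``results`` maps section names ("per_study_fits", "ancova", "sweep",
    "deltas", "config") to result objects or plain dicts; every numeric
    field round-trips through the JSON.  Returns the JSON path; the text
    summary sits alongside with suffix ``.txt``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    payload.update(results)
    text = _dumps(payload)
    path.write_text(text)

    lines = ["bexcess calibration report", "=" * 27]
    clean = _sanitize(payload)
    fits = clean.get("per_study_fits", {})
    for sid, fit in fits.items():
        lines.append(
            f"study {sid}: slope {fit['slope']:+.4f} mmol/L per mmHg "
            f"{_fmt_ci(fit['ci_low'], fit['ci_high'])}, p={fit['p_value']:.4g}, "
            f"n={fit['n']}"
        )
    anc = clean.get("ancova")
    if anc:
        lines.append(
            f"ANCOVA: intercepts F={anc['intercept_f']:.2f} "
            f"p={anc['intercept_p']:.4g}; slopes (interaction) "
            f"F={anc['slope_f']:.2f} p={anc['slope_p']:.4g}"
        )
    sweep = clean.get("sweep")
    if sweep:
        lines.append(
            f"beta sweep: beta* = {sweep['beta_star']:.4f} "
            f"{_fmt_ci(sweep['ci_low'], sweep['ci_high'])} "
            f"[analytic -a/b = {sweep['beta_analytic']:.4f}]"
        )
    deltas = clean.get("deltas")
    if deltas:
        lines.append(
            f"per-subject SBE deltas: cohort range {deltas['cohort_min']:+.2f} "
            f"to {deltas['cohort_max']:+.2f} mmol/L over "
            f"{deltas['n_subjects']} subjects"
        )
    cfg = clean.get("config")
    if cfg:
        lines.append(f"config: {json.dumps(cfg, sort_keys=True)}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path
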