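"""File formats: count-table CSV, curve JSON, submissions, references, reports.

All formats are plain text, comma-delimited with "." as the decimal mark
and UTF-8 encoded, independent of the process locale.  The count table is
the wide dicentric-distribution layout conventional in cytogenetic
reporting: one row per sample with columns ``c0, c1, ...`` counting the
cells that carry 0, 1, ... dicentrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .counts import AberrationDistribution, DoseDefinition, ScoringMode
from .errors import ValidationError
from .fitting import CalibrationCurve
from .ilc import ILCReport, LabSubmission, ReferenceDose
from .simulate import GroundTruth

logger = logging.getLogger("dicentric")


def _json_default(obj):
    """Coerce numpy scalars so serialization never depends on caller types."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


# -- count tables -------------------------------------------------------------


def write_count_table(
    distributions: list[AberrationDistribution], path: str | Path
) -> None:
    """Write distributions as a wide count-table CSV (c0 ... c_kmax)."""
    path = Path(path)
    kmax = max((max(d.counts) for d in distributions), default=0)
    rows = []
    for d in distributions:
        row: dict[str, object] = {}
        if d.sample_id is not None:
            row["sample_id"] = d.sample_id
        row["dose"] = "" if d.dose is None else d.dose
        row["n_cells"] = d.n_cells
        spectrum = d.spectrum()
        for k in range(kmax + 1):
            row[f"c{k}"] = int(spectrum[k]) if k < len(spectrum) else 0
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_table(path: str | Path) -> list[AberrationDistribution]:
    """Parse a count-table CSV, validating every row's invariants.

    Violations (``sum c_k != n_cells``, negative counts) are reported
    with the 1-based data-row number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("count table %s is empty", path)
        return []
    if frame.empty:
        logger.warning("count table %s has no data rows", path)
        return []
    count_cols = sorted(
        (c for c in frame.columns if c.startswith("c") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if "n_cells" not in frame.columns or not count_cols:
        raise ValidationError(
            f"{path}: count table needs an 'n_cells' column and c0, c1, ... columns"
        )
    out: list[AberrationDistribution] = []
    for idx, row in frame.iterrows():
        rowno = int(idx) + 1
        counts = {}
        for col in count_cols:
            value = row[col]
            c = 0 if pd.isna(value) else int(value)
            if c < 0:
                raise ValidationError(f"{path}: negative count in data row {rowno}")
            counts[int(col[1:])] = c
        n_declared = int(row["n_cells"])
        if sum(counts.values()) != n_declared:
            raise ValidationError(
                f"{path}: data row {rowno}: counts sum to "
                f"{sum(counts.values())} but n_cells = {n_declared}"
            )
        dose = None
        if "dose" in frame.columns and not pd.isna(row["dose"]):
            dose = float(row["dose"])
        sample_id = None
        if "sample_id" in frame.columns and not pd.isna(row["sample_id"]):
            sample_id = str(row["sample_id"])
        out.append(
            AberrationDistribution(counts=counts, dose=dose, sample_id=sample_id)
        )
    return out


# -- curves -------------------------------------------------------------------


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    payload = {
        "background": curve.background,
        "alpha": curve.alpha,
        "beta": curve.beta,
        "covariance": None
        if curve.covariance is None
        else [float(v) for v in np.asarray(curve.covariance).ravel()],
        "dose_definition": curve.dose_definition.value,
        "scoring_mode": curve.scoring_mode.value,
        "max_calibration_dose": curve.max_calibration_dose,
        "n_dose_points": curve.n_dose_points,
        "deviance": curve.deviance,
        "df": curve.df,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default), encoding="utf-8")


def read_curve(path: str | Path) -> CalibrationCurve:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    cov = payload.get("covariance")
    if cov is not None:
        cov = np.array(cov, dtype=float).reshape(3, 3)
    return CalibrationCurve(
        background=payload["background"],
        alpha=payload["alpha"],
        beta=payload["beta"],
        covariance=cov,
        dose_definition=DoseDefinition(payload["dose_definition"]),
        scoring_mode=ScoringMode(payload["scoring_mode"]),
        max_calibration_dose=payload["max_calibration_dose"],
        n_dose_points=payload.get("n_dose_points"),
        deviance=payload.get("deviance"),
        df=payload.get("df"),
    )


# -- submissions and references ----------------------------------------------

_SUBMISSION_COLUMNS = [
    "lab_id",
    "sample_id",
    "scoring_mode",
    "dose_estimate",
    "ci_low",
    "ci_high",
    "dose_definition",
    "n_cells",
    "n_dicentrics",
]


def write_submissions(submissions: list[LabSubmission], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "lab_id": s.lab_id,
                "sample_id": s.sample_id,
                "scoring_mode": s.scoring_mode.value,
                "dose_estimate": s.dose_estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "dose_definition": s.dose_definition.value,
                "n_cells": s.n_cells,
                "n_dicentrics": s.n_dicentrics,
            }
            for s in submissions
        ],
        columns=_SUBMISSION_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_submissions(path: str | Path) -> list[LabSubmission]:
    frame = pd.read_csv(path)
    missing = set(_SUBMISSION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        LabSubmission(
            lab_id=str(row.lab_id),
            sample_id=str(row.sample_id),
            scoring_mode=ScoringMode(row.scoring_mode),
            dose_estimate=float(row.dose_estimate),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
            dose_definition=DoseDefinition(row.dose_definition),
            n_cells=int(row.n_cells),
            n_dicentrics=int(row.n_dicentrics),
        )
        for row in frame.itertuples()
    ]


def write_references(references: list[ReferenceDose], path: str | Path) -> None:
    payload = [
        {
            "sample_id": r.sample_id,
            "air_kerma": r.air_kerma,
            "dose_to_blood": r.dose_to_blood,
        }
        for r in references
    ]
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default), encoding="utf-8")


def read_references(path: str | Path) -> list[ReferenceDose]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [ReferenceDose(**entry) for entry in payload]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "samples": [
            {"sample_id": sid, "air_kerma": kerma, "dose_to_blood": blood}
            for sid, kerma, blood in truth.samples
        ],
        "labs": {
            lab_id: {
                "alpha": p.alpha,
                "beta": p.beta,
                "background": p.background,
                "dose_definition": p.dose_definition.value,
                "scoring_mode": p.scoring_mode.value,
                "cells_per_blind_sample": p.cells_per_blind_sample,
                "calibration_doses": list(p.calibration_doses),
                "cells_per_calibration_dose": list(p.cells_per_calibration_dose),
                "dispersion": p.dispersion,
                "bias_factor": p.bias_factor,
            }
            for lab_id, p in truth.profiles.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default), encoding="utf-8")


# -- reports ------------------------------------------------------------------


def write_report(report: ILCReport, path: str | Path, format: str = "json") -> None:
    """Write an ILC report as JSON (round-trippable) or as flat CSV rows."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=_json_default), encoding="utf-8"
        )
    elif format == "csv":
        lab_info = {s.lab_id: s for s in report.lab_summaries}
        rows = []
        for rec in report.records:
            summary = lab_info[rec.lab_id]
            row = {
                "lab_id": rec.lab_id,
                "sample_id": rec.sample_id,
                "scoring_mode": rec.scoring_mode,
                "dose_estimate": rec.dose_estimate,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "reference": rec.reference,
                "deviation": rec.deviation,
                "z_score": rec.z_score,
                "z_flag": rec.z_flag,
                "ci_contains_reference": rec.ci_contains_reference,
                "triage_category": rec.triage_category,
                "within_band": rec.within_band,
                "bias_class": summary.bias_class,
                "ranking_correct": summary.ranking_correct,
            }
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> ILCReport:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return ILCReport.from_dict(payload)


# -- run manifest -------------------------------------------------------------


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seed: int | None,
    inputs: list[str] | None = None,
) -> Path:
    """Record the resolved configuration, seed and package version of a run."""
    out_dir = Path(out_dir)
    config_text = json.dumps(config, sort_keys=True)
    manifest = {
        "package": "dicentric",
        "version": __version__,
        "seed": seed,
        "inputs": sorted(inputs or []),
        "config": config,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default), encoding="utf-8")
    return path
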