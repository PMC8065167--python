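"""File formats: geometry JSON, cohort/metrics CSV, and run configuration.

Geometry travels as a schema-versioned JSON document (human-diffable, fully
validated on read); tabular outputs are CSV; configuration is YAML. OS eyes
are mirrored into the internal OD frame exactly once on read, with the
transformation recorded on the returned objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pydantic
import yaml
from pydantic import BaseModel, Field

from .containers import CircleScanProfile, RadialScan, RadialScanSet
from .synthetic import CohortSpec

__all__ = [
    "SCHEMA_VERSION",
    "GeometryDocument",
    "SchemaError",
    "read_geometry",
    "write_geometry",
    "RunConfig",
    "load_run_config",
    "load_cohort_spec",
]

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """Geometry document failed schema validation."""


class _ScanModel(BaseModel):
    scan_angle_deg: float
    bmo: list[list[float]] = Field(min_length=2, max_length=2)
    bmb: list[list[float]] = Field(min_length=2, max_length=2)
    ilm: list[list[float]] = Field(min_length=2)


class _CircleModel(BaseModel):
    diameter_mm: float = 3.5
    angle_deg: list[float]
    ilm: list[float]
    rnfl_posterior: list[float]
    bm_posterior: list[float]
    choroid_posterior: list[float]


class _EyeMeta(BaseModel):
    eye_id: str
    patient_id: Optional[str] = None
    laterality: Literal["OD", "OS"]
    fobmo_deg: float
    quality_score_db: float
    normalized: bool = False


class GeometryDocument(BaseModel):
    """Schema-versioned geometry interchange document for one eye."""

    schema_version: str
    units: dict[str, str] = Field(default_factory=lambda: {"length": "um", "angle": "deg"})
    eye: _EyeMeta
    radial_scans: list[_ScanModel]
    circle_scan: Optional[_CircleModel] = None

    @pydantic.model_validator(mode="after")
    def _check_version(self) -> "GeometryDocument":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unknown schema_version {self.schema_version!r}; expected {SCHEMA_VERSION!r}"
            )
        return self


def write_geometry(
    path: str | Path,
    scans: RadialScanSet,
    profile: CircleScanProfile | None = None,
    patient_id: str | None = None,
) -> None:
    """Serialize one eye's geometry to the JSON interchange schema."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": {"length": "um", "angle": "deg"},
        "eye": {
            "eye_id": scans.eye_id,
            "patient_id": patient_id,
            "laterality": scans.laterality,
            "fobmo_deg": scans.fobmo_deg,
            "quality_score_db": scans.quality_score_db,
            "normalized": scans.normalized,
        },
        "radial_scans": [
            {
                "scan_angle_deg": s.scan_angle_deg,
                "bmo": s.bmo_points.tolist(),
                "bmb": s.bmb_points.tolist(),
                "ilm": s.ilm_curve.tolist(),
            }
            for s in scans.scans
        ],
    }
    if profile is not None:
        doc["circle_scan"] = {
            "diameter_mm": profile.diameter_mm,
            "angle_deg": profile.angle_deg.tolist(),
            "ilm": profile.ilm.tolist(),
            "rnfl_posterior": profile.rnfl_posterior.tolist(),
            "bm_posterior": profile.bm_posterior.tolist(),
            "choroid_posterior": profile.choroid_posterior.tolist(),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_geometry(
    path: str | Path, normalize: bool = True
) -> tuple[RadialScanSet, CircleScanProfile | None]:
    """Read and validate a geometry document.

    Schema violations raise :class:`SchemaError` naming the offending JSON
    location; container-invariant violations raise the containers' typed
    :class:`~onhmorph.containers.ValidationError`. With ``normalize=True``
    (default) OS eyes are mirrored into the internal OD frame exactly once
    (the document's ``normalized`` flag guards idempotence).
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid JSON ({err})") from err
    try:
        doc = GeometryDocument.model_validate(raw)
    except pydantic.ValidationError as err:
        first = err.errors()[0]
        pointer = "/" + "/".join(str(part) for part in first["loc"])
        raise SchemaError(f"{path}: schema violation at {pointer}: {first['msg']}") from err

    scans = RadialScanSet(
        eye_id=doc.eye.eye_id,
        laterality=doc.eye.laterality,
        fobmo_deg=doc.eye.fobmo_deg,
        scans=tuple(
            RadialScan(
                scan_angle_deg=s.scan_angle_deg,
                bmo_points=np.asarray(s.bmo),
                bmb_points=np.asarray(s.bmb),
                ilm_curve=np.asarray(s.ilm),
            )
            for s in doc.radial_scans
        ),
        quality_score_db=doc.eye.quality_score_db,
        normalized=doc.eye.normalized,
    )
    profile = None
    if doc.circle_scan is not None:
        c = doc.circle_scan
        profile = CircleScanProfile(
            eye_id=doc.eye.eye_id,
            laterality=doc.eye.laterality,
            fobmo_deg=doc.eye.fobmo_deg,
            angle_deg=np.asarray(c.angle_deg),
            ilm=np.asarray(c.ilm),
            rnfl_posterior=np.asarray(c.rnfl_posterior),
            bm_posterior=np.asarray(c.bm_posterior),
            choroid_posterior=np.asarray(c.choroid_posterior),
            quality_score_db=doc.eye.quality_score_db,
            diameter_mm=c.diameter_mm,
            normalized=doc.eye.normalized,
        )
    if normalize:
        scans = scans.to_od_frame()
        profile = profile.to_od_frame() if profile is not None else None
    return scans, profile


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (YAML-loadable)."""

    seed: int = 0
    cohort_spec: Optional[str] = None  # YAML path; None uses the built-in default
    quality_threshold_db: float = 15.0
    sector_map: Literal["garway-heath"] = "garway-heath"
    pct_mode: Literal["normal", "axial"] = "normal"
    crossval_ring_um: Optional[float] = 1700.0
    out_dir: str = "onhmorph_out"

    @pydantic.model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not np.isfinite(self.quality_threshold_db):
            raise ValueError("quality_threshold_db must be finite")
        if self.cohort_spec is not None and not Path(self.cohort_spec).exists():
            raise ValueError(f"cohort_spec path not found: {self.cohort_spec}")
        return self


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    data = yaml.safe_load(Path(path).read_text())
    return CohortSpec.model_validate(data)


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.model_dump(mode="json"), sort_keys=False))
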