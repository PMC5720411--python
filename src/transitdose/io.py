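"""Plain-text I/O for slices, profiles, calibration data and models.

Formats are deliberately simple and diff-friendly:

* density slices — a text grid with a ``#``-prefixed header carrying the
  shape, spacing and origin;
* transit and dose profiles — CSV with a ``#``-prefixed key:value
  metadata block;
* calibration samples and QA records — headered CSV (pandas);
* calibration models and beam configs — YAML with a schema version.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSample, CorrelationModel, ScatterModel
from .geometry import BeamGeometry, PhantomSlice
from .qa import QASessionRecord
from .reconstruction import DoseProfile, TransitProfile

__all__ = [
    "read_slice", "write_slice",
    "read_transit_profile", "write_transit_profile",
    "write_dose_profile",
    "read_calibration_samples", "write_calibration_samples",
    "read_models", "write_models",
    "read_beam_config", "write_beam_config",
    "read_qa_records", "write_qa_records",
]

SCHEMA_VERSION = 1

_CALIB_COLUMNS = ["w_cm", "st_cu", "dm_gy", "wedge_deg", "field_cm", "r_cm", "d_cm"]


# -- density slices ---------------------------------------------------------

def write_slice(path: str | Path, slice_: PhantomSlice) -> None:
    ny, nx = slice_.grid.shape
    header = (
        f"rows {ny}\ncols {nx}\nspacing_cm {slice_.spacing!r}\n"
        f"origin_cm {slice_.origin[0]!r} {slice_.origin[1]!r}\n"
        f"body_threshold {slice_.body_threshold!r}"
    )
    np.savetxt(path, slice_.grid, fmt="%.6g", header=header)


def read_slice(path: str | Path) -> PhantomSlice:
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts:
                meta[parts[0]] = parts[1:]
    grid = np.loadtxt(path)
    return PhantomSlice(
        grid=grid,
        spacing=float(meta["spacing_cm"][0]),
        origin=(float(meta["origin_cm"][0]), float(meta["origin_cm"][1])),
        body_threshold=float(meta.get("body_threshold", ["0.05"])[0]),
    )


# -- transit / dose profiles ------------------------------------------------

def _write_csv_with_meta(path: str | Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_meta_block(path: str | Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            value = value.strip()
            try:
                meta[key.strip()] = float(value)
            except ValueError:
                meta[key.strip()] = value
    return meta


def write_transit_profile(path: str | Path, profile: TransitProfile) -> None:
    df = pd.DataFrame(
        {"position_cm": profile.positions, "signal_cu": profile.signals}
    )
    _write_csv_with_meta(path, df, profile.meta)


def read_transit_profile(path: str | Path) -> TransitProfile:
    meta = _read_meta_block(path)
    df = pd.read_csv(path, comment="#")
    return TransitProfile(
        positions=df["position_cm"].to_numpy(),
        signals=df["signal_cu"].to_numpy(),
        meta=meta,
    )


def write_dose_profile(path: str | Path, profile: DoseProfile) -> None:
    df = pd.DataFrame(
        {
            "position_cm": profile.positions,
            "dose_gy": profile.dose,
            "c_factor": profile.c_factor,
            "excluded": profile.excluded.astype(int),
            "reason": profile.exclusion_reason,
        }
    )
    _write_csv_with_meta(path, df, profile.meta)


# -- calibration samples ----------------------------------------------------

def write_calibration_samples(
    path: str | Path, samples: list[CalibrationSample]
) -> None:
    df = pd.DataFrame(
        [
            (s.w, s.st, s.dm, s.wedge, s.field_length, s.r, s.d)
            for s in samples
        ],
        columns=_CALIB_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_calibration_samples(path: str | Path) -> list[CalibrationSample]:
    df = pd.read_csv(path)
    return [
        CalibrationSample(
            w=row.w_cm, st=row.st_cu, dm=row.dm_gy, wedge=row.wedge_deg,
            field_length=row.field_cm, r=row.r_cm, d=row.d_cm,
        )
        for row in df.itertuples()
    ]


# -- models and beam configuration ------------------------------------------

def write_models(
    path: str | Path, corr: CorrelationModel, scat: ScatterModel
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "correlation": {
            "a1": float(corr.a1), "a2": float(corr.a2), "a3": float(corr.a3),
            "valid_w_cm": [float(v) for v in corr.valid_w],
            "fit_residual_2sd_percent": corr.fit_residual_2sd,
        },
        "scatter": {
            "radii_cm": [float(v) for v in scat.radii],
            "f0_per_cm": [float(v) for v in scat.f0],
            "valid_d_cm": [float(v) for v in scat.valid_d],
            "fit_residual_2sd_percent": scat.fit_residual_2sd,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_models(path: str | Path) -> tuple[CorrelationModel, ScatterModel]:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    c, s = doc["correlation"], doc["scatter"]
    return (
        CorrelationModel(
            a1=c["a1"], a2=c["a2"], a3=c["a3"],
            valid_w=tuple(c["valid_w_cm"]),
            fit_residual_2sd=c.get("fit_residual_2sd_percent"),
        ),
        ScatterModel(
            radii=tuple(s["radii_cm"]), f0=tuple(s["f0_per_cm"]),
            valid_d=tuple(s["valid_d_cm"]),
            fit_residual_2sd=s.get("fit_residual_2sd_percent"),
        ),
    )


def write_beam_config(path: str | Path, beam: BeamGeometry) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "sad_cm": beam.sad, "sed_cm": beam.sed,
        "field_length_cm": beam.field_length,
        "field_width_cm": beam.field_width,
        "wedge_angle_deg": beam.wedge_angle, "gantry_deg": beam.gantry,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_beam_config(path: str | Path) -> BeamGeometry:
    doc = yaml.safe_load(Path(path).read_text())
    return BeamGeometry(
        sad=doc.get("sad_cm", 100.0), sed=doc.get("sed_cm", 150.0),
        field_length=doc.get("field_length_cm", 20.0),
        field_width=doc.get("field_width_cm", 20.0),
        wedge_angle=doc.get("wedge_angle_deg", 0.0),
        gantry=doc.get("gantry_deg", 90.0),
    )


# -- QA records --------------------------------------------------------------

def write_qa_records(path: str | Path, records: list[QASessionRecord]) -> None:
    df = pd.DataFrame(
        [
            (r.session_id, r.field_id, r.dm, r.dm_tps, r.ratio_r, r.shift_s)
            for r in records
        ],
        columns=["session_id", "field_id", "dm_gy", "dm_tps_gy", "ratio_r",
                 "shift_cm"],
    )
    df.to_csv(path, index=False)


def read_qa_records(path: str | Path) -> list[QASessionRecord]:
    df = pd.read_csv(path)
    return [
        QASessionRecord(
            session_id=str(row.session_id), field_id=str(row.field_id),
            dm=row.dm_gy, dm_tps=row.dm_tps_gy,
            shift_s=getattr(row, "shift_cm", 0.0),
        )
        for row in df.itertuples()
    ]
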