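"""Reading and writing gaze recordings, ground-truth tables and manifests.

File dialects
-------------
Gaze recordings are comma-delimited text with a ``t,x,y`` header and an
optional ``valid`` column; timestamps are seconds, positions either pixels or
degrees of visual angle.  Which unit a file uses, and the screen geometry
needed to convert pixels to degrees, live in a YAML manifest next to the data
rather than in the data file itself.

Ground truth is one CSV row per session keyed by ``participant_id`` and
``session_id``; empty cells are explicit absences.

All readers validate and reject malformed rows (duplicate timestamps,
missing columns) with the offending row named — they never coerce silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import GazeDataError, GazeRecording, InvalidParameterError, ScreenGeometry
from .study import CrtResult, SessionGroundTruth

GAZE_COLUMNS = ("t", "x", "y")

GROUND_TRUTH_COLUMNS = (
    "participant_id",
    "session_id",
    "au",
    "crt_pre_mean",
    "crt_pre_sd",
    "crt_pre_errors",
    "crt_post_mean",
    "crt_post_sd",
    "crt_post_errors",
    "vasf_fatigue",
    "vasf_energy",
)


@dataclass(frozen=True)
class GazeFormat:
    """Dialect of a gaze file: column names and position units."""

    t_col: str = "t"
    x_col: str = "x"
    y_col: str = "y"
    valid_col: str | None = "valid"
    units: str = "deg"  # "deg" or "px"
    geometry: ScreenGeometry | None = None

    def __post_init__(self) -> None:
        if self.units not in ("deg", "px"):
            raise InvalidParameterError(f"unknown position units {self.units!r}")
        if self.units == "px" and self.geometry is None:
            raise InvalidParameterError("pixel units require a ScreenGeometry")


def pixels_to_degrees(
    x_px: np.ndarray | float, y_px: np.ndarray | float, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Convert pixel coordinates to per-axis visual angle about screen center.

    Each axis is converted independently as
    ``deg = atan(offset_mm / viewing_distance_mm) * 180 / pi``,
    with the offset measured from the screen center.  The arctangent form is
    exact at wide angles where the small-angle approximation drifts.
    """
    if geom.viewing_distance_mm <= 0:
        raise InvalidParameterError("viewing distance must be positive")
    x_mm = (np.asarray(x_px, dtype=float) - geom.width_px / 2.0) * (
        geom.width_mm / geom.width_px
    )
    y_mm = (np.asarray(y_px, dtype=float) - geom.height_px / 2.0) * (
        geom.height_mm / geom.height_px
    )
    x_deg = np.degrees(np.arctan2(x_mm, geom.viewing_distance_mm))
    y_deg = np.degrees(np.arctan2(y_mm, geom.viewing_distance_mm))
    return x_deg, y_deg


def degrees_to_pixels(
    x_deg: np.ndarray | float, y_deg: np.ndarray | float, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pixels_to_degrees` (exact within screen bounds)."""
    if geom.viewing_distance_mm <= 0:
        raise InvalidParameterError("viewing distance must be positive")
    x_mm = np.tan(np.radians(np.asarray(x_deg, float))) * geom.viewing_distance_mm
    y_mm = np.tan(np.radians(np.asarray(y_deg, float))) * geom.viewing_distance_mm
    x_px = x_mm / (geom.width_mm / geom.width_px) + geom.width_px / 2.0
    y_px = y_mm / (geom.height_mm / geom.height_px) + geom.height_px / 2.0
    return x_px, y_px


def read_gaze(path: str | Path, fmt: GazeFormat | None = None) -> GazeRecording:
    """Read a delimited gaze file into a validated :class:`GazeRecording`.

    Rows with non-finite coordinates are marked invalid, not dropped, so gap
    durations stay observable.  Duplicate or decreasing timestamps raise a
    :class:`GazeDataError` naming the offending row.
    """
    fmt = fmt or GazeFormat()
    path = Path(path)
    df = pd.read_csv(path)
    for col in (fmt.t_col, fmt.x_col, fmt.y_col):
        if col not in df.columns:
            raise GazeDataError(f"{path.name}: missing column {col!r}")
    t = df[fmt.t_col].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise GazeDataError(
                f"{path.name}: timestamps not strictly increasing at row {bad[0] + 1}"
            )
    x = df[fmt.x_col].to_numpy(dtype=float)
    y = df[fmt.y_col].to_numpy(dtype=float)
    if fmt.units == "px":
        x, y = pixels_to_degrees(x, y, fmt.geometry)
    valid = None
    if fmt.valid_col is not None and fmt.valid_col in df.columns:
        valid = df[fmt.valid_col].to_numpy(dtype=bool)
    return GazeRecording(t=t, x=x, y=y, valid=valid, meta={"source": str(path)})


def write_gaze(rec: GazeRecording, path: str | Path) -> None:
    """Write a recording as ``t,x,y,valid`` CSV (always degree units)."""
    df = pd.DataFrame(
        {"t": rec.t, "x": rec.x, "y": rec.y, "valid": rec.valid.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def _opt_float(row, col) -> float | None:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _crt(row, prefix: str) -> CrtResult | None:
    mean = _opt_float(row, f"{prefix}_mean")
    if mean is None:
        return None
    sd = _opt_float(row, f"{prefix}_sd") or 0.0
    errs = _opt_float(row, f"{prefix}_errors") or 0.0
    return CrtResult(mean_rt=mean, sd_rt=sd, n_errors=int(errs))


def read_ground_truth(path: str | Path) -> list[SessionGroundTruth]:
    """Read a per-session ground-truth CSV.

    Missing cells are preserved as ``None`` on the record; a duplicated
    (participant_id, session_id) key is a :class:`GazeDataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "session_id": str})
    for col in ("participant_id", "session_id"):
        if col not in df.columns:
            raise GazeDataError(f"{path.name}: missing column {col!r}")
    keys = list(zip(df["participant_id"], df["session_id"]))
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise GazeDataError(f"{path.name}: duplicate session key {dup}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SessionGroundTruth(
                participant_id=str(row["participant_id"]),
                session_id=str(row["session_id"]),
                au=_opt_float(row, "au"),
                crt_pre=_crt(row, "crt_pre"),
                crt_post=_crt(row, "crt_post"),
                vasf_fatigue=_opt_float(row, "vasf_fatigue"),
                vasf_energy=_opt_float(row, "vasf_energy"),
            )
        )
    return records


def write_ground_truth(records: list[SessionGroundTruth], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "session_id": r.session_id,
            "au": r.au,
            "vasf_fatigue": r.vasf_fatigue,
            "vasf_energy": r.vasf_energy,
        }
        for prefix, crt in (("crt_pre", r.crt_pre), ("crt_post", r.crt_post)):
            row[f"{prefix}_mean"] = None if crt is None else crt.mean_rt
            row[f"{prefix}_sd"] = None if crt is None else crt.sd_rt
            row[f"{prefix}_errors"] = None if crt is None else crt.n_errors
        rows.append(row)
    pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS)).to_csv(path, index=False)


def write_study(study, directory: str | Path) -> None:
    """Write a study as one gaze CSV per session plus a ground-truth table
    and a YAML manifest, all in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sess in study:
        pid, sid = sess.ground_truth.participant_id, sess.ground_truth.session_id
        write_gaze(sess.recording, directory / f"gaze_{pid}_{sid}.csv")
    write_ground_truth(study.ground_truth_rows(), directory / "ground_truth.csv")
    write_manifest(directory / "manifest.yaml", units="deg", **study.meta)


def read_study(directory: str | Path):
    """Read a study directory written by :func:`write_study`."""
    from .study import Session, StudyDataset

    directory = Path(directory)
    fmt = (
        read_manifest(directory / "manifest.yaml")
        if (directory / "manifest.yaml").exists()
        else GazeFormat()
    )
    sessions = []
    for gt in read_ground_truth(directory / "ground_truth.csv"):
        path = directory / f"gaze_{gt.participant_id}_{gt.session_id}.csv"
        if not path.exists():
            raise GazeDataError(f"missing gaze file {path.name}")
        rec = read_gaze(path, fmt).with_meta(
            participant=gt.participant_id, session=gt.session_id
        )
        sessions.append(Session(recording=rec, ground_truth=gt,
                                participant=gt.participant_id))
    return StudyDataset(sessions=sessions)


def write_manifest(path: str | Path, *, units: str = "deg",
                   geometry: ScreenGeometry | None = None, **extra) -> None:
    """Write a YAML sidecar manifest describing units and screen geometry."""
    doc: dict = {"schema_version": 1, "units": units}
    if geometry is not None:
        doc["geometry"] = {
            "width_px": geometry.width_px,
            "height_px": geometry.height_px,
            "width_mm": geometry.width_mm,
            "height_mm": geometry.height_mm,
            "viewing_distance_mm": geometry.viewing_distance_mm,
        }
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path) -> GazeFormat:
    doc = yaml.safe_load(Path(path).read_text())
    geom = None
    if "geometry" in doc:
        geom = ScreenGeometry(**doc["geometry"])
    return GazeFormat(units=doc.get("units", "deg"), geometry=geom)
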