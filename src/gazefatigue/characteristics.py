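"""The oculomotor characteristic catalogue and feature-matrix construction.

The catalogue holds 27 named characteristics of one recording (or one
sliding window) at one fixation-area diameter, grouped as velocity-based,
temporal-based, percentage-based, quantitative-based (per-minute counts),
saccade-length-based and trajectory-based.  Twenty-six come from screening
the full correlation table; the final entry, *average speed in the fixation
area*, is the expert-added one — path length over duration, as opposed to
the *average velocity within the fixation area*, which is net displacement
over duration (the only reading under which the two names differ).

Duration-bin conventions (fixed so the complement identities hold exactly):
"shorter than T" means duration < T, "longer than T" means duration >= T,
and "between 150 and 900 ms" means [0.150, 0.900).  Proportion-of-time
entries use total fixation time as the denominator, so the three bins
{<150, [150,900), >=900} partition 100%.

Per-recording characteristic values are event-weighted means over events
(fixations, saccades, sample triplets, 1 s bins), not time-weighted.
Undefined entries (no saccades, no fixations, ...) are explicit absences
(None / NaN), never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import (
    EventConfig,
    FixationList,
    KinematicSeries,
    Saccade,
    clean_recording,
    compute_kinematics,
    derive_saccades,
    detect_fixations,
)
from .recording import GazeDataError, GazeRecording, InvalidParameterError
from .study import StudyDataset


@dataclass(frozen=True)
class CharacteristicDef:
    key: str
    label: str
    group: str


#: Catalogue order follows the screening table; the expert addition is last.
CATALOGUE: tuple[CharacteristicDef, ...] = (
    CharacteristicDef("fixation_velocity_mean", "Average velocity within the fixation area, °/s", "velocity"),
    CharacteristicDef("curvature_mean", "Average curvature of the gaze trajectory", "trajectory"),
    CharacteristicDef("second_velocity_min", "Min. velocity of gaze movement in the second interval, °/s", "velocity"),
    CharacteristicDef("fixation_velocity_min", "Minimum velocity within the fixation area, °/s", "velocity"),
    CharacteristicDef("curvature_min", "Minimum curvature of the gaze trajectory", "trajectory"),
    CharacteristicDef("saccade_length_min", "Minimum saccade length, °", "saccade_length"),
    CharacteristicDef("saccade_length_max", "Maximum saccade length, °", "saccade_length"),
    CharacteristicDef("pct_fixations_150_900", "Percentage of fixations between 150 and 900 ms, %", "percentage"),
    CharacteristicDef("saccade_length_mean", "Average saccade length, °", "saccade_length"),
    CharacteristicDef("saccade_duration_mean", "Average saccade duration, s", "temporal"),
    CharacteristicDef("fixation_time_150_900", "Total duration of fixations between 150 and 900 ms, s", "temporal"),
    CharacteristicDef("time_share_fixations_150_900", "Proportion of time spent in fixations between 150 and 900 ms, %", "percentage"),
    CharacteristicDef("velocity_max", "Maximum instantaneous gaze velocity, °/s", "velocity"),
    CharacteristicDef("curvature_max", "Maximum curvature of the gaze trajectory", "trajectory"),
    CharacteristicDef("pct_fixations_lt_150", "Percentage of fixations shorter than 150 ms, %", "percentage"),
    CharacteristicDef("pct_fixations_ge_150", "Percentage of fixations longer than 150 ms, %", "percentage"),
    CharacteristicDef("pct_fixations_lt_180", "Percentage of fixations shorter than 180 ms, %", "percentage"),
    CharacteristicDef("pct_fixations_ge_180", "Percentage of fixations longer than 180 ms, %", "percentage"),
    CharacteristicDef("saccade_velocity_mean", "Average saccade velocity, °/s", "velocity"),
    CharacteristicDef("false_fixations_per_minute", "False fixations per minute", "quantitative"),
    CharacteristicDef("second_accel_modulus", "Modulus of average acceleration in second interval, °/s²", "velocity"),
    CharacteristicDef("fixations_ge_900_per_minute", "Fixations longer than 900 ms per minute", "quantitative"),
    CharacteristicDef("time_share_fixations_lt_150", "Proportion of time spent in fixations shorter than 150 milliseconds, %", "percentage"),
    CharacteristicDef("saccade_duration_max", "Maximum saccade duration, s", "temporal"),
    CharacteristicDef("fixations_lt_180_per_minute", "Fixations shorter than 180 ms per minute", "quantitative"),
    CharacteristicDef("time_share_fixations_ge_150", "Proportion of time spent in fixations longer than 150 ms, %", "percentage"),
    CharacteristicDef("fixation_speed_mean", "Average speed in the fixation area, °/s", "velocity"),
)

CATALOGUE_KEYS: tuple[str, ...] = tuple(c.key for c in CATALOGUE)
LABELS: dict[str, str] = {c.key: c.label for c in CATALOGUE}

#: The six screening-selected characteristics plus the expert addition.
SELECTED_CHARACTERISTICS: tuple[str, ...] = (
    "fixation_velocity_mean",
    "curvature_mean",
    "curvature_min",
    "saccade_length_min",
    "pct_fixations_lt_150",
    "time_share_fixations_lt_150",
    "fixation_speed_mean",
)
EXPERT_ADDITIONS: tuple[str, ...] = ("fixation_speed_mean",)


@dataclass
class CharacteristicVector:
    """All catalogue entries of one recording/window at one diameter."""

    values: dict[str, float | None]
    area_diameter: float

    def __getitem__(self, key: str) -> float | None:
        return self.values[key]

    def as_series(self) -> pd.Series:
        return pd.Series(
            {k: (np.nan if v is None else v) for k, v in self.values.items()},
            index=list(CATALOGUE_KEYS),
            dtype=float,
        )


def _mean(vals: Sequence[float]) -> float | None:
    return float(np.mean(vals)) if len(vals) else None


def _stat(arr: np.ndarray, fn) -> float | None:
    return float(fn(arr)) if arr.size else None


def compute_characteristics(
    rec: GazeRecording,
    fixations: FixationList,
    saccades: Sequence[Saccade],
    kin: KinematicSeries,
    cfg: EventConfig,
) -> CharacteristicVector:
    """Populate every catalogue entry from pre-computed events/kinematics.

    The events must come from *this* recording at *this* configuration; a
    mismatched provenance raises :class:`GazeDataError`.
    """
    if fixations.config is not None and fixations.config.area_diameter != cfg.area_diameter:
        raise GazeDataError(
            "fixation list was produced at a different fixation-area diameter"
        )
    for f in fixations.fixations[:1]:
        if not np.isclose(rec.t[f.start_idx], f.start):
            raise GazeDataError("fixation list does not belong to this recording")

    v: dict[str, float | None] = {k: None for k in CATALOGUE_KEYS}

    total_time = sum(
        float(rec.t[hi - 1] - rec.t[lo]) for lo, hi in rec.valid_segments(min_samples=2)
    )
    minutes = total_time / 60.0 if total_time > 0 else None

    durs = fixations.durations()
    nfix = durs.size
    if nfix:
        lt150 = durs < 0.150
        lt180 = durs < 0.180
        mid = (durs >= 0.150) & (durs < 0.900)
        ge900 = durs >= 0.900
        # "longer than" shares are written as exact complements so that the
        # <T / >=T pairs sum to 100 to the last bit
        v["pct_fixations_lt_150"] = 100.0 * lt150.mean()
        v["pct_fixations_ge_150"] = 100.0 - v["pct_fixations_lt_150"]
        v["pct_fixations_lt_180"] = 100.0 * lt180.mean()
        v["pct_fixations_ge_180"] = 100.0 - v["pct_fixations_lt_180"]
        v["pct_fixations_150_900"] = 100.0 * mid.mean()
        fix_time = float(durs.sum())
        if fix_time > 0:
            v["time_share_fixations_lt_150"] = 100.0 * float(durs[lt150].sum()) / fix_time
            v["time_share_fixations_ge_150"] = 100.0 - v["time_share_fixations_lt_150"]
            v["time_share_fixations_150_900"] = 100.0 * float(durs[mid].sum()) / fix_time
        v["fixation_time_150_900"] = float(durs[mid].sum())
        if minutes:
            v["fixations_ge_900_per_minute"] = float(ge900.sum()) / minutes
            v["fixations_lt_180_per_minute"] = float(lt180.sum()) / minutes
        fvel = [f.velocity for f in fixations]
        v["fixation_velocity_mean"] = _mean(fvel)
        v["fixation_velocity_min"] = float(np.min(fvel))
        v["fixation_speed_mean"] = _mean([f.speed for f in fixations])
    if minutes:
        v["false_fixations_per_minute"] = fixations.false_fixation_count / minutes

    if saccades:
        lens = np.array([s.length for s in saccades])
        sdur = np.array([s.duration for s in saccades])
        v["saccade_length_min"] = float(lens.min())
        v["saccade_length_max"] = float(lens.max())
        v["saccade_length_mean"] = float(lens.mean())
        v["saccade_duration_mean"] = float(sdur.mean())
        v["saccade_duration_max"] = float(sdur.max())
        v["saccade_velocity_mean"] = _mean([s.mean_velocity for s in saccades])

    v["velocity_max"] = _stat(kin.velocity, np.max)
    v["curvature_mean"] = _stat(kin.curvature, np.mean)
    v["curvature_min"] = _stat(kin.curvature, np.min)
    v["curvature_max"] = _stat(kin.curvature, np.max)
    v["second_velocity_min"] = _stat(kin.second_v_min, np.mean)
    v["second_accel_modulus"] = _stat(kin.second_a_mod, np.mean)

    return CharacteristicVector(values=v, area_diameter=cfg.area_diameter)


def recording_characteristics(
    rec: GazeRecording, cfg: EventConfig | None = None
) -> CharacteristicVector:
    """Clean, detect events, compute kinematics and the full catalogue."""
    cfg = cfg or EventConfig()
    cleaned = clean_recording(rec, cfg)
    fx = detect_fixations(cleaned, cfg)
    sc = derive_saccades(cleaned, fx)
    kin = compute_kinematics(cleaned)
    return compute_characteristics(cleaned, fx, sc, kin, cfg)


def windowed_characteristics(
    rec: GazeRecording,
    window_s: float,
    step_s: float,
    cfg: EventConfig | None = None,
) -> pd.DataFrame:
    """Characteristic vectors over a sliding window, aligned to window end.

    Rows are indexed by window-end time; windows with too few events carry
    NaN in the affected entries.  A window longer than the recording yields
    an empty frame.
    """
    if window_s < 5.0:
        raise InvalidParameterError("window_s must be >= 5 s")
    if step_s <= 0:
        raise InvalidParameterError("step_s must be positive")
    cfg = cfg or EventConfig()
    t0 = float(rec.t[0]) if len(rec) else 0.0
    # nominal span: a recording of n samples at rate r covers n/r seconds
    dur = rec.duration
    if rec.sample_rate:
        dur += 1.0 / rec.sample_rate
    ends = []
    e = window_s
    while e <= dur + 1e-9:
        ends.append(t0 + e)
        e += step_s
    rows = {}
    for end in ends:
        # half-open [end - window, end): every window spans the same count
        sub = rec.time_slice(end - window_s, end)
        rows[end] = recording_characteristics(sub, cfg).as_series()
    out = pd.DataFrame(rows).T
    out.index.name = "window_end"
    return out


@dataclass(frozen=True)
class FeatureSummary:
    """The seven summary statistics of one feature time series."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    p25: float
    p50: float
    p75: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
        }


def summarize_series(series: Sequence[float] | np.ndarray) -> FeatureSummary | None:
    """Mean, SD, min, max and quartiles of a feature series.

    Percentiles use linear interpolation; SD uses the n-1 denominator (0
    for a single value).  An empty series is an error; a series of only
    NaN (all values absent) returns None.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise GazeDataError("cannot summarize an empty series")
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return None
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    p25, p50, p75 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return FeatureSummary(
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        p25=p25,
        p50=p50,
        p75=p75,
    )


FEATURE_SET_TOKENS = ("coordinates", "selected", "all")


def _coordinate_features(rec: GazeRecording) -> dict[str, float]:
    """Seven summary statistics of the raw x, y and velocity series."""
    kin = compute_kinematics(rec)
    out: dict[str, float] = {}
    for name, series in (
        ("x", rec.x[rec.valid]),
        ("y", rec.y[rec.valid]),
        ("v", kin.velocity),
    ):
        summ = summarize_series(series) if len(series) else None
        for stat, val in (summ.as_dict() if summ else {}).items():
            out[f"coord_{name}_{stat}"] = val
    return out


def _resolve_feature_sets(feature_sets: str | Iterable[str]) -> list[str]:
    if isinstance(feature_sets, str):
        feature_sets = feature_sets.split("+")
    tokens = [s.strip() for s in feature_sets]
    for tok in tokens:
        if tok not in FEATURE_SET_TOKENS:
            raise InvalidParameterError(
                f"unknown feature set {tok!r}; expected one of {FEATURE_SET_TOKENS}"
            )
    return tokens


def recording_features(
    rec: GazeRecording,
    cfg: EventConfig,
    feature_sets: str | Iterable[str],
    all_keys: Sequence[str] | None = None,
) -> dict[str, float]:
    """Feature-set values of one recording/window as a flat name->value dict.

    This is the shared row builder behind :func:`build_feature_matrix` and
    the streaming assessor, so training and inference are guaranteed to use
    the same feature definition.
    """
    tokens = _resolve_feature_sets(feature_sets)
    row: dict[str, float] = {}
    vec = None
    if "selected" in tokens or "all" in tokens:
        vec = recording_characteristics(rec, cfg).as_series()
    if "coordinates" in tokens:
        row.update(_coordinate_features(rec))
    if "selected" in tokens:
        for k in SELECTED_CHARACTERISTICS:
            row[k] = vec[k]
    if "all" in tokens:
        for k in (all_keys if all_keys is not None else CATALOGUE_KEYS):
            row[k] = vec[k]
    return row


def build_feature_matrix(
    study: StudyDataset,
    cfg: EventConfig | None = None,
    feature_sets: str | Iterable[str] = "selected",
    samples_per_session: int = 1,
    screening_p: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-sample feature matrix for classification.

    ``feature_sets`` is a token or union ("coordinates", "selected", "all",
    or e.g. "coordinates+selected"): *coordinates* are the seven summary
    statistics of the raw x, y and per-sample velocity series; *selected*
    are the seven expert-chosen characteristics; *all* is every catalogue
    entry whose screening p-value (if ``screening_p`` is given) is <= alpha.
    Each session contributes ``samples_per_session`` rows by splitting its
    recording into equal consecutive windows.  Metadata columns
    (participant_id, session_id, window, au) precede the feature columns.
    """
    cfg = cfg or EventConfig()
    tokens = _resolve_feature_sets(feature_sets)
    if samples_per_session < 1:
        raise InvalidParameterError("samples_per_session must be >= 1")

    if "all" in tokens and screening_p is not None:
        all_keys = [k for k in CATALOGUE_KEYS if screening_p.get(k, 1.0) <= alpha]
    else:
        all_keys = list(CATALOGUE_KEYS)

    rows = []
    for sess in study:
        rec = sess.recording
        dur = rec.duration
        t0 = float(rec.t[0]) if len(rec) else 0.0
        for w in range(samples_per_session):
            lo = t0 + dur * w / samples_per_session
            hi = t0 + dur * (w + 1) / samples_per_session
            sub = rec.time_slice(lo, hi + (1e-12 if w == samples_per_session - 1 else 0))
            row = recording_features(sub, cfg, tokens, all_keys)
            meta = {
                "participant_id": sess.ground_truth.participant_id,
                "session_id": sess.ground_truth.session_id,
                "window": w,
                "au": sess.ground_truth.au,
            }
            rows.append({**meta, **row})
    df = pd.DataFrame(rows)
    if df.columns.duplicated().any():
        raise GazeDataError("duplicate feature column names")
    return df


META_COLUMNS = ("participant_id", "session_id", "window", "au")


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the non-metadata columns of a feature matrix."""
    return [c for c in matrix.columns if c not in META_COLUMNS]
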