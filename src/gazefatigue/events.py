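"""Cleaning, fixation/saccade detection, and per-sample kinematics.

Fixations are detected with a dispersion-threshold algorithm (I-DT family):
a maximal run of samples counts as a fixation when its *dispersion* — the
maximum pairwise Euclidean distance between samples, i.e. the diameter of
the point set — stays within the configured fixation-area diameter and the
run lasts at least the minimum fixation duration.  The area diameter is the
central tunable of the whole method: every characteristic downstream can be
recomputed on a grid of diameters (0.1–2.5 degrees of visual angle).

Dispersion-qualified runs too short to be fixations are counted separately
as *false fixations*; their rate per minute is itself a characteristic.

Saccades are derived, not detected: one per consecutive fixation pair, with
amplitude measured centroid-to-centroid.

Kinematics: instantaneous velocity from first differences, acceleration from
velocity-vector differences, and discrete curvature of the gaze trajectory as
Menger curvature (reciprocal circumradius of each sample triplet, 1/deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .recording import GazeRecording, InvalidParameterError


@dataclass(frozen=True)
class EventConfig:
    """Parameters of cleaning and event detection.

    area_diameter : fixation-area diameter in degrees of visual angle.
    min_fixation_duration : shortest run that counts as a fixation (s).
    false_fixation_max_duration : longest dispersion-qualified run that is
        counted as a false fixation (s); defaults to min_fixation_duration.
    max_gap_interpolation : longest invalid-sample gap bridged by linear
        interpolation (s); longer gaps split the recording into segments.
    """

    area_diameter: float = 1.0
    min_fixation_duration: float = 0.05
    false_fixation_max_duration: float | None = None
    max_gap_interpolation: float = 0.075

    def __post_init__(self) -> None:
        if self.area_diameter <= 0:
            raise InvalidParameterError("area_diameter must be positive")
        if self.min_fixation_duration < 0:
            raise InvalidParameterError("min_fixation_duration must be >= 0")
        if self.false_fixation_max_duration is None:
            object.__setattr__(
                self, "false_fixation_max_duration", self.min_fixation_duration
            )
        if self.false_fixation_max_duration < 0:
            raise InvalidParameterError("false_fixation_max_duration must be >= 0")

    def with_diameter(self, d: float) -> "EventConfig":
        return EventConfig(
            area_diameter=d,
            min_fixation_duration=self.min_fixation_duration,
            false_fixation_max_duration=self.false_fixation_max_duration,
            max_gap_interpolation=self.max_gap_interpolation,
        )


@dataclass(frozen=True)
class Fixation:
    start: float
    end: float
    centroid: tuple[float, float]
    dispersion: float
    path_length: float
    net_displacement: float
    start_idx: int
    end_idx: int  # inclusive sample index
    segment: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def velocity(self) -> float:
        """Net displacement over duration, deg/s ('velocity within the fixation area')."""
        return self.net_displacement / self.duration if self.duration > 0 else 0.0

    @property
    def speed(self) -> float:
        """Path length over duration, deg/s ('speed in the fixation area')."""
        return self.path_length / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class Saccade:
    start: float
    end: float
    length: float
    peak_velocity: float
    mean_velocity: float
    segment: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FixationList:
    fixations: list[Fixation] = field(default_factory=list)
    false_fixation_count: int = 0
    config: EventConfig | None = None

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    def __getitem__(self, i):
        return self.fixations[i]

    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


@dataclass
class KinematicSeries:
    """Per-sample kinematics plus non-overlapping 1 s bin aggregates."""

    velocity_t: np.ndarray  # midpoint times of velocity samples
    velocity: np.ndarray  # |dp|/dt, deg/s
    accel_t: np.ndarray
    accel_x: np.ndarray  # acceleration vector components, deg/s^2
    accel_y: np.ndarray
    curvature_t: np.ndarray
    curvature: np.ndarray  # Menger curvature, 1/deg
    second_v_mean: np.ndarray  # per 1 s bin: mean velocity
    second_v_min: np.ndarray  # per 1 s bin: min velocity
    second_a_mod: np.ndarray  # per 1 s bin: |mean acceleration vector|

    @property
    def accel_mag(self) -> np.ndarray:
        return np.hypot(self.accel_x, self.accel_y)


def clean_recording(rec: GazeRecording, cfg: EventConfig) -> GazeRecording:
    """Interpolate short dropout gaps; leave long gaps as segment breaks.

    A run of invalid samples flanked by valid samples is linearly
    interpolated in place when the flank-to-flank time span is at most
    ``cfg.max_gap_interpolation``; no data is fabricated across longer gaps.
    Sample count is never changed.
    """
    t, x, y = rec.t.copy(), rec.x.copy(), rec.y.copy()
    valid = rec.valid.copy()
    n = len(t)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            if i > 0 and j < n and (t[j] - t[i - 1]) <= cfg.max_gap_interpolation:
                frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
                x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
                y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
                valid[i:j] = True
            i = j
        else:
            i += 1
    return GazeRecording(
        t=t, x=x, y=y, valid=valid, sample_rate=rec.sample_rate, meta=dict(rec.meta)
    )


def _grow_window(
    x: np.ndarray, y: np.ndarray, i: int, hi: int, diameter: float
) -> int:
    """Largest end index b such that the dispersion of [i, b] is <= diameter.

    Dispersion is maintained incrementally: appending a sample can only add
    pairwise distances that involve it, so the new dispersion is the maximum
    of the old one and the distances from the new sample to the window.
    """
    disp = 0.0
    b = i
    for j in range(i + 1, hi):
        dx = x[i : j] - x[j]
        dy = y[i : j] - y[j]
        cand = max(disp, float(np.max(np.hypot(dx, dy))))
        if cand > diameter:
            break
        disp = cand
        b = j
    return b


def detect_fixations(rec: GazeRecording, cfg: EventConfig) -> FixationList:
    """Dispersion-threshold fixation detection on a cleaned recording.

    Within each valid segment the scan is greedy left-to-right: grow a
    window rightward while its dispersion stays within the fixation-area
    diameter; if the maximal window lasts at least the minimum fixation
    duration it is emitted and the scan restarts just past it, otherwise
    the window start advances one sample.  Maximal dispersion-qualified
    windows of at least two samples that are too short to be fixations are
    tallied (without overlap) as false fixations.
    """
    fixations: list[Fixation] = []
    false_count = 0
    t, x, y = rec.t, rec.x, rec.y
    for seg_id, (lo, hi) in enumerate(rec.valid_segments()):
        i = lo
        last_counted_end = lo - 1
        while i < hi:
            b = _grow_window(x, y, i, hi, cfg.area_diameter)
            dur = float(t[b] - t[i])
            if b > i and dur >= cfg.min_fixation_duration:
                xs, ys = x[i : b + 1], y[i : b + 1]
                steps = np.hypot(np.diff(xs), np.diff(ys))
                fixations.append(
                    Fixation(
                        start=float(t[i]),
                        end=float(t[b]),
                        centroid=(float(xs.mean()), float(ys.mean())),
                        dispersion=_dispersion(xs, ys),
                        path_length=float(steps.sum()),
                        net_displacement=float(
                            np.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
                        ),
                        start_idx=i,
                        end_idx=b,
                        segment=seg_id,
                    )
                )
                last_counted_end = b
                i = b + 1
            else:
                if (
                    b > i
                    and i > last_counted_end
                    and dur <= cfg.false_fixation_max_duration
                ):
                    false_count += 1
                    last_counted_end = b
                i += 1
    return FixationList(fixations=fixations, false_fixation_count=false_count, config=cfg)


def _dispersion(xs: np.ndarray, ys: np.ndarray) -> float:
    """Max pairwise Euclidean distance (diameter of the sample cloud)."""
    if len(xs) < 2:
        return 0.0
    dx = xs[:, None] - xs[None, :]
    dy = ys[:, None] - ys[None, :]
    return float(np.max(np.hypot(dx, dy)))


def derive_saccades(rec: GazeRecording, fixations: FixationList) -> list[Saccade]:
    """One saccade per consecutive fixation pair within a segment.

    Amplitude is the angular distance between the flanking fixation
    centroids; duration is the inter-fixation interval.  Peak velocity is
    the largest instantaneous velocity over the samples spanning the gap.
    """
    sacc: list[Saccade] = []
    t, x, y = rec.t, rec.x, rec.y
    fx = fixations.fixations
    for f1, f2 in zip(fx, fx[1:]):
        if f1.segment != f2.segment:
            continue
        dur = f2.start - f1.end
        if dur <= 0:
            continue
        length = float(
            np.hypot(f2.centroid[0] - f1.centroid[0], f2.centroid[1] - f1.centroid[1])
        )
        a, b = f1.end_idx, f2.start_idx
        dt = np.diff(t[a : b + 1])
        step = np.hypot(np.diff(x[a : b + 1]), np.diff(y[a : b + 1]))
        v = step / dt
        path = float(step.sum())
        sacc.append(
            Saccade(
                start=float(f1.end),
                end=float(f2.start),
                length=length,
                peak_velocity=float(v.max()) if v.size else length / dur,
                mean_velocity=path / dur if dur > 0 else 0.0,
                segment=f1.segment,
            )
        )
    return sacc


def _menger_curvature(
    xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Menger curvature at each interior point of a polyline (1/deg).

    For a triplet (a, b, c) the curvature is ``4 * area / (|ab| |bc| |ca|)``,
    the reciprocal of the circumradius; collinear triplets give 0.
    """
    ax, ay = xs[:-2], ys[:-2]
    bx, by = xs[1:-1], ys[1:-1]
    cx, cy = xs[2:], ys[2:]
    cross = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    area2 = np.abs(cross)  # 2 * triangle area
    dab = np.hypot(bx - ax, by - ay)
    dbc = np.hypot(cx - bx, cy - by)
    dca = np.hypot(ax - cx, ay - cy)
    denom = dab * dbc * dca
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * area2 / np.where(denom > 0, denom, 1.0), 0.0)
    return k


def compute_kinematics(rec: GazeRecording) -> KinematicSeries:
    """Velocity, acceleration and curvature series plus 1 s bin aggregates.

    Differences never cross segment boundaries.  "Second intervals" are
    non-overlapping 1 s bins anchored at the recording start; a bin
    aggregates the velocity samples whose midpoint time falls inside it.
    """
    vt, vm, at_, ax_, ay_, kt, kv = [], [], [], [], [], [], []
    t = rec.t
    for (lo, hi) in rec.valid_segments(min_samples=2):
        ts, xs, ys = t[lo:hi], rec.x[lo:hi], rec.y[lo:hi]
        dt = np.diff(ts)
        vx = np.diff(xs) / dt
        vy = np.diff(ys) / dt
        tmid = 0.5 * (ts[:-1] + ts[1:])
        vt.append(tmid)
        vm.append(np.hypot(vx, vy))
        if len(ts) >= 3:
            dtm = np.diff(tmid)
            ax_.append(np.diff(vx) / dtm)
            ay_.append(np.diff(vy) / dtm)
            at_.append(ts[1:-1])
            kt.append(ts[1:-1])
            kv.append(_menger_curvature(xs, ys))

    def cat(parts):
        return np.concatenate(parts) if parts else np.array([], dtype=float)

    velocity_t, velocity = cat(vt), cat(vm)
    accel_t, accel_x, accel_y = cat(at_), cat(ax_), cat(ay_)
    curvature_t, curvature = cat(kt), cat(kv)

    sv_mean, sv_min, sa_mod = [], [], []
    if len(t):
        t0 = float(t[0])
        nbins = max(1, int(np.ceil((float(t[-1]) - t0))) if len(t) > 1 else 1)
        for k in range(nbins):
            lo_t, hi_t = t0 + k, t0 + k + 1
            m = (velocity_t >= lo_t) & (velocity_t < hi_t)
            if m.any():
                sv_mean.append(float(velocity[m].mean()))
                sv_min.append(float(velocity[m].min()))
            ma = (accel_t >= lo_t) & (accel_t < hi_t)
            if ma.any():
                sa_mod.append(
                    float(np.hypot(accel_x[ma].mean(), accel_y[ma].mean()))
                )
    return KinematicSeries(
        velocity_t=velocity_t,
        velocity=velocity,
        accel_t=accel_t,
        accel_x=accel_x,
        accel_y=accel_y,
        curvature_t=curvature_t,
        curvature=curvature,
        second_v_mean=np.asarray(sv_mean, dtype=float),
        second_v_min=np.asarray(sv_min, dtype=float),
        second_a_mod=np.asarray(sa_mod, dtype=float),
    )
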