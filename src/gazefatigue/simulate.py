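"""Seeded synthetic gaze-study simulator.

Emulates eye-tracker recordings of PC operators: alternating fixation
epochs and saccadic jumps on a uniform sample grid, with blinks as gaps of
invalid samples.  Saccade displacement follows a minimum-jerk profile whose
analytic peak velocity is ``15 A / (8 T)`` for amplitude ``A`` over
duration ``T`` — so fixing the main-sequence slope (peak velocity per
amplitude) fixes the saccade duration.

Generative details, chosen so every catalogue characteristic downstream has
realistic structure and no detector artifacts:

* fixation durations come from a three-component log-normal mixture (short
  ~85 ms, regular ~300 ms, long tail ~1.3 s), populating all duration bins;
* within-fixation drift moves along a small circle, so its spatial extent
  is hard-bounded and long fixations are never chopped by a dispersion
  window;
* physiological tremor is an elliptical orbit at ~37 Hz: the fixed minor
  axis bounds the sampled second difference away from zero (no chance
  near-collinear triplets inside fixations) while the major axis sets the
  typical discrete curvature of the trajectory;
* AR(1) measurement noise applies to every sample;
* saccade amplitudes are an exponential-family excess over a hard floor
  (the floor moves the minimum detected saccade length while the mean
  stays put), trajectories bow sideways into a parabolic arc of constant
  curvature ~``8 c / A``, and reported gaze snaps to the flanking fixation
  position near take-off and landing, emulating tracker smoothing — and
  preventing mid-flight samples from sitting just inside a fixation
  window's dispersion budget, which would split fixations into artifact
  events.

Fatigue is a level in [0, 1] that reshapes parameters monotonically
(multipliers interpolated log-linearly, offsets linearly).  The default
effect configuration targets the seven characteristics the relevance
screening is expected to single out; see docs/methods.md for the mechanism
behind each lever and for what the generator does not emulate.

Ground-truth tests (Landolt Au, CRT, VAS-F) are generated from the same
fatigue level with additive Gaussian noise; a zero-noise mode makes them
deterministic for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np
from scipy.signal import lfilter

from .recording import GazeRecording, InvalidParameterError
from .study import CrtResult, Session, SessionGroundTruth, StudyDataset

AU_RANGE = (-0.5, 4.0)


@dataclass(frozen=True)
class SimParams:
    """Physical parameters of the gaze simulator.

    Durations in seconds, positions and amplitudes in degrees of visual
    angle, rates in Hz.  ``main_sequence_slope`` is the peak-velocity per
    amplitude coefficient (1/s).  ``saccade_amplitude_shape`` is the gamma
    shape of the amplitude excess over ``saccade_amplitude_min``;
    ``math.inf`` degenerates the distribution to its mean.
    ``saccade_curvature`` is the sideways bow of a saccade as a fraction of
    its amplitude; ``saccade_snap_distance`` is how close to either
    endpoint the reported gaze sticks to the flanking fixation.
    ``intra_fixation_drift_speed`` moves the fixation point around a circle
    of ``drift_radius``; ``tremor_amplitude``/``tremor_minor`` are the
    major/minor axes of the elliptical tremor orbit;
    ``intra_fixation_noise_ar`` is the AR(1) coefficient of the
    measurement noise.  A ``landing_overshoot`` (off by default) adds a
    decaying post-saccadic transient along the incoming direction.
    """

    sample_rate: float = 100.0
    fixation_duration_median: float = 0.30
    fixation_duration_sigma: float = 0.45
    short_fixation_weight: float = 0.34
    short_fixation_median: float = 0.085
    short_fixation_sigma: float = 0.05
    fixation_tail_weight: float = 0.04
    fixation_tail_median: float = 1.3
    fixation_tail_sigma: float = 0.4
    saccade_amplitude_mean: float = 5.0
    saccade_amplitude_min: float = 2.0
    saccade_amplitude_shape: float = 1.0
    main_sequence_slope: float = 40.0
    saccade_curvature: float = 0.005
    saccade_snap_distance: float = 1.8
    landing_overshoot: float = 0.0
    landing_duration: float = 0.04
    intra_fixation_drift_speed: float = 1.2
    drift_radius: float = 0.15
    tremor_amplitude: float = 0.12
    tremor_minor: float = 0.06
    tremor_frequency: float = 37.0
    intra_fixation_noise_sd: float = 0.015
    intra_fixation_noise_ar: float = 0.2
    blink_rate: float = 10.0  # events per minute
    blink_gap_duration: float = 0.15
    screen_bounds: tuple[float, float] = (16.0, 10.0)  # half extents, deg

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        for name in (
            "fixation_duration_median",
            "fixation_duration_sigma",
            "short_fixation_median",
            "short_fixation_sigma",
            "fixation_tail_median",
            "fixation_tail_sigma",
            "saccade_amplitude_mean",
            "saccade_amplitude_shape",
            "main_sequence_slope",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in (
            "intra_fixation_drift_speed",
            "tremor_amplitude",
            "tremor_minor",
            "tremor_frequency",
            "intra_fixation_noise_sd",
            "blink_rate",
            "blink_gap_duration",
            "saccade_curvature",
            "saccade_amplitude_min",
            "saccade_snap_distance",
            "landing_overshoot",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.drift_radius <= 0 or self.landing_duration <= 0:
            raise InvalidParameterError("drift_radius and landing_duration must be > 0")
        if self.tremor_amplitude < self.tremor_minor:
            raise InvalidParameterError(
                "tremor_amplitude (major axis) must be >= tremor_minor"
            )
        if not 0 <= self.short_fixation_weight < 1:
            raise InvalidParameterError("short_fixation_weight must be in [0, 1)")
        if not 0 <= self.fixation_tail_weight < 1:
            raise InvalidParameterError("fixation_tail_weight must be in [0, 1)")
        if self.short_fixation_weight + self.fixation_tail_weight >= 1:
            raise InvalidParameterError("mixture weights must sum below 1")
        if not -1 < self.intra_fixation_noise_ar < 1:
            raise InvalidParameterError("intra_fixation_noise_ar must be in (-1, 1)")
        if self.saccade_amplitude_min >= self.saccade_amplitude_mean:
            raise InvalidParameterError(
                "saccade_amplitude_min must be below saccade_amplitude_mean"
            )
        if self.screen_bounds[0] <= 0 or self.screen_bounds[1] <= 0:
            raise InvalidParameterError("screen_bounds must be positive")


#: SimParams fields receiving multiplicative between-session variability,
#: with per-field scales on the study-level jitter sigma.
JITTER_FIELDS: dict[str, float] = {
    "intra_fixation_drift_speed": 1.0,
    "intra_fixation_noise_sd": 1.2,
    "tremor_minor": 2.0,
    "tremor_frequency": 1.0,
    "fixation_duration_median": 2.5,
    "short_fixation_weight": 1.0,
    "fixation_tail_weight": 4.0,
    "fixation_tail_median": 2.0,
    "saccade_amplitude_mean": 1.0,
    "main_sequence_slope": 1.0,
}


@dataclass(frozen=True)
class FatigueEffectConfig:
    """Monotone fatigue effects on simulator parameters.

    ``param_multipliers`` maps a :class:`SimParams` field to its multiplier
    at fatigue level 1; at level ``f`` the parameter is scaled by
    ``multiplier ** f`` (log-linear).  ``param_offsets`` adds
    ``offset * f`` instead (used for signed parameters like the noise
    autocorrelation).  ``within_session_increment`` is how much the fatigue
    level rises from the start to the end of one session's recording.
    ``ground_truth_noise`` scales the additive noise on Au/CRT/VAS-F
    (0 = deterministic ground truth).
    """

    param_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "intra_fixation_drift_speed": 0.12,
            "short_fixation_median": 1.60,
            "fixation_tail_weight": 4.5,
            "saccade_amplitude_min": 0.52,
            "saccade_curvature": 50.0,
            "tremor_amplitude": 0.7,
        }
    )
    param_offsets: dict[str, float] = field(default_factory=dict)
    within_session_increment: float = 0.4
    ground_truth_noise: float = 1.0

    def __post_init__(self) -> None:
        names = {f.name for f in fields(SimParams)}
        for k, v in {**self.param_multipliers, **self.param_offsets}.items():
            if k not in names:
                raise InvalidParameterError(f"unknown SimParams field {k!r}")
            if not math.isfinite(v):
                raise InvalidParameterError(f"effect size for {k} must be finite")
        for k, v in self.param_multipliers.items():
            if v <= 0:
                raise InvalidParameterError(f"multiplier for {k} must be > 0")

    @classmethod
    def null(cls) -> "FatigueEffectConfig":
        """No oculomotor or within-session effects (for null studies)."""
        return cls(param_multipliers={}, param_offsets={}, within_session_increment=0.0)

    def apply(self, params: SimParams, fatigue_level: float) -> SimParams:
        """Parameters at a given fatigue level in [0, 1]."""
        if not 0.0 <= fatigue_level <= 1.0:
            raise InvalidParameterError("fatigue_level must be in [0, 1]")
        changes: dict[str, float] = {
            k: getattr(params, k) * (m ** fatigue_level)
            for k, m in self.param_multipliers.items()
        }
        for k, off in self.param_offsets.items():
            changes[k] = getattr(params, k) + off * fatigue_level
        major = changes.get("tremor_amplitude", params.tremor_amplitude)
        if params.tremor_minor > major:
            changes["tremor_minor"] = major
        return replace(params, **changes)


@dataclass(frozen=True)
class GroundTruthModel:
    """Linear fatigue -> test-score mappings with additive Gaussian noise.

    Au falls from its rested to its fatigued value as fatigue goes 0 -> 1
    (crossing the 1.5 dichotomy threshold at fatigue 0.5 by default); CRT
    mean reaction time and the VAS-F fatigue score rise; VAS-F energy falls.
    """

    au_rested: float = 3.0
    au_fatigued: float = 0.0
    au_sd: float = 0.15
    crt_mean_rested: float = 0.45
    crt_mean_slope: float = 0.25
    crt_mean_sd: float = 0.02
    crt_sd_rested: float = 0.08
    crt_sd_slope: float = 0.05
    crt_error_rate_rested: float = 1.0
    crt_error_rate_slope: float = 4.0
    vasf_fatigue_rested: float = 2.0
    vasf_fatigue_slope: float = 6.0
    vasf_sd: float = 0.5


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a simulated study.

    The default shape mirrors a longitudinal PC-operator study: 15
    participants recorded over 7 days with three sessions per day.
    ``fatigue_schedule(day, session_index) -> level in [0, 1]``; the
    default ramps across the sessions of a day.  ``param_jitter_sigma`` is
    the log-SD of multiplicative between-session variability applied to
    the fields in :data:`JITTER_FIELDS` — the biological and instrumental
    heterogeneity that makes sessions of equal fatigue non-identical.
    """

    n_participants: int = 15
    n_days: int = 7
    sessions_per_day: int = 3
    session_duration: float = 3600.0
    fatigue_schedule: Callable[[int, int], float] | None = None
    param_jitter_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_days, self.sessions_per_day) < 1:
            raise InvalidParameterError("design counts must be >= 1")
        if self.session_duration < 10.0:
            raise InvalidParameterError("session_duration must be >= 10 s")
        if self.param_jitter_sigma < 0:
            raise InvalidParameterError("param_jitter_sigma must be >= 0")

    def fatigue_level(self, day: int, session_index: int) -> float:
        if self.fatigue_schedule is not None:
            f = float(self.fatigue_schedule(day, session_index))
        elif self.sessions_per_day > 1:
            f = session_index / (self.sessions_per_day - 1)
        else:
            f = 0.5
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError("fatigue schedule must map into [0, 1]")
        return f

    @property
    def n_sessions(self) -> int:
        return self.n_participants * self.n_days * self.sessions_per_day


def _fixation_duration(p: SimParams, rng: np.random.Generator) -> float:
    """Three-component log-normal mixture: short / regular / long-tail."""
    u = rng.uniform()
    if u < p.short_fixation_weight:
        med, sig = p.short_fixation_median, p.short_fixation_sigma
    elif u < p.short_fixation_weight + p.fixation_tail_weight:
        med, sig = p.fixation_tail_median, p.fixation_tail_sigma
    else:
        med, sig = p.fixation_duration_median, p.fixation_duration_sigma
    return float(rng.lognormal(math.log(med), sig))


def _saccade_amplitude(p: SimParams, rng: np.random.Generator) -> float:
    excess_mean = p.saccade_amplitude_mean - p.saccade_amplitude_min
    k = p.saccade_amplitude_shape
    if math.isinf(k):
        return p.saccade_amplitude_mean
    return p.saccade_amplitude_min + float(rng.gamma(k, excess_mean / k))


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _ar1_noise_schedule(
    n: int,
    rate: float,
    params_at: Callable[[float], SimParams],
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1) measurement noise with slowly varying parameters, shape (n, 2).

    Generated in 1 s blocks with the filter state carried across blocks, so
    the autocorrelation and SD can ramp over the recording while the noise
    stays continuous.
    """
    if n == 0:
        return np.zeros((0, 2))
    block = max(1, int(round(rate)))
    out = np.empty((n, 2))
    y_last = None
    for start in range(0, n, block):
        stop = min(n, start + block)
        p = params_at(min(1.0, (start / rate) / duration))
        sd, ar = p.intra_fixation_noise_sd, p.intra_fixation_noise_ar
        if sd == 0:
            out[start:stop] = 0.0
            y_last = np.zeros(2)
            continue
        eps = rng.normal(0.0, sd * math.sqrt(1.0 - ar * ar), size=(stop - start, 2))
        if y_last is None:
            eps[0] = rng.normal(0.0, sd, size=2)
            y_last = np.zeros(2)
        zi = (ar * y_last)[None, :]
        seg, zf = lfilter([1.0], [1.0, -ar], eps, axis=0, zi=zi)
        out[start:stop] = seg
        y_last = seg[-1]
    return out


def simulate_recording_schedule(
    params_at: Callable[[float], SimParams],
    duration: float,
    seed: int | np.random.Generator,
) -> GazeRecording:
    """Simulate a recording whose parameters may drift over its course.

    ``params_at(progress)`` gives the simulator parameters at the
    fractional progress (0 at start, 1 at end) of the recording; each
    fixation/saccade epoch is generated with the parameters at its onset.
    Deterministic given the seed.
    """
    if duration < 1.0:
        raise InvalidParameterError("duration must be >= 1 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = params_at(0.0)
    rate = p0.sample_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.empty(n)
    y = np.empty(n)
    in_flight = np.zeros(n, dtype=bool)  # strictly mid-flight saccade samples

    pos = np.zeros(2)
    incoming = np.array([1.0, 0.0])  # unit direction of the last saccade
    first_epoch = True
    now = 0.0  # epoch clock, seconds
    filled = 0  # samples written
    while filled < n:
        p = params_at(min(1.0, now / duration))
        # --- fixation epoch: drift along a small circle, entered through a
        # decaying landing overshoot of the incoming saccade ---
        fix_dur = _fixation_duration(p, rng)
        end = min(now + fix_dur, duration)
        j = min(n, int(math.ceil(end * rate - 1e-9)))
        omega = p.intra_fixation_drift_speed / p.drift_radius
        spin = rng.choice([-1.0, 1.0])
        psi0 = rng.uniform(0.0, 2.0 * math.pi)
        center = pos - p.drift_radius * np.array([math.cos(psi0), math.sin(psi0)])
        if j > filled:
            tt = t[filled:j] - now
            psi = psi0 + spin * omega * tt
            seg = center[None, :] + p.drift_radius * np.column_stack(
                [np.cos(psi), np.sin(psi)]
            )
            if p.landing_overshoot > 0 and not first_epoch:
                envelope = np.clip(1.0 - tt / p.landing_duration, 0.0, 1.0) ** 2
                seg = seg + (p.landing_overshoot * envelope)[:, None] * incoming[None, :]
            x[filled:j] = seg[:, 0]
            y[filled:j] = seg[:, 1]
            filled = j
        psi_end = psi0 + spin * omega * (end - now)
        pos = center + p.drift_radius * np.array([math.cos(psi_end), math.sin(psi_end)])
        now = end
        first_epoch = False
        if filled >= n:
            break
        # --- saccade epoch: minimum-jerk jump bowed into a parabolic arc ---
        amp = _saccade_amplitude(p, rng)
        bx, by = p.screen_bounds
        margin = 0.9
        for _ in range(64):
            phi = rng.uniform(0.0, 2.0 * math.pi)
            target = pos + amp * np.array([math.cos(phi), math.sin(phi)])
            if abs(target[0]) <= margin * bx and abs(target[1]) <= margin * by:
                break
        else:  # amplitude cannot fit the screen: aim through the center,
            # capping the travel so the landing stays on screen — the jump
            # keeps (almost all of) its amplitude
            norm = float(np.linalg.norm(pos))
            direction = -pos / norm if norm > 1e-9 else np.array([1.0, 0.0])
            amp_eff = min(amp, norm + 0.85 * min(bx, by))
            target = pos + amp_eff * direction
        sac_dur = 15.0 / (8.0 * p.main_sequence_slope)
        end = min(now + sac_dur, duration)
        j = min(n, int(math.ceil(end * rate - 1e-9)))
        chord = target - pos
        if j > filled:
            tau = np.clip((t[filled:j] - now) / sac_dur, 0.0, 1.0)
            u = _minimum_jerk(tau)
            # tracker-style endpoint snapping: near take-off and landing the
            # reported gaze sticks to the flanking fixation position, so
            # mid-flight samples never sit just inside a fixation window's
            # dispersion budget
            snap = p.saccade_snap_distance
            u = np.where(u * amp < snap, 0.0, u)
            u = np.where((1.0 - u) * amp < snap, 1.0, u)
            seg = pos[None, :] + u[:, None] * chord[None, :]
            in_flight[filled:j] = (u > 0.0) & (u < 1.0)
            if p.saccade_curvature > 0:
                perp = np.array([-chord[1], chord[0]])
                nrm = float(np.linalg.norm(perp))
                if nrm > 0:
                    # parabolic arc: constant curvature ~ 8 c / amplitude
                    bow = 4.0 * p.saccade_curvature * amp * u * (1.0 - u)
                    seg = seg + bow[:, None] * (perp / nrm)[None, :]
            x[filled:j] = seg[:, 0]
            y[filled:j] = seg[:, 1]
            filled = j
        nrm = float(np.linalg.norm(chord))
        if nrm > 0:
            incoming = chord / nrm
        pos = target
        now = end

    noise = _ar1_noise_schedule(n, rate, params_at, duration, rng)
    x += noise[:, 0]
    y += noise[:, 1]
    # physiological tremor, elliptically polarized: the gaze point orbits
    # an ellipse at the tremor frequency.  The minor axis bounds the
    # sampled second difference away from zero, so near-collinear sample
    # triplets cannot occur by chance inside fixations; the major axis
    # (which may ramp over the recording; evaluated per 1 s block) sets
    # the typical discrete curvature of the trajectory.
    phase = rng.uniform(0.0, 2.0 * math.pi)
    orient = rng.uniform(0.0, 2.0 * math.pi)
    spin = rng.choice([-1.0, 1.0])
    major = np.empty(n)
    block = max(1, int(round(rate)))
    for start in range(0, n, block):
        stop = min(n, start + block)
        pb = params_at(min(1.0, (start / rate) / duration))
        major[start:stop] = max(pb.tremor_amplitude, pb.tremor_minor)
    omega = 2.0 * math.pi * p0.tremor_frequency
    u_t = major * np.cos(omega * t + phase)
    v_t = p0.tremor_minor * spin * np.sin(omega * t + phase)
    # saccadic motion swamps tremor: mid-flight samples carry none
    keep = ~in_flight
    x[keep] += (u_t * math.cos(orient) - v_t * math.sin(orient))[keep]
    y[keep] += (u_t * math.sin(orient) + v_t * math.cos(orient))[keep]
    bx, by = p0.screen_bounds
    np.clip(x, -bx, bx, out=x)
    np.clip(y, -by, by, out=y)

    valid = np.ones(n, dtype=bool)
    if p0.blink_rate > 0 and p0.blink_gap_duration > 0:
        n_blinks = rng.poisson(p0.blink_rate / 60.0 * duration)
        starts = np.sort(rng.uniform(0.0, duration, size=n_blinks))
        for s in starts:
            lo, hi = np.searchsorted(t, [s, s + p0.blink_gap_duration])
            valid[lo:hi] = False
    x[~valid] = np.nan
    y[~valid] = np.nan
    return GazeRecording(t=t, x=x, y=y, valid=valid, sample_rate=rate)


def simulate_recording(
    params: SimParams, duration: float, seed: int | np.random.Generator
) -> GazeRecording:
    """Simulate one recording with constant parameters (seed-deterministic)."""
    return simulate_recording_schedule(lambda _: params, duration, seed)


def _jittered(
    params: SimParams, sigma: float, rng: np.random.Generator
) -> SimParams:
    """Multiplicative log-normal between-session variability."""
    if sigma <= 0:
        return params
    changes = {
        k: getattr(params, k) * float(rng.lognormal(0.0, sigma * scale))
        for k, scale in JITTER_FIELDS.items()
    }
    # the short-fixation mixture weight is a probability, keep it one
    if "short_fixation_weight" in changes:
        changes["short_fixation_weight"] = min(0.9, changes["short_fixation_weight"])
    # the tremor minor axis may not exceed the fatigue-scaled major axis,
    # which can shrink to ~0.55x of its base value
    if "tremor_minor" in changes:
        changes["tremor_minor"] = min(
            changes["tremor_minor"], 0.55 * params.tremor_amplitude
        )
    return replace(params, **changes)


def _ground_truth(
    participant_id: str,
    session_id: str,
    f_start: float,
    f_end: float,
    gt: GroundTruthModel,
    noise_scale: float,
    rng: np.random.Generator,
) -> SessionGroundTruth:
    def g(sd: float) -> float:
        return float(rng.normal(0.0, sd * noise_scale)) if noise_scale > 0 else 0.0

    f_mid = 0.5 * (f_start + f_end)
    au = gt.au_rested + (gt.au_fatigued - gt.au_rested) * f_mid + g(gt.au_sd)
    au = float(np.clip(au, *AU_RANGE))

    def crt(level: float) -> CrtResult:
        lam = gt.crt_error_rate_rested + gt.crt_error_rate_slope * level
        n_err = int(rng.poisson(lam)) if noise_scale > 0 else int(round(lam))
        return CrtResult(
            mean_rt=gt.crt_mean_rested + gt.crt_mean_slope * level + g(gt.crt_mean_sd),
            sd_rt=max(0.0, gt.crt_sd_rested + gt.crt_sd_slope * level + g(0.01)),
            n_errors=n_err,
        )

    vf = gt.vasf_fatigue_rested + gt.vasf_fatigue_slope * f_start + g(gt.vasf_sd)
    return SessionGroundTruth(
        participant_id=participant_id,
        session_id=session_id,
        au=au,
        crt_pre=crt(f_start),
        crt_post=crt(f_end),
        vasf_fatigue=float(np.clip(vf, 0.0, 10.0)),
        vasf_energy=float(np.clip(10.0 - vf, 0.0, 10.0)),
    )


def simulate_session(
    design: StudyDesign,
    participant: int,
    day: int,
    session_index: int,
    effects: FatigueEffectConfig | None = None,
    params: SimParams | None = None,
    gt_model: GroundTruthModel | None = None,
) -> Session:
    """Simulate one session: fatigue-shifted recording plus ground truth.

    The fatigue level ramps from the scheduled level at session start to
    that level plus the configured within-session increment at session end;
    the CRT is "administered" at both ends, so its post-minus-pre delta
    carries the within-session increment.
    """
    effects = effects or FatigueEffectConfig()
    params = params or SimParams()
    gt_model = gt_model or GroundTruthModel()
    if not (0 <= participant < design.n_participants):
        raise InvalidParameterError("participant index out of design range")
    if not (0 <= day < design.n_days):
        raise InvalidParameterError("day index out of design range")
    if not (0 <= session_index < design.sessions_per_day):
        raise InvalidParameterError("session index out of design range")

    f0 = design.fatigue_level(day, session_index)
    f1 = min(1.0, f0 + effects.within_session_increment)
    rng = np.random.default_rng(
        [design.seed % (2**31), participant, day, session_index]
    )
    base = _jittered(params, design.param_jitter_sigma, rng)
    rec = simulate_recording_schedule(
        lambda prog: effects.apply(base, f0 + (f1 - f0) * prog),
        design.session_duration,
        rng,
    )
    pid = f"p{participant:02d}"
    sid = f"d{day}s{session_index}"
    truth = _ground_truth(pid, sid, f0, f1, gt_model, effects.ground_truth_noise, rng)
    rec = rec.with_meta(participant=pid, day=day, session=session_index)
    return Session(
        recording=rec,
        ground_truth=truth,
        participant=pid,
        day=day,
        session_index=session_index,
    )


def simulate_study(
    design: StudyDesign,
    effects: FatigueEffectConfig | None = None,
    params: SimParams | None = None,
    gt_model: GroundTruthModel | None = None,
    max_samples: float = 5e7,
) -> StudyDataset:
    """Simulate a full study (every participant x day x session).

    Refuses designs whose total sample count exceeds ``max_samples``.
    Reproducible: the session at a given (participant, day, session) index
    depends only on the design seed and that index.
    """
    params = params or SimParams()
    total = design.n_sessions * design.session_duration * params.sample_rate
    if total > max_samples:
        raise InvalidParameterError(
            f"design would generate {total:.3g} samples, over the {max_samples:.3g} "
            "budget; reduce the design or raise max_samples"
        )
    sessions = [
        simulate_session(design, p, d, s, effects, params, gt_model)
        for p in range(design.n_participants)
        for d in range(design.n_days)
        for s in range(design.sessions_per_day)
    ]
    return StudyDataset(
        sessions=sessions,
        meta={
            "seed": design.seed,
            "n_participants": design.n_participants,
            "n_days": design.n_days,
            "sessions_per_day": design.sessions_per_day,
            "session_duration": design.session_duration,
        },
    )
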