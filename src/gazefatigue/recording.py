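"""Core containers for gaze data.

A :class:`GazeRecording` is a uniformly timestamped 2-D gaze-position series
in degrees of visual angle.  Samples may be flagged invalid (tracker dropout,
blinks); invalid samples are kept in place, never silently dropped, so that
cleaning and segmentation logic downstream can reason about gap durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np


class GazeDataError(ValueError):
    """Malformed gaze data or ground-truth table."""


class InvalidParameterError(ValueError):
    """A configuration or geometry parameter is out of its valid range."""


@dataclass
class GazeRecording:
    """Timestamped 2-D gaze positions in degrees of visual angle.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds, strictly increasing.
    x, y : array of float
        Horizontal / vertical gaze position in degrees of visual angle.
        May be NaN where ``valid`` is False.
    valid : bool array
        Per-sample validity flag.  Invalid samples mark tracker dropouts
        and blink gaps.
    sample_rate : float
        Nominal sampling rate in Hz.
    meta : dict
        Free-form identifiers (participant, day, session, ...).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None
    sample_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if len(self.x) != n or len(self.y) != n:
            raise GazeDataError(
                f"array length mismatch: t={n}, x={len(self.x)}, y={len(self.y)}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise GazeDataError("validity flag length mismatch")
            # non-finite coordinates can never be valid
            self.valid = self.valid & np.isfinite(self.x) & np.isfinite(self.y)
        if n > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise GazeDataError(
                    f"timestamps not strictly increasing at row {bad[0] + 1}"
                )
        if self.sample_rate is None and n > 1:
            self.sample_rate = 1.0 / float(np.median(np.diff(self.t)))
        if self.sample_rate is not None and n > 1:
            med_rate = 1.0 / float(np.median(np.diff(self.t)))
            if not (0.9 * med_rate <= self.sample_rate <= 1.1 * med_rate):
                raise GazeDataError(
                    f"declared sample_rate {self.sample_rate:.3g} Hz deviates more "
                    f"than 10% from median inter-sample rate {med_rate:.3g} Hz"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span from first to last timestamp, in seconds."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def slice(self, start: int, stop: int) -> "GazeRecording":
        """Sub-recording over sample indices ``[start, stop)``."""
        return GazeRecording(
            t=self.t[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            valid=self.valid[start:stop],
            sample_rate=self.sample_rate,
            meta=dict(self.meta),
        )

    def time_slice(self, t0: float, t1: float) -> "GazeRecording":
        """Sub-recording over the half-open time interval ``[t0, t1)``."""
        i0, i1 = np.searchsorted(self.t, [t0, t1])
        return self.slice(int(i0), int(i1))

    def with_meta(self, **kv) -> "GazeRecording":
        meta = dict(self.meta)
        meta.update(kv)
        return replace(self, meta=meta)

    def valid_segments(self, min_samples: int = 1) -> Iterator[tuple[int, int]]:
        """Yield ``(start, stop)`` index pairs of maximal runs of valid samples."""
        v = self.valid
        n = len(v)
        i = 0
        while i < n:
            if v[i]:
                j = i
                while j < n and v[j]:
                    j += 1
                if j - i >= min_samples:
                    yield (i, j)
                i = j
            else:
                i += 1


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description for pixel-to-degree conversion."""

    width_px: float
    height_px: float
    width_mm: float
    height_mm: float
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "width_mm",
            "height_mm",
            "viewing_distance_mm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
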