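"""Study-level containers: sessions, ground-truth tests, whole datasets.

A study is a set of recording sessions.  Each session carries one gaze
recording plus the ground-truth tests administered around it: the Landolt
rings attention-correction test (its Au mental-performance index), the
choice-reaction-time task (CRT) at session start and end, and the VAS-F
visual-analogue fatigue scale filled in once before the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .recording import GazeRecording


@dataclass(frozen=True)
class CrtResult:
    """Choice-reaction-time outcome: mean RT, its SD (seconds), error count."""

    mean_rt: float
    sd_rt: float
    n_errors: int

    def __post_init__(self) -> None:
        if self.sd_rt < 0:
            raise ValueError("sd_rt must be >= 0")
        if self.n_errors < 0:
            raise ValueError("n_errors must be >= 0")


@dataclass
class SessionGroundTruth:
    """Per-session ground truth.

    ``au`` is the Landolt-rings mental-performance index (dimensionless;
    observed range roughly -0.5 .. 4, dichotomised at 1.5 downstream).
    Absent tests are ``None``, never silently imputed.
    """

    participant_id: str
    session_id: str
    au: float | None = None
    crt_pre: CrtResult | None = None
    crt_post: CrtResult | None = None
    vasf_fatigue: float | None = None
    vasf_energy: float | None = None

    @property
    def crt_delta(self) -> float | None:
        """Within-session slowing: post minus pre mean reaction time (s)."""
        if self.crt_pre is None or self.crt_post is None:
            return None
        return self.crt_post.mean_rt - self.crt_pre.mean_rt


@dataclass
class Session:
    """One recording session with its ground truth."""

    recording: GazeRecording
    ground_truth: SessionGroundTruth
    participant: str = ""
    day: int = 0
    session_index: int = 0

    @property
    def key(self) -> tuple[str, str]:
        gt = self.ground_truth
        return (gt.participant_id, gt.session_id)


@dataclass
class StudyDataset:
    """A collection of sessions, real or simulated."""

    sessions: list[Session] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def ground_truth_rows(self) -> list[SessionGroundTruth]:
        return [s.ground_truth for s in self.sessions]
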