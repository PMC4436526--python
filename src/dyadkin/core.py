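"""Domain types shared across the pipeline.

A dyad consists of an *actor* (who freely moves balls across a pegboard)
and an *imitator* (who copies the actor's movements).  Each person wears
seven electromagnetic motion trackers, each reporting six degrees of
freedom at 240 Hz: position in millimetres (x, y, z) and orientation in
degrees (azimuth, elevation, roll).  A session is one crossed condition of
the 2x2 design (feedback: face-to-face vs. live video projection;
difficulty: one ball vs. three balls).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical tracker order (proximal-to-distal plus head first).
TRACKERS = ("head", "shoulder", "elbow", "wrist", "thumb", "index", "little")

#: Canonical degree-of-freedom order within each tracker.
DOFS = ("x", "y", "z", "azimuth", "elevation", "roll")

POSITION_DOFS = ("x", "y", "z")
ORIENTATION_DOFS = ("azimuth", "elevation", "roll")

#: The 42 data channels in canonical column order (tracker-major).
CHANNELS = tuple(f"{t}_{d}" for t in TRACKERS for d in DOFS)

DEFAULT_SAMPLE_RATE = 240.0


class Role(str, enum.Enum):
    actor = "actor"
    imitator = "imitator"


class Feedback(str, enum.Enum):
    face_to_face = "face_to_face"
    video = "video"


class Difficulty(str, enum.Enum):
    simple = "simple"
    complex = "complex"


@dataclass(frozen=True)
class CrossedCondition:
    """One cell of the 2x2 within-subject design."""

    feedback: Feedback
    difficulty: Difficulty

    @property
    def label(self) -> str:
        return f"{self.feedback.value}_{self.difficulty.value}"


#: All four design cells, in a fixed reporting order.
CONDITIONS = tuple(
    CrossedCondition(f, d) for f in Feedback for d in Difficulty
)


@dataclass(frozen=True)
class TrialWindow:
    """Half-open sample range [start, end) of one detected action trial."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid trial window [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration_s(self, sample_rate: float) -> float:
        return self.n_samples / sample_rate


@dataclass
class Recording:
    """One person's full-session multi-tracker time series.

    ``data`` holds the 42 channels in canonical column order; positions are
    in mm, orientations in degrees.  ``start_point`` is the 3D position of
    the board's start marker in the recording frame, used for trial
    segmentation.
    """

    person_id: str
    role: Role
    feedback: Feedback
    difficulty: Difficulty
    data: pd.DataFrame
    start_point: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.feedback = Feedback(self.feedback)
        self.difficulty = Difficulty(self.difficulty)
        self.start_point = np.asarray(self.start_point, dtype=float)
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"recording is missing channels: {missing}")
        # Normalize column order; drop any extras (e.g. a time column).
        self.data = self.data.loc[:, list(CHANNELS)].astype(float)
        self.data.reset_index(drop=True, inplace=True)

    def validate(self) -> "Recording":
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.data) == 0:
            raise ValueError("recording has no samples")
        if self.start_point.shape != (3,):
            raise ValueError("start_point must be a 3-vector")
        if not np.isfinite(self.data.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy()))[0]
            raise ValueError(
                f"non-finite value at sample {bad[0]}, channel {CHANNELS[bad[1]]}"
            )
        if not np.isfinite(self.start_point).all():
            raise ValueError("non-finite start_point")
        return self

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def condition(self) -> CrossedCondition:
        return CrossedCondition(self.feedback, self.difficulty)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def position(self, tracker: str) -> np.ndarray:
        """(n, 3) position of one tracker in mm."""
        cols = [f"{tracker}_{d}" for d in POSITION_DOFS]
        return self.data[cols].to_numpy()

    def with_data(self, data: pd.DataFrame) -> "Recording":
        return replace(self, data=data)

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())
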