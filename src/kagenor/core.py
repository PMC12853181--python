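"""Core data containers for homecage NOR analysis.

The pipeline's central objects are a per-frame keypoint track recorded at a
fixed frame rate (2 frames/s in the automated homecage), a per-frame boolean
exploration state for each object side, the phase schedule that defines the
analysis windows (habituation / sample / retention / test), and the cage
geometry used to convert keypoints into posture features.

Conventions: coordinates are image pixels with the origin at the top-left and
y increasing downward; centimetres via ``px_per_cm``; frames are 0-based; time
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FRAME_RATE = 2.0

PHASE_NAMES = ("habituation", "sample", "retention", "test")

BODYPARTS = (
    "snout",
    "ear_left",
    "ear_right",
    "spine_1",
    "spine_2",
    "spine_3",
    "tail_base",
)


class ScheduleError(ValueError):
    """Raised for inconsistent phase schedules."""


class TrackFormatError(ValueError):
    """Raised for malformed keypoint tracks."""


def frames_to_seconds(n_frames: int | np.ndarray, frame_rate: float = DEFAULT_FRAME_RATE) -> float | np.ndarray:
    """Convert a frame count to seconds at the given frame rate.

    At the native 2 frames/s, 500 frames correspond to 250 s.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return np.asarray(n_frames, dtype=float) / frame_rate if isinstance(n_frames, np.ndarray) else n_frames / frame_rate


@dataclass(frozen=True)
class Phase:
    """One schedule phase with its per-side object assignment."""

    name: str
    start_s: float
    end_s: float
    object_left: str = "baseline"
    object_right: str = "baseline"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, time_s: float) -> bool:
        return self.start_s <= time_s < self.end_s


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous phases plus the test-phase novelty map.

    ``novel_side`` names the side ('left' or 'right') carrying the
    never-seen object during the test phase; the other side holds the
    familiar duplicate.
    """

    phases: tuple[Phase, ...]
    novel_side: str

    def __post_init__(self) -> None:
        if self.novel_side not in ("left", "right"):
            raise ScheduleError(f"novel_side must be 'left' or 'right', got {self.novel_side!r}")
        names = [p.name for p in self.phases]
        for p in self.phases:
            if p.name not in PHASE_NAMES:
                raise ScheduleError(f"unknown phase name {p.name!r}")
            if p.duration_s <= 0:
                raise ScheduleError(f"phase {p.name!r} has non-positive duration")
        if len(set(names)) != len(names):
            raise ScheduleError("duplicate phase names")
        for a, b in zip(self.phases[:-1], self.phases[1:]):
            if not np.isclose(a.end_s, b.start_s):
                raise ScheduleError(f"phases {a.name!r} and {b.name!r} are not contiguous")

    @property
    def familiar_side(self) -> str:
        return "right" if self.novel_side == "left" else "left"

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1].end_s - self.phases[0].start_s

    def phase(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def has_phase(self, name: str) -> bool:
        return any(p.name == name for p in self.phases)

    def frame_slice(self, name: str, frame_rate: float = DEFAULT_FRAME_RATE) -> slice:
        """Half-open frame range of a phase at the given frame rate."""
        p = self.phase(name)
        return slice(int(round(p.start_s * frame_rate)), int(round(p.end_s * frame_rate)))

    def to_dict(self) -> dict:
        return {
            "novel_side": self.novel_side,
            "phases": [
                {
                    "name": p.name,
                    "start_s": p.start_s,
                    "end_s": p.end_s,
                    "object_left": p.object_left,
                    "object_right": p.object_right,
                }
                for p in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhaseSchedule":
        phases = tuple(
            Phase(
                name=p["name"],
                start_s=float(p["start_s"]),
                end_s=float(p["end_s"]),
                object_left=p.get("object_left", "baseline"),
                object_right=p.get("object_right", "baseline"),
            )
            for p in d["phases"]
        )
        return cls(phases=phases, novel_side=d["novel_side"])

    @classmethod
    def standard(
        cls,
        habituation_s: float = 9 * 86400.0,
        sample_s: float = 86400.0,
        retention_s: float = 86400.0,
        test_s: float = 7200.0,
        novel_side: str = "left",
        sample_objects: tuple[str, str] = ("wood", "metal"),
        test_novel_object: str = "acrylic",
    ) -> "PhaseSchedule":
        """The standard four-phase protocol schedule: 9 d habituation, 24 h sample,
        24 h (or 7 d) retention, then test. Durations are configurable so
        desk-scale simulations can use shorter phases."""
        t0 = 0.0
        t1 = t0 + habituation_s
        t2 = t1 + sample_s
        t3 = t2 + retention_s
        t4 = t3 + test_s
        left_sample, right_sample = sample_objects
        if novel_side == "left":
            test_left, test_right = test_novel_object, right_sample
        else:
            test_left, test_right = left_sample, test_novel_object
        return cls(
            phases=(
                Phase("habituation", t0, t1, "baseline", "baseline"),
                Phase("sample", t1, t2, left_sample, right_sample),
                Phase("retention", t2, t3, "baseline", "baseline"),
                Phase("test", t3, t4, test_left, test_right),
            ),
            novel_side=novel_side,
        )


@dataclass
class KeypointTrack:
    """Per-frame body-part coordinates and confidences at a fixed frame rate.

    ``data`` has a two-level column index (bodypart, coord) with coords
    x / y / likelihood, one row per frame, mirroring DeepLabCut output.
    """

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise TrackFormatError("frame_rate must be positive")
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise TrackFormatError("keypoint data needs (bodypart, coord) columns")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) array of x/y for one body part."""
        if bodypart not in self.bodyparts:
            raise TrackFormatError(f"missing body part {bodypart!r}")
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, bodypart: str) -> np.ndarray:
        if bodypart not in self.bodyparts:
            raise TrackFormatError(f"missing body part {bodypart!r}")
        return self.data[(bodypart, "likelihood")].to_numpy(dtype=float)

    def require_bodyparts(self, parts: Iterable[str]) -> None:
        missing = [p for p in parts if p not in self.bodyparts]
        if missing:
            raise TrackFormatError(f"missing body part column(s): {', '.join(missing)}")

    @classmethod
    def from_arrays(
        cls,
        coords: Mapping[str, np.ndarray],
        likelihoods: Mapping[str, np.ndarray] | None = None,
        frame_rate: float = DEFAULT_FRAME_RATE,
    ) -> "KeypointTrack":
        """Build a track from per-bodypart (n, 2) coordinate arrays."""
        cols = {}
        for part, xy in coords.items():
            xy = np.asarray(xy, dtype=float)
            cols[(part, "x")] = xy[:, 0]
            cols[(part, "y")] = xy[:, 1]
            if likelihoods is not None and part in likelihoods:
                cols[(part, "likelihood")] = np.asarray(likelihoods[part], dtype=float)
            else:
                cols[(part, "likelihood")] = np.ones(len(xy))
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
        return cls(data=df, frame_rate=frame_rate)


@dataclass
class ExplorationSeries:
    """Per-frame boolean exploration state per object side.

    The two sides are mutually exclusive on any frame: the cage geometry
    makes simultaneous exploration of both objects physically impossible.
    """

    explore_left: np.ndarray
    explore_right: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.explore_left = np.asarray(self.explore_left, dtype=bool)
        self.explore_right = np.asarray(self.explore_right, dtype=bool)
        if self.explore_left.shape != self.explore_right.shape:
            raise ValueError("left/right label arrays differ in length")
        if np.any(self.explore_left & self.explore_right):
            raise ValueError("exploration labels true on both sides in one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.explore_left)

    @property
    def any_explore(self) -> np.ndarray:
        return self.explore_left | self.explore_right

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def side(self, which: str) -> np.ndarray:
        if which == "left":
            return self.explore_left
        if which == "right":
            return self.explore_right
        raise KeyError(which)

    def seconds(self, which: str, window: slice | None = None) -> float:
        arr = self.side(which)
        if window is not None:
            arr = arr[window]
        return float(arr.sum()) / self.frame_rate

    def window_frames(self, start_s: float, end_s: float) -> slice:
        return slice(int(round(start_s * self.frame_rate)), int(round(end_s * self.frame_rate)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.time_s,
                "explore_left": self.explore_left.astype(int),
                "explore_right": self.explore_right.astype(int),
            }
        )


@dataclass(frozen=True)
class ObjectWindow:
    """Access window through which the mouse reaches one object."""

    x: float
    y: float
    radius: float  # px

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class CageLayout:
    """Cage geometry in image pixels, calibrated by ``px_per_cm``.

    Defaults encode a 39 x 32 cm homecage at 5 px/cm with the two object
    windows at the mid-height of the left and right walls and the drinking
    corridor entries near the bottom corners.
    """

    width_px: float = 195.0
    height_px: float = 160.0
    px_per_cm: float = 5.0
    object_window_left: ObjectWindow = field(default_factory=lambda: ObjectWindow(8.0, 80.0, 18.0))
    object_window_right: ObjectWindow = field(default_factory=lambda: ObjectWindow(187.0, 80.0, 18.0))
    corridor_entry_left: ObjectWindow = field(default_factory=lambda: ObjectWindow(25.0, 150.0, 15.0))
    corridor_entry_right: ObjectWindow = field(default_factory=lambda: ObjectWindow(170.0, 150.0, 15.0))

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        for w in (
            self.object_window_left,
            self.object_window_right,
            self.corridor_entry_left,
            self.corridor_entry_right,
        ):
            if w.radius <= 0:
                raise ValueError("window radii must be positive")
        d = np.hypot(
            self.object_window_left.x - self.object_window_right.x,
            self.object_window_left.y - self.object_window_right.y,
        )
        if d <= self.object_window_left.radius + self.object_window_right.radius:
            raise ValueError("left/right object windows overlap")

    def object_window(self, side: str) -> ObjectWindow:
        return self.object_window_left if side == "left" else self.object_window_right

    def corridor_entry(self, side: str) -> ObjectWindow:
        return self.corridor_entry_left if side == "left" else self.corridor_entry_right

    def px_to_cm(self, value_px: float | np.ndarray) -> float | np.ndarray:
        return value_px / self.px_per_cm

    def mirrored(self) -> "CageLayout":
        """Left-right mirror of the cage (used for symmetry checks)."""

        def flip(w: ObjectWindow) -> ObjectWindow:
            return ObjectWindow(self.width_px - w.x, w.y, w.radius)

        return replace(
            self,
            object_window_left=flip(self.object_window_right),
            object_window_right=flip(self.object_window_left),
            corridor_entry_left=flip(self.corridor_entry_right),
            corridor_entry_right=flip(self.corridor_entry_left),
        )


def sides() -> Sequence[str]:
    return ("left", "right")
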