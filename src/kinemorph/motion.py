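"""Data model and file I/O for 2D landmark motion trajectories.

Coordinates follow a screen convention with the origin at the lower-left
and y increasing upward, so vertical amplitudes grow as the hands rise
above the desk line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical 12-landmark set for an upper-body speaker figure.  The five
#: anatomically named landmarks (forehead, throat, hands, centre of gravity)
#: drive standardization and expansiveness scoring; the rest exist so the
#: rendered figure has limbs to interpolate.
CANONICAL_LANDMARKS: tuple[str, ...] = (
    "forehead",
    "throat",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hand",
    "right_hand",
    "left_hip",
    "right_hip",
    "centre_of_gravity",
    "sternum",
)

REQUIRED_LANDMARKS = frozenset(
    {"forehead", "throat", "right_hand", "left_hand", "centre_of_gravity"}
)

#: Default playback rate of the source material, frames per second.
DEFAULT_FPS = 25

#: Default vertical level of the desk line, pixels.
DEFAULT_DESK_Y = 400.0


class MotionError(ValueError):
    """Invalid motion data (structure, values, or lookup failure)."""


@dataclass(frozen=True)
class Skeleton:
    """Named landmark set plus the desk reference line.

    Parameters
    ----------
    landmark_names : sequence of str
        Exactly 12 unique identifiers including the five anatomical
        landmarks used throughout (forehead, throat, left/right hand,
        centre_of_gravity).
    desk_y : float
        Vertical level of the desk in pixels; vertical expansiveness is
        measured as height above this line.
    """

    landmark_names: tuple[str, ...] = CANONICAL_LANDMARKS
    desk_y: float = DEFAULT_DESK_Y

    def __post_init__(self) -> None:
        names = tuple(self.landmark_names)
        object.__setattr__(self, "landmark_names", names)
        if len(names) != 12:
            raise MotionError(f"skeleton needs exactly 12 landmarks, got {len(names)}")
        if len(set(names)) != len(names):
            raise MotionError("landmark names must be unique")
        missing = REQUIRED_LANDMARKS - set(names)
        if missing:
            raise MotionError(f"skeleton is missing required landmarks: {sorted(missing)}")

    def index(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise MotionError(f"unknown landmark {name!r}") from None


@dataclass(frozen=True)
class MotionSequence:
    """Per-frame 2D coordinates for a named landmark set.

    ``coords`` has shape ``(n_frames, n_landmarks, 2)`` with the last axis
    holding (x, y) in pixels.
    """

    skeleton: Skeleton
    coords: np.ndarray
    fps: int = DEFAULT_FPS
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise MotionError(f"coords must have shape (frames, landmarks, 2), got {arr.shape}")
        if arr.shape[1] != len(self.skeleton.landmark_names):
            raise MotionError(
                f"frame width {arr.shape[1]} does not match skeleton "
                f"({len(self.skeleton.landmark_names)} landmarks)"
            )
        if arr.shape[0] < 2:
            raise MotionError("a motion sequence needs at least 2 frames")
        if not np.all(np.isfinite(arr)):
            raise MotionError("all coordinates must be finite")
        if not (isinstance(self.fps, (int, np.integer)) and self.fps >= 1):
            raise MotionError(f"fps must be a positive integer, got {self.fps!r}")
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)
        object.__setattr__(self, "fps", int(self.fps))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def track(self, landmark: str) -> np.ndarray:
        """(n_frames, 2) trajectory of one landmark."""
        return self.coords[:, self.skeleton.index(landmark), :]

    def x(self, landmark: str) -> np.ndarray:
        return self.track(landmark)[:, 0]

    def y(self, landmark: str) -> np.ndarray:
        return self.track(landmark)[:, 1]

    def with_coords(self, coords: np.ndarray, **changes) -> "MotionSequence":
        return replace(self, coords=coords, **changes)


@dataclass(frozen=True)
class DotSequence:
    """A single moving point: the body-form-free reduction of a figure."""

    coords: np.ndarray  # (n_frames, 2)
    fps: int = DEFAULT_FPS
    source_landmark: str = "right_hand"
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise MotionError(f"dot coords must have shape (frames, 2), got {arr.shape}")
        if arr.shape[0] < 2:
            raise MotionError("a dot sequence needs at least 2 frames")
        if not np.all(np.isfinite(arr)):
            raise MotionError("all coordinates must be finite")
        if not (isinstance(self.fps, (int, np.integer)) and self.fps >= 1):
            raise MotionError(f"fps must be a positive integer, got {self.fps!r}")
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)
        object.__setattr__(self, "fps", int(self.fps))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def to_dot(seq: MotionSequence, landmark: str = "right_hand") -> DotSequence:
    """Reduce a figure to a single moving dot (by default the right hand)."""
    track = seq.track(landmark)  # raises MotionError on unknown landmark
    return DotSequence(coords=track.copy(), fps=seq.fps, source_landmark=landmark, label=seq.label)


def embed_dot(dot: DotSequence, skeleton: Skeleton) -> MotionSequence:
    """Embed a dot track back into a full sequence: every landmark follows the dot.

    Useful for pushing dot stimuli through figure-shaped machinery.
    """
    n = dot.n_frames
    coords = np.repeat(dot.coords[:, None, :], len(skeleton.landmark_names), axis=1)
    return MotionSequence(skeleton=skeleton, coords=coords, fps=dot.fps, label=dot.label)


# ---------------------------------------------------------------------------
# File I/O.  Tidy CSV (frame,landmark,x,y with a '#fps=' header comment) and
# a JSON dialect that round-trips coordinates bit-exactly.
# ---------------------------------------------------------------------------

def _infer_skeleton(names: Sequence[str], desk_y: float) -> Skeleton:
    ordered = [n for n in CANONICAL_LANDMARKS if n in names]
    extras = [n for n in names if n not in CANONICAL_LANDMARKS]
    return Skeleton(landmark_names=tuple(ordered + extras), desk_y=desk_y)


def read_motion(path: str | Path, format: str | None = None) -> MotionSequence:
    """Read a landmark trajectory file (tidy CSV or JSON).

    The format is inferred from the suffix when not given.  CSV files carry
    one record per (frame, landmark) with columns ``frame,landmark,x,y`` and
    optional ``#fps=``/``#desk_y=``/``#label=`` header comments; fps defaults
    to 25 when absent.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        skeleton = Skeleton(
            landmark_names=tuple(payload["skeleton"]),
            desk_y=float(payload.get("desk_y", DEFAULT_DESK_Y)),
        )
        return MotionSequence(
            skeleton=skeleton,
            coords=np.asarray(payload["frames"], dtype=float),
            fps=int(payload.get("fps", DEFAULT_FPS)),
            label=str(payload.get("label", "")),
        )
    if fmt != "csv":
        raise MotionError(f"unknown format {fmt!r}")

    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    table = pd.read_csv(path, comment="#")
    required_cols = {"frame", "landmark", "x", "y"}
    if not required_cols.issubset(table.columns):
        raise MotionError(f"CSV must have columns {sorted(required_cols)}")
    if not (
        pd.api.types.is_numeric_dtype(table["x"]) and pd.api.types.is_numeric_dtype(table["y"])
    ):
        raise MotionError("non-numeric coordinate values in CSV")

    fps = int(meta.get("fps", DEFAULT_FPS))
    desk_y = float(meta.get("desk_y", DEFAULT_DESK_Y))
    names = list(dict.fromkeys(table["landmark"]))
    skeleton = _infer_skeleton(names, desk_y)
    frame_ids = np.sort(table["frame"].unique())
    wide = table.set_index(["frame", "landmark"])
    coords = np.empty((len(frame_ids), 12, 2), dtype=float)
    for t, frame_id in enumerate(frame_ids):
        for i, name in enumerate(skeleton.landmark_names):
            try:
                row = wide.loc[(frame_id, name)]
            except KeyError:
                raise MotionError(
                    f"frame {frame_id} is missing landmark {name!r}"
                ) from None
            coords[t, i] = (float(row["x"]), float(row["y"]))
    return MotionSequence(
        skeleton=skeleton, coords=coords, fps=fps, label=meta.get("label", "")
    )


def write_motion(seq: MotionSequence, path: str | Path, format: str | None = None) -> Path:
    """Write a sequence to disk.

    JSON round-trips coordinates bit-exactly; CSV prints 6 decimals.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {
            "fps": seq.fps,
            "label": seq.label,
            "desk_y": seq.skeleton.desk_y,
            "skeleton": list(seq.skeleton.landmark_names),
            "frames": seq.coords.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path
    if fmt != "csv":
        raise MotionError(f"unknown format {fmt!r}")
    records = []
    for t in range(seq.n_frames):
        for i, name in enumerate(seq.skeleton.landmark_names):
            records.append((t, name, seq.coords[t, i, 0], seq.coords[t, i, 1]))
    table = pd.DataFrame(records, columns=["frame", "landmark", "x", "y"])
    with open(path, "w") as fh:
        fh.write(f"#fps={seq.fps}\n#desk_y={seq.skeleton.desk_y}\n")
        if seq.label:
            fh.write(f"#label={seq.label}\n")
        table.to_csv(fh, index=False, float_format="%.6f")
    return path
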