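"""Axis-isolated motion prototypes and slider-controlled stimulus morphing.

A *prototype* moves along exactly one axis: a vertical prototype keeps the
x-coordinates of every frame pinned to a neutral "standard" posture while
the y-coordinates move, and vice versa.  A stimulus is composed from one
vertical and one horizontal prototype by taking, per landmark and frame, a
weighted mean between the prototype coordinate and the standard posture:

    y'_{i,t} = w_v * y_{i,t} + (1 - w_v) * ybar_i
    x'_{i,t} = w_h * x_{i,t} + (1 - w_h) * xbar_i

with the weights w = s/10 set by integer sliders s in 0..10.  A third
slider maps linearly to playback frame rate between 25 and 58 fps, making
the same trajectory appear slower or faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .motion import CANONICAL_LANDMARKS, MotionSequence, Skeleton

FPS_MIN = 25
FPS_MAX = 58

# Neutral reference posture: centered over the middle of the desk, hands
# held close together at navel height.  The exact numbers are a package
# convention chosen to be consistent with a standardized figure (275 px
# forehead-to-centre-of-gravity stretch, centre of gravity at (345, 341),
# desk line at y = 400 just below the resting hands).
_STANDARD_COORDS = {
    "forehead": (345.0, 616.0),
    "throat": (345.0, 560.0),
    "left_shoulder": (305.0, 548.0),
    "right_shoulder": (385.0, 548.0),
    "left_elbow": (295.0, 478.0),
    "right_elbow": (395.0, 478.0),
    "left_hand": (338.0, 420.0),
    "right_hand": (352.0, 420.0),
    "left_hip": (315.0, 365.0),
    "right_hip": (375.0, 365.0),
    "centre_of_gravity": (345.0, 341.0),
    "sternum": (345.0, 530.0),
}


class SliderError(ValueError):
    """Slider value outside the 0..10 range."""


@dataclass(frozen=True)
class StandardFigure:
    """Static neutral posture used as the damping target for both axes."""

    skeleton: Skeleton
    coords: np.ndarray  # (n_landmarks, 2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.shape != (len(self.skeleton.landmark_names), 2):
            raise ValueError(f"standard figure coords shape {arr.shape} invalid")
        if not np.all(np.isfinite(arr)):
            raise ValueError("standard figure coordinates must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)

    def x(self, landmark: str) -> float:
        return float(self.coords[self.skeleton.index(landmark), 0])

    def y(self, landmark: str) -> float:
        return float(self.coords[self.skeleton.index(landmark), 1])

    def as_sequence(self, n_frames: int, fps: int = FPS_MIN) -> MotionSequence:
        coords = np.repeat(self.coords[None, :, :], n_frames, axis=0)
        return MotionSequence(
            skeleton=self.skeleton, coords=coords, fps=fps, label="standard"
        )


def standard_figure(desk_y: float = 400.0) -> StandardFigure:
    """Package-default standard figure on the canonical skeleton."""
    skeleton = Skeleton(landmark_names=CANONICAL_LANDMARKS, desk_y=desk_y)
    coords = np.array([_STANDARD_COORDS[name] for name in skeleton.landmark_names])
    return StandardFigure(skeleton=skeleton, coords=coords)


@dataclass(frozen=True)
class Prototype:
    """A motion sequence constrained to a single axis."""

    seq: MotionSequence
    axis: str  # vertical | horizontal

    def __post_init__(self) -> None:
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError(f"axis must be vertical or horizontal, got {self.axis!r}")
        frozen_axis = 0 if self.axis == "vertical" else 1
        track = self.seq.coords[:, :, frozen_axis]
        if not np.all(track == track[0]):
            raise ValueError(
                f"a {self.axis} prototype must have constant "
                f"{'x' if frozen_axis == 0 else 'y'}-coordinates"
            )


@dataclass(frozen=True)
class SliderState:
    """The three integer slider positions: vertical, horizontal, velocity."""

    s_v: int
    s_h: int
    s_vel: int

    def __post_init__(self) -> None:
        for name, value in (("s_v", self.s_v), ("s_h", self.s_h), ("s_vel", self.s_vel)):
            if not (isinstance(value, (int, np.integer)) and 0 <= value <= 10):
                raise SliderError(f"{name} must be an integer in 0..10, got {value!r}")


@dataclass(frozen=True)
class Stimulus:
    """A composed animation plus the slider triplet that produced it."""

    seq: MotionSequence
    sliders: SliderState
    vproto_id: str = ""
    hproto_id: str = ""


def slider_to_weight(s: int) -> float:
    """Map an integer slider position 0..10 to an interpolation weight s/10."""
    if not (isinstance(s, (int, np.integer)) and 0 <= s <= 10):
        raise SliderError(f"slider value must be an integer in 0..10, got {s!r}")
    return s / 10


def velocity_to_fps(s_vel: int) -> int:
    """Linear slider-to-frame-rate map hitting 25 fps at 0 and 58 fps at 10.

    Intermediate positions round half away from zero (slider 5 -> 42 fps).
    """
    if not (isinstance(s_vel, (int, np.integer)) and 0 <= s_vel <= 10):
        raise SliderError(f"velocity slider must be an integer in 0..10, got {s_vel!r}")
    raw = FPS_MIN + s_vel * (FPS_MAX - FPS_MIN) / 10
    return int(np.floor(raw + 0.5))


def isolate_axis(seq: MotionSequence, standard: StandardFigure, axis: str) -> Prototype:
    """Freeze the off-axis coordinates of every frame to the standard posture."""
    if axis not in ("vertical", "horizontal"):
        raise ValueError(f"axis must be vertical or horizontal, got {axis!r}")
    if tuple(seq.skeleton.landmark_names) != tuple(standard.skeleton.landmark_names):
        raise ValueError("sequence and standard figure skeletons differ")
    coords = seq.coords.copy()
    frozen_axis = 0 if axis == "vertical" else 1
    coords[:, :, frozen_axis] = standard.coords[None, :, frozen_axis]
    return Prototype(seq=seq.with_coords(coords), axis=axis)


def interpolate_axis(
    proto: Prototype, standard: StandardFigure, w: float
) -> MotionSequence:
    """Weighted mean between prototype and standard posture on the moving axis.

    w = 0 damps the axis completely (standard posture); w = 1 reproduces the
    prototype; the off-axis track is untouched.
    """
    if not (0.0 <= w <= 1.0):
        raise SliderError(f"weight must lie in [0, 1], got {w!r}")
    moving_axis = 1 if proto.axis == "vertical" else 0
    coords = proto.seq.coords.copy()
    coords[:, :, moving_axis] = (
        w * coords[:, :, moving_axis]
        + (1.0 - w) * standard.coords[None, :, moving_axis]
    )
    return proto.seq.with_coords(coords)


def compose_stimulus(
    vproto: Prototype,
    hproto: Prototype,
    standard: StandardFigure,
    sliders: SliderState,
) -> Stimulus:
    """Merge a vertical and a horizontal prototype under the current sliders.

    The y-track comes from damping the vertical prototype by s_v/10, the
    x-track from damping the horizontal prototype by s_h/10, and the frame
    rate from the velocity slider.  Pure: identical inputs give identical
    output.  Prototypes of unequal length are truncated to the shorter with
    a warning.
    """
    if vproto.axis != "vertical" or hproto.axis != "horizontal":
        raise ValueError("compose_stimulus needs a (vertical, horizontal) prototype pair")
    n_v, n_h = vproto.seq.n_frames, hproto.seq.n_frames
    if n_v != n_h:
        warnings.warn(
            f"prototype frame counts differ ({n_v} vs {n_h}); truncating to the shorter",
            stacklevel=2,
        )
        n = min(n_v, n_h)
        vproto = Prototype(seq=vproto.seq.with_coords(vproto.seq.coords[:n].copy()), axis="vertical")
        hproto = Prototype(seq=hproto.seq.with_coords(hproto.seq.coords[:n].copy()), axis="horizontal")

    y_seq = interpolate_axis(vproto, standard, slider_to_weight(sliders.s_v))
    x_seq = interpolate_axis(hproto, standard, slider_to_weight(sliders.s_h))
    coords = np.stack([x_seq.coords[:, :, 0], y_seq.coords[:, :, 1]], axis=2)
    seq = MotionSequence(
        skeleton=standard.skeleton,
        coords=coords,
        fps=velocity_to_fps(sliders.s_vel),
        label=f"stim:{vproto.seq.label}|{hproto.seq.label}",
    )
    return Stimulus(
        seq=seq,
        sliders=sliders,
        vproto_id=vproto.seq.label,
        hproto_id=hproto.seq.label,
    )
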