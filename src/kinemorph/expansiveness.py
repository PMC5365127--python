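"""Per-frame motion expansiveness scoring and maximal-window selection.

Vertical expansiveness of a frame is the summed height of the two hands and
the throat above the desk line; horizontal expansiveness is the summed
horizontal offset of the hands from the throat plus the throat's offset
from the coordinate origin (body sway).  Five-second windows maximizing the
summed score identify each figure's most expansive episode, and the top-k
episodes across a catalog become prototype candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import MotionSequence

HAND_LANDMARKS = ("right_hand", "left_hand", "throat")


@dataclass(frozen=True)
class ExpansivenessSeries:
    """Per-frame nonnegative expansiveness scores for one axis."""

    values: np.ndarray
    axis: str
    source_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("expansiveness series must be one-dimensional")
        if np.any(arr < 0):
            raise ValueError("expansiveness values must be nonnegative")
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError(f"axis must be vertical or horizontal, got {self.axis!r}")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WindowSelection:
    """A maximal-expansiveness window within one source sequence."""

    start_frame: int
    length_frames: int
    score: float
    axis: str
    source_label: str = ""
    source_index: int = -1
    amplitudes: dict = field(default_factory=dict)  # landmark -> (x_amp, y_amp)

    def __post_init__(self) -> None:
        if self.start_frame < 0 or self.length_frames < 1:
            raise ValueError("invalid window bounds")
        if self.score < 0:
            raise ValueError("window score must be nonnegative")


def vertical_expansiveness(seq: MotionSequence) -> ExpansivenessSeries:
    """E_v(t) = |y_rhand - desk| + |y_lhand - desk| + |y_throat - desk|."""
    desk = seq.skeleton.desk_y
    values = sum(np.abs(seq.y(name) - desk) for name in HAND_LANDMARKS)
    return ExpansivenessSeries(values=values, axis="vertical", source_label=seq.label)


def horizontal_expansiveness(seq: MotionSequence) -> ExpansivenessSeries:
    """E_h(t) = |x_rhand - x_throat| + |x_lhand - x_throat| + |x_throat|."""
    throat_x = seq.x("throat")
    values = (
        np.abs(seq.x("right_hand") - throat_x)
        + np.abs(seq.x("left_hand") - throat_x)
        + np.abs(throat_x)
    )
    return ExpansivenessSeries(values=values, axis="horizontal", source_label=seq.label)


def expansiveness(seq: MotionSequence, axis: str) -> ExpansivenessSeries:
    if axis == "vertical":
        return vertical_expansiveness(seq)
    if axis == "horizontal":
        return horizontal_expansiveness(seq)
    raise ValueError(f"axis must be vertical or horizontal, got {axis!r}")


def _window_amplitudes(seq: MotionSequence, start: int, length: int) -> dict:
    sub = seq.coords[start : start + length]
    span = sub.max(axis=0) - sub.min(axis=0)  # (landmarks, 2)
    return {
        name: (float(span[i, 0]), float(span[i, 1]))
        for i, name in enumerate(seq.skeleton.landmark_names)
    }


def max_window(
    series: ExpansivenessSeries,
    length_frames: int = 125,
    seq: MotionSequence | None = None,
) -> WindowSelection:
    """Window of the given length maximizing the summed per-frame score.

    Ties break to the earliest start.  If the source sequence is supplied,
    per-landmark (max - min) amplitudes within the window are reported.
    """
    n = len(series)
    if length_frames > n:
        raise ValueError(f"series of length {n} is shorter than window ({length_frames})")
    # cumulative-sum sliding window; exact because values are modest floats
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    window_sums = csum[length_frames:] - csum[:-length_frames]
    start = int(np.argmax(window_sums))  # argmax takes the first maximum
    amplitudes = (
        _window_amplitudes(seq, start, length_frames) if seq is not None else {}
    )
    return WindowSelection(
        start_frame=start,
        length_frames=length_frames,
        score=float(window_sums[start]),
        axis=series.axis,
        source_label=series.source_label,
        amplitudes=amplitudes,
    )


def extract_window(seq: MotionSequence, selection: WindowSelection) -> MotionSequence:
    """Cut the selected window out of its source sequence."""
    lo, hi = selection.start_frame, selection.start_frame + selection.length_frames
    return seq.with_coords(seq.coords[lo:hi].copy())


def rank_and_select(
    catalog: list[MotionSequence],
    axis: str,
    k: int = 10,
    length_frames: int = 125,
) -> list[WindowSelection]:
    """One maximal window per catalog entry; top k by score, descending.

    Ties keep catalog order (stable sort), so the result is deterministic.
    """
    if not catalog:
        raise ValueError("catalog must be nonempty")
    if k > len(catalog):
        raise ValueError(f"cannot select top {k} from a catalog of {len(catalog)}")
    selections = []
    for idx, seq in enumerate(catalog):
        sel = max_window(expansiveness(seq, axis), length_frames, seq=seq)
        selections.append(
            WindowSelection(
                start_frame=sel.start_frame,
                length_frames=sel.length_frames,
                score=sel.score,
                axis=sel.axis,
                source_label=sel.source_label,
                source_index=idx,
                amplitudes=sel.amplitudes,
            )
        )
    order = sorted(range(len(selections)), key=lambda i: -selections[i].score)
    return [selections[i] for i in order[:k]]
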