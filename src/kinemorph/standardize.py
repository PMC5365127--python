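"""Bring every figure to a standard height and screen position.

Differences in body height and limb length between recorded speakers are a
confound for amplitude-based motion measures.  Each figure is therefore
uniformly rescaled so its maximal forehead-to-centre-of-gravity stretch
equals a standard height (275 px), then rigidly translated so the centre of
gravity sits at a fixed anchor point in the frame of maximum stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .motion import MotionSequence


class DegenerateFigureError(ValueError):
    """Figure has zero height in every frame; cannot be standardized."""


@dataclass(frozen=True)
class StandardizationParams:
    """Standard height and anchor position, in pixels."""

    target_height: float = 275.0
    anchor_x: float = 345.0
    anchor_y: float = 341.0

    def __post_init__(self) -> None:
        if self.target_height <= 0 or self.anchor_x <= 0 or self.anchor_y <= 0:
            raise ValueError("standardization parameters must be strictly positive")


def _stretch_per_frame(seq: MotionSequence) -> np.ndarray:
    return np.abs(seq.y("forehead") - seq.y("centre_of_gravity"))


def figure_height(seq: MotionSequence) -> float:
    """Maximal vertical forehead-to-centre-of-gravity distance over all frames."""
    height = float(_stretch_per_frame(seq).max())
    if height <= 0.0:
        raise DegenerateFigureError(
            "figure has zero forehead-to-centre-of-gravity stretch in every frame"
        )
    return height


def max_stretch_frame(seq: MotionSequence) -> int:
    """Index of the frame attaining the maximal stretch (earliest on ties)."""
    return int(np.argmax(_stretch_per_frame(seq)))


def normalize_height(
    seq: MotionSequence, params: StandardizationParams = StandardizationParams()
) -> MotionSequence:
    """Uniformly scale all coordinates so the figure height equals the target.

    Scaling is about the coordinate origin with the same factor on both
    axes, so shape and amplitude ratios are preserved; position is fixed
    afterwards by :func:`reposition`.  The desk line scales with the figure.
    """
    factor = params.target_height / figure_height(seq)
    skeleton = replace(seq.skeleton, desk_y=seq.skeleton.desk_y * factor)
    return MotionSequence(
        skeleton=skeleton, coords=seq.coords * factor, fps=seq.fps, label=seq.label
    )


def reposition(
    seq: MotionSequence, params: StandardizationParams = StandardizationParams()
) -> MotionSequence:
    """Rigidly translate the figure so its centre of gravity in the
    maximum-stretch frame lands on the anchor point."""
    t = max_stretch_frame(seq)
    cog = seq.track("centre_of_gravity")[t]
    shift = np.array([params.anchor_x, params.anchor_y]) - cog
    skeleton = replace(seq.skeleton, desk_y=seq.skeleton.desk_y + shift[1])
    return MotionSequence(
        skeleton=skeleton, coords=seq.coords + shift, fps=seq.fps, label=seq.label
    )


def standardize(
    seq: MotionSequence, params: StandardizationParams = StandardizationParams()
) -> MotionSequence:
    """Height normalization followed by repositioning; idempotent."""
    return reposition(normalize_height(seq, params), params)
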