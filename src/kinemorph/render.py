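"""Headless animation export for composed stimuli and dot sequences.

Frames are drawn on a 768x432 canvas (the original animation window size)
and written as an animated GIF.  GIF stores frame durations in 10 ms
units, so the exact requested frame rate is additionally recorded in a
JSON sidecar manifest next to the animation file.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .morph import Stimulus  # noqa: E402
from .motion import DotSequence, MotionSequence  # noqa: E402

CANVAS_PX = (768, 432)

# limb segments drawn in stick mode (pairs of landmark names)
SKELETON_EDGES = (
    ("forehead", "throat"),
    ("throat", "sternum"),
    ("sternum", "centre_of_gravity"),
    ("throat", "left_shoulder"),
    ("throat", "right_shoulder"),
    ("left_shoulder", "left_elbow"),
    ("right_shoulder", "right_elbow"),
    ("left_elbow", "left_hand"),
    ("right_elbow", "right_hand"),
    ("centre_of_gravity", "left_hip"),
    ("centre_of_gravity", "right_hip"),
)


def _viewport(points: np.ndarray) -> tuple:
    """Axis limits with the canvas aspect ratio covering all points."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    center = (lo + hi) / 2
    span = np.maximum(hi - lo, 1.0) * 1.15
    aspect = CANVAS_PX[0] / CANVAS_PX[1]
    w = max(span[0], span[1] * aspect)
    h = w / aspect
    return (center[0] - w / 2, center[0] + w / 2, center[1] - h / 2, center[1] + h / 2)


def _draw_frames(coords: np.ndarray, mode: str, skeleton=None) -> list[np.ndarray]:
    limits = _viewport(coords.reshape(-1, 2))
    dpi = 96
    fig, ax = plt.subplots(
        figsize=(CANVAS_PX[0] / dpi, CANVAS_PX[1] / dpi), dpi=dpi
    )
    frames = []
    try:
        for frame in coords:
            ax.clear()
            ax.set_xlim(limits[0], limits[1])
            ax.set_ylim(limits[2], limits[3])
            ax.set_axis_off()
            if mode == "stick":
                idx = {n: i for i, n in enumerate(skeleton.landmark_names)}
                for a, b in SKELETON_EDGES:
                    if a in idx and b in idx:
                        pa, pb = frame[idx[a]], frame[idx[b]]
                        ax.plot([pa[0], pb[0]], [pa[1], pb[1]], "k-", lw=2)
                ax.plot(frame[:, 0], frame[:, 1], "ko", ms=4)
            else:  # dot: exactly one marker
                ax.plot(frame[0, 0], frame[0, 1], "ko", ms=10)
            fig.canvas.draw()
            buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3]
            frames.append(buf.copy())
    finally:
        plt.close(fig)
    return frames


def render_animation(
    stim: Stimulus | MotionSequence | DotSequence,
    path: str | Path,
    mode: str = "stick",
) -> Path:
    """Write an animated GIF of a stimulus (stick mode) or a dot sequence.

    A ``<path>.json`` sidecar records the exact frame rate and frame
    count, since the GIF container quantizes frame durations to 10 ms.
    """
    if mode not in ("stick", "dot"):
        raise ValueError(f"mode must be 'stick' or 'dot', got {mode!r}")
    path = Path(path)

    if isinstance(stim, Stimulus):
        seq = stim.seq
    else:
        seq = stim
    if isinstance(seq, DotSequence):
        coords = seq.coords[:, None, :]
        skeleton = None
        mode = "dot"
    else:
        coords = seq.coords
        skeleton = seq.skeleton
        if mode == "dot":
            coords = seq.track("right_hand")[:, None, :]

    frames = _draw_frames(coords, mode, skeleton)
    iio.imwrite(path, frames, extension=".gif", duration=1000 / seq.fps, loop=0)
    manifest = {
        "fps": seq.fps,
        "n_frames": len(frames),
        "mode": mode,
        "canvas_px": list(CANVAS_PX),
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))
    return path
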