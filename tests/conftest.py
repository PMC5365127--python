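import numpy as np
import pandas as pd
import pytest

from kinemorph.morph import Prototype, isolate_axis, standard_figure
from kinemorph.motion import CANONICAL_LANDMARKS, MotionSequence, Skeleton


@pytest.fixture
def std():
    return standard_figure()


@pytest.fixture
def make_sequence():
    """Factory for random valid 12-landmark sequences."""

    def _make(n_frames=20, seed=0, fps=25, scale=50.0, desk_y=400.0):
        rng = np.random.default_rng(seed)
        skeleton = Skeleton(landmark_names=CANONICAL_LANDMARKS, desk_y=desk_y)
        base = standard_figure(desk_y).coords
        coords = base[None, :, :] + scale * rng.standard_normal((n_frames, 12, 2))
        return MotionSequence(skeleton=skeleton, coords=coords, fps=fps, label=f"rand-{seed}")

    return _make


@pytest.fixture
def make_prototype_pair(make_sequence, std):
    """Factory for a (vertical, horizontal) prototype pair of equal length."""

    def _make(n_frames=20, seed=0):
        v = isolate_axis(make_sequence(n_frames, seed), std, "vertical")
        h = isolate_axis(make_sequence(n_frames, seed + 1000), std, "horizontal")
        return v, h

    return _make


@pytest.fixture
def toy_records():
    """A tiny hand-built response table with a clean positive s_v effect."""
    rows = []
    rng = np.random.default_rng(42)
    for pid in range(20):
        for category in ("dominant", "friendly"):
            for polarity in (1, 0):
                base = 6 if polarity else 4
                rows.append(
                    {
                        "participant_id": pid,
                        "category": category,
                        "polarity": polarity,
                        "s_h": int(np.clip(base + rng.integers(-4, 5), 0, 10)),
                        "s_v": int(np.clip(base + rng.integers(-4, 5), 0, 10)),
                        "s_vel": int(rng.integers(0, 11)),
                        "experiment": "stick",
                    }
                )
    return pd.DataFrame(rows)
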