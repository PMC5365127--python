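"""Headless reverse-rating session protocol.

A session presents ten rounds — a "high" and a "low" version of each of
five social-category items, in random order.  Each round pairs a randomly
drawn vertical prototype with a randomly drawn horizontal prototype (10x10
pool gives 100 possible pairings), starts all three sliders at the center
position (5, 5, 5), and unlocks completion only once every slider has been
touched.  Finalizing a round emits an immutable response record with the
high version coded 1 and the low version coded 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .morph import SliderState

DEFAULT_CATEGORIES = ("dominant", "trustworthy", "friendly", "aggressive", "competent")
POLARITIES = ("high", "low")
SLIDER_NAMES = ("v", "h", "vel")
INITIAL_SLIDER = 5


class SessionError(RuntimeError):
    """Protocol violation: locked round finalized or finalized round touched."""


@dataclass(frozen=True)
class ItemSet:
    """The categories rated in a session, each in a high and a low version."""

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    polarities: tuple[str, ...] = POLARITIES

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        if len(set(cats)) != len(cats) or not cats:
            raise ValueError("categories must be nonempty and unique")
        if set(self.polarities) != {"high", "low"}:
            raise ValueError("both polarities (high, low) must be present")

    @property
    def item_versions(self) -> list[tuple[str, str]]:
        return [(c, p) for c in self.categories for p in ("high", "low")]


@dataclass(frozen=True)
class Round:
    """One item-version presentation with its slider state machine."""

    category: str
    polarity: str  # high | low
    vproto_id: object
    hproto_id: object
    sliders: tuple[int, int, int] = (INITIAL_SLIDER, INITIAL_SLIDER, INITIAL_SLIDER)
    touched: tuple[bool, bool, bool] = (False, False, False)
    finalized: bool = False

    @property
    def completable(self) -> bool:
        return all(self.touched)


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's final slider triplet for one item-version round."""

    participant_id: object
    category: str
    polarity: int  # 1 = high, 0 = low
    s_h: int
    s_v: int
    s_vel: int
    experiment: str = "stick"  # stick | dot

    def __post_init__(self) -> None:
        if self.polarity not in (0, 1):
            raise ValueError("polarity must be coded 1 (high) or 0 (low)")
        for name in ("s_h", "s_v", "s_vel"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 10):
                raise ValueError(f"{name} must be an integer in 0..10, got {v!r}")


def build_session(
    items: ItemSet,
    vpool: Sequence,
    hpool: Sequence,
    seed: int | np.random.Generator,
) -> list[Round]:
    """Build the ten rounds of one session.

    Item versions appear exactly once each, in a seeded uniform random
    order; every round draws its (vertical, horizontal) prototype pair
    independently and uniformly from ``vpool x hpool``.  Pure function of
    (items, pools, seed).
    """
    if len(vpool) == 0 or len(hpool) == 0:
        raise ValueError("prototype pools must be nonempty")
    rng = np.random.default_rng(seed)
    versions = items.item_versions
    order = rng.permutation(len(versions))
    rounds = []
    for idx in order:
        category, polarity = versions[idx]
        rounds.append(
            Round(
                category=category,
                polarity=polarity,
                vproto_id=vpool[int(rng.integers(len(vpool)))],
                hproto_id=hpool[int(rng.integers(len(hpool)))],
            )
        )
    return rounds


def touch_slider(round_: Round, which: str, value: int) -> Round:
    """Set one slider and mark it touched.

    Touching counts as interaction even when the value equals the initial
    center position: the unlock rule is about having moved every control,
    and a participant who wants the center value must still touch it.
    """
    if round_.finalized:
        raise SessionError("cannot touch sliders of a finalized round")
    if which not in SLIDER_NAMES:
        raise ValueError(f"unknown slider {which!r}; expected one of {SLIDER_NAMES}")
    if not (isinstance(value, (int, np.integer)) and 0 <= value <= 10):
        raise ValueError(f"slider value must be an integer in 0..10, got {value!r}")
    i = SLIDER_NAMES.index(which)
    sliders = list(round_.sliders)
    sliders[i] = int(value)
    touched = list(round_.touched)
    touched[i] = True
    return replace(round_, sliders=tuple(sliders), touched=tuple(touched))


def finalize_round(
    round_: Round, participant_id: object = None, experiment: str = "stick"
) -> ResponseRecord:
    """Emit the immutable response record once every slider was touched."""
    untouched = [name for name, t in zip(SLIDER_NAMES, round_.touched) if not t]
    if untouched:
        raise SessionError(
            f"round not completable: slider(s) {', '.join(untouched)} untouched"
        )
    s_v, s_h, s_vel = round_.sliders
    return ResponseRecord(
        participant_id=participant_id,
        category=round_.category,
        polarity=1 if round_.polarity == "high" else 0,
        s_h=s_h,
        s_v=s_v,
        s_vel=s_vel,
        experiment=experiment,
    )


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Response records as a tidy table (one row per round)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "category": r.category,
                "polarity": r.polarity,
                "s_h": r.s_h,
                "s_v": r.s_v,
                "s_vel": r.s_vel,
                "experiment": r.experiment,
            }
            for r in records
        ]
    )
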