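"""Synthetic gesture motion and simulated participant responses.

The generator stands in for two things no deposited data exists for: the
speech-gesture corpus the stimuli were cut from, and the human slider
responses.  Gesture kinematics are smooth sinusoid-plus-jitter limb paths
with controllable vertical/horizontal amplitude; responses are drawn per
slider from a rounded Gaussian around category-specific medians, clipped
to the 0..10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .morph import SliderState, standard_figure
from .motion import MotionSequence
from .session import ItemSet, build_session, finalize_round, records_to_frame, touch_slider

# ---------------------------------------------------------------------------
# Gesture motion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GestureParams:
    """Controls for one synthetic speaker-like gesture sequence.

    Amplitudes are the realized right-hand (max - min) excursions in
    pixels; published corpus summaries place plausible right-hand vertical
    amplitudes around 137-204 px and horizontal ones around 92-243 px.
    Oscillation frequencies are in Hz per limb; jitter_scale is the
    relative magnitude of smoothed Gaussian roughness added on top of the
    sinusoidal paths.
    """

    duration_s: float = 15.0
    fps: int = 25
    vertical_amplitude: float = 170.0
    horizontal_amplitude: float = 160.0
    frequencies: dict = field(
        default_factory=lambda: {"right_hand": 0.45, "left_hand": 0.35, "sway": 0.20}
    )
    phases: dict = field(default_factory=dict)
    jitter_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 5.0:
            raise ValueError("duration must be at least 5 s for window extraction")
        if self.vertical_amplitude < 0 or self.horizontal_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.fps < 1:
            raise ValueError("fps must be positive")


def _smooth_noise(rng: np.random.Generator, n: int, fps: int) -> np.ndarray:
    return gaussian_filter1d(rng.standard_normal(n), sigma=max(fps / 5, 1.0))


def synth_motion(params: GestureParams) -> MotionSequence:
    """Generate one 12-landmark speaker-like gesture sequence.

    Hands oscillate about the neutral posture with limb-specific frequency
    and phase; elbows follow at half amplitude; the upper body sways
    gently.  After composition the motion is rescaled per axis so the
    realized right-hand (max - min) amplitude equals the requested one
    exactly (a zero requested amplitude freezes that axis).  Deterministic
    per seed.
    """
    rng = np.random.default_rng(params.seed)
    std = standard_figure()
    names = std.skeleton.landmark_names
    n = max(int(round(params.duration_s * params.fps)), 2)
    t = np.arange(n) / params.fps
    freqs = params.frequencies
    coords = np.repeat(std.coords[None, :, :], n, axis=0).copy()

    def osc(freq_key: str, phase_key: str, default_phase: float) -> np.ndarray:
        freq = freqs.get(freq_key, 0.4)
        phase = params.phases.get(phase_key, default_phase)
        wave = np.sin(2 * np.pi * freq * t + phase)
        return wave + params.jitter_scale * 3.0 * _smooth_noise(rng, n, params.fps)

    # unit-scale motion patterns per landmark and axis; hands carry full
    # amplitude, elbows half, the upper body a gentle sway
    motion = {name: [np.zeros(n), np.zeros(n)] for name in names}
    rh_x, rh_y = osc("right_hand", "rh_x", 0.0), osc("right_hand", "rh_y", np.pi / 2)
    lh_x, lh_y = osc("left_hand", "lh_x", np.pi), osc("left_hand", "lh_y", np.pi / 3)
    sway = osc("sway", "sway", 0.7)
    bob = osc("sway", "bob", 2.1)
    motion["right_hand"] = [0.5 * rh_x, 0.5 * rh_y]
    motion["left_hand"] = [-0.5 * lh_x, 0.5 * lh_y]
    motion["right_elbow"] = [0.25 * rh_x, 0.25 * rh_y]
    motion["left_elbow"] = [-0.25 * lh_x, 0.25 * lh_y]
    for name in ("throat", "forehead", "sternum", "left_shoulder", "right_shoulder"):
        motion[name] = [0.12 * sway, 0.05 * bob]
    for name in ("left_hip", "right_hip", "centre_of_gravity"):
        motion[name] = [0.05 * sway, 0.02 * bob]

    for axis, amplitude in ((0, params.horizontal_amplitude), (1, params.vertical_amplitude)):
        if amplitude == 0:
            continue
        pattern = np.stack([motion[name][axis] for name in names], axis=1)
        realized = np.ptp(pattern[:, names.index("right_hand")])
        coords[:, :, axis] += pattern * (amplitude / realized)

    return MotionSequence(
        skeleton=std.skeleton,
        coords=coords,
        fps=params.fps,
        label=f"synth-{params.seed}",
    )


def synth_corpus(
    n: int,
    seed: int = 0,
    amplitude_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (90.0, 250.0),
        (130.0, 210.0),
    ),
    duration_s: float = 15.0,
    fps: int = 25,
) -> list[MotionSequence]:
    """A catalog of n gesture sequences with amplitudes spread over
    plausible corpus ranges ((horizontal), (vertical)); deterministic per seed."""
    rng = np.random.default_rng(seed)
    (h_lo, h_hi), (v_lo, v_hi) = amplitude_ranges
    corpus = []
    for i in range(n):
        params = GestureParams(
            duration_s=duration_s,
            fps=fps,
            horizontal_amplitude=float(rng.uniform(h_lo, h_hi)),
            vertical_amplitude=float(rng.uniform(v_lo, v_hi)),
            frequencies={
                "right_hand": float(rng.uniform(0.3, 0.6)),
                "left_hand": float(rng.uniform(0.25, 0.5)),
                "sway": float(rng.uniform(0.1, 0.3)),
            },
            phases={k: float(rng.uniform(0, 2 * np.pi)) for k in
                    ("rh_x", "rh_y", "lh_x", "lh_y", "sway", "bob")},
            seed=int(rng.integers(2**31)),
        )
        corpus.append(synth_motion(params))
    return corpus


# ---------------------------------------------------------------------------
# Participant responses
# ---------------------------------------------------------------------------

# Published median slider settings (horizontal, vertical, velocity) per
# item version; the templates for simulated response tendencies.
STICK_MEDIANS = {
    ("dominant", "high"): (7.0, 7.0, 6.0),
    ("dominant", "low"): (1.0, 1.0, 2.5),
    ("aggressive", "high"): (9.0, 10.0, 10.0),
    ("aggressive", "low"): (2.5, 2.0, 2.0),
    ("trustworthy", "high"): (4.0, 4.0, 3.0),
    ("trustworthy", "low"): (7.0, 6.0, 7.0),
    ("competent", "high"): (4.5, 5.0, 4.0),
    ("competent", "low"): (6.0, 4.0, 7.0),
    ("friendly", "high"): (4.0, 4.0, 3.0),
    ("friendly", "low"): (6.0, 8.0, 7.5),
}

DOT_MEDIANS = {
    ("dominant", "high"): (5.0, 8.0, 6.0),
    ("dominant", "low"): (2.0, 1.5, 2.0),
    ("aggressive", "high"): (8.5, 9.0, 10.0),
    ("aggressive", "low"): (3.0, 1.0, 1.0),
    ("trustworthy", "high"): (5.0, 2.5, 2.0),
    ("trustworthy", "low"): (7.5, 6.0, 7.0),
    ("competent", "high"): (5.0, 5.0, 3.0),
    ("competent", "low"): (6.0, 5.0, 7.0),
    ("friendly", "high"): (5.0, 5.0, 3.0),
    ("friendly", "low"): (6.5, 5.0, 7.5),
}


@dataclass(frozen=True)
class ResponseProfile:
    """Generative description of a simulated participant population.

    ``medians`` maps (category, polarity) to target medians (m_h, m_v,
    m_vel) on the 0..10 slider scale.  Each slider response is drawn as
    clip(round(Normal(median, sigma)), 0, 10), independently across
    sliders; setting ``noise_corr`` to a nonzero value switches to a
    Gaussian copula with that pairwise latent correlation, for
    stress-testing multicollinearity handling.
    """

    medians: dict
    sigma: float = 3.0
    noise_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (-0.5 <= self.noise_corr < 1.0):
            raise ValueError("noise_corr must lie in [-0.5, 1)")
        for key, m in self.medians.items():
            if len(m) != 3 or not all(0 <= v <= 10 for v in m):
                raise ValueError(f"medians for {key} must be three values in [0, 10]")

    @classmethod
    def stick(cls, sigma: float = 3.0, noise_corr: float = 0.0) -> "ResponseProfile":
        return cls(medians=dict(STICK_MEDIANS), sigma=sigma, noise_corr=noise_corr)

    @classmethod
    def dot(cls, sigma: float = 3.0, noise_corr: float = 0.0) -> "ResponseProfile":
        return cls(medians=dict(DOT_MEDIANS), sigma=sigma, noise_corr=noise_corr)

    @classmethod
    def null(cls, medians: tuple = (5.0, 5.0, 5.0), sigma: float = 3.0,
             categories: tuple = ("dominant", "trustworthy", "friendly",
                                  "aggressive", "competent")) -> "ResponseProfile":
        """Identical tendencies for high and low versions of every item."""
        table = {(c, p): medians for c in categories for p in ("high", "low")}
        return cls(medians=table, sigma=sigma)


def sample_sliders(
    profile: ResponseProfile, category: str, polarity: str, rng: np.random.Generator
) -> SliderState:
    """Draw one (s_v, s_h, s_vel) triplet for an item version."""
    try:
        m_h, m_v, m_vel = profile.medians[(category, polarity)]
    except KeyError:
        raise KeyError(f"profile has no entry for ({category!r}, {polarity!r})") from None
    means = np.array([m_h, m_v, m_vel])
    if profile.noise_corr == 0.0:
        z = rng.standard_normal(3)
    else:
        cov = np.full((3, 3), profile.noise_corr)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(3), cov)
    draws = np.clip(np.floor(means + profile.sigma * z + 0.5), 0, 10).astype(int)
    return SliderState(s_v=int(draws[1]), s_h=int(draws[0]), s_vel=int(draws[2]))


def generate_dataset(
    n_participants: int,
    profile: ResponseProfile,
    experiment: str = "stick",
    seed: int = 0,
    items: ItemSet | None = None,
    vpool: tuple = tuple(range(10)),
    hpool: tuple = tuple(range(10)),
) -> pd.DataFrame:
    """Simulate a full experiment: n participants x 10 rounds each.

    Every participant runs one session (seeded independently via a spawned
    child of the master seed), touches all three sliders with draws from
    the profile, and finalizes every round.  Reproducible per master seed.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    items = items or ItemSet()
    children = np.random.SeedSequence(seed).spawn(n_participants)
    records = []
    for pid, child in enumerate(children):
        rng = np.random.default_rng(child)
        rounds = build_session(items, vpool, hpool, rng)
        for round_ in rounds:
            sliders = sample_sliders(profile, round_.category, round_.polarity, rng)
            for which, value in (("v", sliders.s_v), ("h", sliders.s_h), ("vel", sliders.s_vel)):
                round_ = touch_slider(round_, which, value)
            records.append(finalize_round(round_, participant_id=pid, experiment=experiment))
    return records_to_frame(records)
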