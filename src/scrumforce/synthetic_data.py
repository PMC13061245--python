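"""Seeded scrum-engagement simulator.

Generates velocity-force profiles — and, on request, the raw 50 Hz landmark
tracks and 500 Hz force traces they would have come from — with a known
deterministic velocity-to-force mapping, so the preprocessing, augmentation
and prediction stages can all be exercised and scored against ground truth
without any measured data.

What the simulator emulates, statistically: smooth unimodal engagement-speed
profiles peaking at 2.5-4.5 m/s; monotone-trending contact-force rises that
end at their 1-4 kN peak; a positive but noisy association between peak
speed and peak force (moderate correlation, by design, reflecting that pack
mass and technique — unobserved by the predictor — also drive force); and
lower peak forces for the PreBind engagement technique. It does not attempt
biomechanical fidelity (no pushing phase after the peak within the analysed
window, no per-player asymmetries, no sensor drift).

Ground truth: ``force_gt(t) = F_peak * s(t)**gamma`` with ``s`` a normalised
sigmoid ramp and ``F_peak = slope * v_peak + intercept`` scaled by the
technique factor (PreBind < 1). Observation noise is smooth, multiplicative,
vanishes at the window ends, and is excluded from the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_preprocess import (
    N_POINTS,
    TECHNIQUES,
    PAIRINGS,
    EngagementTrial,
    ForceTrace,
    InvalidConfigError,
    LandmarkTrack,
    VelocityForcePair,
)

_SIGMOID_STEEPNESS = (6.0, 10.0)  # ramp steepness range (dimensionless)
_SIGMOID_CENTER = (0.45, 0.6)  # ramp midpoint range, normalised time
_GAMMA_RANGE = (1.0, 2.0)  # force-shape exponent range
_F_ONSET_N = 15.0  # force at contact onset (just above the 10 N threshold)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults sit inside the cleaning bounds so that a default dataset
    survives :func:`scrumforce.io_preprocess.clean_trials` unchanged. The
    peak-force mapping ``slope * v_peak + intercept`` (700 N/(m/s), -500 N)
    spans ~1.25-2.65 kN over the speed range before technique scaling and
    noise, which — with the 350 N mapping noise — yields a moderate
    (~0.5-0.7) peak-speed/peak-force correlation.
    """

    n_trials: int = 42
    seed: int = 0
    v_peak_range: tuple[float, float] = (2.5, 4.5)  # m/s, uniform
    f_peak_range: tuple[float, float] = (1050.0, 3950.0)  # N, clip bounds
    technique_mix: dict = field(
        default_factory=lambda: {"CTPE": 1 / 3, "CTS": 1 / 3, "PreBind": 1 / 3}
    )
    prebind_force_scale: float = 0.85  # multiplicative peak-force reduction
    noise_sd: float = 0.02  # relative smooth noise on the force curve
    f_slope: float = 700.0  # N per (m/s) of peak speed
    f_intercept: float = -500.0  # N
    f_noise_sd: float = 350.0  # N, additive noise on the peak-force mapping

    def __post_init__(self):
        if self.n_trials < 0:
            raise InvalidConfigError("n_trials must be >= 0")
        total = sum(self.technique_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"technique_mix probabilities must sum to 1, got {total}")
        for name in self.technique_mix:
            if name not in TECHNIQUES:
                raise InvalidConfigError(f"unknown technique {name!r}")
        if not (0 < self.prebind_force_scale <= 1):
            raise InvalidConfigError("prebind_force_scale must be in (0, 1]")
        for lo, hi in (self.v_peak_range, self.f_peak_range):
            if not lo < hi:
                raise InvalidConfigError("ranges must satisfy min < max")


@dataclass
class SimTrial:
    """A raw simulated trial plus the ground truth that produced it."""

    trial: EngagementTrial
    pair: VelocityForcePair  # what preprocessing should (approximately) recover
    force_gt: np.ndarray  # noise-free 101-point force curve
    params: dict  # draw parameters (v_peak, f_peak_det, gamma, ...)


def _sigmoid_ramp(t: np.ndarray, k: float, t0: float) -> np.ndarray:
    """Sigmoid in t rescaled to run exactly from 0 to 1 on [0, 1]."""
    raw = 1.0 / (1.0 + np.exp(-k * (t - t0)))
    return (raw - raw[0]) / (raw[-1] - raw[0])


def ground_truth_force(velocity: np.ndarray, technique: str, cfg: SimConfig, shape: dict) -> np.ndarray:
    """The deterministic velocity-to-force functional (no observation noise).

    Exposed so predictor tests can compute an irreducible-error floor.
    ``shape`` carries the per-trial curve parameters (k, t0, gamma).
    """
    t = np.linspace(0.0, 1.0, len(velocity))
    s = _sigmoid_ramp(t, shape["k"], shape["t0"])
    v_peak = float(np.max(velocity))
    f_peak = cfg.f_slope * v_peak + cfg.f_intercept
    if technique == "PreBind":
        f_peak *= cfg.prebind_force_scale
    f_peak = float(np.clip(f_peak, cfg.f_peak_range[0], cfg.f_peak_range[1]))
    return _F_ONSET_N + (f_peak - _F_ONSET_N) * s ** shape["gamma"]


def simulate_pair(cfg: SimConfig, rng: np.random.Generator) -> tuple[VelocityForcePair, np.ndarray]:
    """Draw one 101-point pair; returns (pair, noise-free ground-truth force)."""
    t = np.linspace(0.0, 1.0, N_POINTS)
    techniques = sorted(cfg.technique_mix)
    probs = np.array([cfg.technique_mix[k] for k in techniques])
    technique = techniques[rng.choice(len(techniques), p=probs / probs.sum())]
    pairing = PAIRINGS[rng.integers(len(PAIRINGS))]

    v_peak = rng.uniform(*cfg.v_peak_range)
    t_p = rng.uniform(0.55, 0.8)  # speed peaks late in the engagement
    width = rng.uniform(0.18, 0.28)
    v_shape = {"v_peak": v_peak, "t_p": t_p, "width": width}
    velocity = v_peak * np.exp(-0.5 * ((t - t_p) / width) ** 2)

    shape = {
        "k": rng.uniform(*_SIGMOID_STEEPNESS),
        "t0": rng.uniform(*_SIGMOID_CENTER),
        "gamma": rng.uniform(*_GAMMA_RANGE),
    }
    force_gt = ground_truth_force(velocity, technique, cfg, shape)

    # peak-force mapping noise: rescale the whole curve by a noisy peak
    f_peak_det = float(force_gt[-1])
    f_peak_obs = f_peak_det + rng.normal(0.0, cfg.f_noise_sd)
    f_peak_obs = float(np.clip(f_peak_obs, cfg.f_peak_range[0], cfg.f_peak_range[1]))
    force = _F_ONSET_N + (force_gt - _F_ONSET_N) * (f_peak_obs - _F_ONSET_N) / (f_peak_det - _F_ONSET_N)

    # smooth multiplicative curve noise vanishing at both window ends
    if cfg.noise_sd > 0:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        eta = sum(np.sin((j + 1) * np.pi * t + phases[j]) for j in range(3)) / np.sqrt(3)
        force = force * (1.0 + cfg.noise_sd * eta * np.sin(np.pi * t))
        force = np.minimum(force, force[-1])  # keep the peak at the final sample

    pair = VelocityForcePair(
        velocity=velocity,
        force=force,
        meta={
            "trial_id": f"sim_{rng.integers(1 << 30)}",
            "technique": technique,
            "pairing": pairing,
        },
        source="synthetic",
    )
    pair.meta["shape"] = shape
    pair.meta["v_shape"] = v_shape
    pair.meta["f_peak_det"] = f_peak_det
    return pair, force_gt


def simulate_raw_trial(cfg: SimConfig, rng: np.random.Generator, jitter_m: float = 0.002) -> SimTrial:
    """Invert a simulated pair into raw 50 Hz tracks and a 500 Hz force trace.

    The trace gets a quiet pre-contact segment (< 10 N), the engagement
    window carries the pair's force curve, and a sub-peak decay tail follows
    it, so the full preprocessing chain (filter - differentiate - segment -
    normalise) approximately recovers the pair. ``jitter_m`` is the SD of
    white positional noise added to each landmark sample.
    """
    pair, force_gt = simulate_pair(cfg, rng)
    v_rate, f_rate = 50.0, 500.0
    t_pre = 0.6
    # snap the engagement duration to the 50 Hz video grid so the force
    # window's endpoints correspond to whole video frames
    t_eng = round(rng.uniform(0.9, 1.3) * v_rate) / v_rate
    t_post = 0.3

    # --- force trace (500 Hz) ---
    n_pre = int(round(t_pre * f_rate))
    n_eng = int(round(t_eng * f_rate))
    n_post = int(round(t_post * f_rate))
    t_norm = np.linspace(0.0, 1.0, n_eng)
    eng = np.interp(t_norm, np.linspace(0, 1, N_POINTS), pair.force)
    pre = rng.uniform(0.0, 2.0, size=n_pre)  # sensor noise floor, well below 10 N
    peak = eng[-1]
    post = peak * 0.95 * np.exp(-np.linspace(0, 4, n_post))
    force = ForceTrace(np.concatenate([pre, eng, post]), rate_hz=f_rate)

    # --- landmark tracks (50 Hz): midpoint speed follows the velocity profile ---
    # midpoint speed follows the pair's analytic Gaussian profile over the
    # whole trial (its tails cover approach and post-peak), so the track is
    # smooth everywhere and the 20 Hz filter leaves it essentially unchanged
    n_frames = int(round((t_pre + t_eng + t_post) * v_rate))
    tt = np.arange(n_frames) / v_rate
    vs = pair.meta["v_shape"]
    t_norm_all = (tt - t_pre) / t_eng
    speed = vs["v_peak"] * np.exp(-0.5 * ((t_norm_all - vs["t_p"]) / vs["width"]) ** 2)

    tracks = []
    for direction, pid in ((1.0, "A1"), (-1.0, "B3")):
        x = np.concatenate([[0.0], np.cumsum(direction * 0.5 * (speed[:-1] + speed[1:]) / v_rate)])
        pos = np.stack([x, np.zeros_like(x)], axis=1)
        jitter = rng.normal(0.0, jitter_m, size=(n_frames, 2)) if jitter_m > 0 else 0.0
        tracks.append(
            LandmarkTrack(
                c7_xy=pos + np.array([0.0, 0.25]) + jitter,
                lumbar_xy=pos + np.array([0.0, -0.25]) + jitter,
                rate_hz=v_rate,
                player_id=pid,
            )
        )

    trial = EngagementTrial(
        trial_id=pair.meta["trial_id"],
        technique=pair.meta["technique"],
        pairing=pair.meta["pairing"],
        track_a=tracks[0],
        track_b=tracks[1],
        force=force,
    )
    params = {"t_eng": t_eng, **{k: pair.meta[k] for k in ("shape", "f_peak_det")}}
    return SimTrial(trial=trial, pair=pair, force_gt=force_gt, params=params)


def simulate_dataset(cfg: SimConfig, raw: bool = False) -> list:
    """n_trials independent seeded draws.

    With ``raw=False`` returns ``[(VelocityForcePair, force_gt), ...]``;
    with ``raw=True`` returns ``[SimTrial, ...]`` including the raw signals.
    """
    if cfg.n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    if raw:
        return [simulate_raw_trial(cfg, rng) for _ in range(cfg.n_trials)]
    return [simulate_pair(cfg, rng) for _ in range(cfg.n_trials)]
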