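"""Raw scrum-trial signals -> cleaned 101-point velocity-force pairs.

The measurement setup this module serves: front-row players tracked from a
top-view camera (C7 vertebra and a lumbar point, 2-D metric coordinates,
50 Hz) while the instrumented team wears shoulder pressure sensors sampled
at 500 Hz. For each shoulder-contact event the pipeline

1. low-pass filters landmarks (20 Hz) and force (100 Hz) with a zero-phase
   second-order Butterworth filter,
2. differentiates the C7-lumbar midpoint to an engagement speed per player
   and averages the two engaged players,
3. windows the event from the first force sample above 10 N to the force
   peak,
4. resamples both channels onto 101 points of normalised time, and
5. discards trials whose peaks fall outside 2.5-4.5 m/s or 1-4 kN.

Forces are segmented on the 500 Hz clock; window boundaries are mapped to
the 50 Hz video clock by rounding to the nearest frame, after which the
independent 101-point normalisation of each channel makes the 10:1 rate
mismatch irrelevant downstream.

Indices are 0-based and windows are closed ``[start, end]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

logger = logging.getLogger("scrumforce")

N_POINTS = 101
TECHNIQUES = ("CTPE", "CTS", "PreBind")
PAIRINGS = ("A1L-B3", "A1R-B3", "A2L-B3", "A2R-B2", "A3L-B2", "A3R-B1")

VIDEO_RATE_HZ = 50.0
FORCE_RATE_HZ = 500.0
LANDMARK_CUTOFF_HZ = 20.0
FORCE_CUTOFF_HZ = 100.0


class PreprocessError(ValueError):
    """Base class for preprocessing failures."""


class InvalidConfigError(PreprocessError):
    pass


class InsufficientDataError(PreprocessError):
    pass


class NoContactError(PreprocessError):
    """Force trace never exceeds the contact threshold."""


class DegenerateWindowError(PreprocessError):
    """Engagement window collapses to fewer than two samples."""


class ShapeError(PreprocessError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LandmarkTrack:
    """Per-frame C7 and lumbar 2-D positions (metres) for one player."""

    c7_xy: np.ndarray  # (frames, 2)
    lumbar_xy: np.ndarray  # (frames, 2)
    rate_hz: float = VIDEO_RATE_HZ
    player_id: str = ""

    def __post_init__(self):
        self.c7_xy = np.asarray(self.c7_xy, dtype=float)
        self.lumbar_xy = np.asarray(self.lumbar_xy, dtype=float)
        if self.c7_xy.shape != self.lumbar_xy.shape or self.c7_xy.ndim != 2 or self.c7_xy.shape[1] != 2:
            raise ShapeError(
                f"landmark arrays must share shape (frames, 2); got {self.c7_xy.shape} and {self.lumbar_xy.shape}"
            )
        if not (np.isfinite(self.c7_xy).all() and np.isfinite(self.lumbar_xy).all()):
            raise PreprocessError("landmark track contains missing/non-finite samples")
        if self.rate_hz <= 0:
            raise InvalidConfigError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def frames(self) -> int:
        return self.c7_xy.shape[0]


@dataclass
class ForceTrace:
    """Raw per-shoulder contact force in newtons."""

    samples: np.ndarray
    rate_hz: float = FORCE_RATE_HZ
    shoulder: str = "left"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ShapeError(f"force trace must be 1-D, got shape {self.samples.shape}")
        if not np.isfinite(self.samples).all():
            raise PreprocessError("force trace contains non-finite samples")
        if self.rate_hz <= 0:
            raise InvalidConfigError(f"rate_hz must be positive, got {self.rate_hz}")


@dataclass
class EngagementTrial:
    """One shoulder-contact event: two tracked players plus the force trace."""

    trial_id: str
    technique: str
    pairing: str
    track_a: LandmarkTrack
    track_b: LandmarkTrack
    force: ForceTrace

    def __post_init__(self):
        if self.technique not in TECHNIQUES:
            raise InvalidConfigError(f"technique {self.technique!r} not in {TECHNIQUES}")
        if self.pairing not in PAIRINGS:
            raise InvalidConfigError(f"pairing {self.pairing!r} not in {PAIRINGS}")


@dataclass
class VelocityForcePair:
    """The pipeline's central currency: one 101-point velocity-force profile.

    ``source`` records provenance: 'measured' (preprocessed real data),
    'synthetic' (simulator), 'gan' or 'mixup' (augmentation). Measured,
    and synthetic curves satisfy the structural invariants
    ``force[-1] == max(force)`` (the window ends at the force peak) and
    ``velocity >= 0`` (speed magnitude); GAN emissions — and Mixup
    combinations, which may inherit GAN parents — are exempt.
    """

    velocity: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)
    source: str = "measured"

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.velocity.shape != (N_POINTS,) or self.force.shape != (N_POINTS,):
            raise ShapeError(
                f"velocity/force must each have {N_POINTS} samples; got "
                f"{self.velocity.shape} and {self.force.shape}"
            )
        if not (np.isfinite(self.velocity).all() and np.isfinite(self.force).all()):
            raise PreprocessError("pair contains non-finite samples")
        if self.source not in ("gan", "mixup"):
            if self.velocity.min() < -1e-9:
                raise PreprocessError("velocity magnitude cannot be negative")
            if self.force[-1] < self.force.max() - 1e-9 * max(1.0, self.force.max()):
                raise PreprocessError("force must attain its maximum at the last sample")

    @property
    def v_peak(self) -> float:
        return float(self.velocity.max())

    @property
    def f_peak(self) -> float:
        return float(self.force.max())


@dataclass
class CleaningConfig:
    """Peak-plausibility bounds (inclusive) and the contact threshold."""

    v_peak_min: float = 2.5
    v_peak_max: float = 4.5
    f_peak_min: float = 1000.0
    f_peak_max: float = 4000.0
    contact_threshold: float = 10.0

    def __post_init__(self):
        if not (self.v_peak_min < self.v_peak_max and self.f_peak_min < self.f_peak_max):
            raise InvalidConfigError("peak ranges must satisfy min < max")
        if self.contact_threshold <= 0:
            raise InvalidConfigError("contact_threshold must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def butterworth_lowpass(signal: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth low-pass filter.

    The dual pass squares the single-pass magnitude response and cancels the
    phase, so symmetric pulses keep their timing. Cutoffs at or above 80% of
    Nyquist are allowed but logged, since the digital response there is
    strongly warped.
    """
    signal = np.asarray(signal, dtype=float)
    nyquist = rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise InvalidConfigError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz (rate {rate_hz} Hz)"
        )
    if cutoff_hz >= 0.8 * nyquist:
        logger.warning(
            "cutoff %.3g Hz is >= 80%% of Nyquist (%.3g Hz); response is heavily warped",
            cutoff_hz,
            nyquist,
        )
    b, a = butter(2, cutoff_hz / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if signal.shape[-1] <= padlen:
        raise InsufficientDataError(
            f"signal of length {signal.shape[-1]} too short for zero-phase filtering (needs > {padlen})"
        )
    return filtfilt(b, a, signal, axis=-1)


def midpoint_velocity(track: LandmarkTrack) -> np.ndarray:
    """Speed (m/s) of the C7-lumbar midpoint.

    Central finite differences on interior frames, one-sided at the ends,
    scaled by the frame rate; the returned series is the Euclidean norm of
    the velocity vector, hence non-negative.
    """
    if track.frames < 3:
        raise InsufficientDataError(f"need >= 3 frames to differentiate, got {track.frames}")
    mid = 0.5 * (track.c7_xy + track.lumbar_xy)
    vel = np.gradient(mid, 1.0 / track.rate_hz, axis=0)
    return np.linalg.norm(vel, axis=1)


def pair_mean_velocity(v_a: np.ndarray, v_b: np.ndarray) -> np.ndarray:
    """Element-wise mean of the two engaged players' speed series."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise ShapeError(f"velocity series lengths differ: {v_a.shape[0]} vs {v_b.shape[0]}")
    return 0.5 * (v_a + v_b)


def segment_engagement(force: ForceTrace | np.ndarray, threshold: float = 10.0) -> tuple[int, int]:
    """Closed engagement window [start, end] on the force trace's own clock.

    start: first sample strictly above ``threshold``; end: index of the
    global maximum (first occurrence on ties). ``end >= start`` always holds
    because the maximum exceeds the threshold.
    """
    samples = force.samples if isinstance(force, ForceTrace) else np.asarray(force, dtype=float)
    above = samples > threshold
    if not above.any():
        raise NoContactError(
            f"force never exceeds the {threshold} N contact threshold (max {samples.max():.3g} N)"
        )
    start = int(np.argmax(above))
    end = int(np.argmax(samples))
    return start, end


def time_normalize(signal: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Linearly resample a series onto ``n_points`` over normalised time [0, 1].

    Endpoints are preserved exactly; an input already of length ``n_points``
    is returned unchanged (up to float identity of np.interp at the knots).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < 2:
        raise InsufficientDataError(f"cannot time-normalize a series of length {signal.shape[-1]}")
    t_in = np.linspace(0.0, 1.0, signal.shape[-1])
    t_out = np.linspace(0.0, 1.0, n_points)
    return np.interp(t_out, t_in, signal)


def clean_trials(
    pairs: Sequence[VelocityForcePair], cfg: CleaningConfig | None = None
) -> tuple[list[VelocityForcePair], list[dict]]:
    """Keep pairs whose peaks are physiologically plausible.

    A pair survives iff peak velocity lies in [v_peak_min, v_peak_max] and
    peak force in [f_peak_min, f_peak_max], all bounds inclusive. Returns
    the kept pairs and a rejection log of ``{"trial_id", "reason"}`` dicts
    (reasons: 'velocity-range', 'force-range', or both comma-joined).
    """
    cfg = cfg or CleaningConfig()
    if len(pairs) == 0:
        logger.warning("clean_trials called on an empty pair list")
        return [], []
    kept: list[VelocityForcePair] = []
    rejected: list[dict] = []
    for p in pairs:
        reasons = []
        if not (cfg.v_peak_min <= p.v_peak <= cfg.v_peak_max):
            reasons.append("velocity-range")
        if not (cfg.f_peak_min <= p.f_peak <= cfg.f_peak_max):
            reasons.append("force-range")
        if reasons:
            rejected.append({"trial_id": p.meta.get("trial_id", "?"), "reason": ",".join(reasons)})
        else:
            kept.append(p)
    return kept, rejected


def build_pair(trial: EngagementTrial, cfg: CleaningConfig | None = None) -> VelocityForcePair:
    """Run the full preprocessing chain on one trial.

    Filter -> midpoint speeds -> pair mean -> force segmentation -> window
    mapping to video frames (nearest-frame rounding) -> 101-point
    normalisation of both channels. Does NOT apply the peak-range cleaning;
    use :func:`clean_trials` on the resulting pairs.
    """
    cfg = cfg or CleaningConfig()
    try:
        force_f = butterworth_lowpass(trial.force.samples, trial.force.rate_hz, FORCE_CUTOFF_HZ)
        tracks_f = []
        for tr in (trial.track_a, trial.track_b):
            c7 = butterworth_lowpass(tr.c7_xy.T, tr.rate_hz, LANDMARK_CUTOFF_HZ).T
            lum = butterworth_lowpass(tr.lumbar_xy.T, tr.rate_hz, LANDMARK_CUTOFF_HZ).T
            tracks_f.append(replace(tr, c7_xy=c7, lumbar_xy=lum))
        v_mean = pair_mean_velocity(*(midpoint_velocity(tr) for tr in tracks_f))

        start, end = segment_engagement(ForceTrace(force_f, trial.force.rate_hz), cfg.contact_threshold)
        if end - start < 1:
            raise DegenerateWindowError(
                f"engagement window [{start}, {end}] has fewer than two force samples"
            )
        # map the window (force clock, seconds) onto video frames
        v_rate = trial.track_a.rate_hz
        f_start = int(round(start / trial.force.rate_hz * v_rate))
        f_end = int(round(end / trial.force.rate_hz * v_rate))
        f_start = min(f_start, len(v_mean) - 1)
        f_end = min(f_end, len(v_mean) - 1)
        if f_end - f_start < 1:
            raise DegenerateWindowError(
                f"engagement window maps to fewer than two video frames ([{f_start}, {f_end}])"
            )
        velocity = time_normalize(v_mean[f_start : f_end + 1])
        force = time_normalize(force_f[start : end + 1])
        return VelocityForcePair(
            velocity=np.maximum(velocity, 0.0),
            force=force,
            meta={"trial_id": trial.trial_id, "technique": trial.technique, "pairing": trial.pairing},
            source="measured",
        )
    except PreprocessError as exc:
        raise type(exc)(f"trial {trial.trial_id!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV + JSON interchange dialect
# ---------------------------------------------------------------------------


def save_pair(pair: VelocityForcePair, path: str | Path) -> None:
    """Write a pair as ``<path>.csv`` (t_norm, velocity_ms, force_n) + ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_norm": np.linspace(0.0, 1.0, N_POINTS),
            "velocity_ms": pair.velocity,
            "force_n": pair.force,
        }
    )
    df.to_csv(path.with_suffix(".csv"), index=False)
    meta = dict(pair.meta)
    meta["source"] = pair.source
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_pair(path: str | Path) -> VelocityForcePair:
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"))
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    source = meta.pop("source", "measured")
    return VelocityForcePair(
        velocity=df["velocity_ms"].to_numpy(), force=df["force_n"].to_numpy(), meta=meta, source=source
    )


def save_pairs(pairs: Iterable[VelocityForcePair], directory: str | Path, prefix: str = "pair") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, pair in enumerate(pairs):
        stem = directory / f"{prefix}_{idx:04d}"
        save_pair(pair, stem)
        paths.append(stem)
    return paths


def load_pairs(directory: str | Path, prefix: str = "pair") -> list[VelocityForcePair]:
    directory = Path(directory)
    stems = sorted(p.with_suffix("") for p in directory.glob(f"{prefix}_*.csv"))
    return [load_pair(stem) for stem in stems]


def load_trial(landmark_csv: str | Path, force_csv: str | Path, meta_json: str | Path) -> EngagementTrial:
    """Assemble an :class:`EngagementTrial` from the raw-file dialect.

    Landmark CSV columns: frame, player_id, c7_x, c7_y, lum_x, lum_y (metres,
    one row per frame per player, exactly two players). Force CSV columns:
    sample, force_n. Metadata JSON keys: trial_id, technique, pairing,
    video_rate_hz, force_rate_hz, and the force shoulder side.
    """
    meta = json.loads(Path(meta_json).read_text())
    lm = pd.read_csv(landmark_csv)
    players = list(dict.fromkeys(lm["player_id"]))
    if len(players) != 2:
        raise PreprocessError(f"landmark file must contain exactly 2 players, got {players}")
    tracks = []
    for pid in players:
        sub = lm[lm["player_id"] == pid].sort_values("frame")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise PreprocessError(f"player {pid!r}: frame gaps are a load-time error")
        tracks.append(
            LandmarkTrack(
                c7_xy=sub[["c7_x", "c7_y"]].to_numpy(),
                lumbar_xy=sub[["lum_x", "lum_y"]].to_numpy(),
                rate_hz=float(meta.get("video_rate_hz", VIDEO_RATE_HZ)),
                player_id=str(pid),
            )
        )
    fc = pd.read_csv(force_csv)
    force = ForceTrace(
        samples=fc["force_n"].to_numpy(),
        rate_hz=float(meta.get("force_rate_hz", FORCE_RATE_HZ)),
        shoulder=meta.get("shoulder", "left"),
    )
    return EngagementTrial(
        trial_id=str(meta["trial_id"]),
        technique=meta["technique"],
        pairing=meta["pairing"],
        track_a=tracks[0],
        track_b=tracks[1],
        force=force,
    )


def zenodo_adapter_stub() -> str:
    """How to map the published measured dataset onto this package's dialect.

    The study's measured data (landmark tracks, shoulder force traces and the
    trained network) are deposited at DOI 10.5281/zenodo.18048888. This
    package does not download them; to use them, export each trial to the
    raw-file dialect of :func:`load_trial` — one landmark CSV per engaged
    player pair (metric top-view coordinates, pixel-to-metre calibration
    applied upstream), one force CSV per instrumented shoulder, and a JSON
    sidecar naming trial_id, technique, pairing and the two sampling rates —
    then run the standard pipeline.
    """
    return zenodo_adapter_stub.__doc__
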