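"""Synthetic data with known ground truth for every pipeline stage.

Generates (i) smooth mean-reverting feedback-cue processes at 30 Hz,
(ii) hidden-state paths and song labels from a generative HMM-GLM whose
default emulates the three empirical rules (a mostly-silent *whatever*
state, a pulse-biased *chasing* state driven by distance and lateral
speed, and a sine-biased *close* state), (iii) scripted two-fly pose
scenarios with known transition times, and (iv) pulse/sine audio.

All generators are deterministic under a fixed seed and return their
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import raised_cosine_basis
from .design import build_design
from .kinematics import FEATURE_NAMES, FeedbackFeatures, PosePair
from .model import (
    PULSE,
    SILENCE,
    SINE,
    HMMGLMParams,
    sample_emissions,
    sample_states,
)

FRAME_RATE = 30.0
AUDIO_RATE = 10_000

# feature process defaults: (mean, sd, timescale s, transform)
# transforms: None (signed), "abs" (speeds/distance), "fold" (angles -> [0,180])
FEATURE_PROCESSES: dict[str, tuple[float, float, float, str | None]] = {
    "cFV": (5.0, 4.0, 0.5, None),
    "pFV": (2.0, 3.0, 0.5, None),
    "cLS": (2.0, 2.0, 0.4, "abs"),
    "pLS": (1.5, 1.5, 0.4, "abs"),
    "cRS": (60.0, 50.0, 0.3, "abs"),
    "pRS": (40.0, 40.0, 0.3, "abs"),
    "dis": (5.0, 3.0, 1.0, "abs"),
    "ctheta": (90.0, 50.0, 1.0, "fold"),
    "ptheta": (90.0, 50.0, 1.0, "fold"),
    "phi": (90.0, 50.0, 1.0, "fold"),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generators."""

    seed: int = 0
    frame_rate: float = FRAME_RATE
    feature_processes: dict = field(default_factory=lambda: dict(FEATURE_PROCESSES))
    # audio
    pulse_carrier_hz: float = 250.0
    pulse_width_ms: float = 4.0       # envelope full width at half maximum
    ipi_ms: float = 36.0
    sine_carrier_hz: float = 150.0
    noise_sd: float = 0.01
    n_amplitude_steps: int = 10
    amplitude_step_s: float = 30.0


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    states: np.ndarray | None = None          # hidden rule path z
    labels: np.ndarray | None = None          # song modes y
    features: FeedbackFeatures | None = None
    event_times_s: np.ndarray | None = None   # scripted transition times
    params: HMMGLMParams | None = None


# ---------------------------------------------------------------------------
# feature processes


def simulate_features(
    config: SyntheticConfig | None = None,
    T: int = 18_000,
    seed: int | None = None,
) -> FeedbackFeatures:
    """Mean-reverting Gaussian feature processes at 30 Hz.

    Each cue follows a discretized Ornstein-Uhlenbeck process with the
    configured stationary mean/sd and correlation timescale.  Speed-like
    cues take the absolute value of the process and angular cues are
    folded into [0, 180], so their realized moments differ from the
    underlying Gaussian ones (which the configuration states).
    """
    config = config or SyntheticConfig()
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = 1.0 / config.frame_rate
    cols = {}
    for name in FEATURE_NAMES:
        mu, sd, tau, transform = config.feature_processes[name]
        rho = np.exp(-dt / tau)
        innov_sd = sd * np.sqrt(1 - rho**2)
        x = np.empty(T)
        x[0] = rng.normal(mu, sd)
        eps = rng.normal(0.0, innov_sd, size=T - 1)
        for t in range(1, T):
            x[t] = mu + rho * (x[t - 1] - mu) + eps[t - 1]
        if transform == "abs":
            x = np.abs(x)
        elif transform == "fold":
            x = np.abs(x) % 360.0
            x = np.where(x > 180.0, 360.0 - x, x)
        cols[name] = x
    return FeedbackFeatures(
        data=pd.DataFrame(cols), frame_rate=config.frame_rate,
        fly_length=np.array([2.5, 2.5]),
    )


# ---------------------------------------------------------------------------
# generative song model


def default_true_params(
    n_basis: int = 10, n_lags: int = 120, seed: int | None = None
) -> HMMGLMParams:
    """The default 3-rule generative model.

    State 0 (*whatever*) is strongly silence-biased; state 1 (*chasing*)
    is pulse-biased with its pulse filter loading on distance and courter
    lateral speed; state 2 (*close*) is sine-biased with a distance
    loading on the sine filter.  Transitions are sticky (diagonal 0.97).
    Filter weights act on the z-scored basis-projected design.
    """
    basis = raised_cosine_basis(n_lags=n_lags, n_basis=n_basis)
    P = 10 * n_basis + 1
    W = np.zeros((3, 3, P))
    bias = P - 1

    def block(feature: str) -> slice:
        i = FEATURE_NAMES.index(feature)
        return slice(i * n_basis, (i + 1) * n_basis)

    # decaying loading across basis functions (recent history matters most)
    load = np.exp(-np.arange(n_basis) / 3.0)
    load /= np.linalg.norm(load)

    # whatever: silence dominates
    W[0, PULSE, bias] = -2.5
    W[0, SINE, bias] = -2.5
    # chasing: pulse-biased, driven by distance and lateral speed
    W[1, PULSE, bias] = 1.3
    W[1, SINE, bias] = -1.5
    W[1, PULSE, block("dis")] = 0.8 * load
    W[1, PULSE, block("cLS")] = 0.6 * load
    # close: sine-biased, driven by (small) distance
    W[2, SINE, bias] = 1.3
    W[2, PULSE, bias] = -1.5
    W[2, SINE, block("dis")] = -0.8 * load
    W[2, SINE, block("cLS")] = -0.4 * load

    alpha = np.full((3, 3), 0.015)
    np.fill_diagonal(alpha, 0.97)
    return HMMGLMParams(
        pi=np.full(3, 1 / 3), alpha=alpha, weights=W, basis=basis, seed=seed,
    )


def simulate_song(
    params: HMMGLMParams | None = None,
    features: FeedbackFeatures | None = None,
    seed: int | None = 0,
    T: int = 18_000,
) -> GroundTruth:
    """Sample a hidden rule path and song labels given feedback features.

    The design is built from ``features`` with its own normalization
    statistics (stored back into the returned ground-truth parameters so
    that a fit on the same data sees an identical transform).
    """
    rng = np.random.default_rng(seed)
    params = params or default_true_params()
    if features is None:
        features = simulate_features(T=T, seed=int(rng.integers(2**31)))
    design = build_design(features, basis=params.basis)
    params.stats = design.stats
    z = sample_states(params, len(design.X), rng)
    y = sample_emissions(params, design.X, z, rng)
    return GroundTruth(states=z, labels=y, features=features, params=params)


# ---------------------------------------------------------------------------
# scripted pose scenarios


_PART_OFFSETS = {  # along-axis offsets from thorax, in fly lengths
    "head": 0.5, "neck": 0.25, "thorax": 0.0, "abdomen": -0.5,
}


def _skeleton(
    pos: np.ndarray, heading_rad: np.ndarray, fly_length: float,
    wing_angle_deg: np.ndarray,
) -> np.ndarray:
    """(T, 6, 2) keypoints from thorax path, heading and wing angles.

    ``wing_angle_deg`` is (T, 2) for left/right, measured from the folded
    (backward) position; 0 = wing along the body axis.
    """
    T = len(pos)
    u = np.stack([np.cos(heading_rad), np.sin(heading_rad)], axis=-1)
    out = np.empty((T, 6, 2))
    for i, part in enumerate(("head", "neck", "thorax", "abdomen")):
        out[:, i] = pos + _PART_OFFSETS[part] * fly_length * u
    wing_len = 0.45 * fly_length
    for w, sign in ((0, 1.0), (1, -1.0)):  # left, right
        ang = heading_rad + np.pi - sign * np.radians(wing_angle_deg[:, w])
        out[:, 4 + w] = pos + wing_len * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return out


def simulate_pose_scenario(
    scenario: str,
    duration_s: float = 60.0,
    seed: int | None = 0,
    frame_rate: float = 100.0,
    fly_length_mm: float = 2.5,
) -> tuple[PosePair, GroundTruth]:
    """Scripted two-fly pose tracks with known event times.

    ``male_turns``: the courter follows the partner from behind (tail
    quadrant); at scripted times the partner executes a rapid heading
    reversal toward the courter, placing the courter in the head quadrant.
    The reversal times are the ground-truth tail-to-head transitions.

    ``female_slows``: the partner walks with a forward speed that drops
    during scripted song epochs while the courter trails at close range;
    ground truth records the song-epoch boundaries.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * frame_rate))
    dt = 1.0 / frame_rate
    t = np.arange(T) * dt
    jitter = 0.01  # mm positional noise

    if scenario == "male_turns":
        # The partner alternates between walking forward along +x with the
        # courter trailing 3 mm behind (tail phase) and standing reversed,
        # facing the trailing courter (head phase).  Both fly paths are
        # continuous; only the partner's heading flips at the scripted
        # times, which are the ground-truth tail-to-head transitions.
        phase_s = 6.0
        turn_times = np.arange(phase_s, duration_s - phase_s / 2, 2 * phase_s)
        head_phase = np.zeros(T, dtype=bool)
        for tt in turn_times:
            i = int(round(tt * frame_rate))
            head_phase[i: i + int(phase_s * frame_rate)] = True
        heading_p = np.where(head_phase, np.pi, 0.0)
        speed_p = np.where(head_phase, 0.0, 4.0)
        pos_p = np.cumsum(
            speed_p[:, None] * dt * np.stack([np.cos(0 * t), np.sin(0 * t)], -1), axis=0
        )
        pos_c = pos_p - np.array([3.0, 0.0])  # trails along the walking axis
        heading_c = np.zeros(T)  # always facing the partner (+x)
        events = turn_times
    elif scenario == "female_slows":
        song_epochs = [(10.0, 20.0), (35.0, 45.0)]
        speed_p = np.full(T, 8.0)
        for s, e in song_epochs:
            speed_p[int(s * frame_rate): int(e * frame_rate)] = 2.0
        heading_p = 0.2 * np.sin(2 * np.pi * 0.03 * t)
        pos_p = np.cumsum(
            speed_p[:, None] * dt * np.stack([np.cos(heading_p), np.sin(heading_p)], -1),
            axis=0,
        )
        # courter circles toward the partner's front at ~3 mm
        orbit = np.pi * np.clip(t / duration_s, 0, 1)  # tail -> head over the trial
        offs = 3.0 * np.stack(
            [np.cos(heading_p + np.pi - orbit), np.sin(heading_p + np.pi - orbit)], -1
        )
        pos_c = pos_p + offs
        vec = pos_p - pos_c
        heading_c = np.arctan2(vec[:, 1], vec[:, 0])
        events = np.array([s for s, _ in song_epochs])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    wings = np.zeros((T, 2))
    xy = np.stack(
        [
            _skeleton(pos_c, heading_c, fly_length_mm, wings)
            + rng.normal(0, jitter, (T, 6, 2)),
            _skeleton(pos_p, heading_p, fly_length_mm, wings)
            + rng.normal(0, jitter, (T, 6, 2)),
        ]
    )
    pose = PosePair(xy=xy, frame_rate=frame_rate,
                    fly_length=np.array([fly_length_mm, fly_length_mm]))
    return pose, GroundTruth(event_times_s=np.asarray(events))


# ---------------------------------------------------------------------------
# audio


def _gaussian_pulse(config: SyntheticConfig) -> np.ndarray:
    """One pulse: carrier under a Gaussian envelope (FWHM = pulse_width_ms)."""
    sigma_s = config.pulse_width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(round(4 * sigma_s * AUDIO_RATE))
    tt = np.arange(-half, half + 1) / AUDIO_RATE
    env = np.exp(-0.5 * (tt / sigma_s) ** 2)
    return env * np.sin(2 * np.pi * config.pulse_carrier_hz * tt)


def synth_audio(
    annotation: pd.DataFrame,
    config: SyntheticConfig | None = None,
    seed: int | None = 0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render audio from an interval annotation table.

    ``annotation`` has columns (onset_s, offset_s, label); pulse spans are
    filled with a regular train of Gaussian-enveloped carrier pulses at the
    configured inter-pulse interval, sine spans with a pure tone, and
    everything else with the noise floor.  Returns (waveform, pulse
    center times in s) at 10 kHz.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = float(annotation["offset_s"].max())
    n = int(round(duration_s * AUDIO_RATE))
    wav = rng.normal(0.0, config.noise_sd, size=n)
    pulse = _gaussian_pulse(config)
    half = len(pulse) // 2
    centers = []
    ipi = config.ipi_ms / 1000.0
    for _, row in annotation.iterrows():
        if row["label"] == "pulse":
            c = row["onset_s"] + ipi / 2
            while c < row["offset_s"]:
                i = int(round(c * AUDIO_RATE))
                lo, hi = max(0, i - half), min(n, i + half + 1)
                wav[lo:hi] += pulse[lo - (i - half): len(pulse) - ((i + half + 1) - hi)]
                centers.append(c)
                c += ipi
        elif row["label"] == "sine":
            i0, i1 = int(round(row["onset_s"] * AUDIO_RATE)), int(round(row["offset_s"] * AUDIO_RATE))
            tt = np.arange(i0, min(i1, n)) / AUDIO_RATE
            wav[i0:min(i1, n)] += np.sin(2 * np.pi * config.sine_carrier_hz * tt)
    return wav, np.asarray(centers)


def playback_stimulus(config: SyntheticConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """The artificial pulse-song playback: 4 ms pulses at a 36 ms IPI.

    Ten amplitude steps at increasing volume, each lasting ~30 s.  Returns
    (waveform, pulse center times in s).
    """
    config = config or SyntheticConfig()
    ipi = config.ipi_ms / 1000.0
    total_s = config.n_amplitude_steps * config.amplitude_step_s
    n = int(round(total_s * AUDIO_RATE))
    wav = np.zeros(n)
    pulse = _gaussian_pulse(config)
    half = len(pulse) // 2
    centers = np.arange(ipi, total_s - ipi, ipi)
    amps = np.linspace(0.1, 1.0, config.n_amplitude_steps)
    for c in centers:
        step = min(int(c // config.amplitude_step_s), config.n_amplitude_steps - 1)
        i = int(round(c * AUDIO_RATE))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        wav[lo:hi] += amps[step] * pulse[lo - (i - half): len(pulse) - ((i + half + 1) - hi)]
    return wav, centers
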