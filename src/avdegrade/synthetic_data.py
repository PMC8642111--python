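"""Synthetic inputs for every pipeline stage, with known ground truth.

The experiment's stimuli and human data are licensed/unavailable, so each
stage is exercised on generated material instead:

* speech-like audio — tilted broadband noise whose log-spaced subbands carry
  independent slow (2-8 Hz) lognormal amplitude modulations;
* face/hand track points — an anatomically ordered landmark set on an
  elliptical face with smooth sinusoidal motion;
* gaze event streams — an alternating fixation/saccade renewal process with
  group- and condition-dependent means, Poisson blinks, and landing
  positions biased toward the face for intact video and away from it for
  degraded video;
* responses — correct with a configured probability per group x condition,
  with confusion errors weighted by valence/arousal proximity and a
  response-bias vector (so unbiased and raw hit-rates differ).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from avdegrade.behavior_metrics import (
    CONDITIONS,
    EMOTION_QUADRANT,
    EMOTIONS,
)
from avdegrade.hearing_sim import AudioSignal

__all__ = [
    "GeneratorConfig",
    "VIDEO_DEGRADED_CONDITIONS",
    "VIDEO_INTACT_CONDITIONS",
    "gen_speech_like_audio",
    "gen_actor_trackpoints",
    "gen_gaze_trace",
    "gen_responses",
]

#: Conditions in which the video stream is shown degraded / intact.
VIDEO_DEGRADED_CONDITIONS = ("AdV", "dAdV", "dV")
VIDEO_INTACT_CONDITIONS = ("AV", "dAV", "V")

_DEF_ACC_YOUNG = {
    "A": 0.45,
    "V": 0.55,
    "AV": 0.70,
    "dA": 0.38,
    "dV": 0.42,
    "AdV": 0.62,
    "dAV": 0.66,
    "dAdV": 0.52,
}


def _default_accuracy():
    older = {c: max(p - 0.12, 0.15) for c, p in _DEF_ACC_YOUNG.items()}
    return {"young": dict(_DEF_ACC_YOUNG), "older": older}


def _default_fixation_ms():
    # intact-video / degraded-video mean fixation durations
    return {
        "young": {"intact": 500.0, "degraded": 275.0},
        "older": {"intact": 374.0, "degraded": 363.0},
    }


def _default_amplitude_deg():
    # intact-video / degraded-video mean saccadic amplitudes
    return {
        "young": {"intact": 2.83, "degraded": 6.54},
        "older": {"intact": 1.58, "degraded": 2.78},
    }


def _default_bias():
    # mild bias toward one emotion per quadrant, so Hu < raw hit-rate
    bias = np.ones(len(EMOTIONS))
    bias[EMOTIONS.index("joy")] = 2.0
    bias[EMOTIONS.index("sadness")] = 1.5
    return tuple(bias / bias.sum())


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the synthetic study."""

    seed: int = 0
    n_young: int = 24
    n_older: int = 21
    # behavioral model
    accuracy: dict = field(default_factory=_default_accuracy)
    response_bias: tuple = field(default_factory=_default_bias)
    confusion_decay: float = 1.0  # error weight ~ exp(-decay * quadrant distance)
    participant_sd: float = 0.3  # participant accuracy spread, logit scale
    # gaze model
    fixation_ms: dict = field(default_factory=_default_fixation_ms)
    amplitude_deg: dict = field(default_factory=_default_amplitude_deg)
    fixation_shape: float = 4.0  # Gamma shape of fixation durations
    amplitude_shape: float = 9.0  # Gamma shape of saccadic amplitudes
    blink_rate_hz: float = 0.15
    blink_ms_mean: float = 120.0
    saccade_ms: float = 40.0
    pixels_per_deg: float = 1920.0 / 43.0
    screen_px: tuple = (1920, 1080)
    face_center_px: tuple = (960.0, 450.0)
    # audio model
    audio_duration_s: float = 2.5
    audio_rate_hz: float = 22050.0
    modulation_depth: float = 0.7
    modulation_band_hz: tuple = (2.0, 8.0)
    spectral_tilt_corner_hz: float = 500.0
    n_audio_subbands: int = 6

    def video_state(self, condition: str) -> str:
        if condition in VIDEO_DEGRADED_CONDITIONS:
            return "degraded"
        if condition in VIDEO_INTACT_CONDITIONS:
            return "intact"
        raise ValueError(f"condition {condition!r} has no video stream")


# --------------------------------------------------------------------------
# Audio
# --------------------------------------------------------------------------

def gen_speech_like_audio(
    cfg: GeneratorConfig, seed: int | None = None
) -> AudioSignal:
    """Speech-shaped amplitude-modulated noise.

    Broadband Gaussian noise with a -6 dB/oct spectral tilt above the corner
    frequency, split into log-spaced subbands that are each modulated by an
    independent lognormal 2-8 Hz envelope process (crude analogue of the
    partly independent formant-band modulations of running speech).
    """
    if not 1.0 <= cfg.audio_duration_s <= 7.0:
        raise ValueError("audio duration must lie in [1, 7] s")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.audio_rate_hz
    n = int(round(cfg.audio_duration_s * fs))
    f = np.fft.rfftfreq(n, 1.0 / fs)

    X = np.fft.rfft(rng.standard_normal(n))
    tilt = np.ones_like(f)
    above = f > cfg.spectral_tilt_corner_hz
    tilt[above] = (f[above] / cfg.spectral_tilt_corner_hz) ** -1.0  # -6 dB/oct

    lo, hi = cfg.modulation_band_hz
    edges = np.geomspace(80.0, 10000.0, cfg.n_audio_subbands + 1)
    y = np.zeros(n)
    for i in range(cfg.n_audio_subbands):
        sel = (f >= edges[i]) & (f < edges[i + 1])
        sub = np.fft.irfft(X * tilt * sel, n)
        G = np.fft.rfft(rng.standard_normal(n))
        env = np.fft.irfft(G * ((f >= lo) & (f <= hi)), n)
        std = env.std()
        if std > 0:
            env = env / std
        y += sub * np.exp(cfg.modulation_depth * env)
    rms = np.sqrt(np.mean(y**2))
    y = 0.1 * y / rms
    return AudioSignal(y, fs, calibration_spl=100.0)


# --------------------------------------------------------------------------
# Track points
# --------------------------------------------------------------------------

#: Landmark offsets (px) from the face center; left/right in actor reference
#: (the actor's left is on the observer's right).
_LANDMARK_OFFSETS = {
    "left_eyebrow_outer": (110.0, -100.0),
    "left_eyebrow_middle": (70.0, -108.0),
    "left_eyebrow_inner": (30.0, -100.0),
    "right_eyebrow_outer": (-110.0, -100.0),
    "right_eyebrow_middle": (-70.0, -108.0),
    "right_eyebrow_inner": (-30.0, -100.0),
    "left_pupil": (70.0, -55.0),
    "right_pupil": (-70.0, -55.0),
    "nose_tip": (0.0, 30.0),
    "left_nostril": (30.0, 45.0),
    "right_nostril": (-30.0, 45.0),
    "mouth_top": (0.0, 90.0),
    "mouth_bottom": (0.0, 135.0),
    "mouth_left": (60.0, 112.0),
    "mouth_right": (-60.0, 112.0),
}
_HAND_OFFSETS = {"left_hand": (280.0, 440.0), "right_hand": (-280.0, 440.0)}


def gen_actor_trackpoints(
    cfg: GeneratorConfig,
    n_frames: int,
    seed: int | None = None,
    motion_px: float = 12.0,
    frame_rate: float = 25.0,
) -> pd.DataFrame:
    """Per-frame landmark table (columns frame, landmark, x, y).

    The face translates smoothly (seeded sinusoids, ~0.3-0.8 Hz); hands move
    independently with larger excursions. Anatomical ordering (eyebrows
    above pupils above nose tip above mouth) holds in every frame.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = np.arange(n_frames) / frame_rate
    cx, cy = cfg.face_center_px

    def wobble(scale):
        fhz = 0.3 + 0.5 * rng.random(2)
        ph = 2 * np.pi * rng.random(2)
        return (
            scale * np.sin(2 * np.pi * fhz[0] * t + ph[0]),
            scale * np.sin(2 * np.pi * fhz[1] * t + ph[1]),
        )

    fx, fy = wobble(motion_px)
    rows = []
    for name, (ox, oy) in _LANDMARK_OFFSETS.items():
        for k in range(n_frames):
            rows.append((k, name, cx + ox + fx[k], cy + oy + fy[k]))
    for name, (ox, oy) in _HAND_OFFSETS.items():
        hx, hy = wobble(3 * motion_px)
        for k in range(n_frames):
            rows.append((k, name, cx + ox + hx[k], cy + oy + hy[k]))
    return pd.DataFrame(rows, columns=["frame", "landmark", "x", "y"])


# --------------------------------------------------------------------------
# Gaze
# --------------------------------------------------------------------------

def gen_gaze_trace(
    cfg: GeneratorConfig,
    trial_meta: dict,
    seed: int | None = None,
) -> pd.DataFrame:
    """One trial's fixation/saccade/blink event table.

    ``trial_meta`` needs ``trial`` (id), ``age_group``, ``condition`` (a
    video condition), and optionally ``duration_ms`` (default 3000). The
    process alternates Gamma-duration fixations with fixed-duration
    saccades whose amplitudes are Gamma with the configured group x
    video-state mean; landings head toward the face center under intact
    video and away from it under degraded video. Blinks arrive as a Poisson
    process with Gamma durations.
    """
    duration_ms = float(trial_meta.get("duration_ms", 3000.0))
    if duration_ms < 1000.0:
        raise ValueError("trial must last at least 1000 ms")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    group = trial_meta["age_group"]
    state = cfg.video_state(trial_meta["condition"])
    trial = trial_meta["trial"]
    fix_mean = cfg.fixation_ms[group][state]
    amp_mean = cfg.amplitude_deg[group][state]
    ppd = cfg.pixels_per_deg
    w, h = cfg.screen_px
    cx, cy = cfg.face_center_px

    rows = []
    t = 0.0
    x, y = cx + rng.normal(0, 20), cy + rng.normal(0, 20)
    while t < duration_ms:
        dur = rng.gamma(cfg.fixation_shape, fix_mean / cfg.fixation_shape)
        rows.append((trial, "fixation", t, min(t + dur, duration_ms), x, y, np.nan))
        t += dur
        if t >= duration_ms:
            break
        amp = rng.gamma(cfg.amplitude_shape, amp_mean / cfg.amplitude_shape)
        to_face = np.arctan2(cy - y, cx - x)
        theta = (
            to_face + rng.normal(0, 0.8)
            if state == "intact"
            else to_face + np.pi + rng.normal(0, 0.8)
        )
        x = float(np.clip(x + amp * ppd * np.cos(theta), 0, w - 1))
        y = float(np.clip(y + amp * ppd * np.sin(theta), 0, h - 1))
        rows.append(
            (trial, "saccade", t, min(t + cfg.saccade_ms, duration_ms), np.nan, np.nan, amp)
        )
        t += cfg.saccade_ms

    n_blinks = rng.poisson(cfg.blink_rate_hz * duration_ms / 1000.0)
    for _ in range(n_blinks):
        on = rng.uniform(0, duration_ms)
        dur = rng.gamma(4.0, cfg.blink_ms_mean / 4.0)
        rows.append((trial, "blink", on, min(on + dur, duration_ms), np.nan, np.nan, np.nan))

    events = pd.DataFrame(
        rows, columns=["trial", "kind", "t_on", "t_off", "x", "y", "amplitude"]
    )
    return events.sort_values("t_on", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# Responses
# --------------------------------------------------------------------------

def _quadrant_distance(i: int, j: int) -> float:
    qi, qj = EMOTION_QUADRANT[i], EMOTION_QUADRANT[j]
    # quadrants differ in valence (bit 1) and/or arousal (bit 0)
    return float((qi // 2 != qj // 2) + (qi % 2 != qj % 2))


def gen_responses(
    cfg: GeneratorConfig,
    schedule: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill a schedule's response column from the configured accuracy model.

    Each trial is answered correctly with the group x condition probability
    (shifted per participant by a logit-normal offset); otherwise the error
    response is drawn with weights decaying in valence/arousal distance from
    the true emotion, multiplied by the response-bias vector.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bias = np.asarray(cfg.response_bias)
    n_emotions = len(EMOTIONS)
    e_index = {e: i for i, e in enumerate(EMOTIONS)}

    dist = np.array(
        [
            [_quadrant_distance(i, j) for j in range(n_emotions)]
            for i in range(n_emotions)
        ]
    )
    error_w = np.exp(-cfg.confusion_decay * dist) * bias[np.newaxis, :]
    np.fill_diagonal(error_w, 0.0)
    error_w /= error_w.sum(axis=1, keepdims=True)

    offsets = {
        p: rng.normal(0, cfg.participant_sd)
        for p in schedule["participant"].unique()
    }

    out = schedule.copy()
    responses = []
    for row in out.itertuples():
        p_correct = cfg.accuracy[row.age_group][row.condition]
        logit = np.log(p_correct / (1 - p_correct)) + offsets[row.participant]
        p = 1.0 / (1.0 + np.exp(-logit))
        i = e_index[row.emotion]
        if rng.random() < p:
            responses.append(row.emotion)
        else:
            responses.append(EMOTIONS[rng.choice(n_emotions, p=error_w[i])])
    out["response"] = responses
    out["correct"] = out["response"] == out["emotion"]
    return out
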