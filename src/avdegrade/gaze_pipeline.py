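"""Trial-level filtering of parsed gaze events and dynamic-AOI scoring.

Events arrive pre-parsed (fixations, saccades, blinks with on/off times; an
Eyelink-style event stream). The pipeline restricts analysis to the first
1000 ms after stimulus onset, discards trials containing a single blink
longer than 300 ms inside that window, removes saccades larger than the
display diagonal, constructs dynamic areas of interest (eyes, nose, mouth,
hands) from per-frame face/hand track points, and scores per-trial fixation
proportions on those AOIs at 1-ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANALYSIS_WINDOW_MS",
    "BLINK_EXCLUSION_MS",
    "AOI_NAMES",
    "AOITrack",
    "window_trial",
    "exclude_blink_trials",
    "filter_saccades",
    "build_aoi_track",
    "fixation_proportions",
    "keep_correct_trials",
]

ANALYSIS_WINDOW_MS = 1000.0
BLINK_EXCLUSION_MS = 300.0
HAND_BOX_PX = 80.0
AOI_EXPANSION_PX = 10.0

AOI_NAMES = ("eyes", "nose", "mouth", "hands")

#: Landmarks required per frame to build the face/hand AOIs. Left/right are
#: in reference to the actor.
REQUIRED_LANDMARKS = (
    "left_eyebrow_outer",
    "left_eyebrow_inner",
    "left_eyebrow_middle",
    "right_eyebrow_outer",
    "right_eyebrow_inner",
    "right_eyebrow_middle",
    "left_pupil",
    "right_pupil",
    "nose_tip",
    "left_nostril",
    "right_nostril",
    "mouth_top",
    "mouth_bottom",
    "mouth_left",
    "mouth_right",
    "left_hand",
    "right_hand",
)

_EVENT_COLUMNS = ["trial", "kind", "t_on", "t_off", "x", "y", "amplitude"]


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"gaze event table lacks columns {missing}")
    if (events["t_off"] < events["t_on"]).any():
        raise ValueError("events must have t_off >= t_on")
    return events


def window_trial(
    events: pd.DataFrame,
    stim_on: float,
    window_ms: float = ANALYSIS_WINDOW_MS,
) -> pd.DataFrame:
    """Restrict events to [stim_on, stim_on + window_ms].

    Events overlapping the window are kept; events straddling a boundary
    are truncated at the boundary so durations count only in-window time.
    """
    events = _validate_events(events)
    lo, hi = stim_on, stim_on + window_ms
    keep = (events["t_off"] > lo) & (events["t_on"] < hi)
    out = events.loc[keep].copy()
    out["t_on"] = out["t_on"].clip(lower=lo)
    out["t_off"] = out["t_off"].clip(upper=hi)
    return out


def exclude_blink_trials(
    trials: dict, threshold_ms: float = BLINK_EXCLUSION_MS
) -> dict:
    """Drop whole trials containing any single blink longer than
    ``threshold_ms`` (strictly) inside the analysis window.

    ``trials`` maps trial id to a windowed event table.
    """
    kept = {}
    for trial_id, events in trials.items():
        blinks = events[events["kind"] == "blink"]
        durations = blinks["t_off"] - blinks["t_on"]
        if not (durations > threshold_ms).any():
            kept[trial_id] = events
    return kept


def filter_saccades(events: pd.DataFrame, max_amplitude_deg: float) -> pd.DataFrame:
    """Remove saccades with amplitude strictly larger than the maximum
    (nominally the display diagonal)."""
    if max_amplitude_deg <= 0:
        raise ValueError("max amplitude must be positive")
    drop = (events["kind"] == "saccade") & (events["amplitude"] > max_amplitude_deg)
    return events.loc[~drop].copy()


@dataclass(frozen=True)
class AOITrack:
    """Per-frame AOI rectangles: (left, top, right, bottom) pixels.

    ``rects`` has shape (n_frames, n_rects, 4) with matching ``labels``
    (one label per rectangle; the two eye boxes and the two hand boxes
    share their label). ``times_ms`` gives frame timestamps.
    """

    times_ms: np.ndarray
    rects: np.ndarray
    labels: tuple

    def frame_nearest(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


def _landmark_frame(track_points: pd.DataFrame, frame: int) -> dict:
    rows = track_points[track_points["frame"] == frame]
    pts = {r.landmark: (float(r.x), float(r.y)) for r in rows.itertuples()}
    for name in REQUIRED_LANDMARKS:
        if name not in pts:
            raise ValueError(f"frame {frame}: missing landmark {name!r}")
    return pts


def build_aoi_track(
    track_points: pd.DataFrame,
    frame_rate: float = 25.0,
    hand_box_px: float = HAND_BOX_PX,
    expansion_px: float = AOI_EXPANSION_PX,
) -> AOITrack:
    """Construct dynamic AOI rectangles from per-frame track points.

    Corner rules (left/right in reference to the actor):

    * eyes (each side): lateral x = eyebrow outer, medial x = eyebrow
      inner, top y = eyebrow middle, bottom y = the eye-nose border (the
      midpoint of the left-pupil y and nose-tip y);
    * nose: top = eye-nose border, bottom = nose-mouth border (midpoint of
      right-nostril y and mouth-top y), lateral x = the two nostrils;
    * mouth: lateral x = mouth corners, top = nose-mouth border, bottom =
      mouth-bottom y;
    * hands: fixed ``hand_box_px`` square centered on each hand point.

    Every AOI is expanded by ``expansion_px`` on each side except across the
    shared eye-nose and nose-mouth borders, so face AOIs touch but never
    overlap.
    """
    frames = np.sort(track_points["frame"].unique())
    times = frames / frame_rate * 1000.0
    e = expansion_px
    rects = np.empty((len(frames), 6, 4))
    labels = ("eyes", "eyes", "nose", "mouth", "hands", "hands")
    for i, fr in enumerate(frames):
        p = _landmark_frame(track_points, fr)
        eye_nose_border = (p["left_pupil"][1] + p["nose_tip"][1]) / 2.0
        nose_mouth_border = (p["right_nostril"][1] + p["mouth_top"][1]) / 2.0
        boxes = []
        for side in ("left", "right"):
            xs = sorted(
                [p[f"{side}_eyebrow_outer"][0], p[f"{side}_eyebrow_inner"][0]]
            )
            top = p[f"{side}_eyebrow_middle"][1]
            boxes.append(
                (xs[0] - e, top - e, xs[1] + e, eye_nose_border)  # no bottom exp
            )
        nx = sorted([p["left_nostril"][0], p["right_nostril"][0]])
        boxes.append((nx[0] - e, eye_nose_border, nx[1] + e, nose_mouth_border))
        mx = sorted([p["mouth_left"][0], p["mouth_right"][0]])
        boxes.append(
            (mx[0] - e, nose_mouth_border, mx[1] + e, p["mouth_bottom"][1] + e)
        )
        half = hand_box_px / 2.0
        for side in ("left", "right"):
            hx, hy = p[f"{side}_hand"]
            boxes.append((hx - half, hy - half, hx + half, hy + half))
        rects[i] = boxes
    return AOITrack(times, rects, labels)


def _point_in_rect(x: float, y: float, rect) -> bool:
    left, top, right, bottom = rect
    return left <= x <= right and top <= y <= bottom


def fixation_proportions(
    events: pd.DataFrame,
    aoi_track: AOITrack,
    sample_ms: float = 1.0,
) -> pd.Series:
    """Per-trial mean fixation proportion on each AOI plus "elsewhere".

    Fixation events are resampled to ``sample_ms`` time-points carrying the
    fixation's mean position; each time-point is scored against the AOI
    rectangles of the temporally nearest frame (first matching AOI in the
    canonical order wins, so touching borders never double-count).
    Proportions over all time-points sum to exactly 1.
    """
    fixations = events[events["kind"] == "fixation"]
    counts = dict.fromkeys(AOI_NAMES + ("elsewhere",), 0)
    n_total = 0
    for row in fixations.itertuples():
        t_points = np.arange(row.t_on, row.t_off, sample_ms)
        for t in t_points:
            k = aoi_track.frame_nearest(t)
            hit = "elsewhere"
            for rect, label in zip(aoi_track.rects[k], aoi_track.labels):
                if _point_in_rect(row.x, row.y, rect):
                    hit = label
                    break
            counts[hit] += 1
            n_total += 1
    if n_total == 0:
        raise ValueError("no fixation time-points in trial; trial excluded")
    return pd.Series({k: v / n_total for k, v in counts.items()})


def keep_correct_trials(
    trials: dict,
    responses: pd.DataFrame,
    require_correct: bool = True,
) -> dict:
    """Keep only trials answered correctly (gaze analysis precedes correct
    recognition). ``responses`` must carry ``trial`` and ``correct`` columns.

    With ``require_correct=False`` the trials pass through unchanged (the
    no-difference control analysis).
    """
    if not require_correct:
        return dict(trials)
    correct_map = responses.set_index("trial")["correct"]
    kept = {}
    for trial_id, events in trials.items():
        if trial_id not in correct_map.index:
            raise KeyError(f"trial {trial_id!r} has no matching response")
        if bool(correct_map.loc[trial_id]):
            kept[trial_id] = events
    return kept
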