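"""Experiment schedule and bias-corrected recognition accuracy.

The design crosses 12 emotions x 8 actors (96 stimuli) with 8 presentation
conditions (audio and video each intact, degraded, or absent). Accuracy is
scored as the unbiased hit-rate Hu = correct^2 / (occurrences x responses
used), i.e. recall x precision, which penalizes response bias; Hu values are
arcsine-square-root transformed before modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "EMOTIONS",
    "PRACTICE_CONDITION_ORDER",
    "balanced_latin_square",
    "build_schedule",
    "confusion_table",
    "unbiased_hit_rate",
    "hu_table",
    "arcsine_transform",
    "chance_level",
]

#: The 8 presentation conditions: audio/video intact (A/V), degraded (dA/dV
#: prefix "d"), or absent.
CONDITIONS = ("AV", "AdV", "A", "dAV", "dAdV", "dA", "V", "dV")

#: The 12 emotion categories, grouped by valence (pos/neg) and arousal
#: (high/low) quadrant.
EMOTIONS = (
    # positive, high arousal
    "amusement",
    "joy",
    "pride",
    # positive, low arousal
    "interest",
    "pleasure",
    "relief",
    # negative, high arousal
    "anger",
    "fear",
    "despair",
    # negative, low arousal
    "anxiety",
    "irritation",
    "sadness",
)

#: Valence/arousal quadrant index of each emotion (same order as EMOTIONS).
EMOTION_QUADRANT = (0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3)

MAIN_ACTORS = tuple(f"actor{i:02d}" for i in range(1, 9))
PRACTICE_ACTORS = ("practice01", "practice02")

PRACTICE_CONDITION_ORDER = ("AV", "V", "A", "AdV", "dAV", "dV", "dA", "dAdV")

N_BLOCKS = 6
N_SUBBLOCK_TRIALS = 16  # one sixth of the 96 stimuli
N_PRACTICE_PER_CONDITION = 8

_COLUMNS = [
    "participant",
    "age_group",
    "block",
    "sub_block",
    "trial",
    "condition",
    "emotion",
    "actor",
    "practice",
    "response",
    "correct",
]


def balanced_latin_square(n: int) -> np.ndarray:
    """Balanced Latin square of order ``n`` (n even).

    Row 0 follows the standard zig-zag sequence 0, 1, n-1, 2, n-2, ...;
    subsequent rows add the row index modulo n. Every condition precedes
    and follows every other equally often across rows.
    """
    if n % 2 != 0:
        raise ValueError("balanced Latin squares require an even order")
    first = np.empty(n, dtype=int)
    first[0::2] = np.arange((n + 1) // 2)
    first[1::2] = n - 1 - np.arange(n // 2)
    return (first[np.newaxis, :] + np.arange(n)[:, np.newaxis]) % n


def build_schedule(
    participants,
    seed: int = 0,
    age_groups=None,
    two_session_actor_split: bool = False,
) -> pd.DataFrame:
    """Build the full trial schedule (responses empty) for each participant.

    Per participant: 64 practice trials (8 per condition, practice actors,
    fixed condition order) followed by 6 blocks x 8 sub-blocks x 16 trials =
    768 main trials. Every (emotion, actor, condition) triple appears
    exactly once in the main trials; sub-block condition orders follow a
    balanced Latin square (the participant index rotates the row
    assignment); stimulus order within conditions is seeded-random.

    ``two_session_actor_split`` emulates the older-participant schedule in
    which blocks 1-3 use one pseudo-random half of the actors (2 male + 2
    female by position) and blocks 4-6 the other half.
    """
    participants = list(participants)
    if len(participants) < 1:
        raise ValueError("at least one participant required")
    if age_groups is None:
        age_groups = {p: "young" for p in participants}
    rng = np.random.default_rng(seed)
    square = balanced_latin_square(len(CONDITIONS))

    stimuli = [(e, a) for e in EMOTIONS for a in MAIN_ACTORS]
    rows = []
    for p_idx, participant in enumerate(participants):
        age = age_groups[participant]
        # practice block: fixed condition order, random stimuli from the
        # practice actors
        practice_stimuli = [(e, a) for e in EMOTIONS for a in PRACTICE_ACTORS]
        trial = 0
        for condition in PRACTICE_CONDITION_ORDER:
            pick = rng.permutation(len(practice_stimuli))[:N_PRACTICE_PER_CONDITION]
            for k in pick:
                e, a = practice_stimuli[k]
                rows.append(
                    (participant, age, 0, 0, trial, condition, e, a, True, None, None)
                )
                trial += 1

        # main trials: per condition, split the 96 stimuli into 6 chunks of 16
        chunks: dict = {}
        for condition in CONDITIONS:
            if two_session_actor_split:
                half = rng.permutation(8)
                first_actors = {MAIN_ACTORS[i] for i in half[:4]}
                first = [s for s in stimuli if s[1] in first_actors]
                second = [s for s in stimuli if s[1] not in first_actors]
                order = [first[i] for i in rng.permutation(len(first))] + [
                    second[i] for i in rng.permutation(len(second))
                ]
            else:
                order = [stimuli[i] for i in rng.permutation(len(stimuli))]
            chunks[condition] = [
                order[b * N_SUBBLOCK_TRIALS : (b + 1) * N_SUBBLOCK_TRIALS]
                for b in range(N_BLOCKS)
            ]
        for block in range(N_BLOCKS):
            cond_order = square[(p_idx + block) % len(CONDITIONS)]
            for sub, c_idx in enumerate(cond_order):
                condition = CONDITIONS[c_idx]
                for e, a in chunks[condition][block]:
                    rows.append(
                        (
                            participant,
                            age,
                            block + 1,
                            sub + 1,
                            trial,
                            condition,
                            e,
                            a,
                            False,
                            None,
                            None,
                        )
                    )
                    trial += 1
    return pd.DataFrame(rows, columns=_COLUMNS)


def confusion_table(trials: pd.DataFrame) -> pd.DataFrame:
    """12x12 confusion counts (true emotion x response) from responded trials.

    Practice trials and trials without a response are ignored. Returns a
    DataFrame indexed by true emotion with response columns, both in the
    canonical emotion order.
    """
    t = trials[(~trials["practice"]) & trials["response"].notna()]
    table = pd.crosstab(t["emotion"], t["response"])
    table = table.reindex(index=EMOTIONS, columns=EMOTIONS, fill_value=0)
    table.index.name = "emotion"
    table.columns.name = "response"
    return table


def unbiased_hit_rate(table: pd.DataFrame, emotion: str) -> float:
    """Unbiased hit-rate Hu = correct^2 / (occurrences x responses used).

    Equals recall x precision. Defined as 0 when the response was never
    used (the numerator is then necessarily 0).
    """
    if emotion not in table.index:
        raise KeyError(f"unknown emotion {emotion!r}")
    occurrence = int(table.loc[emotion].sum())
    if occurrence == 0:
        raise ValueError(f"emotion {emotion!r} never occurred; Hu undefined")
    responded = int(table[emotion].sum())
    correct = int(table.loc[emotion, emotion])
    if responded == 0:
        return 0.0
    return correct**2 / (occurrence * responded)


def hu_table(trials: pd.DataFrame, by=("participant", "condition")) -> pd.DataFrame:
    """Tidy unbiased hit-rates per grouping cell and emotion.

    Returns columns ``by + [emotion, hu, hu_asin]``.
    """
    rows = []
    grouped = trials[~trials["practice"]].groupby(list(by), observed=True)
    for key, cell in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        table = confusion_table(cell)
        for emotion in EMOTIONS:
            hu = unbiased_hit_rate(table, emotion)
            rows.append(key + (emotion, hu, arcsine_transform(hu)))
    return pd.DataFrame(rows, columns=list(by) + ["emotion", "hu", "hu_asin"])


def arcsine_transform(p):
    """Variance-stabilizing transform asin(sqrt(p)), radians in [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def chance_level(n_emotions: int) -> float:
    """Chance proportion correct in an n-alternative forced choice."""
    if n_emotions < 2:
        raise ValueError("need at least two response categories")
    return 1.0 / n_emotions
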