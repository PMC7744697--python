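"""Scoring of intrinsic scales and per-video message ratings.

Subjects bring three intrinsic self-report measures (marijuana-use risk,
sensation seeking, task compliance) and rate each of the 32 PSA videos on
several dimensions: perceived message sensation value (pMSV), perceived
argument strength (pAS), ad liking, 14 emotion items (collapsed into a
positive and a negative composite), and two thought items whose difference
is the thought-valence score. Missing responses are imputed with the mean
of the non-missing responses to the same question.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE_EMOTION_ITEMS = ("good", "happy", "inspired")
NEGATIVE_EMOTION_ITEMS = ("sad", "afraid", "bad", "guilty", "angry", "disgusted", "sympathetic")
# four emotion items are collected but enter neither composite; carried through untouched
UNUSED_EMOTION_ITEMS = ("surprised", "calm", "bored", "confused")
EMOTION_ITEMS = POSITIVE_EMOTION_ITEMS + NEGATIVE_EMOTION_ITEMS + UNUSED_EMOTION_ITEMS

THOUGHT_ITEMS = ("stay_away", "want_try")

#: Likert bounds per rating measure (inclusive).
RATING_BOUNDS: dict[str, tuple[float, float]] = {
    "pMSV": (1, 5),
    "pAS": (1, 5),
    "AdLike": (1, 7),
    "emotion": (1, 4),
    "thought": (1, 7),
}

RATING_MEASURES = ("pMSV", "pAS", "AdLike", "pos", "neg", "ThVal")


class AllMissingError(ValueError):
    """Every response to a scale/question is missing; nothing to impute from."""


@dataclass(frozen=True)
class ScaleDef:
    """A multi-item Likert scale summarized by the arithmetic mean of its items."""

    name: str
    item_ids: tuple[str, ...]
    response_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise ValueError(f"scale {self.name!r} has no items")
        lo, hi = self.response_range
        if not lo < hi:
            raise ValueError(f"scale {self.name!r} has an empty response range")


SENSATION_SEEKING = ScaleDef("SSscore", tuple(f"ss{i}" for i in range(1, 5)), (1, 5))
MARIJUANA_RISK = ScaleDef("MJrisk", tuple(f"mj{i}" for i in range(1, 6)), (1, 5))
COMPLIANCE = ScaleDef("Compliance", tuple(f"comp{i}" for i in range(1, 5)), (1, 5))
DEFAULT_SCALES = (MARIJUANA_RISK, SENSATION_SEEKING, COMPLIANCE)


def impute_missing(column: Sequence[float] | pd.Series, name: str = "column") -> np.ndarray:
    """Replace NaNs with the mean of the non-missing entries of the same column.

    This is a per-question rule: the mean is taken across subjects who
    answered that question, never across a subject's other answers.
    """
    vals = np.asarray(pd.Series(column, dtype=float))
    missing = np.isnan(vals)
    if missing.all():
        raise AllMissingError(f"cannot impute {name!r}: all values missing")
    out = vals.copy()
    out[missing] = vals[~missing].mean()
    return out


def score_scale(item_responses: Sequence[float], scale: ScaleDef) -> float:
    """Arithmetic mean of a subject's item responses for one scale."""
    vals = np.asarray(item_responses, dtype=float)
    if len(vals) != len(scale.item_ids):
        raise ValueError(
            f"scale {scale.name!r} expects {len(scale.item_ids)} items, got {len(vals)}"
        )
    lo, hi = scale.response_range
    if np.any(vals < lo) or np.any(vals > hi):
        raise ValueError(f"response outside {scale.name!r} range [{lo}, {hi}]: {vals.tolist()}")
    return float(vals.mean())


def aggregate_emotions(ratings: Mapping[str, float]) -> tuple[float, float]:
    """Collapse the 14 emotion items into (pos, neg) composites.

    pos averages the 3 positive items, neg the 7 negative items; the
    remaining 4 items do not enter either composite.
    """
    for item in POSITIVE_EMOTION_ITEMS + NEGATIVE_EMOTION_ITEMS:
        if item not in ratings or np.isnan(float(ratings[item])):
            raise ValueError(f"emotion item {item!r} missing after imputation")
    pos = float(np.mean([ratings[i] for i in POSITIVE_EMOTION_ITEMS]))
    neg = float(np.mean([ratings[i] for i in NEGATIVE_EMOTION_ITEMS]))
    return pos, neg


def thought_valence(stay_item: float, try_item: float) -> float:
    """Thought-valence difference score: stay-away minus want-try.

    Higher values mean message-consistent thoughts predominate. The sign
    convention is inert downstream: pairwise |Δ| similarity is invariant
    to a global sign flip.
    """
    lo, hi = RATING_BOUNDS["thought"]
    for v, name in ((stay_item, "stay_away"), (try_item, "want_try")):
        if not lo <= v <= hi:
            raise ValueError(f"thought item {name!r} outside [{lo}, {hi}]: {v}")
    return float(stay_item) - float(try_item)


def score_subjects(
    items: pd.DataFrame, scales: Sequence[ScaleDef] = DEFAULT_SCALES
) -> pd.DataFrame:
    """Score intrinsic scales for every subject.

    ``items`` has one row per subject (index = subject_id) and one column
    per item id; missing responses are imputed per item column first.
    Returns a DataFrame indexed by subject with one column per scale.
    """
    out = {}
    for scale in scales:
        missing_cols = [c for c in scale.item_ids if c not in items.columns]
        if missing_cols:
            raise ValueError(f"scale {scale.name!r} missing item column(s): {missing_cols}")
        block = pd.DataFrame(
            {c: impute_missing(items[c], name=c) for c in scale.item_ids}, index=items.index
        )
        out[scale.name] = [score_scale(row, scale) for row in block.to_numpy()]
    return pd.DataFrame(out, index=items.index)


def _check_bounds(df: pd.DataFrame) -> None:
    for measure, grp in df.dropna(subset=["value"]).groupby("measure"):
        if measure not in RATING_BOUNDS:
            raise ValueError(f"unknown rating measure {measure!r}")
        lo, hi = RATING_BOUNDS[measure]
        v = grp["value"].to_numpy(dtype=float)
        if np.any(v < lo) or np.any(v > hi):
            raise ValueError(f"{measure} rating outside Likert bounds [{lo}, {hi}]")


def prepare_ratings(ratings: pd.DataFrame, n_videos: int | None = None) -> dict[str, pd.DataFrame]:
    """Impute and summarize the long-format rating table.

    ``ratings`` columns: subject_id, video_id, measure, item, value (empty
    value = missing; item is empty for single-value measures). Imputation
    is per question, i.e. per (measure, item, video) cell across subjects.

    Returns one subject x video matrix per derived measure:
    pMSV, pAS, AdLike, pos, neg, ThVal.
    """
    df = ratings.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["item"] = df.get("item", pd.Series("", index=df.index)).fillna("")
    _check_bounds(df)

    def _impute_question(s: pd.Series) -> pd.Series:
        measure, item, video = s.name
        name = f"{measure}/{item}/video{video}" if item else f"{measure}/video{video}"
        return pd.Series(impute_missing(s, name=name), index=s.index)

    df["value"] = df.groupby(["measure", "item", "video_id"])["value"].transform(_impute_question)

    def pivot(measure: str, item: str = "") -> pd.DataFrame:
        sub = df[(df["measure"] == measure) & (df["item"] == item)]
        wide = sub.pivot(index="subject_id", columns="video_id", values="value").sort_index(axis=1)
        return wide

    subjects = sorted(df["subject_id"].unique())
    out: dict[str, pd.DataFrame] = {}
    for m in ("pMSV", "pAS", "AdLike"):
        out[m] = pivot(m).loc[subjects]

    emotion = {item: pivot("emotion", item) for item in sorted(df.loc[df["measure"] == "emotion", "item"].unique())}
    for item in POSITIVE_EMOTION_ITEMS + NEGATIVE_EMOTION_ITEMS:
        if item not in emotion:
            raise ValueError(f"emotion item {item!r} absent from the rating table")
    out["pos"] = sum(emotion[i] for i in POSITIVE_EMOTION_ITEMS) / len(POSITIVE_EMOTION_ITEMS)
    out["neg"] = sum(emotion[i] for i in NEGATIVE_EMOTION_ITEMS) / len(NEGATIVE_EMOTION_ITEMS)
    out["pos"] = out["pos"].loc[subjects]
    out["neg"] = out["neg"].loc[subjects]

    stay = pivot("thought", "stay_away").loc[subjects]
    want = pivot("thought", "want_try").loc[subjects]
    out["ThVal"] = stay - want

    n_vid = out["pMSV"].shape[1] if n_videos is None else n_videos
    for m, wide in out.items():
        if wide.shape[1] != n_vid:
            raise ValueError(f"{m}: expected {n_vid} videos, found {wide.shape[1]}")
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()].tolist()
            raise ValueError(f"{m}: missing values remain after imputation in videos {bad}")
    return out
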