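"""Motor factor scoring for the 33-item Part III motor examination.

The default structure partitions the 33 items into 7 factors — midline
function, rest tremor, rigidity, right/left upper-extremity bradykinesia,
postural/kinetic tremor, and lower-limb bradykinesia — with uniform per-item
weights.  Published per-item loadings can be substituted via a weights CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical item codes of the 33-item motor exam, in exam order
ITEM_CODES: tuple[str, ...] = (
    "3.1", "3.2",
    "3.3a", "3.3b", "3.3c", "3.3d", "3.3e",
    "3.4a", "3.4b",
    "3.5a", "3.5b",
    "3.6a", "3.6b",
    "3.7a", "3.7b",
    "3.8a", "3.8b",
    "3.9", "3.10", "3.11", "3.12", "3.13", "3.14",
    "3.15a", "3.15b",
    "3.16a", "3.16b",
    "3.17a", "3.17b", "3.17c", "3.17d", "3.17e",
    "3.18",
)

FACTOR_NAMES: tuple[str, ...] = (
    "midline function",
    "rest tremor",
    "rigidity",
    "bradykinesia right upper extremity",
    "bradykinesia left upper extremity",
    "postural and kinetic tremors",
    "lower limb bradykinesia",
)

_DEFAULT_ASSIGNMENT: dict[str, int] = {
    # factor 1: midline function (8 items)
    "3.1": 1, "3.2": 1, "3.9": 1, "3.10": 1, "3.11": 1, "3.12": 1,
    "3.13": 1, "3.14": 1,
    # factor 2: rest tremor (6 items)
    "3.17a": 2, "3.17b": 2, "3.17c": 2, "3.17d": 2, "3.17e": 2, "3.18": 2,
    # factor 3: rigidity (5 items)
    "3.3a": 3, "3.3b": 3, "3.3c": 3, "3.3d": 3, "3.3e": 3,
    # factor 4: bradykinesia right upper extremity (3 items)
    "3.4a": 4, "3.5a": 4, "3.6a": 4,
    # factor 5: bradykinesia left upper extremity (3 items)
    "3.4b": 5, "3.5b": 5, "3.6b": 5,
    # factor 6: postural and kinetic tremors (4 items)
    "3.15a": 6, "3.15b": 6, "3.16a": 6, "3.16b": 6,
    # factor 7: lower limb bradykinesia (4 items)
    "3.7a": 7, "3.7b": 7, "3.8a": 7, "3.8b": 7,
}

EXPECTED_FACTOR_SIZES = (8, 6, 5, 3, 3, 4, 4)


@dataclass(frozen=True)
class ItemRatings:
    """Complete item scores for one subject in one medication condition."""

    subject_id: str
    condition: str
    scores: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in ITEM_CODES if c not in self.scores]
        if missing:
            raise ValueError(f"missing item ratings: {', '.join(missing)}")
        extra = set(self.scores) - set(ITEM_CODES)
        if extra:
            raise ValueError(f"unknown item codes: {sorted(extra)}")
        for code, s in self.scores.items():
            if s not in (0, 1, 2, 3, 4):
                raise ValueError(f"item {code}: score {s!r} not in 0..4")


@dataclass(frozen=True)
class FactorStructure:
    """Item-to-factor partition with positive per-item weights."""

    assignment: Mapping[str, int]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(ITEM_CODES):
            raise ValueError("assignment must cover exactly the 33 item codes")
        if set(self.weights) != set(ITEM_CODES):
            raise ValueError("weights must cover exactly the 33 item codes")
        for code, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"item {code}: weight must be > 0, got {w}")
        sizes = self.factor_sizes()
        if sorted(self.assignment.values()) != sorted(
                f for f, n in enumerate(sizes, start=1) for _ in range(n)):
            raise ValueError("factor indices must lie in 1..7")

    def factor_items(self, factor: int) -> list[str]:
        return [c for c in ITEM_CODES if self.assignment[c] == factor]

    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(sum(1 for f in self.assignment.values() if f == k)
                     for k in range(1, 8))


@dataclass(frozen=True)
class FactorScores:
    """Raw sums and weighted averages (0-4 item scale) for the 7 factors."""

    subject_id: str
    condition: str
    raw_sums: tuple[float, ...]
    weighted_averages: tuple[float, ...]


def default_factor_structure(weights: Mapping[str, float] | None = None) -> FactorStructure:
    """The canonical 7-factor partition; uniform weights unless overridden."""
    if weights is None:
        weights = {code: 1.0 for code in ITEM_CODES}
    return FactorStructure(assignment=dict(_DEFAULT_ASSIGNMENT), weights=dict(weights))


def load_factor_weights_csv(path) -> FactorStructure:
    """Read a (item_code, factor, weight) CSV into a FactorStructure."""
    df = pd.read_csv(path, dtype={"item_code": str})
    required = {"item_code", "factor", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"weights CSV must have columns {sorted(required)}")
    assignment = dict(zip(df["item_code"], df["factor"].astype(int)))
    weights = dict(zip(df["item_code"], df["weight"].astype(float)))
    return FactorStructure(assignment=assignment, weights=weights)


def factor_scores(ratings: ItemRatings,
                  structure: FactorStructure | None = None) -> FactorScores:
    """Raw sum and weighted average of item scores per factor."""
    if structure is None:
        structure = default_factor_structure()
    raw = []
    weighted = []
    for f in range(1, 8):
        items = structure.factor_items(f)
        scores = np.array([ratings.scores[c] for c in items], dtype=float)
        w = np.array([structure.weights[c] for c in items], dtype=float)
        raw.append(float(scores.sum()))
        weighted.append(float(np.sum(w * scores) / np.sum(w)))
    return FactorScores(ratings.subject_id, ratings.condition,
                        tuple(raw), tuple(weighted))


def sdr_change(off: FactorScores, on: FactorScores) -> tuple[float, ...]:
    """Per-factor change in weighted-average score; positive = improvement."""
    return tuple(o - n for o, n in zip(off.weighted_averages, on.weighted_averages))


def scores_to_frame(all_scores: list[FactorScores]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "condition": s.condition, "factor": f,
         "raw_sum": s.raw_sums[f - 1], "weighted_average": s.weighted_averages[f - 1]}
        for s in all_scores for f in range(1, 8)
    ]
    return pd.DataFrame(rows)


def ratings_from_frame(df: pd.DataFrame) -> list[ItemRatings]:
    """Parse a tidy (subject_id, condition, item_code, score) table."""
    required = {"subject_id", "condition", "item_code", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    out = []
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        scores = dict(zip(grp["item_code"].astype(str), grp["score"].astype(int)))
        out.append(ItemRatings(str(sid), str(cond), scores))
    return out
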