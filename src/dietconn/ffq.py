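"""Mediterranean-diet adherence scoring from food-frequency data.

Monthly serving counts for 11 fixed food categories are mapped onto 0-5
frequency categories with a monotone step function, detrimental categories
are reverse-scored, and the 11 category scores are summed into a 0-55
adherence total.  Totals are split into low / moderate / high groups at the
tertiles of the cohort distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BENEFICIAL_CATEGORIES: tuple[str, ...] = (
    "non-refined cereals",
    "potatoes",
    "fruits",
    "vegetables",
    "legumes",
    "fish",
    "olive oil",
)
DETRIMENTAL_CATEGORIES: tuple[str, ...] = (
    "poultry",
    "red meat",
    "full-fat dairy",
    "alcohol",
)
ALL_CATEGORIES: tuple[str, ...] = BENEFICIAL_CATEGORIES + DETRIMENTAL_CATEGORIES

#: Default servings/month thresholds for frequency categories 1..5
#: (roughly: never, < weekly, 1-3x/week, ~ daily, > 2x/day).  Not fixed by
#: any external convention; override via config where needed.
DEFAULT_CUTPOINTS: tuple[float, ...] = (1.0, 5.0, 13.0, 31.0, 61.0)

GROUP_LEVELS: tuple[str, ...] = ("low", "moderate", "high")

MAX_CATEGORY_SCORE = 5
MAX_TOTAL = MAX_CATEGORY_SCORE * len(ALL_CATEGORIES)  # 55


class IncompleteIntakeError(ValueError):
    """Raised when a participant lacks a record for one of the 11 categories."""


@dataclass
class MediScore:
    """Per-participant adherence score.

    ``category_scores`` hold the final 0-5 values (detrimental already
    reversed).  ``beneficial_sum`` ranges 0-35, ``detrimental_avoidance_sum``
    0-20, and their sum equals ``total``.
    """

    participant_id: object
    category_scores: dict[str, int]
    total: int
    beneficial_sum: int
    detrimental_avoidance_sum: int
    group: str | None = field(default=None)


def categorize_frequency(
    servings_per_month: float,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> int:
    """Map a monthly serving count onto a 0-5 frequency category.

    The category is the number of cutpoints ``<=`` the intake, so the map is
    a monotone step function with ``categorize_frequency(0) == 0`` and
    saturation at 5 above the last cutpoint.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.shape != (5,):
        raise ValueError("exactly 5 cutpoints required")
    if not np.all(np.diff(cuts) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    x = float(servings_per_month)
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"servings_per_month must be finite and >= 0, got {x}")
    return int(np.searchsorted(cuts, x, side="right"))


def score_medi(
    intakes: Mapping[str, float],
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    participant_id: object = None,
    reverse_detrimental_sum: bool = True,
) -> MediScore:
    """Score one participant's 11-category intake profile.

    Beneficial categories keep their raw frequency category; detrimental
    categories are reversed (``5 - category``) so that higher always means
    more adherent.  ``reverse_detrimental_sum=False`` reports the detrimental
    subscore on the raw (un-reversed) orientation instead; the total is
    unaffected.
    """
    missing = [c for c in ALL_CATEGORIES if c not in intakes]
    if missing:
        raise IncompleteIntakeError(
            f"participant {participant_id!r} missing categories: {missing}"
        )
    scores: dict[str, int] = {}
    for cat in BENEFICIAL_CATEGORIES:
        scores[cat] = categorize_frequency(intakes[cat], cutpoints)
    raw_detrimental = 0
    for cat in DETRIMENTAL_CATEGORIES:
        raw = categorize_frequency(intakes[cat], cutpoints)
        raw_detrimental += raw
        scores[cat] = MAX_CATEGORY_SCORE - raw
    beneficial_sum = sum(scores[c] for c in BENEFICIAL_CATEGORIES)
    avoidance = sum(scores[c] for c in DETRIMENTAL_CATEGORIES)
    detrimental_sum = avoidance if reverse_detrimental_sum else raw_detrimental
    return MediScore(
        participant_id=participant_id,
        category_scores=scores,
        total=beneficial_sum + avoidance,
        beneficial_sum=beneficial_sum,
        detrimental_avoidance_sum=detrimental_sum,
    )


def score_table(
    ffq: pd.DataFrame,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    reverse_detrimental_sum: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Score a long-format FFQ table.

    ``ffq`` needs columns ``participant_id``, ``category``,
    ``servings_per_month``.  Returns a per-participant score table and the
    list of participant ids flagged diet-missing (incomplete category set);
    flagged participants receive no score row.
    """
    required = {"participant_id", "category", "servings_per_month"}
    if not required.issubset(ffq.columns):
        raise ValueError(f"ffq table must have columns {sorted(required)}")
    unknown = set(ffq["category"]) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown food categories: {sorted(unknown)}")

    wide = ffq.pivot_table(
        index="participant_id",
        columns="category",
        values="servings_per_month",
        aggfunc="first",
    )
    complete = wide.dropna(subset=list(ALL_CATEGORIES), how="any") \
        if set(ALL_CATEGORIES).issubset(wide.columns) else wide.iloc[0:0]
    missing_ids = sorted(set(wide.index) - set(complete.index))

    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.shape != (5,) or not np.all(np.diff(cuts) > 0):
        raise ValueError("cutpoints must be 5 strictly increasing thresholds")
    if complete.empty:
        servings = np.empty((0, len(ALL_CATEGORIES)))
    else:
        servings = complete[list(ALL_CATEGORIES)].to_numpy(dtype=float)
    if servings.size and (np.any(servings < 0) or not np.all(np.isfinite(servings))):
        raise ValueError("servings_per_month must be finite and >= 0")
    categories = np.searchsorted(cuts, servings, side="right")
    n_beneficial = len(BENEFICIAL_CATEGORIES)
    beneficial = categories[:, :n_beneficial].sum(axis=1)
    raw_detrimental = categories[:, n_beneficial:].sum(axis=1)
    avoidance = MAX_CATEGORY_SCORE * len(DETRIMENTAL_CATEGORIES) - raw_detrimental
    out = pd.DataFrame(
        {
            "participant_id": complete.index.to_numpy(),
            "medi_total": beneficial + avoidance,
            "beneficial_sum": beneficial,
            "detrimental_sum": avoidance if reverse_detrimental_sum else raw_detrimental,
        }
    )
    return out, missing_ids


def assign_tertiles(totals: Iterable[float]) -> np.ndarray:
    """Split adherence totals into low / moderate / high at the tertiles.

    Cuts are the 33 1/3 and 66 2/3 percentiles of ``totals``; scores tied
    with a cut fall into the lower group.  Raises on degenerate input
    (< 3 scores, or all scores equal).
    """
    t = np.asarray(list(totals), dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 participants for tertile grouping")
    if np.all(t == t[0]):
        raise ValueError("degenerate score distribution: all totals equal")
    q_low, q_high = np.percentile(t, [100.0 / 3.0, 200.0 / 3.0])
    labels = np.where(t <= q_low, "low", np.where(t <= q_high, "moderate", "high"))
    return labels


def score_and_group(
    ffq: pd.DataFrame,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> tuple[pd.DataFrame, list]:
    """Score an FFQ table and append tertile group labels."""
    scores, missing = score_table(ffq, cutpoints)
    if len(scores) >= 3 and scores["medi_total"].nunique() > 1:
        scores = scores.copy()
        scores["medi_group"] = assign_tertiles(scores["medi_total"].to_numpy())
    else:
        scores = scores.copy()
        scores["medi_group"] = None
    return scores, missing
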