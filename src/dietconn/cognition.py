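"""Task z-scoring and the four cognitive-ability composites.

Twelve task scores, three per domain, are standardized against reference
norms and averaged within domain into SPEED, FLUID, MEMORY and VOCAB
composites.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Domain -> (task columns).  Exactly 4 domains x 3 tasks.
TASK_BATTERY: dict[str, tuple[str, str, str]] = {
    "SPEED": ("digit_symbol", "letter_comparison", "pattern_comparison"),
    "FLUID": ("paper_folding", "matrix_reasoning", "letter_sets"),
    "MEMORY": ("logical_memory", "word_order", "paired_associates"),
    "VOCAB": ("antonyms", "synonyms", "picture_naming"),
}
DOMAINS: tuple[str, ...] = tuple(TASK_BATTERY)
ALL_TASKS: tuple[str, ...] = tuple(t for tasks in TASK_BATTERY.values() for t in tasks)


def zscore_task(raw: float, ref_mean: float, ref_sd: float) -> float:
    """Standardize a raw task score against a reference mean/SD."""
    if not ref_sd > 0:
        raise ValueError(f"reference SD must be > 0, got {ref_sd}")
    return (raw - ref_mean) / ref_sd


def composite_ra(z1: float, z2: float, z3: float) -> float:
    """Average three within-domain task z-scores into one ability score."""
    zs = np.asarray([z1, z2, z3], dtype=float)
    if np.any(np.isnan(zs)):
        return float("nan")
    return float(zs.mean())


def score_battery(
    tasks: pd.DataFrame,
    norms: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, list]:
    """Score a participant x 12-task table into the four composites.

    ``norms`` maps task name -> (reference mean, reference SD).  When absent
    the cohort's own mean/SD are used (logged, since external norms are the
    intended reference).  Participants with any missing task are flagged
    cognition-missing and receive NaN composites.
    """
    missing_cols = [t for t in ALL_TASKS if t not in tasks.columns]
    if missing_cols:
        raise ValueError(f"task table missing columns: {missing_cols}")
    if norms is None:
        log.info("no reference norms supplied; standardizing against cohort mean/SD")
        norms = {
            t: (float(tasks[t].mean()), float(tasks[t].std(ddof=1)))
            for t in ALL_TASKS
        }
    for t in ALL_TASKS:
        mean, sd = norms[t]
        if not sd > 0:
            raise ValueError(f"reference SD for task {t!r} must be > 0")

    out = pd.DataFrame(index=tasks.index)
    if "participant_id" in tasks.columns:
        out["participant_id"] = tasks["participant_id"]
    for domain, (t1, t2, t3) in TASK_BATTERY.items():
        zs = [
            (tasks[t] - norms[t][0]) / norms[t][1] for t in (t1, t2, t3)
        ]
        out[domain] = sum(zs) / 3.0
    flagged = out[out[list(DOMAINS)].isna().any(axis=1)]
    missing_ids = (
        flagged["participant_id"].tolist()
        if "participant_id" in out.columns
        else flagged.index.tolist()
    )
    return out, missing_ids
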