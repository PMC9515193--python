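"""Replicate-level parameter-recovery and calibration studies.

These drive the acceptance checks: simulate many cohorts under a planted
effect preset, push each through scoring -> assembly -> model fitting, and
summarize how well the planted coefficients are recovered (or, under the
null preset, how often the joint interaction test rejects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dietconn.cohort import assemble
from dietconn.ffq import GROUP_LEVELS, score_and_group
from dietconn.models import interaction_model, stratified_model
from dietconn.synthetic import Cohort, SimulationConfig, generate_cohort


def make_config(
    preset: str,
    n: int = 201,
    seed: int = 0,
    fast: bool = True,
    missingness: tuple[int, int, int, int] = (0, 0, 0, 0),
    **overrides,
) -> SimulationConfig:
    """Convenience constructor for recovery-study cohorts (no missingness)."""
    return SimulationConfig(
        n_enrolled=n, effect_preset=preset, seed=seed, fast=fast,
        missingness_counts=missingness, **overrides,
    )


def analytic_table(cohort: Cohort, tr: float = 2.0) -> pd.DataFrame:
    """Score diet, merge stage outputs and apply the exclusion cascade.

    Fast-mode cohorts carry connectivity scalars directly; otherwise each
    participant's time series is pushed through the processing pipeline
    first (its scrub percentage then replaces the drawn covariate).
    """
    medi, _ = score_and_group(cohort.ffq)
    rsfc_df = cohort.rsfc
    if rsfc_df is None:
        from dietconn.rsfc import process_participant, summary_to_row

        rows = []
        for pid, ts in cohort.timeseries.items():
            summary, scrub_pct = process_participant(
                ts, cohort.motion[pid], cohort.nuisance[pid],
                cohort.parcellation, tr=tr,
            )
            rows.append(summary_to_row(pid, summary, scrub_pct))
        rsfc_df = pd.DataFrame(rows)
    analytic, _ = assemble(
        cohort.participants, medi_scores=medi,
        rsfc_summaries=rsfc_df, ra_scores=cohort.ra,
    )
    return analytic


def simulate_analytic(config: SimulationConfig) -> pd.DataFrame:
    return analytic_table(generate_cohort(config))


def replicate_study(
    preset: str,
    n_reps: int,
    n: int = 201,
    seed: int = 0,
    outcome: str = "FLUID",
    **config_overrides,
) -> pd.DataFrame:
    """Per-replicate stratified slopes, interaction estimates and joint p.

    Each replicate simulates a fresh fast-mode cohort (seeded from ``seed``),
    fits the full interaction model and the three stratified models for
    ``outcome`` on overall connectivity, and records:

    - ``strat_low`` / ``strat_moderate`` / ``strat_high``: within-group slopes,
    - ``inter_moderate`` / ``inter_high``: group x connectivity coefficients,
    - ``joint_p``: the 2-df Wald p for both interaction terms.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    rows = []
    for rep_seed in seeds:
        config = make_config(preset, n=n, seed=int(rep_seed), **config_overrides)
        df = simulate_analytic(config)
        inter = interaction_model(df, "rsfc_overall", outcome)
        row = {
            "inter_moderate": inter.term("rsfc:medi[moderate]").B,
            "inter_high": inter.term("rsfc:medi[high]").B,
            "joint_p": inter.joint["interaction"][2],
        }
        for g in GROUP_LEVELS:
            row[f"strat_{g}"] = stratified_model(df, "rsfc_overall", outcome, g).term("rsfc").B
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_means(results: pd.DataFrame) -> dict[str, float]:
    return {col: float(results[col].mean()) for col in results.columns}


def null_rejection_rate(
    n_reps: int = 1000,
    alpha: float = 0.10,
    n: int = 201,
    seed: int = 0,
    **config_overrides,
) -> float:
    """Type-I error of the 2-df interaction test under the null preset."""
    results = replicate_study("null", n_reps, n=n, seed=seed, **config_overrides)
    return float((results["joint_p"] < alpha).mean())
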