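"""Sequential exclusion cascade and analytic-table covariate preparation."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Cascade stages in the order they are applied: (stage name, flag column).
CASCADE_STAGES: tuple[tuple[str, str], ...] = (
    ("diet", "diet_missing"),
    ("rsfc", "rsfc_missing"),
    ("structural", "structural_missing"),
    ("cognitive", "cognitive_missing"),
)

RACE_LEVELS: tuple[str, ...] = (
    "non-Hispanic white",  # reference category (largest group)
    "non-Hispanic black",
    "other",
)

#: Model covariate columns produced by :func:`prepare_covariates`.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age",
    "female",
    "race_black",
    "race_other",
    "education",
    "nart_iq",
    "caloric_intake",
    "cortical_thickness",
    "brain_volume",
    "scrub_pct",
    "log_wmh",
    "fa",
)

DEFAULT_SCRUB_CUT = 30.0
WMH_LOG_OFFSET = 1.0


def exclusion_cascade(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged participants stage by stage.

    Participants are removed in cascade order (diet, rsfc, structural,
    cognitive); the flow report lists the remaining count after every stage.
    An empty analytic set is allowed (reported, not raised).
    """
    for _, flag in CASCADE_STAGES:
        if flag not in records.columns:
            raise ValueError(f"records lack flag column {flag!r}")
    flow: dict[str, int] = {"enrolled": len(records)}
    current = records
    for stage, flag in CASCADE_STAGES:
        current = current[~current[flag].astype(bool)]
        flow[f"after_{stage}"] = len(current)
    return current.copy(), flow


def prepare_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Build the numeric covariate block for the regression models.

    White-matter-hyperintensity volume is mapped through ``ln(wmh + 1)`` (the
    offset guards zero volumes), race/ethnicity becomes two indicators with
    non-Hispanic white as reference, and gender is the ``female`` indicator
    (male = 0).  All other covariates pass through unchanged.
    """
    required = {
        "age", "female", "race", "education", "nart_iq", "caloric_intake",
        "cortical_thickness", "brain_volume", "scrub_pct", "wmh", "fa",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack covariate columns {sorted(missing)}")
    unknown = set(records["race"]) - set(RACE_LEVELS)
    if unknown:
        raise ValueError(f"unknown race/ethnicity levels: {sorted(unknown)}")
    wmh = records["wmh"].to_numpy(dtype=float)
    if np.any(wmh < 0):
        raise ValueError("negative WMH volume")

    cols = {
        "age": records["age"].to_numpy(dtype=float),
        "female": records["female"].to_numpy(dtype=float),
        "race_black": (records["race"] == "non-Hispanic black").to_numpy(dtype=float),
        "race_other": (records["race"] == "other").to_numpy(dtype=float),
        "education": records["education"].to_numpy(dtype=float),
        "nart_iq": records["nart_iq"].to_numpy(dtype=float),
        "caloric_intake": records["caloric_intake"].to_numpy(dtype=float),
        "cortical_thickness": records["cortical_thickness"].to_numpy(dtype=float),
        "brain_volume": records["brain_volume"].to_numpy(dtype=float),
        "scrub_pct": records["scrub_pct"].to_numpy(dtype=float),
        "log_wmh": np.log(wmh + WMH_LOG_OFFSET),
        "fa": records["fa"].to_numpy(dtype=float),
    }
    out = pd.DataFrame(cols, index=records.index)
    values = out.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = out.columns[~np.isfinite(values).all(axis=0)].tolist()
        raise ValueError(f"non-finite covariate values in columns {bad}")
    return out[list(COVARIATE_COLUMNS)]


def sensitivity_filter(
    records: pd.DataFrame, scrub_cut: float = DEFAULT_SCRUB_CUT
) -> pd.DataFrame:
    """Drop records whose scrub percentage strictly exceeds the cut."""
    if "scrub_pct" not in records.columns:
        raise ValueError("records lack scrub_pct")
    return records[records["scrub_pct"].astype(float) <= scrub_cut].copy()


def assemble(
    participants: pd.DataFrame,
    medi_scores: pd.DataFrame | None = None,
    rsfc_summaries: pd.DataFrame | None = None,
    ra_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge stage outputs into one analytic table and apply the cascade.

    Each optional table is joined on ``participant_id``; participants absent
    from a table (or with NaN key values) have the corresponding missingness
    flag raised in addition to any flag already set on ``participants``.
    """
    df = participants.copy()
    for _, flag in CASCADE_STAGES:
        if flag not in df.columns:
            df[flag] = False

    def _merge(table: pd.DataFrame, flag: str, key_cols: list[str]) -> None:
        nonlocal df
        overlap = [c for c in table.columns if c in df.columns and c != "participant_id"]
        df = df.drop(columns=overlap).merge(table, on="participant_id", how="left")
        present = df[key_cols].notna().all(axis=1)
        df[flag] = df[flag].astype(bool) | ~present

    if medi_scores is not None:
        _merge(medi_scores, "diet_missing", ["medi_total", "medi_group"])
    if rsfc_summaries is not None:
        _merge(rsfc_summaries, "rsfc_missing", ["rsfc_overall"])
    if ra_scores is not None:
        _merge(ra_scores, "cognitive_missing", ["FLUID", "MEMORY", "VOCAB", "SPEED"])

    return exclusion_cascade(df)
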