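"""Publication-style tables, the moderation figure, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from dietconn.cohort import prepare_covariates  # noqa: E402
from dietconn.ffq import GROUP_LEVELS  # noqa: E402
from dietconn.models import (  # noqa: E402
    ModelResult,
    Z95,
    foodtype_interaction,
    group_descriptives,
    interaction_model,
    stratified_model,
)
from dietconn.rsfc import NETWORKS  # noqa: E402

DOMAINS = ("FLUID", "MEMORY", "VOCAB", "SPEED")


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Traceability record for one orchestrated run."""

    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    decisions: dict = field(default_factory=dict)

    def add_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages.append({"stage": name, "inputs": inputs, "outputs": outputs})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def interaction_table(analytic: pd.DataFrame, rsfc_col: str = "rsfc_overall") -> pd.DataFrame:
    """Interaction + stratified estimates for each ability outcome."""
    rows = []
    for outcome in DOMAINS:
        inter = interaction_model(analytic, rsfc_col, outcome)
        row = {
            "outcome": outcome,
            "joint_interaction_p": inter.joint["interaction"][2],
        }
        for level in ("moderate", "high"):
            t = inter.term(f"rsfc:medi[{level}]")
            row[f"{level}_vs_low_B"] = t.B
            row[f"{level}_vs_low_LL"] = t.LL
            row[f"{level}_vs_low_UL"] = t.UL
            row[f"{level}_vs_low_p"] = t.p
        for g in GROUP_LEVELS:
            t = stratified_model(analytic, rsfc_col, outcome, g).term("rsfc")
            row[f"stratified_{g}_B"] = t.B
            row[f"stratified_{g}_p"] = t.p
        rows.append(row)
    return pd.DataFrame(rows)


def network_table(analytic: pd.DataFrame, outcome: str = "FLUID") -> pd.DataFrame:
    """Per-network stratified slopes (overall row first)."""
    rows = []

    def _row(label: str, col: str) -> dict:
        row: dict = {"network": label}
        for g in GROUP_LEVELS:
            t = stratified_model(analytic, col, outcome, g).term("rsfc")
            row[f"{g}_B"] = t.B
            row[f"{g}_LL"] = t.LL
            row[f"{g}_UL"] = t.UL
            row[f"{g}_p"] = t.p
        return row

    rows.append(_row("All", "rsfc_overall"))
    for net in NETWORKS:
        col = f"rsfc_net_{net}"
        if col in analytic.columns:
            rows.append(_row(net, col))
    return pd.DataFrame(rows)


def foodtype_table(analytic: pd.DataFrame, outcome: str = "FLUID") -> pd.DataFrame:
    """Beneficial / detrimental subscore x connectivity interactions per network."""
    rows = []
    cols = [("All", "rsfc_overall")] + [
        (net, f"rsfc_net_{net}") for net in NETWORKS
        if f"rsfc_net_{net}" in analytic.columns
    ]
    for label, col in cols:
        row: dict = {"network": label}
        for subscore in ("beneficial", "detrimental"):
            t = foodtype_interaction(analytic, col, outcome, subscore).term(
                f"rsfc:{subscore}_sum")
            row[f"{subscore}_B"] = t.B
            row[f"{subscore}_LL"] = t.LL
            row[f"{subscore}_UL"] = t.UL
            row[f"{subscore}_p"] = t.p
        rows.append(row)
    return pd.DataFrame(rows)


def moderation_figure(
    analytic: pd.DataFrame,
    path: str | Path,
    rsfc_col: str = "rsfc_overall",
    outcome: str = "FLUID",
) -> None:
    """Predicted outcome vs connectivity per diet group with 95% bands.

    Predictions hold every covariate at its sample mean and trace the fitted
    interaction model over the observed connectivity range.
    """
    res = interaction_model(analytic, rsfc_col, outcome)
    cov_means = prepare_covariates(analytic).mean().to_numpy()
    grid = np.linspace(analytic[rsfc_col].min(), analytic[rsfc_col].max(), 50)
    beta = np.array([t.B for t in res.terms])

    fig, ax = plt.subplots(figsize=(6, 4))
    for g in GROUP_LEVELS:
        d_mod = 1.0 if g == "moderate" else 0.0
        d_high = 1.0 if g == "high" else 0.0
        rows = np.column_stack([
            np.ones_like(grid), grid,
            np.full_like(grid, d_mod), np.full_like(grid, d_high),
            grid * d_mod, grid * d_high,
            np.tile(cov_means, (grid.size, 1)),
        ])
        pred = rows @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", rows, res.cov, rows))
        ax.plot(grid, pred, label=f"{g} adherence")
        ax.fill_between(grid, pred - Z95 * se, pred + Z95 * se, alpha=0.2)
    ax.set_xlabel("overall internetwork connectivity (z)")
    ax.set_ylabel(f"predicted {outcome}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def models_long_table(results: list[ModelResult]) -> pd.DataFrame:
    frames = [r.to_frame() for r in results]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["label", "outcome", "term", "role", "B", "LL", "UL", "p", "n"])


def render_tables(analytic: pd.DataFrame, outdir: str | Path) -> dict[str, str]:
    """Write the four analysis tables and the moderation figure."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    tables = {
        "table1.csv": group_descriptives(analytic),
        "table2.csv": interaction_table(analytic),
        "table3.csv": network_table(analytic),
        "table4.csv": foodtype_table(analytic),
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written[name] = str(path)
    fig_path = out / "figure1.png"
    moderation_figure(analytic, fig_path)
    written["figure1.png"] = str(fig_path)
    return written
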