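"""Synthetic cohort generator with planted, recoverable ground truth.

Generates every input the analysis stages consume — demographics and
covariates, a long-format food-frequency table, per-participant ROI time
series (or, in fast mode, the connectivity scalar directly), in-scanner
task scores, and sequential disjoint missingness flags — under known
parameters stored in a :class:`GroundTruth` record.

Ability scores follow

    RA = alpha_g + B_g * z + gamma' (covariates - mean) + eps,

where ``z`` is the participant's true cross-network connectivity (Fisher-z
scale), ``g`` the diet-adherence tertile, and ``eps ~ N(0, noise_sd^2)``.
Effect presets plant the slope patterns used by the recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from dietconn.cognition import TASK_BATTERY
from dietconn.ffq import ALL_CATEGORIES, GROUP_LEVELS, assign_tertiles
from dietconn.rsfc import EXCLUDED_LABEL, NETWORKS

#: ROIs per network; the excluded remainder pads the parcellation to 264.
DEFAULT_PARCELLATION_SPEC: dict[str, int] = {
    "Hand": 30, "Vis": 31, "Mouth": 5, "Aud": 13, "DMN": 58,
    "Sal": 18, "CO": 14, "FP": 25, "DAN": 11, "VAN": 9,
    EXCLUDED_LABEL: 50,
}

#: Slope of each ability on connectivity by diet group (low, moderate, high).
#: "tab2-stratified" plants the stratified estimates; "tab2-interaction"
#: plants the low-group slope plus the printed interaction deltas (the two
#: published sets are not mutually consistent, hence two presets).
EFFECT_PRESETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "tab2-stratified": {"slopes": (-5.354, -0.605, 0.177)},
    "tab2-interaction": {"slopes": (-5.354, -5.354 + 5.620, -5.354 + 4.779)},
    "null": {"slopes": (-2.0, -2.0, -2.0)},
}

#: Default mean/SD (or probabilities) for covariate draws.
COVARIATE_DEFAULTS: dict[str, tuple[float, float]] = {
    "age": (54.10, 15.98),
    "education": (16.14, 2.26),
    "nart_iq": (117.28, 8.10),
    "caloric_intake": (1800.0, 500.0),
    "cortical_thickness": (2.55, 0.12),
    "brain_volume": (0.0, 50000.0),
    "fa": (0.443, 0.021),
}
FEMALE_PROB = 0.53
RACE_PROBS = (0.662, 0.224, 0.114)  # white, black, other
RACE_LEVELS = ("non-Hispanic white", "non-Hispanic black", "other")

#: Covariate effects on every ability (applied to centered covariates).
DEFAULT_GAMMA: dict[str, float] = {"age": -0.012, "education": 0.03, "nart_iq": 0.01}

#: Slope shared by all groups for the non-targeted abilities.
OTHER_RA_SLOPE = -1.0

FFQ_BAND_EDGES = (0.0, 1.0, 5.0, 13.0, 31.0, 61.0, 100.0)


@dataclass
class SimulationConfig:
    n_enrolled: int = 425
    n_frames: int = 285            # scan duration is a study knob; assumed
    tr: float = 2.0                # repetition time unreported; assumed 2 s
    parcellation_spec: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARCELLATION_SPEC))
    rho_within: float = 0.45
    rsfc_mean: float = 0.25        # Fisher-z scale
    rsfc_sd: float = 0.045
    effect_preset: str = "tab2-stratified"
    intercepts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    covariate_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COVARIATE_DEFAULTS))
    gamma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    noise_sd: float = 0.3
    network_jitter_sd: float = 0.01  # spread of per-network / pairwise z around overall
    task_noise_sd: float = 0.3
    missingness_counts: tuple[int, int, int, int] = (108, 22, 87, 7)
    motion_trans_sd: float = 0.01
    motion_rot_sd: float = 1e-4
    spike_frames: tuple[int, ...] = ()
    spike_rate: float = 0.02       # expected fraction of random spike frames
    spike_mm: float = 1.0
    nuisance_loading: float = 0.0
    seed: int = 0
    fast: bool = True

    def __post_init__(self) -> None:
        if self.n_enrolled <= 0 or self.n_frames <= 0 or self.tr <= 0:
            raise ValueError("counts and tr must be positive")
        if any(c < 0 for c in self.missingness_counts):
            raise ValueError("missingness counts must be non-negative")
        if sum(self.missingness_counts) >= self.n_enrolled:
            raise ValueError("missingness counts must sum to < n_enrolled")
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if not -1 < np.tanh(self.rsfc_mean) < 1:
            raise ValueError("rsfc_mean out of range")
        if self.effect_preset not in EFFECT_PRESETS:
            raise ValueError(
                f"unknown effect preset {self.effect_preset!r}; "
                f"known: {sorted(EFFECT_PRESETS)}"
            )
        if any(v <= 0 for v in self.parcellation_spec.values()):
            raise ValueError("parcellation counts must be positive")

    @property
    def slopes(self) -> tuple[float, float, float]:
        return EFFECT_PRESETS[self.effect_preset]["slopes"]


@dataclass
class GroundTruth:
    """Planted parameters stored beside every generated cohort."""

    seed: int
    effect_preset: str
    slopes: dict[str, float]
    intercepts: dict[str, float]
    gamma: dict[str, float]
    noise_sd: float
    true_z: list[float]
    group: list[str]
    missing_ids: dict[str, list[int]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        data["missing_ids"] = {k: list(v) for k, v in data["missing_ids"].items()}
        return cls(**data)


@dataclass
class Cohort:
    participants: pd.DataFrame
    ffq: pd.DataFrame
    tasks: pd.DataFrame
    ra: pd.DataFrame
    rsfc: pd.DataFrame | None
    parcellation: pd.DataFrame | None
    timeseries: dict[int, np.ndarray]
    motion: dict[int, np.ndarray]
    nuisance: dict[int, np.ndarray]
    ground_truth: GroundTruth


def build_parcellation(spec: dict[str, int] | None = None) -> pd.DataFrame:
    """Deterministic grid parcellation: centers 25 mm apart, labeled by network."""
    spec = spec or dict(DEFAULT_PARCELLATION_SPEC)
    n_total = sum(spec.values())
    side = int(np.ceil(n_total ** (1 / 3)))
    coords = [(25.0 * x, 25.0 * y, 25.0 * z)
              for x, y, z in product(range(side), repeat=3)][:n_total]
    labels = [net for net, count in spec.items() for _ in range(count)]
    return pd.DataFrame(
        {
            "roi_id": np.arange(n_total),
            "x_mm": [c[0] for c in coords],
            "y_mm": [c[1] for c in coords],
            "z_mm": [c[2] for c in coords],
            "network": labels,
        }
    )


def block_correlation(
    labels: np.ndarray, rho_within: float, rho_cross: float
) -> np.ndarray:
    """Block correlation matrix: ``rho_within`` inside a network label,
    ``rho_cross`` between labels, unit diagonal.  Raises if not PSD."""
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, rho_within, rho_cross)
    np.fill_diagonal(sigma, 1.0)
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin < -1e-8:
        raise ValueError(
            f"requested correlation structure is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return sigma


def generate_roi_timeseries(
    true_z: float,
    parcellation: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One participant's frames x ROIs draw plus motion and nuisance traces.

    The signal is multivariate normal under the block correlation implied by
    ``tanh(true_z)`` between networks and ``rho_within`` inside them.
    Motion is a small random walk with optional spike frames; the three
    nuisance traces (left/right white matter, ventricles) are noise with a
    configurable loading on the global mean signal.
    """
    labels = parcellation["network"].to_numpy()
    sigma = block_correlation(labels, config.rho_within, float(np.tanh(true_z)))
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(len(sigma)))
    ts = rng.standard_normal((config.n_frames, len(sigma))) @ chol.T

    motion = np.cumsum(
        np.column_stack([
            rng.normal(0.0, config.motion_trans_sd, (config.n_frames, 3)),
            rng.normal(0.0, config.motion_rot_sd, (config.n_frames, 3)),
        ]),
        axis=0,
    )
    spikes = np.zeros(config.n_frames, dtype=bool)
    if config.spike_rate > 0:
        spikes = rng.random(config.n_frames) < config.spike_rate
    spikes[list(config.spike_frames)] = True
    motion[spikes, 0] += config.spike_mm

    global_mean = ts.mean(axis=1)
    nuis = (
        config.nuisance_loading * global_mean[:, None]
        + rng.standard_normal((config.n_frames, 3))
    )
    return ts, motion, nuis


def _draw_covariates(rng: np.random.Generator, n: int,
                     params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    for name, (mean, sd) in params.items():
        df[name] = rng.normal(mean, sd, n)
    df["age"] = np.clip(df["age"], 20.0, 80.0)
    df["female"] = (rng.random(n) < FEMALE_PROB).astype(int)
    df["race"] = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    df["wmh"] = rng.lognormal(6.0, 1.2, n)
    df["scrub_pct"] = np.clip(rng.gamma(1.2, 5.0, n), 0.0, 60.0)
    return df


def _draw_ffq(rng: np.random.Generator, n: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Long FFQ table plus the underlying 0-5 levels (participants x 11)."""
    k = len(ALL_CATEGORIES)
    levels = rng.integers(0, 6, size=(n, k))
    edges = np.asarray(FFQ_BAND_EDGES)
    lo, hi = edges[levels], edges[levels + 1]
    servings = lo + rng.random((n, k)) * (hi - lo) * 0.999
    ffq = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(1, n + 1), k),
            "category": np.tile(np.asarray(ALL_CATEGORIES, dtype=object), n),
            "servings_per_month": servings.ravel(),
        }
    )
    return ffq, levels


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full set of study inputs plus their ground truth.

    In fast mode the per-participant connectivity scalar is drawn directly
    from ``N(rsfc_mean, rsfc_sd)`` and no time series are produced; the full
    mode additionally draws frames x ROIs series whose planted block
    correlation the processing pipeline can recover.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    n = config.n_enrolled
    ids = np.arange(1, n + 1)

    participants = _draw_covariates(rng, n, config.covariate_params)
    ffq, levels = _draw_ffq(rng, n)

    beneficial = levels[:, :7].sum(axis=1)
    avoidance = (5 - levels[:, 7:]).sum(axis=1)
    totals = beneficial + avoidance
    group = assign_tertiles(totals)

    true_z = rng.normal(config.rsfc_mean, config.rsfc_sd, n)
    slopes = dict(zip(GROUP_LEVELS, config.slopes))
    intercepts = dict(zip(GROUP_LEVELS, config.intercepts))
    b = np.array([slopes[g] for g in group])
    a = np.array([intercepts[g] for g in group])

    lin = np.zeros(n)
    for cov_name, coef in config.gamma.items():
        x = participants[cov_name].to_numpy(dtype=float)
        lin += coef * (x - x.mean())

    ra_cols: dict[str, np.ndarray] = {"participant_id": ids}
    ra_cols["FLUID"] = a + b * true_z + lin + rng.normal(0.0, config.noise_sd, n)
    for other in ("MEMORY", "VOCAB", "SPEED"):
        ra_cols[other] = (
            OTHER_RA_SLOPE * true_z + lin + rng.normal(0.0, config.noise_sd, n)
        )
    ra = pd.DataFrame(ra_cols)

    task_cols: dict[str, np.ndarray] = {"participant_id": ids}
    for domain, names in TASK_BATTERY.items():
        for t in names:
            task_cols[t] = 50.0 + 10.0 * (
                ra_cols[domain] + rng.normal(0.0, config.task_noise_sd, n)
            )
    tasks = pd.DataFrame(task_cols)

    # sequential, disjoint missingness in cascade order
    counts = config.missingness_counts
    bounds = np.cumsum((0,) + tuple(counts))
    stages = ("diet", "rsfc", "structural", "cognitive")
    missing_ids: dict[str, list[int]] = {}
    for i, stage in enumerate(stages):
        stage_ids = ids[bounds[i]: bounds[i + 1]]
        missing_ids[stage] = stage_ids.tolist()
        participants[f"{stage}_missing"] = np.isin(ids, stage_ids)

    truth = GroundTruth(
        seed=config.seed,
        effect_preset=config.effect_preset,
        slopes={g: float(v) for g, v in slopes.items()},
        intercepts={g: float(v) for g, v in intercepts.items()},
        gamma={k: float(v) for k, v in config.gamma.items()},
        noise_sd=config.noise_sd,
        true_z=[float(v) for v in true_z],
        group=[str(g) for g in group],
        missing_ids=missing_ids,
    )

    rsfc_df: pd.DataFrame | None = None
    parcellation: pd.DataFrame | None = None
    timeseries: dict[int, np.ndarray] = {}
    motion: dict[int, np.ndarray] = {}
    nuisance: dict[int, np.ndarray] = {}

    if config.fast:
        rsfc_cols: dict[str, np.ndarray] = {
            "participant_id": ids, "rsfc_overall": true_z,
        }
        for net in NETWORKS:
            rsfc_cols[f"rsfc_net_{net}"] = true_z + rng.normal(
                0.0, config.network_jitter_sd, n)
        for a_, b_ in combinations(sorted(NETWORKS), 2):
            rsfc_cols[f"rsfc_pair_{a_}_{b_}"] = true_z + rng.normal(
                0.0, config.network_jitter_sd, n)
        rsfc_df = pd.DataFrame(rsfc_cols)
    else:
        parcellation = build_parcellation(config.parcellation_spec)
        for pid, child in zip(ids, ss.spawn(n)):
            prng = np.random.default_rng(child)
            ts, mot, nuis = generate_roi_timeseries(
                true_z[pid - 1], parcellation, config, prng)
            timeseries[int(pid)] = ts
            motion[int(pid)] = mot
            nuisance[int(pid)] = nuis

    return Cohort(
        participants=participants, ffq=ffq, tasks=tasks, ra=ra, rsfc=rsfc_df,
        parcellation=parcellation, timeseries=timeseries, motion=motion,
        nuisance=nuisance, ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# file round-trip

_FLOAT_FMT = "%.8g"


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write all cohort tables as plain text; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written[name] = str(path)

    _csv(cohort.participants, "participants.csv")
    _csv(cohort.ffq, "ffq.csv")
    _csv(cohort.tasks, "tasks.csv")
    _csv(cohort.ra, "ra_scores.csv")
    if cohort.rsfc is not None:
        _csv(cohort.rsfc, "rsfc_summaries.csv")
    if cohort.parcellation is not None:
        path = out / "parcellation.tsv"
        cohort.parcellation.to_csv(path, sep="\t", index=False,
                                   float_format=_FLOAT_FMT)
        written["parcellation.tsv"] = str(path)
    for name, data in (("timeseries", cohort.timeseries),
                       ("motion", cohort.motion),
                       ("nuisance", cohort.nuisance)):
        if data:
            sub = out / name
            sub.mkdir(exist_ok=True)
            for pid, arr in data.items():
                np.savetxt(sub / f"{pid}.tsv", arr, delimiter="\t", fmt=_FLOAT_FMT)
            written[name] = str(sub)
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    written["ground_truth.json"] = str(out / "ground_truth.json")
    return written


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
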