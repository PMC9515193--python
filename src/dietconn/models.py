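"""OLS model family for the diet x connectivity moderation analysis.

All models are ordinary least squares with the full covariate block from
:mod:`dietconn.cohort`.  Confidence intervals are Wald intervals on the
normal approximation (B +- 1.96 SE) with a switch for t-based intervals;
joint tests of several coefficients are Wald chi-square tests.  Two-sided
p < 0.05 marks significance for main effects and p < 0.10 for interaction
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from dietconn.cohort import COVARIATE_COLUMNS, prepare_covariates
from dietconn.ffq import GROUP_LEVELS
from dietconn.rsfc import NETWORKS

Z95 = float(stats.norm.ppf(0.975))
ALPHA_MAIN = 0.05
ALPHA_INTERACTION = 0.10


@dataclass
class TermResult:
    name: str
    role: str  # intercept | covariate | rsfc_main | group_dummy | interaction | threeway
    B: float
    se: float
    LL: float
    UL: float
    p: float


@dataclass
class ModelResult:
    """One fitted model: coefficient table plus joint Wald tests."""

    outcome: str
    label: str
    n: int
    terms: list[TermResult]
    joint: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    rss: float = float("nan")
    fitted: np.ndarray | None = None
    cov: np.ndarray | None = None

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": self.label,
                "outcome": self.outcome,
                "term": t.name,
                "role": t.role,
                "B": t.B,
                "LL": t.LL,
                "UL": t.UL,
                "p": t.p,
                "n": self.n,
            }
            for t in self.terms
        ]
        for name, (stat, df, p) in self.joint.items():
            rows.append(
                {
                    "label": self.label,
                    "outcome": self.outcome,
                    "term": f"joint:{name}",
                    "role": "joint_test",
                    "B": stat,
                    "LL": float("nan"),
                    "UL": float("nan"),
                    "p": p,
                    "n": self.n,
                }
            )
        return pd.DataFrame(rows)


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    roles: list[str] | None = None,
    use_t: bool = False,
    outcome: str = "y",
    label: str = "ols",
) -> ModelResult:
    """Least-squares fit with Wald inference.

    ``X`` must already contain the intercept column.  SEs come from the
    unbiased residual variance; with ``use_t`` the CI critical value and
    p-values switch from the normal to the t(n-p) distribution.  A perfect
    (zero-residual) fit yields zero-width intervals, p = 0 for nonzero
    coefficients and p = 1 otherwise.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(names) != p:
        raise ValueError("one name per design column required")
    if n <= p:
        raise ValueError(f"n={n} too small for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    roles = roles or ["covariate"] * p

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))

    if use_t:
        crit = float(stats.t.ppf(0.975, dof))
        pval = lambda t: 2.0 * float(stats.t.sf(abs(t), dof))  # noqa: E731
    else:
        crit = Z95
        pval = lambda t: 2.0 * float(stats.norm.sf(abs(t)))  # noqa: E731

    scale = max(1.0, float(np.max(np.abs(beta))))
    terms = []
    for j in range(p):
        if se[j] > 0:
            stat = beta[j] / se[j]
            pj = pval(stat)
        else:  # perfect fit
            pj = 1.0 if abs(beta[j]) < 1e-12 * scale else 0.0
        terms.append(
            TermResult(
                name=names[j],
                role=roles[j],
                B=float(beta[j]),
                se=float(se[j]),
                LL=float(beta[j] - crit * se[j]),
                UL=float(beta[j] + crit * se[j]),
                p=pj,
            )
        )
    return ModelResult(
        outcome=outcome, label=label, n=n, terms=terms, rss=rss,
        fitted=X @ beta, cov=cov,
    )


def joint_wald(result: ModelResult, term_names: list[str]) -> tuple[float, int, float]:
    """Wald chi-square test that the named coefficients are jointly zero."""
    if result.cov is None:
        raise ValueError("model result lacks a covariance matrix")
    index = {t.name: j for j, t in enumerate(result.terms)}
    idx = [index[name] for name in term_names]
    b = np.array([result.terms[j].B for j in idx])
    sub = result.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(sub, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# design helpers

def _group_dummies(groups: pd.Series, reference: str = "low") -> tuple[np.ndarray, list[str]]:
    levels = [g for g in GROUP_LEVELS if g != reference]
    seen = set(groups)
    if not seen.issubset(set(GROUP_LEVELS)):
        raise ValueError(f"unknown group labels: {sorted(seen - set(GROUP_LEVELS))}")
    for level in GROUP_LEVELS:
        if level not in seen:
            raise ValueError(f"group {level!r} is empty")
    cols = np.column_stack([(groups == g).to_numpy(dtype=float) for g in levels])
    return cols, [f"medi[{g}]" for g in levels]


def _covariate_block(df: pd.DataFrame, drop: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    cov = prepare_covariates(df)
    names = [c for c in COVARIATE_COLUMNS if c not in drop]
    return cov[names].to_numpy(dtype=float), names


def _assemble(parts: list[tuple[np.ndarray, list[str], str]]):
    cols, names, roles = [], [], []
    for block, block_names, role in parts:
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] == 1 and len(block_names) == 1:
            block = block.T
        cols.append(block)
        names.extend(block_names)
        roles.extend([role] * len(block_names))
    return np.column_stack(cols), names, roles


# ---------------------------------------------------------------------------
# the model family

def medi_main_effect_on_rsfc(
    df: pd.DataFrame, rsfc_col: str = "rsfc_overall",
    reference: str = "low", use_t: bool = False,
) -> ModelResult:
    """Regress a connectivity summary on diet group plus covariates.

    Reports the two group-dummy estimates (low reference) and their 2-df
    joint Wald test (``joint['group']``).
    """
    n = len(df)
    dummies, dummy_names = _group_dummies(df["medi_group"], reference)
    cov, cov_names = _covariate_block(df)
    X, names, roles = _assemble([
        (np.ones((n, 1)), ["const"], "intercept"),
        (dummies, dummy_names, "group_dummy"),
        (cov, cov_names, "covariate"),
    ])
    res = fit_ols(df[rsfc_col].to_numpy(dtype=float), X, names, roles,
                  use_t=use_t, outcome=rsfc_col, label="medi_main")
    res.joint["group"] = joint_wald(res, dummy_names)
    return res


def interaction_model(
    df: pd.DataFrame, rsfc_col: str = "rsfc_overall", outcome: str = "FLUID",
    reference: str = "low", use_t: bool = False, label: str | None = None,
) -> ModelResult:
    """Group x connectivity moderation model for one ability outcome.

    Design: intercept + connectivity + two group dummies + the two
    group x connectivity products + covariates.  ``joint['interaction']``
    is the 2-df Wald test of both product terms.
    """
    n = len(df)
    rsfc = df[rsfc_col].to_numpy(dtype=float)
    dummies, dummy_names = _group_dummies(df["medi_group"], reference)
    cov, cov_names = _covariate_block(df)
    inter = dummies * rsfc[:, None]
    inter_names = [f"rsfc:{d}" for d in dummy_names]
    X, names, roles = _assemble([
        (np.ones((n, 1)), ["const"], "intercept"),
        (rsfc, ["rsfc"], "rsfc_main"),
        (dummies, dummy_names, "group_dummy"),
        (inter, inter_names, "interaction"),
        (cov, cov_names, "covariate"),
    ])
    res = fit_ols(df[outcome].to_numpy(dtype=float), X, names, roles,
                  use_t=use_t, outcome=outcome,
                  label=label or f"interaction:{rsfc_col}")
    res.joint["interaction"] = joint_wald(res, inter_names)
    return res


def stratified_model(
    df: pd.DataFrame, rsfc_col: str, outcome: str, group: str,
    use_t: bool = False,
) -> ModelResult:
    """Within-group connectivity slope on one ability outcome."""
    sub = df[df["medi_group"] == group]
    n = len(sub)
    cov, cov_names = _covariate_block(sub)
    # indicators with no variation in the stratum are inestimable; drop them
    varying = cov.std(axis=0) > 0
    cov = cov[:, varying]
    cov_names = [name for name, keep in zip(cov_names, varying) if keep]
    if n <= len(cov_names) + 2:
        raise ValueError(f"group {group!r} subsample (n={n}) too small")
    X, names, roles = _assemble([
        (np.ones((n, 1)), ["const"], "intercept"),
        (sub[rsfc_col].to_numpy(dtype=float), ["rsfc"], "rsfc_main"),
        (cov, cov_names, "covariate"),
    ])
    return fit_ols(sub[outcome].to_numpy(dtype=float), X, names, roles,
                   use_t=use_t, outcome=outcome,
                   label=f"stratified:{group}:{rsfc_col}")


def network_level_scan(
    df: pd.DataFrame, outcome: str = "FLUID", use_t: bool = False,
) -> dict[str, dict]:
    """Interaction + stratified fits per single-network connectivity column.

    No multiplicity correction is applied (10 comparisons; the report prints
    the count).
    """
    out: dict[str, dict] = {}
    for net in NETWORKS:
        col = f"rsfc_net_{net}"
        if col not in df.columns:
            continue
        entry = {"interaction": interaction_model(df, col, outcome, use_t=use_t)}
        entry["stratified"] = {
            g: stratified_model(df, col, outcome, g, use_t=use_t)
            for g in GROUP_LEVELS
        }
        out[net] = entry
    return out


def pairwise_scan(
    df: pd.DataFrame, outcome: str = "FLUID", use_t: bool = False,
) -> tuple[dict[tuple[str, str], ModelResult], dict[str, int]]:
    """Interaction model per unordered network-pair connectivity column.

    Returns the fits plus a sign summary counting positive vs total
    interaction estimates across the scan (45 uncorrected comparisons).
    """
    fits: dict[tuple[str, str], ModelResult] = {}
    n_pos = n_total = 0
    for a, b in combinations(sorted(NETWORKS), 2):
        col = f"rsfc_pair_{a}_{b}"
        if col not in df.columns:
            continue
        res = interaction_model(df, col, outcome, use_t=use_t)
        fits[(a, b)] = res
        for t in res.terms:
            if t.role == "interaction":
                n_total += 1
                n_pos += t.B > 0
    return fits, {"positive_interactions": n_pos, "total_interactions": n_total}


def foodtype_interaction(
    df: pd.DataFrame, rsfc_col: str, outcome: str, subscore: str,
    use_t: bool = False,
) -> ModelResult:
    """Continuous food-subscore x connectivity interaction model.

    ``subscore`` is ``"beneficial"`` or ``"detrimental"`` and refers to the
    ``beneficial_sum`` / ``detrimental_sum`` columns.
    """
    if subscore not in ("beneficial", "detrimental"):
        raise ValueError("subscore must be 'beneficial' or 'detrimental'")
    col = f"{subscore}_sum"
    n = len(df)
    rsfc = df[rsfc_col].to_numpy(dtype=float)
    s = df[col].to_numpy(dtype=float)
    cov, cov_names = _covariate_block(df)
    X, names, roles = _assemble([
        (np.ones((n, 1)), ["const"], "intercept"),
        (rsfc, ["rsfc"], "rsfc_main"),
        (s, [col], "covariate"),
        (rsfc * s, [f"rsfc:{col}"], "interaction"),
        (cov, cov_names, "covariate"),
    ])
    return fit_ols(df[outcome].to_numpy(dtype=float), X, names, roles,
                   use_t=use_t, outcome=outcome,
                   label=f"foodtype:{subscore}:{rsfc_col}")


def threeway_interaction(
    df: pd.DataFrame, rsfc_col: str, outcome: str, modifier: str,
    use_t: bool = False,
) -> ModelResult:
    """Modifier x group x connectivity model with all lower-order terms.

    ``modifier`` is ``"age"`` or ``"gender"`` (the female indicator).  The
    modifier is removed from the covariate block to avoid duplication.
    ``joint['threeway']`` is the 2-df Wald test of the two three-way terms.
    """
    if modifier not in ("age", "gender"):
        raise ValueError("modifier must be 'age' or 'gender'")
    mod_col = "age" if modifier == "age" else "female"
    n = len(df)
    m = df[mod_col].to_numpy(dtype=float)
    rsfc = df[rsfc_col].to_numpy(dtype=float)
    dummies, dummy_names = _group_dummies(df["medi_group"])
    cov, cov_names = _covariate_block(df, drop=(mod_col,))
    inter = dummies * rsfc[:, None]
    three = inter * m[:, None]
    three_names = [f"{mod_col}:rsfc:{d}" for d in dummy_names]
    X, names, roles = _assemble([
        (np.ones((n, 1)), ["const"], "intercept"),
        (rsfc, ["rsfc"], "rsfc_main"),
        (dummies, dummy_names, "group_dummy"),
        (m, [mod_col], "covariate"),
        (inter, [f"rsfc:{d}" for d in dummy_names], "interaction"),
        (dummies * m[:, None], [f"{mod_col}:{d}" for d in dummy_names], "interaction"),
        (m * rsfc, [f"{mod_col}:rsfc"], "interaction"),
        (three, three_names, "threeway"),
        (cov, cov_names, "covariate"),
    ])
    res = fit_ols(df[outcome].to_numpy(dtype=float), X, names, roles,
                  use_t=use_t, outcome=outcome,
                  label=f"threeway:{modifier}:{rsfc_col}")
    res.joint["threeway"] = joint_wald(res, three_names)
    return res


# ---------------------------------------------------------------------------
# descriptives

DESCRIPTIVE_CONTINUOUS: tuple[str, ...] = (
    "age", "education", "nart_iq", "cortical_thickness", "brain_volume",
    "wmh", "fa", "scrub_pct", "rsfc_overall",
    "FLUID", "MEMORY", "VOCAB", "SPEED",
)
DESCRIPTIVE_CATEGORICAL: tuple[str, ...] = ("female", "race")


def group_descriptives(
    df: pd.DataFrame,
    continuous: tuple[str, ...] = DESCRIPTIVE_CONTINUOUS,
    categorical: tuple[str, ...] = DESCRIPTIVE_CATEGORICAL,
) -> pd.DataFrame:
    """Per-group means/SDs with one-way ANOVA, and chi-square for categoricals."""
    groups = [df[df["medi_group"] == g] for g in GROUP_LEVELS]
    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        samples = [g[var].to_numpy(dtype=float) for g in groups]
        stat, p = stats.f_oneway(*samples)
        row = {"variable": var, "kind": "continuous", "stat": float(stat),
               "p": float(p)}
        for gname, s in zip(GROUP_LEVELS, samples):
            row[f"{gname}_mean"] = float(np.mean(s))
            row[f"{gname}_sd"] = float(np.std(s, ddof=1))
        rows.append(row)
    for var in categorical:
        if var not in df.columns:
            continue
        table = pd.crosstab(df[var], df["medi_group"])
        table = table[[g for g in GROUP_LEVELS if g in table.columns]]
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        row = {"variable": var, "kind": "categorical", "stat": float(stat),
               "p": float(p)}
        for gname in GROUP_LEVELS:
            if gname in table.columns:
                col = table[gname]
                row[f"{gname}_mean"] = float(
                    100.0 * col.iloc[-1] / col.sum()
                )  # % in top level
                row[f"{gname}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)
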