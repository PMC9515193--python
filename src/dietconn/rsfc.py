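"""ROI time-series processing and internetwork connectivity summaries.

Stages, applied in this order (order is logged by the orchestrator):

1. framewise displacement from 6 rigid-body motion parameters,
2. replacement of high-motion frames by interpolation (scrubbing),
3. zero-phase band-pass filtering (default 0.01-0.08 Hz),
4. least-squares removal of nuisance traces (identically filtered),
5. pairwise Pearson correlation -> Fisher z matrix with exclusion mask
   (self pairs, centers closer than 20 mm, non-positive values),
6. means of retained cross-network entries: one overall value, one per
   network, and one per unordered network pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import squareform, pdist

NETWORKS: tuple[str, ...] = (
    "Hand", "Vis", "Mouth", "Aud", "DMN", "Sal", "CO", "FP", "DAN", "VAN",
)
EXCLUDED_LABEL = "excluded"

DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_MIN_DISTANCE_MM = 20.0
DEFAULT_BAND_HZ = (0.01, 0.08)
SPHERE_RADIUS_MM = 50.0


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix plus exclusion bookkeeping.

    ``excluded`` marks entries that never enter a mean: the diagonal and
    pairs of ROIs with centers closer than the distance cutoff.  Entries
    with ``z <= 0`` are stored but additionally dropped from averages
    (``nonpositive`` mask).
    """

    z: np.ndarray
    excluded: np.ndarray
    nonpositive: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        """Entries eligible for averaging: not excluded and strictly positive."""
        return ~self.excluded & ~self.nonpositive


@dataclass
class InternetworkSummary:
    overall_z: float
    per_network_z: dict[str, float]
    pairwise_z: dict[tuple[str, str], float]


def validate_parcellation(parcellation: pd.DataFrame) -> pd.DataFrame:
    required = {"roi_id", "x_mm", "y_mm", "z_mm", "network"}
    if not required.issubset(parcellation.columns):
        raise ValueError(f"parcellation needs columns {sorted(required)}")
    if parcellation["roi_id"].duplicated().any():
        raise ValueError("duplicate ROI ids in parcellation")
    coords = parcellation[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite ROI coordinates")
    return parcellation


def framewise_displacement(
    motion: np.ndarray, sphere_radius_mm: float = SPHERE_RADIUS_MM
) -> np.ndarray:
    """Per-frame head-motion magnitude.

    ``motion`` is frames x 6: three translations (mm) then three rotations
    (radians).  Rotations are converted to arc length on a sphere of the
    given radius.  The first frame has no predecessor and gets 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be frames x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_and_replace(
    ts: np.ndarray,
    fd: np.ndarray,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
) -> tuple[np.ndarray, float]:
    """Replace frames with ``fd > threshold`` by interpolation.

    Contaminated frames are rebuilt by linear interpolation between the
    nearest clean neighbours; contaminated runs touching an edge take the
    nearest clean value.  Returns the repaired series and the percentage of
    frames replaced.  Frame count is unchanged.
    """
    if not fd_threshold_mm > 0:
        raise ValueError("fd threshold must be > 0")
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise ValueError("fd trace length must match frame count")
    bad = fd > fd_threshold_mm
    n = ts.shape[0]
    if bad.all():
        raise ValueError("all frames exceed the motion threshold")
    if not bad.any():
        return ts.copy(), 0.0
    good_idx = np.flatnonzero(~bad)
    bad_idx = np.flatnonzero(bad)
    out = ts.copy()
    for col in range(ts.shape[1]):
        out[bad_idx, col] = np.interp(bad_idx, good_idx, ts[good_idx, col])
    return out, 100.0 * bad_idx.size / n


def bandpass(
    ts: np.ndarray,
    tr: float,
    f_low: float = DEFAULT_BAND_HZ[0],
    f_high: float = DEFAULT_BAND_HZ[1],
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the frame axis, then demean."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    nyquist = 0.5 / tr
    if not (0 < f_low < f_high < nyquist):
        raise ValueError(
            f"band ({f_low}, {f_high}) Hz invalid for tr={tr}s (Nyquist {nyquist} Hz)"
        )
    sos = signal.butter(order, [f_low, f_high], btype="bandpass",
                        fs=1.0 / tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts, axis=0)
    return filtered - filtered.mean(axis=0, keepdims=True)


def nuisance_regress(ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualize each ROI column against the nuisance traces.

    An intercept is always included.  Raises if the augmented nuisance
    matrix is rank deficient (collinear traces).
    """
    ts = np.asarray(ts, dtype=float)
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != ts.shape[0]:
        raise ValueError("nuisance rows must match frame count")
    X = np.column_stack([np.ones(ts.shape[0]), nuisance])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance set (collinear traces)")
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def rms_signal_change(ts: np.ndarray) -> np.ndarray:
    """Root-mean-square frame-to-frame signal change (0 at the first frame)."""
    ts = np.asarray(ts, dtype=float)
    d = np.sqrt(np.mean(np.diff(ts, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], d])


def connectivity_matrix(
    ts: np.ndarray,
    parcellation: pd.DataFrame,
    min_distance_mm: float = DEFAULT_MIN_DISTANCE_MM,
) -> ConnectivityMatrix:
    """Fisher-z connectivity with self / short-distance / sign exclusions.

    Pearson correlations are clipped to +-(1 - 1e-7) before atanh.  Pairs of
    ROIs with centers strictly closer than ``min_distance_mm`` are excluded,
    as is the diagonal.  Entries with z <= 0 stay in the matrix but are
    flagged out of every mean.
    """
    ts = np.asarray(ts, dtype=float)
    parcellation = validate_parcellation(parcellation)
    if ts.shape[0] < 10:
        raise ValueError("need at least 10 frames for a correlation matrix")
    if ts.shape[1] != len(parcellation):
        raise ValueError(
            f"time series has {ts.shape[1]} ROIs but parcellation lists "
            f"{len(parcellation)}"
        )
    sd = ts.std(axis=0)
    if np.any(sd <= 1e-13 * (np.abs(ts.mean(axis=0)) + 1.0)):
        raise ValueError("zero-variance ROI column: correlation undefined")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    z = 0.5 * (z + z.T)  # enforce exact symmetry (corrcoef is ulp-asymmetric)

    coords = parcellation[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    dist = squareform(pdist(coords))
    excluded = dist < min_distance_mm  # strict: exactly min_distance retained
    np.fill_diagonal(excluded, True)
    return ConnectivityMatrix(z=z, excluded=excluded, nonpositive=z <= 0)


def internetwork_summaries(
    cm: ConnectivityMatrix,
    parcellation: pd.DataFrame,
    include_within: bool = False,
) -> InternetworkSummary:
    """Means of retained positive z entries across network boundaries.

    ROIs labeled ``excluded`` are dropped first.  Each unordered ROI pair
    counts once.  A summary with an empty retained set is reported as NaN
    with a warning.  ``include_within`` additionally admits within-network
    pairs into the overall mean (alternative reading of "between all ROIs").
    """
    parcellation = validate_parcellation(parcellation)
    labels = parcellation["network"].to_numpy()
    keep = labels != EXCLUDED_LABEL
    nets = sorted(set(labels[keep]))
    if len(nets) < 2:
        raise ValueError("need at least 2 labeled networks")

    idx = np.flatnonzero(keep)
    z = cm.z[np.ix_(idx, idx)]
    retained = cm.retained[np.ix_(idx, idx)]
    labels = labels[idx]
    upper = np.triu(np.ones_like(retained, dtype=bool), k=1)
    cross = labels[:, None] != labels[None, :]

    def _mean(mask: np.ndarray, what: str) -> float:
        sel = retained & upper & mask
        if not sel.any():
            warnings.warn(f"no retained entries for {what}; reporting NaN")
            return float("nan")
        return float(z[sel].mean())

    overall_mask = np.ones_like(cross) if include_within else cross
    overall = _mean(overall_mask, "overall summary")

    per_network: dict[str, float] = {}
    for net in nets:
        in_net = labels == net
        mask = cross & (in_net[:, None] | in_net[None, :])
        per_network[net] = _mean(mask, f"network {net}")

    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(nets, 2):
        mask = (labels[:, None] == a) & (labels[None, :] == b)
        mask = mask | mask.T
        pairwise[(a, b)] = _mean(mask, f"pair {a}-{b}")

    return InternetworkSummary(
        overall_z=overall, per_network_z=per_network, pairwise_z=pairwise
    )


def process_participant(
    ts: np.ndarray,
    motion: np.ndarray,
    nuisance: np.ndarray,
    parcellation: pd.DataFrame,
    tr: float,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_distance_mm: float = DEFAULT_MIN_DISTANCE_MM,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    include_within: bool = False,
) -> tuple[InternetworkSummary, float]:
    """Full per-participant pipeline: QC -> filter -> residualize -> summarize.

    ``nuisance`` carries the white-matter / ventricle traces (frames x k);
    the motion-derived FD trace and the RMS signal-change trace are appended
    internally, and all nuisance columns go through the same band-pass as
    the signal before regression.
    """
    fd = framewise_displacement(motion)
    scrubbed, scrub_pct = scrub_and_replace(ts, fd, fd_threshold_mm)
    filtered = bandpass(scrubbed, tr, *band_hz)
    nuis = np.column_stack([fd, rms_signal_change(scrubbed),
                            np.atleast_2d(np.asarray(nuisance, dtype=float))])
    nuis_filtered = bandpass(nuis, tr, *band_hz)
    residual = nuisance_regress(filtered, nuis_filtered)
    cm = connectivity_matrix(residual, parcellation, min_distance_mm)
    summary = internetwork_summaries(cm, parcellation, include_within)
    return summary, scrub_pct


def summary_to_row(
    participant_id: object, summary: InternetworkSummary, scrub_pct: float
) -> dict:
    """Flatten a summary into the wide per-participant row format."""
    row: dict = {"participant_id": participant_id, "rsfc_overall": summary.overall_z}
    for net, value in summary.per_network_z.items():
        row[f"rsfc_net_{net}"] = value
    for (a, b), value in summary.pairwise_z.items():
        row[f"rsfc_pair_{a}_{b}"] = value
    row["scrub_pct"] = scrub_pct
    return row
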