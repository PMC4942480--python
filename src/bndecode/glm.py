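"""Per-stimulus voxel responses as GLM contrast t-statistics.

Ordinary-least-squares fit of an event-related design (one HRF-convolved
boxcar regressor per stimulus, plus nuisance, cosine drift, and intercept
columns); one t-contrast per stimulus yields the trial-by-voxel pattern
matrix used for decoding.  No prewhitening is applied: the fit assumes
white noise, which holds for the synthetic series this package generates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import TrialMatrix, VoxelMeta
from .hrf import double_gamma_hrf
from .synth import EventTable

#: t value reported when a contrast has exactly zero residual variance
T_MAX_DEFAULT = 1e6


@dataclass
class DesignMatrix:
    """GLM design: scans x regressors, with task/nuisance column bookkeeping."""

    matrix: np.ndarray
    names: list[str]
    task_columns: list[int]
    nuisance_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names must match design column count")
        task = self.matrix[:, self.task_columns]
        if np.any(np.all(task == 0, axis=0)):
            raise ValueError("design contains an all-zero task column")

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def cosine_drift_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """DCT-II drift regressors for high-pass filtering at ``cutoff`` seconds.

    Includes frequencies up to 1/cutoff Hz, i.e. k = 1..floor(2*T/cutoff).
    """
    duration = n_scans * tr
    order = int(np.floor(2.0 * duration / cutoff))
    s = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * s + 1) / (2 * n_scans)) * np.sqrt(2.0 / n_scans)
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design_matrix(
    events: EventTable,
    n_scans: int,
    tr: float,
    highpass_cutoff: float | None = 100.0,
    nuisance: np.ndarray | None = None,
    oversample: int = 25,
) -> DesignMatrix:
    """One HRF-convolved boxcar task column per event, plus nuisance columns,
    cosine drift regressors (high-pass), and an intercept.

    The boxcar is built on a grid of ``tr / oversample`` seconds, convolved
    with the canonical double-gamma HRF, and decimated to scan times.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    total = n_scans * tr
    if np.any(events.onsets + events.durations > total):
        raise ValueError("event extends beyond the scan window")
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance row count must equal n_scans")

    dt = tr / oversample
    grid = np.arange(0.0, total, dt)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)

    task_cols = []
    names: list[str] = []
    for i, (onset, dur, cond) in enumerate(
        zip(events.onsets, events.durations, events.conditions)
    ):
        box = ((grid >= onset) & (grid < onset + dur)).astype(float)
        reg = np.convolve(box, hrf)[: len(grid)] * dt
        task_cols.append(reg[scan_idx])
        names.append(f"stim{i}_{cond}")
    X = np.column_stack(task_cols)
    task_idx = list(range(X.shape[1]))

    nuis_blocks = []
    if nuisance is not None and nuisance.shape[1] > 0:
        nuis_blocks.append(nuisance)
        names += [f"nuisance{j}" for j in range(nuisance.shape[1])]
    if highpass_cutoff is not None:
        drifts = cosine_drift_basis(n_scans, tr, highpass_cutoff)
        if drifts.shape[1] > 0:
            nuis_blocks.append(drifts)
            names += [f"drift{k}" for k in range(drifts.shape[1])]
    nuis_blocks.append(np.ones((n_scans, 1)))
    names.append("intercept")

    full = np.column_stack([X] + nuis_blocks)
    nuis_idx = list(range(len(task_idx), full.shape[1]))
    return DesignMatrix(full, names, task_idx, nuis_idx)


def stimulus_contrasts(design: DesignMatrix) -> np.ndarray:
    """One unit contrast per task column (rows of an identity on task cols)."""
    C = np.zeros((len(design.task_columns), design.n_regressors))
    for r, c in enumerate(design.task_columns):
        C[r, c] = 1.0
    return C


def fit_glm_tstats(
    timeseries: np.ndarray,
    design: DesignMatrix,
    contrasts: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    voxel_meta: list[VoxelMeta] | None = None,
    t_max: float = T_MAX_DEFAULT,
) -> TrialMatrix:
    """OLS fit per voxel; return one row of contrast t-statistics per contrast.

    t = (c'b) / sqrt(c' (X'X)^-1 c * s2) with s2 = RSS / (n - rank(X)).
    When a voxel's residual is exactly zero, t is reported as
    sign(c'b) * t_max to keep downstream arithmetic finite.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    Y = np.asarray(timeseries, dtype=float)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("timeseries rows must equal design rows")
    n, p = X.shape
    if contrasts is None:
        contrasts = stimulus_contrasts(design)
    contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))
    if contrasts.shape[1] != p:
        raise ValueError("each contrast must have one entry per regressor")

    # rank check with column identification via pivoted QR
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = sorted(design.names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # (p, voxels)
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    # residual indistinguishable from rounding error counts as zero
    zero_rss = rss <= 1e-12 * (np.sum(Y**2, axis=0) + 1.0)
    dof = n - rank
    sigma2 = rss / dof

    eff = contrasts @ beta  # (n_contrasts, voxels)
    cvar = np.einsum("ij,jk,ik->i", contrasts, XtX_inv, contrasts)  # (n_contrasts,)
    denom = np.sqrt(np.outer(cvar, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / denom
    if np.any(zero_rss):
        t[:, zero_rss] = np.sign(eff[:, zero_rss]) * t_max

    if labels is None:
        labels = np.arange(contrasts.shape[0])
    return TrialMatrix(t, labels, list(voxel_meta) if voxel_meta else [])
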