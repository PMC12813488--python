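"""Fisher-z functional connectomes from parcellated BOLD run time series.

A connectome here is the vectorized upper triangle of the parcel-by-parcel
Pearson correlation matrix of cleaned resting-state time series, Fisher
r-to-z transformed and averaged across eligible runs. Volumes with high
framewise displacement (FD) are censored: they receive spike regressors in
the nuisance regression and are excluded from the correlation. Runs are
eligible only if enough low-motion time survives censoring.

Edge ordering is fixed as the row-major upper triangle (i < j) and is
fingerprinted by a hash so that cross-dataset dot products can refuse
mismatched orderings instead of silently reordering.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RunTimeSeries",
    "EdgeVector",
    "edge_index",
    "edge_order_hash",
    "vectorize",
    "unvectorize",
    "censor_mask",
    "run_eligible",
    "dct_highpass_basis",
    "clean_timeseries",
    "connectome_from_runs",
    "subject_connectome",
]

#: clip |r| below 1 by this margin before atanh
_R_CLIP = 1.0 - 1e-7


@dataclass
class RunTimeSeries:
    """One resting-state run: parcel time series plus motion/nuisance info.

    Parameters
    ----------
    data : (volumes, parcels) array
    tr_seconds : repetition time in seconds
    fd_mm : (volumes,) framewise displacement in mm
    nuisance : (volumes, k) nuisance regressor matrix or None
    """

    data: np.ndarray
    tr_seconds: float
    fd_mm: np.ndarray
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (volumes, parcels)")
        if self.fd_mm.shape != (self.data.shape[0],):
            raise ValueError("fd_mm length must equal the number of volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.data.shape[0]:
                raise ValueError("nuisance rows must equal the number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


def edge_index(n_parcels: int) -> np.ndarray:
    """Fixed (E, 2) array of (i, j) parcel pairs, row-major upper triangle, i < j."""
    iu = np.triu_indices(n_parcels, k=1)
    return np.column_stack(iu)


def edge_order_hash(n_parcels: int, labels: list[str] | None = None) -> str:
    """Fingerprint of the edge ordering convention and parcel labeling."""
    h = hashlib.sha256()
    h.update(b"upper-triangle-row-major-v1|")
    h.update(str(int(n_parcels)).encode())
    if labels is not None:
        h.update(b"|" + "|".join(map(str, labels)).encode())
    return h.hexdigest()[:16]


def vectorize(mat: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a square symmetric matrix."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def unvectorize(vec: np.ndarray, n_parcels: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; fills the diagonal with ``diag``."""
    vec = np.asarray(vec)
    expected = n_parcels * (n_parcels - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(f"expected {expected} edges for {n_parcels} parcels")
    mat = np.full((n_parcels, n_parcels), diag, dtype=float)
    iu = np.triu_indices(n_parcels, k=1)
    mat[iu] = vec
    mat.T[iu] = vec
    return mat


@dataclass
class EdgeVector:
    """Vectorized Fisher-z connectome with a fixed, hash-checked edge order."""

    values: np.ndarray
    n_parcels: int
    labels: list[str] | None = None
    order_hash: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_parcels * (self.n_parcels - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"edge vector length {self.values.shape} does not match "
                f"{self.n_parcels} parcels (expected {expected})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge values must be finite")
        if self.labels is not None and len(self.labels) != self.n_parcels:
            raise ValueError("one network label per parcel required")
        if not self.order_hash:
            self.order_hash = edge_order_hash(self.n_parcels, self.labels)

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index(self.n_parcels)

    def to_matrix(self) -> np.ndarray:
        return unvectorize(self.values, self.n_parcels)


def censor_mask(fd_mm: np.ndarray, threshold_mm: float = 0.5) -> np.ndarray:
    """Keep-mask over volumes; volumes strictly exceeding the FD threshold are dropped.

    The boundary value (FD exactly at threshold) is retained.
    """
    fd = np.asarray(fd_mm, dtype=float)
    if np.any(fd < 0):
        raise ValueError("framewise displacement must be non-negative")
    if threshold_mm <= 0:
        raise ValueError("FD threshold must be positive")
    return fd <= threshold_mm


def run_eligible(mask: np.ndarray, tr_seconds: float, min_minutes: float = 4.0) -> bool:
    """True iff the retained volumes amount to at least ``min_minutes`` of data."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty censoring mask")
    return bool(mask.sum() * tr_seconds >= min_minutes * 60.0)


def dct_highpass_basis(n_volumes: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than ``cutoff_hz``.

    Returns an (n_volumes, K) matrix with K = floor(2 * n * TR * cutoff); the
    constant term is excluded (the regression carries its own intercept).
    Regressing these columns out implements high-pass filtering inside a
    single nuisance regression.
    """
    if cutoff_hz <= 0:
        return np.empty((n_volumes, 0))
    n_basis = int(np.floor(2.0 * n_volumes * tr_seconds * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def _drop_collinear(design: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Return column indices of a full-rank subset (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return np.arange(design.shape[1])
    keep = diag > tol * diag[0]
    kept = np.sort(piv[: keep.sum()])
    if kept.size < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(kept.tolist()))
        warnings.warn(
            f"nuisance design is rank deficient; dropping columns {dropped}",
            RuntimeWarning,
            stacklevel=3,
        )
    return kept


def clean_timeseries(
    run: RunTimeSeries,
    mask: np.ndarray | None = None,
    highpass_hz: float = 0.008,
    detrend: bool = True,
    spike_regressors: bool = True,
) -> np.ndarray:
    """Nuisance-regress a run in a single step and return the residual series.

    The design contains an intercept, a linear trend, the run's nuisance
    columns, a discrete-cosine high-pass basis up to ``highpass_hz``, and one
    spike regressor per censored volume; all are removed in one multiple
    regression per parcel. Spike regressors force censored rows to exactly
    zero residual; those rows should additionally be excluded from any
    correlation computed downstream.
    """
    n = run.n_volumes
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("mask length must equal volume count")

    cols = [np.ones(n)]
    if detrend:
        cols.append(np.linspace(-0.5, 0.5, n))
    if run.nuisance is not None and run.nuisance.shape[1] > 0:
        cols.append(run.nuisance)
    hp = dct_highpass_basis(n, run.tr_seconds, highpass_hz)
    if hp.shape[1]:
        cols.append(hp)
    if spike_regressors:
        censored = np.flatnonzero(~mask)
        if censored.size:
            spikes = np.zeros((n, censored.size))
            spikes[censored, np.arange(censored.size)] = 1.0
            cols.append(spikes)
    design = np.column_stack(cols)
    keep_cols = _drop_collinear(design)
    design = design[:, keep_cols]
    beta, *_ = np.linalg.lstsq(design, run.data, rcond=None)
    return run.data - design @ beta


def connectome_from_runs(
    cleaned_runs: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    labels: list[str] | None = None,
) -> EdgeVector:
    """Per-run Pearson correlation -> Fisher z -> average across runs -> edges.

    Correlations are computed over retained (non-censored) volumes only.
    Edges with |r| at 1 are clipped just inside the open interval before the
    z-transform (with a warning) so the result stays finite.
    """
    if not cleaned_runs:
        raise ValueError("at least one eligible run is required")
    n_parcels = cleaned_runs[0].shape[1]
    z_sum = np.zeros(n_parcels * (n_parcels - 1) // 2)
    for idx, run_data in enumerate(cleaned_runs):
        if run_data.shape[1] != n_parcels:
            raise ValueError("all runs must share the parcel dimension")
        rows = run_data
        if masks is not None:
            rows = run_data[np.asarray(masks[idx], dtype=bool)]
        if rows.shape[0] < 3:
            raise ValueError("too few retained volumes to correlate")
        r = np.corrcoef(rows, rowvar=False)
        r_vec = vectorize(r)
        if np.any(np.abs(r_vec) >= 1.0):
            warnings.warn(
                "perfectly correlated edge encountered; clipping before atanh",
                RuntimeWarning,
                stacklevel=2,
            )
            r_vec = np.clip(r_vec, -_R_CLIP, _R_CLIP)
        z_sum += np.arctanh(r_vec)
    return EdgeVector(z_sum / len(cleaned_runs), n_parcels, labels=labels)


def subject_connectome(
    runs: list[RunTimeSeries],
    fd_threshold_mm: float = 0.5,
    min_minutes: float = 4.0,
    highpass_hz: float = 0.008,
    labels: list[str] | None = None,
    exclude_censored_from_corr: bool = True,
) -> EdgeVector | None:
    """Full per-subject path: censor, drop ineligible runs, clean, correlate, average.

    Returns None when no run survives the eligibility rule (the caller logs
    the exclusion).
    """
    cleaned, masks = [], []
    for run in runs:
        mask = censor_mask(run.fd_mm, fd_threshold_mm)
        if not run_eligible(mask, run.tr_seconds, min_minutes):
            continue
        cleaned.append(clean_timeseries(run, mask, highpass_hz=highpass_hz))
        masks.append(mask if exclude_censored_from_corr else np.ones_like(mask))
    if not cleaned:
        return None
    return connectome_from_runs(cleaned, masks, labels=labels)
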