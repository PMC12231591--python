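"""Time-cumulative expression offsets via sparse functional PCA (PACE).

Each individual contributes a sparse, irregular pseudotime series of one
gene's normalized expression.  Writing the series as

    x_ij = mu(t_ij) + sum_k xi_ik phi_k(t_ij) + eps_ij,

the mean function ``mu`` is estimated by local linear smoothing of the
pooled observations, the covariance surface ``R(s,t)`` by local linear
smoothing of the off-diagonal raw covariances, and the measurement-error
variance ``sigma^2`` from the gap between the smoothed diagonal and
``R(t,t)``.  Eigenpairs come from the grid-discretized covariance operator;
the number of components ``K`` is the smallest one whose fraction of
variance explained reaches the threshold (default 99%).  Principal-component
scores use the conditional expectation ("PACE") formula

    xi_ik = lambda_k phi_ik' Sigma_Xi^{-1} (X_i - mu_i),

which shrinks appropriately for sparse, noisy designs.  The quantity carried
forward to eQTL mapping and MR is the time-cumulative offset

    xtilde_i = integral of (xhat_i(t) - mu(t)) dt = sum_k xi_ik * int phi_k,

the integral of the reconstructed individual deviation over the trajectory.

Bandwidths for both smoothers are selected by generalized cross-validation
over a geometric grid; raw inputs are pre-binned (weighted) so smoothing
cost is governed by the number of distinct pseudotime points, not cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .simulate import CellExpressionDataset

__all__ = [
    "IndividualSeries",
    "AggregatedSeries",
    "PaceFit",
    "CumulativeOffsets",
    "normalize_counts",
    "aggregate_intervals",
    "normalize_for_pace",
    "fit_pace",
    "cumulative_offset",
    "compute_offsets",
]

logger = logging.getLogger("tiscmr.pace")

_EPA = 0.75  # Epanechnikov kernel constant, K(u) = 0.75 (1 - u^2) on |u|<1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IndividualSeries:
    """One individual's sparse pseudotime series of one gene."""

    individual_id: str
    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.size != self.x.size or self.t.size < 1:
            raise ValueError("t and x must be equal-length and nonempty")


@dataclass
class AggregatedSeries:
    """Interval-aggregated series: bin midpoints, per-bin means, cell counts."""

    individual_id: str
    midpoints: np.ndarray
    means: np.ndarray
    counts: np.ndarray


@dataclass
class PaceFit:
    """Fitted mean/eigenstructure and per-individual scores for one gene."""

    grid: np.ndarray
    mu_hat: np.ndarray
    eigvals: np.ndarray            # all retained positive eigenvalues, desc
    eigfuns: np.ndarray            # (n_pos, n_grid), orthonormal w.r.t. trapz
    sigma2_hat: float
    n_components: int              # K, minimal with FVE >= threshold
    fve: np.ndarray                # cumulative FVE per K
    scores: np.ndarray             # (n_individuals, K)
    individual_ids: list[str]
    fve_threshold: float = 0.99
    bandwidth_mean: float = np.nan
    bandwidth_cov: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    def reconstruct(self, i: int) -> np.ndarray:
        """Fitted curve ``xhat_i(t)`` on the grid for individual ``i``."""
        K = self.n_components
        return self.mu_hat + self.scores[i, :K] @ self.eigfuns[:K]


@dataclass
class CumulativeOffsets:
    """Per-individual time-cumulative offsets ``xtilde_i`` for one gene."""

    individual_ids: list[str]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.individual_ids)


# ---------------------------------------------------------------------------
# normalization and interval aggregation
# ---------------------------------------------------------------------------

def normalize_counts(
    cells: CellExpressionDataset, target_sum: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Library-size log-normalize then per-gene z-score.

    Counts are scaled so each cell's library sums to ``target_sum`` (default:
    the median library size), log1p-transformed, and z-scored per gene across
    all cells.  Returns ``(values, kept)`` where genes with zero variance are
    excluded (``kept`` False, column NaN).
    """
    counts = np.asarray(cells.counts, dtype=float)
    lib = counts.sum(axis=1)
    lib[lib == 0] = 1.0
    if target_sum is None:
        target_sum = float(np.median(lib))
    x = np.log1p(counts * (target_sum / lib)[:, None])
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    kept = sd > 0
    if not kept.all():
        logger.warning("excluding %d zero-variance genes", int((~kept).sum()))
    x = np.where(kept[None, :], (x - mean[None, :]) / np.where(kept, sd, 1.0)[None, :], np.nan)
    return x, kept


def _bin_edges(n_intervals: int, t_max: float) -> np.ndarray:
    return np.linspace(0.0, t_max, n_intervals + 1)


def aggregate_intervals(
    cells: CellExpressionDataset,
    n_intervals: int,
    gene: int,
    values: np.ndarray | None = None,
    t_max: float | None = None,
) -> list[AggregatedSeries]:
    """Bin each individual's cells into equal-width pseudotime intervals.

    ``values`` may carry pre-normalized per-cell values for the gene;
    otherwise raw counts are used.  Only nonempty bins appear, represented by
    the interval midpoint and the mean over the individual's cells in it.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    t = cells.cell_meta["pseudotime"].to_numpy()
    if t_max is None:
        t_max = float(np.ceil(t.max()))
    v = np.asarray(cells.counts[:, gene], dtype=float) if values is None else np.asarray(values, dtype=float)
    edges = _bin_edges(n_intervals, t_max)
    mids = 0.5 * (edges[:-1] + edges[1:])
    bins = np.clip(np.digitize(t, edges) - 1, 0, n_intervals - 1)
    out: list[AggregatedSeries] = []
    meta = cells.cell_meta
    for ind_id, idx in meta.groupby("individual_id", sort=True).indices.items():
        vi, bi = v[idx], bins[idx]
        ok = np.isfinite(vi)
        vi, bi = vi[ok], bi[ok]
        if vi.size == 0:
            logger.warning("individual %s has no usable cells; omitted", ind_id)
            continue
        sums = np.bincount(bi, weights=vi, minlength=n_intervals)
        cnts = np.bincount(bi, minlength=n_intervals)
        nz = cnts > 0
        out.append(AggregatedSeries(
            individual_id=str(ind_id),
            midpoints=mids[nz],
            means=sums[nz] / cnts[nz],
            counts=cnts[nz],
        ))
    return out


def normalize_for_pace(
    cells: CellExpressionDataset,
    gene: int,
    n_intervals: int | None = None,
    t_max: float | None = None,
    target_sum: float | None = None,
) -> list[IndividualSeries]:
    """Normalized (and optionally interval-aggregated) series for one gene."""
    values, kept = normalize_counts(cells, target_sum=target_sum)
    if not kept[gene]:
        raise ValueError(f"gene {gene} has zero variance and was excluded")
    if n_intervals is not None:
        aggs = aggregate_intervals(cells, n_intervals, gene, values=values[:, gene], t_max=t_max)
        return [IndividualSeries(a.individual_id, a.midpoints, a.means) for a in aggs]
    out = []
    meta = cells.cell_meta
    t = meta["pseudotime"].to_numpy()
    for ind_id, idx in meta.groupby("individual_id", sort=True).indices.items():
        out.append(IndividualSeries(str(ind_id), t[idx], values[idx, gene]))
    return out


# ---------------------------------------------------------------------------
# local linear smoothers (weighted, Epanechnikov)
# ---------------------------------------------------------------------------

def _bin_pooled(t: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse duplicate time points to weighted means (weights = counts)."""
    order = np.argsort(t)
    t, x = t[order], x[order]
    tu, inv = np.unique(np.round(t, 10), return_inverse=True)
    sums = np.bincount(inv, weights=x)
    cnts = np.bincount(inv).astype(float)
    return tu, sums / cnts, cnts


def _loclin_1d(
    td: np.ndarray, yd: np.ndarray, wd: np.ndarray, tout: np.ndarray, h: float
) -> np.ndarray:
    """Weighted local linear estimate at ``tout``; local-constant fallback."""
    d = tout[:, None] - td[None, :]
    u = d / h
    k = np.where(np.abs(u) < 1.0, _EPA * (1.0 - u**2), 0.0) * wd[None, :]
    s0 = k.sum(axis=1)
    s1 = (k * d).sum(axis=1)
    s2 = (k * d**2).sum(axis=1)
    t0 = (k * yd[None, :]).sum(axis=1)
    t1 = (k * d * yd[None, :]).sum(axis=1)
    den = s0 * s2 - s1**2
    scale = np.maximum(s0, 1e-300) ** 2 * h**2
    good = den > 1e-10 * scale
    est = np.empty(tout.size)
    est[good] = (s2[good] * t0[good] - s1[good] * t1[good]) / den[good]
    lc = ~good & (s0 > 0)
    est[lc] = t0[lc] / s0[lc]
    empty = s0 <= 0
    if empty.any():
        # no data in window: nearest-neighbor fallback
        j = np.abs(tout[empty][:, None] - td[None, :]).argmin(axis=1)
        est[empty] = yd[j]
    return est


def _gcv_1d(td: np.ndarray, yd: np.ndarray, wd: np.ndarray, candidates: np.ndarray) -> float:
    """GCV bandwidth choice for the 1-D local linear smoother."""
    n = td.size
    best_h, best_score = float(candidates[-1]), np.inf
    for h in candidates:
        d = td[:, None] - td[None, :]
        u = d / h
        k = np.where(np.abs(u) < 1.0, _EPA * (1.0 - u**2), 0.0) * wd[None, :]
        s0 = k.sum(axis=1)
        s1 = (k * d).sum(axis=1)
        s2 = (k * d**2).sum(axis=1)
        den = s0 * s2 - s1**2
        if np.any(den <= 0) or np.any(s0 <= 0):
            continue
        l_w = k * (s2[:, None] - d * s1[:, None]) / den[:, None]
        yhat = l_w @ yd
        tr = np.trace(l_w)
        if tr >= n:
            continue
        rss = float(np.sum(wd * (yd - yhat) ** 2) / wd.sum())
        score = rss / (1.0 - tr / n) ** 2
        if score < best_score:
            best_score, best_h = score, float(h)
    return best_h


def _candidate_bandwidths(tu: np.ndarray, n: int = 8) -> np.ndarray:
    rng_t = tu.max() - tu.min()
    if rng_t <= 0:
        raise ValueError("need at least 2 distinct pooled time points")
    gaps = np.diff(np.sort(tu))
    h_min = max(2.0 * np.median(gaps), rng_t / 50.0)
    h_max = rng_t / 2.0
    if h_min >= h_max:
        h_min = h_max / 4.0
    return np.geomspace(h_min, h_max, n)


def _bin_lattice_2d(
    s: np.ndarray, t: np.ndarray, c: np.ndarray, t_lo: float, t_hi: float,
    n_bins: int = 25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bin raw covariance points onto a square lattice (weighted means).

    Returns the bin-center axes and dense ``(n_bins, n_bins)`` weight and
    mean-value matrices; empty cells carry zero weight.
    """
    edges = np.linspace(t_lo, t_hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bi = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    bj = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    flat = bi * n_bins + bj
    sums_c = np.bincount(flat, weights=c, minlength=n_bins**2)
    cnt = np.bincount(flat, minlength=n_bins**2).astype(float)
    C = np.divide(sums_c, cnt, out=np.zeros_like(sums_c), where=cnt > 0)
    return centers, centers, cnt.reshape(n_bins, n_bins), C.reshape(n_bins, n_bins)


def _lattice_2d(
    s: np.ndarray, t: np.ndarray, c: np.ndarray, max_cells: int = 25_000,
    t_lo: float = 0.0, t_hi: float = 1.0, axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse raw covariance points to a lattice of unique coordinates.

    Interval-aggregated series live on a small set of bin midpoints, so the
    exact unique-coordinate lattice is tiny; ``axis`` may carry those known
    midpoints to skip the unique scan.  Continuous designs fall back to a
    fixed square binning.
    """
    if axis is not None and axis.size**2 <= max_cells:
        us = ut = axis
        si = np.searchsorted(axis, np.round(s, 9))
        ti = np.searchsorted(axis, np.round(t, 9))
    else:
        us, si = np.unique(np.round(s, 9), return_inverse=True)
        ut, ti = np.unique(np.round(t, 9), return_inverse=True)
        if us.size * ut.size > max_cells:
            return _bin_lattice_2d(s, t, c, t_lo, t_hi, n_bins=40)
    flat = si * ut.size + ti
    sums = np.bincount(flat, weights=c, minlength=us.size * ut.size)
    cnt = np.bincount(flat, minlength=us.size * ut.size).astype(float)
    C = np.divide(sums, cnt, out=np.zeros_like(sums), where=cnt > 0)
    return us, ut, cnt.reshape(us.size, ut.size), C.reshape(us.size, ut.size)


def _loclin_2d_lattice(
    us: np.ndarray, ut: np.ndarray, W: np.ndarray, C: np.ndarray,
    s_out: np.ndarray, t_out: np.ndarray, h: float,
    return_hat_diag: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Weighted 2-D local linear smoother for lattice-valued data.

    Data live on the axes ``us x ut`` with weights ``W`` (zero marks empty
    cells) and values ``C``; the estimate is returned on the tensor grid
    ``s_out x t_out``.  The product Epanechnikov kernel makes every local
    moment a separable ``A_p @ W @ B_q.T`` matrix product, so cost scales
    with the axis lengths rather than the number of raw pairs.  Falls back
    to local-constant, then nearest-cell, where the local design degenerates.
    """
    ds = us[None, :] - s_out[:, None]                      # (A, I)
    dt = ut[None, :] - t_out[:, None]                      # (B, J)
    ks = np.where(np.abs(ds) < h, _EPA * (1.0 - (ds / h) ** 2), 0.0)
    kt = np.where(np.abs(dt) < h, _EPA * (1.0 - (dt / h) ** 2), 0.0)
    A0, A1, A2 = ks, ks * ds, ks * ds**2
    B0, B1, B2 = kt, kt * dt, kt * dt**2
    WC = W * C
    S00 = A0 @ W @ B0.T
    S10 = A1 @ W @ B0.T
    S01 = A0 @ W @ B1.T
    S20 = A2 @ W @ B0.T
    S11 = A1 @ W @ B1.T
    S02 = A0 @ W @ B2.T
    T00 = A0 @ WC @ B0.T
    T10 = A1 @ WC @ B0.T
    T01 = A0 @ WC @ B1.T

    # solve the symmetric 3x3 normal equations by Cramer's rule, vectorized
    # over all output points (the first coefficient is the estimate)
    c00 = S20 * S02 - S11 * S11
    c01 = S01 * S11 - S10 * S02
    c02 = S10 * S11 - S01 * S20
    det = S00 * c00 + S10 * c01 + S01 * c02
    good = (S00 > 0) & (det > 1e-12 * np.maximum(S00, 1e-300) ** 3 * h**4)
    est = np.empty(S00.shape)
    inv00 = np.zeros(S00.shape)
    safe_det = np.where(good, det, 1.0)
    beta0 = (T00 * c00 + T10 * c01 + T01 * c02) / safe_det
    est[good] = beta0[good]
    if return_hat_diag:
        inv00[good] = (c00 / safe_det)[good]
    lc = ~good & (S00 > 0)
    if lc.any():
        est[lc] = T00[lc] / S00[lc]
        if return_hat_diag:
            inv00[lc] = 1.0 / S00[lc]
    empty = S00 <= 0
    if empty.any():
        # no data in window: nearest nonzero lattice cell
        di, dj = np.nonzero(W)
        ei, ej = np.nonzero(empty)
        dist = (np.abs(s_out[ei][:, None] - us[di][None, :])
                + np.abs(t_out[ej][:, None] - ut[dj][None, :]))
        nearest = dist.argmin(axis=1)
        est[ei, ej] = C[di[nearest], dj[nearest]]
    if return_hat_diag:
        # only meaningful when the output grid coincides with the data lattice
        hat = inv00 * (_EPA**2) * W
        return est, hat
    return est


def _gcv_2d(
    us: np.ndarray, ut: np.ndarray, W: np.ndarray, C: np.ndarray,
    candidates: np.ndarray,
) -> float:
    """GCV bandwidth for the 2-D smoother, evaluated on the data lattice."""
    nz = W > 0
    n = int(nz.sum())
    best_h, best_score = float(candidates[-1]), np.inf
    for h in candidates:
        yhat, hat = _loclin_2d_lattice(us, ut, W, C, us, ut, h, return_hat_diag=True)
        tr = float(hat[nz].sum())
        if not np.isfinite(yhat[nz]).all() or tr >= n:
            continue
        rss = float(np.sum(W[nz] * (C[nz] - yhat[nz]) ** 2) / W[nz].sum())
        score = rss / (1.0 - tr / n) ** 2
        if score < best_score:
            best_score, best_h = score, float(h)
    return best_h


# ---------------------------------------------------------------------------
# PACE fit
# ---------------------------------------------------------------------------

def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def fit_pace(
    series: list[IndividualSeries],
    grid: np.ndarray | None = None,
    fve_threshold: float = 0.99,
    min_individuals: int = 20,
    n_grid: int = 101,
    max_components: int | None = None,
) -> PaceFit:
    """Fit PACE to sparse irregular series and return mean, eigenpairs, scores.

    Steps: pooled local linear mean; local linear smoothing of off-diagonal
    raw covariances; error variance from the smoothed diagonal minus the
    surface diagonal over the central half of the grid; grid-weighted
    eigendecomposition with negative eigenvalues truncated; minimal-K FVE
    rule; conditional-expectation scores with ridge-stabilized inversion.
    """
    if len(series) < min_individuals:
        raise ValueError(f"need >= {min_individuals} individuals, got {len(series)}")
    all_t = np.concatenate([s.t for s in series])
    all_x = np.concatenate([s.x for s in series])
    if np.unique(np.round(all_t, 10)).size < 2:
        raise ValueError("need at least 2 distinct pooled time points")
    if grid is None:
        grid = np.linspace(all_t.min(), all_t.max(), n_grid)
    grid = np.asarray(grid, dtype=float)

    # (i) mean function
    tu, xu, wu = _bin_pooled(all_t, all_x)
    cand = _candidate_bandwidths(tu)
    h_mu = _gcv_1d(tu, xu, wu, cand)
    mu_hat = _loclin_1d(tu, xu, wu, grid, h_mu)
    mu_at = lambda t: np.interp(t, grid, mu_hat)  # noqa: E731

    # (ii) raw covariances, off-diagonal smoothing
    ss, tt, cc = [], [], []
    diag_t, diag_c = [], []
    for s in series:
        r = s.x - mu_at(s.t)
        if s.t.size >= 2:
            prod = np.outer(r, r)
            ti, tj = np.meshgrid(s.t, s.t, indexing="ij")
            off = ~np.eye(s.t.size, dtype=bool)
            ss.append(ti[off])
            tt.append(tj[off])
            cc.append(prod[off])
        diag_t.append(s.t)
        diag_c.append(r**2)
    if not ss:
        raise ValueError("no individual has >= 2 observations; covariance unidentifiable")
    us_, ut_, W2, C2 = _lattice_2d(
        np.concatenate(ss), np.concatenate(tt), np.concatenate(cc),
        t_lo=grid.min(), t_hi=grid.max(), axis=np.unique(np.round(all_t, 9)),
    )
    cand2 = _candidate_bandwidths(us_, n=6)
    h_cov = _gcv_2d(us_, ut_, W2, C2, cand2)
    R = _loclin_2d_lattice(us_, ut_, W2, C2, grid, grid, h_cov)
    R = 0.5 * (R + R.T)

    # (iii) measurement-error variance from the diagonal gap; the diagonal
    # smoother gets its own GCV bandwidth (the variance curve can be much
    # rougher than the mean)
    dtu, dcu, dwu = _bin_pooled(np.concatenate(diag_t), np.concatenate(diag_c))
    h_diag = _gcv_1d(dtu, dcu, dwu, _candidate_bandwidths(dtu))
    V = _loclin_1d(dtu, dcu, dwu, grid, h_diag)
    lo, hi = np.quantile(grid, [0.25, 0.75])
    central = (grid >= lo) & (grid <= hi)
    sigma2 = max(float(np.mean(V[central] - np.diag(R)[central])), 0.0)

    # (iv) eigen-decomposition, grid-weighted
    wq = _trapz_weights(grid)
    sq = np.sqrt(wq)
    A = sq[:, None] * R * sq[None, :]
    evals, evecs = np.linalg.eigh(0.5 * (A + A.T))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * max(evals.max(), 0.0))
    evals, evecs = evals[pos], evecs[:, pos]
    if evals.size == 0:
        evals = np.array([0.0])
        evecs = np.zeros((grid.size, 1))
        evecs[0, 0] = 1.0
    phi = (evecs / sq[:, None]).T                      # (n_pos, n_grid)
    integ = phi @ wq
    for k in range(phi.shape[0]):
        s = integ[k]
        if abs(s) < 1e-12:
            nz = np.nonzero(np.abs(phi[k]) > 1e-12)[0]
            s = phi[k, nz[0]] if nz.size else 1.0
        if s < 0:
            phi[k] = -phi[k]
    if max_components is not None:
        evals, phi = evals[:max_components], phi[:max_components]

    # (v) FVE-minimal K
    fve = np.cumsum(evals) / evals.sum() if evals.sum() > 0 else np.ones_like(evals)
    K = int(np.searchsorted(fve, fve_threshold) + 1)
    K = min(K, evals.size)

    # (vi) conditional-expectation scores with Sigma_Xi = Phi Lambda Phi' +
    # sigma^2 I built from the positive eigenpairs (the raw smoothed surface
    # is indefinite and can make the solve explode).  Observation times are
    # usually a small shared set (interval midpoints), so eigenfunctions and
    # the mean are evaluated once on the pooled unique times and indexed.
    obs_t = np.unique(np.round(all_t, 10))
    # components entering Sigma_Xi: enough eigenpairs to cover essentially
    # all positive variance (the remainder is smoothing noise)
    frac = np.cumsum(evals) / evals.sum() if evals.sum() > 0 else np.ones_like(evals)
    n_use = max(K, int(np.searchsorted(frac, 0.9999) + 1))
    n_use = min(n_use, evals.size, 50)
    phi_obs = np.vstack([np.interp(obs_t, grid, pk) for pk in phi[:n_use]])
    mu_obs = np.interp(obs_t, grid, mu_hat)
    lam_use = evals[:n_use]
    scores = np.zeros((len(series), K))
    ids = [s.individual_id for s in series]
    if evals[0] <= 1e-12:
        # degenerate fit (no variation): all scores stay zero
        series = []
    factor_cache: dict[bytes, tuple] = {}
    for i, s in enumerate(series):
        ix = np.searchsorted(obs_t, np.round(s.t, 10))
        U = phi_obs[:, ix].T                                         # (n_i, n_use)
        resid = s.x - mu_obs[ix]
        # Sigma_Xi = U diag(lam) U' + s2 I, inverted by Woodbury; s2 is the
        # measurement error plus a relative ridge (the prescribed stabilizer
        # when Sigma_Xi is singular, e.g. noiseless fits)
        s2 = sigma2 + 1e-8 * (float(lam_use.sum()) / max(s.t.size, 1) + 1e-12)
        key = ix.tobytes()
        factor = factor_cache.get(key)
        if factor is None:
            core = np.diag(1.0 / lam_use) + (U.T @ U) / s2
            factor = cho_factor(core)
            factor_cache[key] = factor
        sol = resid / s2 - U @ cho_solve(factor, U.T @ resid) / s2**2
        scores[i] = lam_use[:K] * (U[:, :K].T @ sol)

    return PaceFit(
        grid=grid, mu_hat=mu_hat, eigvals=evals, eigfuns=phi,
        sigma2_hat=sigma2, n_components=K, fve=fve, scores=scores,
        individual_ids=ids, fve_threshold=fve_threshold,
        bandwidth_mean=h_mu, bandwidth_cov=h_cov,
        diagnostics={"n_individuals": len(series), "n_obs": int(all_t.size),
                     "bandwidth_diag": h_diag},
    )


def cumulative_offset(fit: PaceFit, method: str = "scores") -> CumulativeOffsets:
    """Time-cumulative offsets ``xtilde_i = int (xhat_i - mu) dt``.

    ``method='scores'`` uses the linearity identity
    ``xtilde_i = sum_k xi_ik int phi_k``; ``method='reconstruction'``
    integrates each reconstructed deviation by the trapezoid rule.  Both
    paths agree to numerical precision.
    """
    K = fit.n_components
    if method == "scores":
        integ = np.array([np.trapezoid(fit.eigfuns[k], fit.grid) for k in range(K)])
        vals = fit.scores[:, :K] @ integ
    elif method == "reconstruction":
        dev = fit.scores[:, :K] @ fit.eigfuns[:K]
        vals = np.trapezoid(dev, fit.grid, axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CumulativeOffsets(individual_ids=list(fit.individual_ids), values=vals)


# ---------------------------------------------------------------------------
# convenience: all-gene offsets matrix
# ---------------------------------------------------------------------------

def compute_offsets(
    cells: CellExpressionDataset,
    n_intervals: int | None = None,
    fve_threshold: float = 0.99,
    t_max: float | None = None,
    n_grid: int = 101,
    genes: list[int] | None = None,
    return_fits: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, PaceFit]]:
    """Per-gene PACE fits -> individuals x genes matrix of cumulative offsets.

    Interval aggregation defaults to six bins per pseudotime unit (capped at
    150): fine enough that binning costs PACE little information, while
    keeping every smoothing input on a small lattice.  Genes excluded during
    normalization are dropped.
    """
    t = cells.cell_meta["pseudotime"].to_numpy()
    if t_max is None:
        t_max = float(np.ceil(t.max()))
    if n_intervals is None:
        n_intervals = min(150, 6 * int(round(t_max)))
    values, kept = normalize_counts(cells)
    gene_idx = genes if genes is not None else list(range(cells.n_genes))

    # shared binning across genes: rows are (individual, nonempty interval)
    edges = _bin_edges(n_intervals, t_max)
    mids = 0.5 * (edges[:-1] + edges[1:])
    bins = np.clip(np.digitize(t, edges) - 1, 0, n_intervals - 1)
    meta = cells.cell_meta
    groups = meta.groupby("individual_id", sort=True).indices

    per_ind: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ind_id, idx in groups.items():
        bi = bins[idx]
        nz = np.unique(bi)
        agg = np.empty((nz.size, len(gene_idx)))
        for r, b in enumerate(nz):
            sel = idx[bi == b]
            agg[r] = values[np.ix_(sel, gene_idx)].mean(axis=0)
        per_ind[str(ind_id)] = (mids[nz], agg)

    grid = np.linspace(0.0, t_max, n_grid)
    cols, data, fits = [], [], {}
    for j, g in enumerate(gene_idx):
        if not kept[g]:
            continue
        series = [
            IndividualSeries(ind_id, tb, ag[:, j])
            for ind_id, (tb, ag) in per_ind.items()
        ]
        fit = fit_pace(series, grid=grid, fve_threshold=fve_threshold)
        off = cumulative_offset(fit)
        cols.append(cells.gene_ids[g])
        data.append(off.to_series())
        if return_fits:
            fits[cells.gene_ids[g]] = fit
    result = pd.concat(data, axis=1)
    result.columns = cols
    if return_fits:
        return result, fits
    return result
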