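"""One-sample transcriptome-level Mendelian randomization with
time-cumulative exposures.

Exposure is either the PACE time-cumulative offset or the per-individual
mean expression of one gene; instruments are its clumped significant
eQTL SNPs.  Estimators:

- 2SLS (quantitative or binary-as-continuous outcomes): stage 1 regresses
  the exposure on instruments; stage 2 regresses the outcome on the fitted
  exposure.  Inference uses the heteroskedasticity-robust IV sandwich, which
  accounts for the generated regressor.
- 2SRI (binary outcomes): stage-1 residuals enter a second-stage logistic
  regression alongside the observed exposure; robust standard errors follow
  Terza's two-stage M-estimator sandwich, stacking the moment conditions of
  both stages.
- Lasso pleiotropy control: the second stage is augmented with direct
  instrument effects ``Z @ pi`` penalized by L1 (the causal coefficient and
  the residual-inclusion coefficient stay unpenalized); the penalty is chosen
  by 10-fold cross-validation (outcome-stratified for binary phenotypes),
  and inference comes from a nonparametric bootstrap over individuals
  (percentile CI, p by CI inversion) at the selected penalty, alongside a
  robust Wald test on the post-selection refit.

Gene-level ranking applies Benjamini-Hochberg across genes and flags
putative causal genes at adjusted p <= alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MrInput",
    "MrResult",
    "fit_2sls",
    "fit_2sri",
    "fit_lasso_pleiotropy",
    "rank_genes",
]

logger = logging.getLogger("tiscmr.mr")


@dataclass
class MrInput:
    """Row-aligned exposure, outcome and instrument dosages for one gene."""

    gene_id: str
    exposure: np.ndarray           # (n,)
    outcome: np.ndarray            # (n,), binary in {0,1} for 2SRI
    instruments: np.ndarray        # (n, k) dosages
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.instruments = np.atleast_2d(np.asarray(self.instruments, dtype=float))
        if self.instruments.shape[0] != self.exposure.size:
            self.instruments = self.instruments.T
        n = self.exposure.size
        if self.outcome.size != n or self.instruments.shape[0] != n:
            raise ValueError("exposure, outcome and instruments must be row-aligned")
        if self.instruments.shape[1] < 1:
            raise ValueError("need at least one instrument")


@dataclass
class MrResult:
    """Causal estimate and inference for one gene under one estimator."""

    gene_id: str
    estimator: str
    beta: float
    se_robust: float
    wald_p: float
    first_stage_r2: float
    first_stage_f: float
    n: int
    n_instruments: int
    boot_ci: tuple[float, float] | None = None
    boot_reps: int = 0
    boot_p: float | None = None
    selected_pleiotropy: list[str] = field(default_factory=list)
    penalty: float | None = None
    bh_adjusted_p: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def ranking_p(self) -> float:
        """p-value used for gene prioritization (bootstrap if available)."""
        return self.boot_p if self.boot_p is not None else self.wald_p


# ---------------------------------------------------------------------------
# stage-1 helpers
# ---------------------------------------------------------------------------

def _first_stage(x: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """OLS of exposure on [1, Z]: fitted values, residuals, R^2, F."""
    n, k = Z.shape
    Z1 = np.column_stack([np.ones(n), Z])
    alpha, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    xhat = Z1 @ alpha
    resid = x - xhat
    tss = float(np.sum((x - x.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df2 = n - k - 1
    f = (r2 / k) / ((1.0 - r2) / df2) if 0 < r2 < 1 and df2 > 0 else (np.inf if r2 >= 1 else 0.0)
    return xhat, resid, r2, f


def _iv_sandwich(X: np.ndarray, Xh: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2SLS point estimate and HC0 sandwich covariance.

    ``X`` holds the structural regressors (observed exposure), ``Xh`` their
    instrument-space projections; residuals are taken against ``X`` so the
    generated-regressor step does not understate the error variance.
    """
    n, k = X.shape
    G = Xh.T @ X
    beta = np.linalg.solve(G, Xh.T @ y)
    e = y - X @ beta
    # HC1 small-sample scaling of the sandwich meat
    meat = (Xh * e[:, None] ** 2).T @ Xh * (n / max(n - k, 1))
    Ginv = np.linalg.inv(G)
    V = Ginv @ meat @ Ginv.T
    return beta, V


# ---------------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------------

def fit_2sls(inp: MrInput, tag: str = "2sls") -> MrResult:
    """Two-stage least squares with robust (IV sandwich) inference."""
    n, k = inp.instruments.shape
    if n <= k + 2:
        raise ValueError("need n > n_instruments + 2")
    xhat, _, r2, f = _first_stage(inp.exposure, inp.instruments)
    X = np.column_stack([np.ones(n), inp.exposure])
    Xh = np.column_stack([np.ones(n), xhat])
    beta, V = _iv_sandwich(X, Xh, inp.outcome)
    se = float(np.sqrt(max(V[1, 1], 0.0)))
    z = beta[1] / se if se > 0 else np.inf * np.sign(beta[1] or 1.0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    flags = []
    if r2 < 1e-10:
        flags.append("weak_instruments")
        p = 1.0
    elif f < 10:
        flags.append("weak_instruments")
    return MrResult(
        gene_id=inp.gene_id, estimator=tag, beta=float(beta[1]), se_robust=se,
        wald_p=p, first_stage_r2=r2, first_stage_f=f, n=n, n_instruments=k,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# logistic machinery for 2SRI
# ---------------------------------------------------------------------------

def _logit_fit(W: np.ndarray, y: np.ndarray, ridge: float = 0.0,
               max_iter: int = 100, tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (coefficients, converged)."""
    n, m = W.shape
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = W @ b
        p = expit(eta)
        wgt = p * (1.0 - p)
        grad = W.T @ (y - p) - ridge * b
        H = (W * wgt[:, None]).T @ W + (ridge + 1e-12) * np.eye(m)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        b_new = b + step
        if not np.isfinite(b_new).all():
            return b, False
        if np.max(np.abs(step)) < tol:
            return b_new, True
        b = b_new
    return b, False


def _detect_separation(W: np.ndarray, y: np.ndarray, b: np.ndarray) -> bool:
    p = expit(W @ b)
    return bool(np.max(np.abs(b[1:])) > 30.0 or np.all((p > 0.5) == (y > 0.5)))


def _terza_sandwich(
    Z: np.ndarray, x: np.ndarray, W: np.ndarray, y: np.ndarray,
    b: np.ndarray, resid_col: int,
) -> np.ndarray:
    """Two-stage M-estimator covariance of the second-stage coefficients.

    Stage-1 moments are the OLS normal equations of the exposure on ``[1,Z]``;
    stage-2 moments are the logistic score of ``y`` on ``W`` whose column
    ``resid_col`` carries the stage-1 residual.  The full sandwich
    ``A^{-1} B A^{-T} / n`` propagates first-stage uncertainty into the
    second stage; the block for the stage-2 coefficients is returned.
    """
    n = x.size
    z1 = np.column_stack([np.ones(n), Z])
    ka = z1.shape[1]
    m = W.shape[1]
    alpha = np.linalg.lstsq(z1, x, rcond=None)[0]
    eps = x - z1 @ alpha
    p = expit(W @ b)
    u = y - p
    wgt = p * (1.0 - p)
    b_r = b[resid_col]

    A = np.zeros((ka + m, ka + m))
    A[:ka, :ka] = z1.T @ z1 / n
    # d g2 / d alpha':  -u_i e_r z_i' + wgt_i b_r W_i z_i'  (negated Jacobian)
    A21 = (wgt * b_r)[:, None, None] * (W[:, :, None] * z1[:, None, :])
    A21[:, resid_col, :] -= u[:, None] * z1
    A[ka:, :ka] = A21.sum(axis=0) / n
    A[ka:, ka:] = (W * wgt[:, None]).T @ W / n

    g = np.concatenate([z1 * eps[:, None], W * u[:, None]], axis=1)  # (n, ka+m)
    B = g.T @ g / n
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv.T / n
    return V[ka:, ka:]


def fit_2sri(inp: MrInput, tag: str = "2sri") -> MrResult:
    """Two-stage residual inclusion for binary outcomes, Terza-robust Wald."""
    y = inp.outcome
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("2SRI requires a binary outcome coded 0/1")
    n, k = inp.instruments.shape
    xhat, ehat, r2, f = _first_stage(inp.exposure, inp.instruments)
    W = np.column_stack([np.ones(n), inp.exposure, ehat])
    b, converged = _logit_fit(W, y)
    flags = []
    if not converged or _detect_separation(W, y, b):
        b, _ = _logit_fit(W, y, ridge=1e-2 * n / 100.0)
        flags.append("separation_ridge")
    V = _terza_sandwich(inp.instruments, inp.exposure, W, y, b, resid_col=2)
    se = float(np.sqrt(max(V[1, 1], 0.0)))
    z = b[1] / se if se > 0 else np.inf * np.sign(b[1] or 1.0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    if r2 < 1e-10:
        flags.append("weak_instruments")
        p = 1.0
    elif f < 10:
        flags.append("weak_instruments")
    return MrResult(
        gene_id=inp.gene_id, estimator=tag, beta=float(b[1]), se_robust=se,
        wald_p=p, first_stage_r2=r2, first_stage_f=f, n=n, n_instruments=k,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# lasso pleiotropy control
# ---------------------------------------------------------------------------

def _cd_quadratic(
    G: np.ndarray, q: np.ndarray, b: np.ndarray, thr: np.ndarray,
    max_sweeps: int = 200, tol: float = 1e-8,
) -> np.ndarray:
    """Penalized coordinate descent on (1/2) b'Gb - q'b + sum_j thr_j |b_j|.

    ``G = X'WX/n`` and ``q = X'Wz/n`` are precomputed Gram quantities;
    ``thr`` carries per-coefficient L1 thresholds (zero = unpenalized).
    """
    m = b.size
    Gb = G @ b
    diag = np.maximum(np.diag(G), 1e-12)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(m):
            r_j = q[j] - Gb[j] + diag[j] * b[j]
            if thr[j] > 0:
                bj = np.sign(r_j) * max(abs(r_j) - thr[j], 0.0) / diag[j]
            else:
                bj = r_j / diag[j]
            d = bj - b[j]
            if d != 0.0:
                Gb += G[:, j] * d
                b[j] = bj
                delta = max(delta, abs(d))
        if delta < tol * max(1.0, float(np.max(np.abs(b)))):
            break
    return b


def _masked_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, penalized: np.ndarray,
    family: str, beta0: np.ndarray | None = None,
    max_outer: int = 30, tol: float = 1e-8,
) -> np.ndarray:
    """Minimize (1/2n)||y-Xb||^2 (or mean logistic deviance) + lam*sum m_j|b_j|.

    Coordinate descent on precomputed Gram matrices; the logistic case wraps
    it in an IRLS loop on the quadratic approximation.  ``penalized`` is a
    boolean mask; unpenalized coefficients (intercept, causal effect,
    residual-inclusion term) are never thresholded.
    """
    n, m = X.shape
    b = np.zeros(m) if beta0 is None else beta0.copy()
    thr = lam * penalized.astype(float)
    if family != "binomial":
        # profile out the unpenalized block analytically: lasso runs on the
        # residualized penalized columns (this also absorbs the exact
        # collinearity of the fitted exposure with the instruments), then
        # the unpenalized coefficients are recovered by least squares
        B = X[:, ~penalized]
        P = X[:, penalized]
        Q, _ = np.linalg.qr(B)
        Pm = P - Q @ (Q.T @ P)
        ym = y - Q @ (Q.T @ y)
        pi = b[penalized].copy()
        pi = _cd_quadratic(Pm.T @ Pm / n, Pm.T @ ym / n, pi,
                           np.full(pi.size, lam), tol=tol)
        b_un = np.linalg.lstsq(B, y - P @ pi, rcond=None)[0]
        b[penalized] = pi
        b[~penalized] = b_un
        return b
    for _ in range(max_outer):
        eta = np.clip(X @ b, -30, 30)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-5)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        G = Xw.T @ X / n
        q = Xw.T @ z / n
        b_old = b.copy()
        b = _cd_quadratic(G, q, b, thr, max_sweeps=50, tol=tol)
        if np.max(np.abs(b - b_old)) < 10 * tol * max(1.0, float(np.max(np.abs(b)))):
            break
    return b


def _second_stage_design(
    inp: MrInput, estimator: str, xhat: np.ndarray, ehat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, str]:
    """Design [1, causal term(s), Z] with penalty mask; returns index of beta."""
    n = inp.exposure.size
    if estimator == "2sls":
        base = np.column_stack([np.ones(n), xhat])
        family = "gaussian"
    elif estimator == "2sri":
        base = np.column_stack([np.ones(n), inp.exposure, ehat])
        family = "binomial"
    else:
        raise ValueError("estimator must be '2sls' or '2sri'")
    X = np.hstack([base, inp.instruments])
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[base.shape[1]:] = True
    return X, mask, 1, family


def _lambda_grid(X: np.ndarray, y: np.ndarray, mask: np.ndarray,
                 family: str, n_lambda: int) -> np.ndarray:
    base = X[:, ~mask]
    if family == "binomial":
        b0, _ = _logit_fit(base, y)
        resid = y - expit(base @ b0)
    else:
        b0 = np.linalg.lstsq(base, y, rcond=None)[0]
        resid = y - base @ b0
    lam_max = float(np.max(np.abs(X[:, mask].T @ resid)) / X.shape[0])
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max * 1.05, lam_max * 1e-3, n_lambda)


def _cv_folds(y: np.ndarray, n_folds: int, family: str,
              rng: np.random.Generator) -> list[np.ndarray]:
    n = y.size
    if family == "binomial":
        folds = [[] for _ in range(n_folds)]
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[j % n_folds].append(i)
        return [np.array(sorted(f)) for f in folds]
    idx = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(idx, n_folds)]


def _refit_design(inp_sub: MrInput, estimator: str) -> tuple[np.ndarray, np.ndarray, str]:
    xhat, ehat, _, _ = _first_stage(inp_sub.exposure, inp_sub.instruments)
    X, mask, _, family = _second_stage_design(inp_sub, estimator, xhat, ehat)
    return X, mask, family


def _apply_design(
    inp: MrInput, rows: np.ndarray, alpha: np.ndarray, estimator: str
) -> np.ndarray:
    """Second-stage design for held-out rows using train-fit stage-1 coefs."""
    Z = inp.instruments[rows]
    x = inp.exposure[rows]
    pred = alpha[0] + Z @ alpha[1:]
    if estimator == "2sls":
        return np.column_stack([np.ones(rows.size), pred, Z])
    return np.column_stack([np.ones(rows.size), x, x - pred, Z])


def _cv_loss(X_test: np.ndarray, y_test: np.ndarray, b: np.ndarray,
             family: str) -> float:
    eta = X_test @ b
    if family == "binomial":
        # mean binomial deviance
        eta = np.clip(eta, -30, 30)
        return float(np.mean(np.log1p(np.exp(eta)) - y_test * eta)) * 2.0
    return float(np.mean((y_test - eta) ** 2))


def fit_lasso_pleiotropy(
    inp: MrInput,
    estimator: str = "2sls",
    n_folds: int = 10,
    n_lambda: int = 20,
    boot_reps: int = 999,
    alpha_ci: float = 0.05,
    rng: np.random.Generator | None = None,
    tag: str | None = None,
) -> MrResult:
    """2SLS/2SRI with L1-penalized direct instrument effects.

    The second stage gains a ``Z @ pi`` term whose coefficients alone are
    penalized; lambda minimizes 10-fold cross-validated MSE (2SLS) or
    deviance (2SRI, outcome-stratified folds) with both stages re-run per
    fold.  The final estimate is refit on all data at the chosen lambda.
    A robust Wald test on the post-selection refit is always reported; when
    ``boot_reps > 0``, individuals are resampled with replacement (both
    stages re-run, lambda fixed) for a percentile CI and a CI-inversion p.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    tag = tag or f"{estimator}_lasso"
    n, k = inp.instruments.shape
    if k < 2:
        logger.info("gene %s: <2 instruments, pleiotropy unidentifiable; plain %s",
                    inp.gene_id, estimator)
        res = fit_2sls(inp, tag=tag) if estimator == "2sls" else fit_2sri(inp, tag=tag)
        res.flags.append("lasso_fallback_plain")
        return res

    X_full, mask, family = _refit_design(inp, estimator)
    beta_ix = 1    # coefficient on the (fitted) exposure in the second stage
    lambdas = _lambda_grid(X_full, inp.outcome, mask, family, n_lambda)
    folds = _cv_folds(inp.outcome, n_folds, family, rng)
    losses = np.zeros((len(folds), lambdas.size))
    for fi, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        sub = MrInput(inp.gene_id, inp.exposure[train], inp.outcome[train],
                      inp.instruments[train], snp_ids=inp.snp_ids)
        X_tr, mask_tr, fam = _refit_design(sub, estimator)
        Z1_tr = np.column_stack([np.ones(train.size), inp.instruments[train]])
        alpha_tr = np.linalg.lstsq(Z1_tr, inp.exposure[train], rcond=None)[0]
        X_te = _apply_design(inp, test, alpha_tr, estimator)
        b = None
        for li, lam in enumerate(lambdas):
            b = _masked_lasso(X_tr, inp.outcome[train], lam, mask_tr, fam, beta0=b)
            losses[fi, li] = _cv_loss(X_te, inp.outcome[test], b, fam)
    mean_loss = losses.mean(axis=0)
    best = int(np.argmin(mean_loss))
    lam_star = float(lambdas[best])
    flags = []
    if best in (0, lambdas.size - 1):
        flags.append("cv_boundary_lambda")

    # full-data fit at lambda*, then post-selection refit for Wald inference
    b_full = None
    for lam in lambdas[: best + 1]:
        b_full = _masked_lasso(X_full, inp.outcome, lam, mask, family, beta0=b_full)
    pi = b_full[mask]
    sel = np.flatnonzero(np.abs(pi) > 1e-8)
    sel_ids = ([inp.snp_ids[j] for j in sel] if inp.snp_ids is not None
               else [f"iv{j}" for j in sel])

    xhat, ehat, r2, f = _first_stage(inp.exposure, inp.instruments)
    Zsel = inp.instruments[:, sel]
    if estimator == "2sls":
        X = np.column_stack([np.ones(n), inp.exposure, Zsel])
        Xh = np.column_stack([np.ones(n), xhat, Zsel])
        coef, V = _iv_sandwich(X, Xh, inp.outcome)
        beta_hat, se = float(coef[1]), float(np.sqrt(max(V[1, 1], 0.0)))
    else:
        W = np.column_stack([np.ones(n), inp.exposure, ehat, Zsel])
        coef, converged = _logit_fit(W, inp.outcome)
        if not converged or _detect_separation(W, inp.outcome, coef):
            coef, _ = _logit_fit(W, inp.outcome, ridge=1e-2 * n / 100.0)
            flags.append("separation_ridge")
        V = _terza_sandwich(inp.instruments, inp.exposure, W, inp.outcome, coef, resid_col=2)
        beta_hat, se = float(coef[1]), float(np.sqrt(max(V[1, 1], 0.0)))
    zstat = beta_hat / se if se > 0 else np.inf * np.sign(beta_hat or 1.0)
    wald_p = float(2.0 * stats.norm.sf(abs(zstat)))
    if f < 10:
        flags.append("weak_instruments")

    boot_ci, boot_p, reps_done = None, None, 0
    if boot_reps > 0:
        betas = np.empty(boot_reps)
        for r in range(boot_reps):
            ix = rng.integers(0, n, size=n)
            sub = MrInput(inp.gene_id, inp.exposure[ix], inp.outcome[ix],
                          inp.instruments[ix], snp_ids=inp.snp_ids)
            try:
                X_b, mask_b, fam = _refit_design(sub, estimator)
                b_b = _masked_lasso(X_b, inp.outcome[ix], lam_star, mask_b, fam,
                                    beta0=b_full)
                betas[r] = b_b[beta_ix]
            except (np.linalg.LinAlgError, ValueError):
                betas[r] = np.nan
        betas = betas[np.isfinite(betas)]
        reps_done = betas.size
        if reps_done >= 10:
            lo, hi = np.percentile(betas, [100 * alpha_ci / 2, 100 * (1 - alpha_ci / 2)])
            boot_ci = (float(lo), float(hi))
            n_le = int(np.sum(betas <= 0.0))
            n_ge = int(np.sum(betas >= 0.0))
            boot_p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (reps_done + 1))

    return MrResult(
        gene_id=inp.gene_id, estimator=tag, beta=beta_hat, se_robust=se,
        wald_p=wald_p, first_stage_r2=r2, first_stage_f=f, n=n,
        n_instruments=k, boot_ci=boot_ci, boot_reps=reps_done, boot_p=boot_p,
        selected_pleiotropy=sel_ids, penalty=lam_star, flags=flags,
    )


# ---------------------------------------------------------------------------
# gene-level ranking
# ---------------------------------------------------------------------------

def rank_genes(results: list[MrResult], alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust across genes and flag putative causal genes (p_adj <= alpha).

    Each gene's ranking p-value is the bootstrap CI-inversion p when a
    bootstrap was run, else the robust Wald p.
    """
    if not results:
        return pd.DataFrame()
    raw = np.array([r.ranking_p for r in results])
    ok = np.isfinite(raw)
    adj = np.full(raw.size, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    rows = []
    for r, a in zip(results, adj):
        r.bh_adjusted_p = float(a) if np.isfinite(a) else None
        rows.append({
            "gene_id": r.gene_id, "estimator": r.estimator, "beta": r.beta,
            "se": r.se_robust, "wald_p": r.wald_p,
            "boot_lo": r.boot_ci[0] if r.boot_ci else np.nan,
            "boot_hi": r.boot_ci[1] if r.boot_ci else np.nan,
            "boot_p": r.boot_p if r.boot_p is not None else np.nan,
            "p": r.ranking_p, "bh_p": a,
            "n_iv": r.n_instruments,
            "f_first_stage": r.first_stage_f,
            "flagged_causal": bool(np.isfinite(a) and a <= alpha),
            "flags": ";".join(r.flags),
        })
    df = pd.DataFrame(rows).sort_values("bh_p", kind="mergesort").reset_index(drop=True)
    return df
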