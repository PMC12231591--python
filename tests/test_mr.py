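"""MR estimators: 2SLS, 2SRI/Terza, masked-penalty lasso, gene ranking."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import Lasso

import tiscmr.mr as M
from tiscmr.mr import (
    MrInput,
    MrResult,
    fit_2sls,
    fit_2sri,
    fit_lasso_pleiotropy,
    rank_genes,
)


def _confounded(seed, n=300, k=5, beta=1.0, binary=False, alpha=0.4,
                pleio=None):
    rg = np.random.default_rng(seed)
    Z = rg.binomial(2, 0.3, (n, k)).astype(float)
    U = rg.normal(0, 1, n)
    x = Z @ np.full(k, alpha) + U + rg.normal(0, 1, n)
    eta = beta * x + U
    if pleio is not None:
        eta = eta + Z @ pleio
    if binary:
        p = 1 / (1 + np.exp(-(eta - eta.mean())))
        y = rg.binomial(1, p).astype(float)
    else:
        y = eta + rg.normal(0, 1, n)
    return MrInput("g", x, y, Z, snp_ids=[f"s{j}" for j in range(k)])


# ---------------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------------

def test_input_validation():
    with pytest.raises(ValueError):
        MrInput("g", np.zeros(5), np.zeros(4), np.zeros((5, 1)))
    with pytest.raises(ValueError):
        fit_2sls(MrInput("g", np.zeros(4), np.zeros(4), np.zeros((4, 3))))


def test_just_identified_equals_wald_ratio():
    rg = np.random.default_rng(0)
    z = rg.binomial(2, 0.4, 200).astype(float)
    x = 0.5 * z + rg.normal(0, 1, 200)
    y = 1.7 * x + rg.normal(0, 1, 200)
    res = fit_2sls(MrInput("g", x, y, z[:, None]))
    wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
    assert abs(res.beta - wald) < 1e-10


def test_noiseless_identification():
    rg = np.random.default_rng(1)
    Z = rg.binomial(2, 0.4, (500, 5)).astype(float)
    x = Z @ rg.normal(0.3, 0.1, 5)
    res = fit_2sls(MrInput("g", x, 3.0 * x, Z))
    assert abs(res.beta - 3.0) < 1e-10


def test_weak_instrument_flagging():
    rg = np.random.default_rng(2)
    Z = rg.binomial(2, 0.4, (200, 3)).astype(float)
    x = rg.normal(0, 1, 200)              # instruments are pure noise
    y = rg.normal(0, 1, 200)
    res = fit_2sls(MrInput("g", x, y, Z))
    assert "weak_instruments" in res.flags
    assert res.first_stage_f < 10


def test_2sls_removes_confounding_bias():
    betas_iv, betas_ols = [], []
    for s in range(30):
        inp = _confounded(100 + s, beta=0.0)
        betas_iv.append(fit_2sls(inp).beta)
        betas_ols.append(sm.OLS(inp.outcome, sm.add_constant(inp.exposure))
                         .fit().params[1])
    assert abs(np.mean(betas_iv)) < 0.1
    assert np.mean(betas_ols) > 0.25       # OLS inherits the confounder


def test_binary_outcome_as_continuous_is_calibrated():
    rej = 0
    for s in range(100):
        inp = _confounded(200 + s, n=400, beta=0.0, alpha=0.5, binary=True)
        rej += fit_2sls(inp).wald_p < 0.05
    assert 0.005 <= rej / 100 <= 0.12


# ---------------------------------------------------------------------------
# 2SRI
# ---------------------------------------------------------------------------

def test_2sri_requires_binary():
    inp = _confounded(3, binary=False)
    with pytest.raises(ValueError):
        fit_2sri(inp)


def test_2sri_matches_logistic_without_confounding():
    """When the residual carries no signal, 2SRI ~ single-stage logistic."""
    rg = np.random.default_rng(4)
    n = 4000
    Z = rg.binomial(2, 0.3, (n, 5)).astype(float)
    x = Z @ np.full(5, 0.5) + rg.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(0.4 * (x - x.mean()))))
    y = rg.binomial(1, p).astype(float)
    res = fit_2sri(MrInput("g", x, y, Z))
    logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert abs(res.beta - logit.params[1]) < 2 * logit.bse[1]


def test_terza_se_close_to_bootstrap():
    inp = _confounded(5, n=400, k=5, beta=0.5, alpha=0.5, binary=True)
    res = fit_2sri(inp)
    rg = np.random.default_rng(99)
    boots = []
    for _ in range(200):
        ix = rg.integers(0, inp.exposure.size, inp.exposure.size)
        b = fit_2sri(MrInput("g", inp.exposure[ix], inp.outcome[ix],
                             inp.instruments[ix]))
        boots.append(b.beta)
    ratio = res.se_robust / np.std(boots, ddof=1)
    assert 0.8 <= ratio <= 1.25


def test_2sri_separation_fallback():
    rg = np.random.default_rng(6)
    Z = rg.binomial(2, 0.3, (80, 2)).astype(float)
    x = rg.normal(0, 1, 80)
    y = (x > 0).astype(float)              # perfectly separable
    res = fit_2sri(MrInput("g", x, y, Z))
    assert "separation_ridge" in res.flags
    assert np.isfinite(res.beta) and np.isfinite(res.wald_p)


# ---------------------------------------------------------------------------
# lasso pleiotropy control
# ---------------------------------------------------------------------------

def test_masked_lasso_matches_sklearn_when_all_penalized():
    rg = np.random.default_rng(7)
    X = rg.normal(size=(150, 6))
    y = X @ np.array([1, 0, 0, 0.5, 0, 0]) + rg.normal(0, 1, 150)
    b = M._masked_lasso(X, y, 0.1, np.ones(6, bool), "gaussian")
    sk = Lasso(alpha=0.1, fit_intercept=False, max_iter=20000,
               tol=1e-12).fit(X, y)
    assert np.abs(b - sk.coef_).max() < 1e-8


def test_masked_lasso_logistic_kkt():
    rg = np.random.default_rng(8)
    X = np.column_stack([np.ones(300), rg.normal(size=(300, 5))])
    eta = X @ np.array([0.2, 1.0, -0.5, 0, 0, 0.3])
    y = rg.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    mask = np.array([False, False] + [True] * 4)
    lam = 0.05
    b = M._masked_lasso(X, y, lam, mask, "binomial")
    p = 1 / (1 + np.exp(-(X @ b)))
    g = X.T @ (p - y) / 300
    assert np.abs(g[~mask]).max() < 1e-6            # unpenalized: stationary
    assert np.abs(g[mask]).max() <= lam + 1e-6      # penalized: KKT bound


def test_lasso_large_penalty_limit_equals_plain():
    inp = _confounded(9, k=6)
    xhat, ehat, *_ = M._first_stage(inp.exposure, inp.instruments)
    X, mask, _, fam = M._second_stage_design(inp, "2sls", xhat, ehat)
    b = M._masked_lasso(X, inp.outcome, 1e8, mask, fam)
    plain = fit_2sls(inp)
    assert abs(b[1] - plain.beta) < 1e-6
    assert np.abs(b[mask]).max() == 0.0


def test_lasso_single_instrument_falls_back():
    inp = _confounded(10, k=1)
    res = fit_lasso_pleiotropy(inp, "2sls", boot_reps=0,
                               rng=np.random.default_rng(0))
    assert "lasso_fallback_plain" in res.flags
    assert abs(res.beta - fit_2sls(inp).beta) < 1e-12


def test_lasso_reduces_pleiotropy_bias():
    better, selected = 0, 0
    for s in range(10):
        pl = np.zeros(8)
        pl[0] = 2.0                        # one invalid instrument
        inp = _confounded(20 + s, k=8, beta=1.0, pleio=pl)
        las = fit_lasso_pleiotropy(inp, "2sls", boot_reps=0,
                                   rng=np.random.default_rng(s))
        plain = fit_2sls(inp)
        better += abs(las.beta - 1.0) < abs(plain.beta - 1.0)
        selected += "s0" in las.selected_pleiotropy
    assert better >= 8 and selected >= 8


def test_lasso_sparse_under_no_pleiotropy():
    """All instruments valid: at most 10% receive a direct-effect term."""
    near_empty = 0
    for s in range(10):
        inp = _confounded(50 + s, k=10, beta=1.0)
        las = fit_lasso_pleiotropy(inp, "2sls", boot_reps=0,
                                   rng=np.random.default_rng(s))
        near_empty += len(las.selected_pleiotropy) <= 1
    assert near_empty >= 9


def test_lasso_bootstrap_inference_and_determinism():
    inp = _confounded(11, n=250, k=5, beta=1.0)
    r1 = fit_lasso_pleiotropy(inp, "2sls", boot_reps=99,
                              rng=np.random.default_rng(42))
    r2 = fit_lasso_pleiotropy(inp, "2sls", boot_reps=99,
                              rng=np.random.default_rng(42))
    assert r1.beta == r2.beta and r1.boot_ci == r2.boot_ci and r1.boot_p == r2.boot_p
    lo, hi = r1.boot_ci
    assert lo < hi and lo <= r1.beta <= hi
    assert r1.boot_p is not None and r1.boot_p <= 0.05   # strong true effect
    assert r1.ranking_p == r1.boot_p


# ---------------------------------------------------------------------------
# gene ranking
# ---------------------------------------------------------------------------

def _result(gene, p):
    return MrResult(gene_id=gene, estimator="pace_linear", beta=1.0,
                    se_robust=0.1, wald_p=p, first_stage_r2=0.5,
                    first_stage_f=50.0, n=100, n_instruments=3)


def test_rank_genes_bh_identity_and_flags():
    assert rank_genes([]).empty
    df = rank_genes([_result("g1", 0.03)], alpha=0.05)
    assert df["flagged_causal"].iloc[0] and np.isclose(df["bh_p"].iloc[0], 0.03)
    df_null = rank_genes([_result(f"g{i}", 1.0) for i in range(10)])
    assert not df_null["flagged_causal"].any()
    mixed = rank_genes([_result("a", 0.001), _result("b", 0.5),
                        _result("c", 0.04)], alpha=0.05)
    assert list(mixed["gene_id"][:1]) == ["a"]
    assert (mixed["bh_p"].to_numpy() >= mixed["p"].to_numpy() - 1e-12).all()
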