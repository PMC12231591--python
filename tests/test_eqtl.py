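"""sc-eQTL mapping: designs, batched OLS, FDR adjustment, LD clumping."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tiscmr.eqtl import (
    _batched_ols,
    _greedy_clump,
    adjust_and_clump,
    build_samples,
    map_eqtl,
    test_snp_gene as snp_gene_test,
)
from tiscmr.pace import compute_offsets, normalize_counts
from tiscmr.simulate import GenotypeMatrix


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_build_samples_avg_is_per_individual_mean(tiny_data):
    geno, cells, _ = tiny_data
    design = build_samples("avg_eqtl", cells=cells, genotypes=geno)
    assert design.n_rows == geno.n_individuals
    vals, kept = normalize_counts(cells)
    gene0 = cells.gene_ids[0]
    first = cells.cell_meta["individual_id"] == design.response.index[0]
    assert np.isclose(design.response[gene0].iloc[0],
                      vals[first.to_numpy(), 0].mean())


def test_build_samples_pseudo_individual_rows(tiny_data):
    geno, cells, _ = tiny_data
    agg = build_samples("agg_eqtl", cells=cells, genotypes=geno,
                        n_intervals=20, t_max=20.0)
    dyn = build_samples("dyn_eqtl", cells=cells, genotypes=geno,
                        n_intervals=20, t_max=20.0)
    assert geno.n_individuals <= agg.n_rows <= geno.n_individuals * 20
    assert agg.pseudotime is not None
    # dyn adds exactly one covariate (pseudotime) to the agg design
    assert dyn.n_rows == agg.n_rows
    assert map_eqtl(dyn, geno).df.shape == map_eqtl(agg, geno).df.shape


def test_build_samples_cum_requires_offsets(tiny_data):
    geno, cells, _ = tiny_data
    with pytest.raises(ValueError):
        build_samples("cum_eqtl", cells=cells, genotypes=geno)
    with pytest.raises(ValueError):
        build_samples("bogus", cells=cells, genotypes=geno)


def test_covariates_rejected_for_pseudo_strategies(tiny_data):
    geno, cells, _ = tiny_data
    design = build_samples("agg_eqtl", cells=cells, genotypes=geno, t_max=20.0)
    with pytest.raises(ValueError):
        map_eqtl(design, geno, covariates=np.ones((design.n_rows, 1)))


# ---------------------------------------------------------------------------
# association engine
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("with_t,interaction", [
    (False, False), (True, False), (True, True),
])
def test_single_pair_matches_statsmodels(with_t, interaction):
    rng = np.random.default_rng(5)
    n = 80
    z = rng.binomial(2, 0.4, n).astype(float)
    t = rng.uniform(0, 20, n)
    y = 0.5 * z + 0.2 * t - 0.03 * z * t + rng.normal(0, 1, n)
    row = snp_gene_test(y, z, pseudotime=t if with_t else None,
                        test_interaction=interaction)
    cols = [t, z, z * t] if interaction else ([t, z] if with_t else [z])
    ref = sm.OLS(y, sm.add_constant(np.column_stack(cols))).fit()
    assert np.isclose(row["beta"], ref.params[len(cols)])
    assert np.isclose(row["se"], ref.bse[len(cols)])
    assert np.isclose(row["p_value"], ref.pvalues[len(cols)])


def test_single_pair_edge_cases():
    z = np.ones(10)
    assert snp_gene_test(np.arange(10.0), z)["zero_variance"]
    row = snp_gene_test(2 * np.array([0, 1, 2, 0, 1, 2.0]),
                        np.array([0, 1, 2, 0, 1, 2.0]))
    assert np.isclose(row["beta"], 2.0) and row["p_value"] < 1e-10
    with pytest.raises(ValueError):
        snp_gene_test(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


def test_batched_engine_agrees_with_per_pair_loop():
    rng = np.random.default_rng(6)
    n, P, G = 60, 7, 4
    Z = rng.binomial(2, 0.3, (n, P)).astype(float)
    Y = rng.normal(size=(n, G))
    t = rng.uniform(0, 10, n)
    shared = np.column_stack([np.ones(n), t])
    beta, se, tstat, df = _batched_ols(Y, Z, shared, interaction_t=t,
                                       test_interaction=True)
    for p in range(P):
        for g in range(G):
            ref = sm.OLS(Y[:, g], sm.add_constant(
                np.column_stack([t, Z[:, p], Z[:, p] * t]))).fit()
            assert np.isclose(beta[p, g], ref.params[3], atol=1e-10)
            assert np.isclose(se[p, g], ref.bse[3], atol=1e-10)


def test_null_pvalues_uniform():
    """Independent responses: per-pair OLS p-values are U(0,1)."""
    rng = np.random.default_rng(7)
    n, P, G = 200, 100, 100
    Z = rng.binomial(2, 0.4, (n, P)).astype(float)
    Y = rng.normal(size=(n, G))
    beta, se, tstat, df = _batched_ols(Y, Z, np.ones((n, 1)), None, False)
    p = 2 * stats.t.sf(np.abs(tstat), df).ravel()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_interaction_null_uniform_on_independent_rows():
    """With truly independent rows the interaction test is calibrated."""
    rng = np.random.default_rng(8)
    n, P, G = 300, 60, 60
    Z = rng.binomial(2, 0.4, (n, P)).astype(float)
    t = rng.uniform(0, 20, n)
    Y = (0.3 * Z[:, :G] + 0.1 * t[:, None] + rng.normal(size=(n, G)))
    shared = np.column_stack([np.ones(n), t])
    beta, se, tstat, df = _batched_ols(Y, Z, shared, interaction_t=t,
                                       test_interaction=True)
    p = 2 * stats.t.sf(np.abs(tstat), df).ravel()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_zero_variance_snp_flagged(tiny_data):
    geno, cells, _ = tiny_data
    geno2 = GenotypeMatrix(geno.dosages.copy(), list(geno.snp_ids),
                           geno.allele_freqs.copy(),
                           list(geno.individual_ids))
    geno2.dosages[:, 0] = 1
    design = build_samples("avg_eqtl", cells=cells, genotypes=geno2)
    table = map_eqtl(design, geno2)
    sub = table.df[table.df["snp_id"] == geno2.snp_ids[0]]
    assert sub["p_value"].isna().all() and sub["zero_variance"].all()


# ---------------------------------------------------------------------------
# FDR + clumping
# ---------------------------------------------------------------------------

def test_bh_adjustment_monotone(tiny_data):
    geno, cells, _ = tiny_data
    design = build_samples("avg_eqtl", cells=cells, genotypes=geno)
    table = map_eqtl(design, geno)
    adjust_and_clump(table, geno)
    df = table.df.dropna(subset=["p_value"]).sort_values("p_value")
    assert (df["fdr_adjusted_p"].to_numpy() >= df["p_value"].to_numpy() - 1e-12).all()
    assert (np.diff(df["fdr_adjusted_p"].cummin().to_numpy()[::-1]) <= 1e-12).all()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), n_snps=st.integers(2, 12),
       r2_cut=st.floats(0.05, 0.9))
def test_clump_invariant_pairwise_r2(seed, n_snps, r2_cut):
    """Whatever the input, retained SNPs are mutually below the r^2 cutoff
    and the best-ranked SNP always survives."""
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, n_snps), (60, n_snps))
    # duplicate a column sometimes to create perfect LD
    if n_snps >= 2 and seed % 3 == 0:
        dos[:, 1] = dos[:, 0]
    keep = _greedy_clump(np.arange(n_snps), dos, r2_cut)
    assert keep[0] == 0
    Z = dos[:, keep].astype(float)
    sd = Z.std(axis=0)
    Z = Z[:, sd > 0]
    if Z.shape[1] > 1:
        r2 = np.corrcoef(Z.T) ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() <= r2_cut + 1e-9


def test_clump_duplicated_snps_keep_one():
    rng = np.random.default_rng(9)
    dos = rng.binomial(2, 0.4, (100, 3)).astype(np.int8)
    dos[:, 1] = dos[:, 0]                 # perfect LD
    keep = _greedy_clump(np.array([0, 1, 2]), dos, r2_cut=0.1)
    assert 0 in keep and 1 not in keep


def test_clump_independent_loci_identity(tiny_data):
    """With independent simulated loci clumping should retain everything."""
    geno, cells, truth = tiny_data
    off = compute_offsets(cells, t_max=20.0)
    design = build_samples("cum_eqtl", genotypes=geno, offsets=off)
    table = map_eqtl(design, geno)
    ivs = adjust_and_clump(table, geno, fdr_cut=0.05, r2_cut=0.1)
    sig = table.df[table.df["fdr_adjusted_p"] < 0.05]
    n_sig = sig.groupby("gene_id").size()
    for gene, s in ivs.items():
        Z = geno.dosages[:, s.snp_idx].astype(float)
        if Z.shape[1] > 1:
            r2 = np.corrcoef(Z.T) ** 2
            np.fill_diagonal(r2, 0)
            assert r2.max() <= 0.1 + 1e-12
        # independent loci: rarely anything dropped
        assert len(s.snp_ids) >= 0.9 * n_sig[gene]
        assert (s.f_stats >= 0).all() and s.weak is not None


def test_all_null_pvalues_give_empty_sets():
    dos = np.random.default_rng(1).binomial(2, 0.4, (50, 4)).astype(np.int8)
    geno = GenotypeMatrix(dos, [f"s{i}" for i in range(4)], np.full(4, 0.4))
    df = pd.DataFrame({
        "snp_id": ["s0", "s1", "s2", "s3"],
        "gene_id": ["g"] * 4,
        "beta": 0.0, "se": 1.0, "statistic": 0.0, "p_value": 1.0,
        "strategy": "avg_eqtl", "n_samples": 50,
    })
    from tiscmr.eqtl import EqtlTable
    ivs = adjust_and_clump(EqtlTable(df, "avg_eqtl", 50), geno)
    assert ivs == {}
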