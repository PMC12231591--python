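"""sc-eQTL mapping with temporal information.

Five mapping strategies turn single-cell expression plus pseudotime into
per-sample design tables and test each SNP-gene pair by ordinary least
squares:

- ``avg_eqtl``:  one sample per individual, response = mean normalized
  expression over the individual's cells.
- ``cum_eqtl``:  one sample per individual, response = the PACE
  time-cumulative offset.
- ``agg_eqtl``:  one sample per (individual, nonempty pseudotime interval)
  "pseudo-individual", response = interval mean.
- ``dyn_eqtl``:  as ``agg_eqtl`` with the interval midpoint pseudotime as a
  covariate.
- ``int_eqtl``:  as ``dyn_eqtl`` but the reported test is on the
  genotype x pseudotime interaction coefficient.

Significant pairs (Benjamini-Hochberg FDR across all tests of a run) are
LD-clumped per gene (greedy, dropping SNPs with dosage r^2 above the cutoff
to a retained SNP) to form instrument sets for MR; per-SNP first-stage F
statistics are recorded and weak instruments (F < 10) flagged but kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pace import _bin_edges, normalize_counts
from .simulate import CellExpressionDataset, GenotypeMatrix

__all__ = [
    "STRATEGIES",
    "DesignTable",
    "EqtlTable",
    "InstrumentSet",
    "build_samples",
    "map_eqtl",
    "test_snp_gene",
    "adjust_and_clump",
]

logger = logging.getLogger("tiscmr.eqtl")

STRATEGIES = ("avg_eqtl", "cum_eqtl", "agg_eqtl", "dyn_eqtl", "int_eqtl")
_PSEUDO = ("agg_eqtl", "dyn_eqtl", "int_eqtl")


@dataclass
class DesignTable:
    """Per-strategy analysis samples: responses, row->individual map, covariates."""

    strategy: str
    response: pd.DataFrame         # rows = samples, columns = gene ids
    individual_index: np.ndarray   # (n_rows,) index into the genotype matrix
    pseudotime: np.ndarray | None = None   # interval midpoints (dyn/int)

    @property
    def n_rows(self) -> int:
        return self.response.shape[0]


@dataclass
class EqtlTable:
    """Long-format association results, one row per tested SNP-gene pair."""

    df: pd.DataFrame               # snp_id, gene_id, beta, se, statistic,
    strategy: str                  # p_value [, fdr_adjusted_p]
    n_samples: int


@dataclass
class InstrumentSet:
    """Clumped significant SNPs for one gene, ordered by ascending p."""

    gene_id: str
    snp_ids: list[str]
    snp_idx: np.ndarray
    p_values: np.ndarray
    f_stats: np.ndarray
    selection_thresholds: dict = field(default_factory=dict)
    weak: np.ndarray | None = None         # F < 10 flags, aligned with snp_ids


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_samples(
    strategy: str,
    cells: CellExpressionDataset | None = None,
    genotypes: GenotypeMatrix | None = None,
    offsets: pd.DataFrame | None = None,
    n_intervals: int | None = None,
    t_max: float | None = None,
) -> DesignTable:
    """Build the per-strategy design table of responses and covariates."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if genotypes is None:
        raise ValueError("genotypes are required")
    ind_lookup = {iid: i for i, iid in enumerate(genotypes.individual_ids)}

    if strategy == "cum_eqtl":
        if offsets is None:
            raise ValueError("cum_eqtl requires a PACE offsets matrix")
        idx = np.array([ind_lookup[i] for i in offsets.index])
        return DesignTable(strategy, offsets.copy(), idx)

    if cells is None:
        raise ValueError(f"{strategy} requires the cell-level dataset")
    values, kept = normalize_counts(cells)
    gene_ids = [g for g, k in zip(cells.gene_ids, kept) if k]
    values = values[:, kept]
    meta = cells.cell_meta
    t = meta["pseudotime"].to_numpy()

    if strategy == "avg_eqtl":
        rows, ids = [], []
        for ind_id, sel in meta.groupby("individual_id", sort=True).indices.items():
            rows.append(values[sel].mean(axis=0))
            ids.append(str(ind_id))
        resp = pd.DataFrame(np.vstack(rows), index=ids, columns=gene_ids)
        idx = np.array([ind_lookup[i] for i in ids])
        return DesignTable(strategy, resp, idx)

    # pseudo-individual strategies: (individual, nonempty interval) rows
    if t_max is None:
        t_max = float(np.ceil(t.max()))
    if n_intervals is None:
        n_intervals = int(round(t_max))
    edges = _bin_edges(n_intervals, t_max)
    mids = 0.5 * (edges[:-1] + edges[1:])
    bins = np.clip(np.digitize(t, edges) - 1, 0, n_intervals - 1)
    rows, idx, pt, row_ids = [], [], [], []
    for ind_id, sel in meta.groupby("individual_id", sort=True).indices.items():
        bi = bins[sel]
        for b in np.unique(bi):
            rows.append(values[sel[bi == b]].mean(axis=0))
            idx.append(ind_lookup[str(ind_id)])
            pt.append(mids[b])
            row_ids.append(f"{ind_id}:bin{b}")
    resp = pd.DataFrame(np.vstack(rows), index=row_ids, columns=gene_ids)
    return DesignTable(strategy, resp, np.asarray(idx), np.asarray(pt))


# ---------------------------------------------------------------------------
# batched OLS association engine
# ---------------------------------------------------------------------------

def _batched_ols(
    Y: np.ndarray,
    Z: np.ndarray,
    shared: np.ndarray,
    interaction_t: np.ndarray | None,
    test_interaction: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of each column of Y on [shared, Z_p (, Z_p*t)] for every SNP p.

    Returns (beta, se, tstat) arrays of shape (P, G) for the tested
    coefficient (the SNP main effect, or the interaction when requested),
    plus the residual degrees of freedom.  Implemented through cross-product
    matrices so cost is a handful of (n x P) x (n x G) matmuls.
    """
    n, G = Y.shape
    P = Z.shape[1]
    c = shared.shape[1]
    ZT = Z * interaction_t[:, None] if test_interaction else None
    k = c + 1 + (1 if test_interaction else 0)
    df = n - k

    CtC = shared.T @ shared                     # (c, c)
    CtY = shared.T @ Y                          # (c, G)
    CtZ = shared.T @ Z                          # (c, P)
    ZtY = Z.T @ Y                               # (P, G)
    Zsq = (Z**2).sum(axis=0)                    # (P,)
    yty = (Y**2).sum(axis=0)                    # (G,)

    A = np.zeros((P, k, k))
    A[:, :c, :c] = CtC[None]
    A[:, :c, c] = CtZ.T
    A[:, c, :c] = CtZ.T
    A[:, c, c] = Zsq
    b = np.zeros((k, P, G))
    b[:c] = np.broadcast_to(CtY[:, None, :], (c, P, G))
    b[c] = ZtY

    if test_interaction:
        CtZT = shared.T @ ZT                    # (c, P)
        ZtZT = (Z * ZT).sum(axis=0)             # (P,)
        ZTsq = (ZT**2).sum(axis=0)
        ZTtY = ZT.T @ Y                         # (P, G)
        A[:, :c, c + 1] = CtZT.T
        A[:, c + 1, :c] = CtZT.T
        A[:, c, c + 1] = ZtZT
        A[:, c + 1, c] = ZtZT
        A[:, c + 1, c + 1] = ZTsq
        b[c + 1] = ZTtY
        jtest = c + 1
    else:
        jtest = c

    dets = np.linalg.det(A)
    scale = np.maximum(np.trace(A, axis1=1, axis2=2) / k, 1e-300) ** k
    valid = dets > 1e-10 * scale
    beta = np.full((P, G), np.nan)
    se = np.full((P, G), np.nan)
    tstat = np.full((P, G), np.nan)
    if valid.any():
        Ainv = np.linalg.inv(A[valid])
        bv = b[:, valid, :]                      # (k, Pv, G)
        B = np.einsum("pjm,mpg->jpg", Ainv, bv)  # coefficients (k, Pv, G)
        sse = yty[None, :] - np.einsum("jpg,jpg->pg", B, bv)
        sse = np.maximum(sse, 0.0)
        var = sse / max(df, 1) * Ainv[:, jtest, jtest][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            se_v = np.sqrt(var)
            t_v = B[jtest] / se_v
        beta[valid] = B[jtest]
        se[valid] = se_v
        tstat[valid] = t_v
    return beta, se, tstat, df


def map_eqtl(
    design: DesignTable,
    genotypes: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> EqtlTable:
    """Test every SNP-gene pair under the design's strategy.

    ``covariates`` (per-individual, e.g. genotype PCs) are supported for the
    one-row-per-individual strategies only; splitting an individual's cells
    across pseudo-individual rows makes individual-level covariates collinear
    with genotype.
    """
    Y = design.response.to_numpy(dtype=float)
    Z = genotypes.dosages[design.individual_index].astype(float)
    n = Y.shape[0]
    shared_cols = [np.ones((n, 1))]
    if design.strategy in ("dyn_eqtl", "int_eqtl"):
        shared_cols.append(design.pseudotime[:, None])
    if covariates is not None:
        if design.strategy in _PSEUDO:
            raise ValueError(
                "individual-level covariates are not supported for "
                "pseudo-individual strategies (collinearity)"
            )
        shared_cols.append(np.asarray(covariates, dtype=float))
    shared = np.hstack(shared_cols)

    zero_var = Z.std(axis=0) == 0
    beta, se, tstat, df = _batched_ols(
        Y, Z, shared,
        interaction_t=design.pseudotime if design.strategy == "int_eqtl" else None,
        test_interaction=design.strategy == "int_eqtl",
    )
    beta[zero_var] = np.nan
    se[zero_var] = np.nan
    tstat[zero_var] = np.nan
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)

    P, G = beta.shape
    df_out = pd.DataFrame({
        "snp_id": np.repeat(genotypes.snp_ids, G),
        "gene_id": np.tile(design.response.columns.to_numpy(), P),
        "beta": beta.ravel(),
        "se": se.ravel(),
        "statistic": tstat.ravel(),
        "p_value": pval.ravel(),
        "strategy": design.strategy,
        "n_samples": n,
    })
    if zero_var.any():
        df_out["zero_variance"] = np.repeat(zero_var, G)
        logger.warning("%d SNPs have zero dosage variance; rows flagged NA", int(zero_var.sum()))
    return EqtlTable(df=df_out, strategy=design.strategy, n_samples=n)


def test_snp_gene(
    response: np.ndarray,
    dosage: np.ndarray,
    pseudotime: np.ndarray | None = None,
    test_interaction: bool = False,
) -> dict:
    """Single SNP-gene OLS test (same engine as :func:`map_eqtl`)."""
    response = np.asarray(response, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if response.size < 3:
        raise ValueError("need at least 3 samples")
    if dosage.std() == 0:
        return {"beta": np.nan, "se": np.nan, "statistic": np.nan,
                "p_value": np.nan, "zero_variance": True}
    n = response.size
    shared = np.ones((n, 1))
    if pseudotime is not None:
        shared = np.hstack([shared, np.asarray(pseudotime, dtype=float)[:, None]])
    beta, se, tstat, df = _batched_ols(
        response[:, None], dosage[:, None], shared,
        interaction_t=np.asarray(pseudotime, dtype=float) if test_interaction else None,
        test_interaction=test_interaction,
    )
    p = 2.0 * stats.t.sf(abs(float(tstat[0, 0])), df)
    return {"beta": float(beta[0, 0]), "se": float(se[0, 0]),
            "statistic": float(tstat[0, 0]), "p_value": float(p),
            "zero_variance": False}


# ---------------------------------------------------------------------------
# FDR adjustment and LD clumping
# ---------------------------------------------------------------------------

def _greedy_clump(
    snp_idx: np.ndarray, dosages: np.ndarray, r2_cut: float
) -> np.ndarray:
    """Keep best-p SNP, drop correlated (r^2 > cutoff), repeat.

    ``snp_idx`` must be sorted by ascending p.  Returns kept positions into
    ``snp_idx``.
    """
    if snp_idx.size <= 1:
        return np.arange(snp_idx.size)
    X = dosages[:, snp_idx].astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = (X - X.mean(axis=0)) / sd
    corr2 = (Xc.T @ Xc / X.shape[0]) ** 2
    kept: list[int] = []
    alive = np.ones(snp_idx.size, dtype=bool)
    for j in range(snp_idx.size):
        if not alive[j]:
            continue
        kept.append(j)
        alive &= corr2[j] <= r2_cut
        alive[j] = False
    return np.array(kept, dtype=int)


def adjust_and_clump(
    table: EqtlTable,
    genotypes: GenotypeMatrix,
    fdr_cut: float = 0.05,
    r2_cut: float = 0.1,
    p_cut: float | None = None,
) -> dict[str, InstrumentSet]:
    """BH-adjust across all tested pairs, then clump per gene.

    Selection uses BH FDR < ``fdr_cut``; passing ``p_cut`` switches to a raw
    p-value threshold (the rule used for cis-eQTL instrument selection on
    real data).  Adds an ``fdr_adjusted_p`` column to the table in place.
    """
    df = table.df
    ok = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["fdr_adjusted_p"] = adj

    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    out: dict[str, InstrumentSet] = {}
    sig = df[df["p_value"] < p_cut] if p_cut is not None else df[df["fdr_adjusted_p"] < fdr_cut]
    thresholds = {"r2_cut": r2_cut}
    thresholds |= {"p_cut": p_cut} if p_cut is not None else {"fdr_cut": fdr_cut}
    for gene_id, sub in sig.groupby("gene_id", sort=True):
        sub = sub.sort_values("p_value", kind="mergesort")
        idx = np.array([snp_pos[s] for s in sub["snp_id"]])
        keep = _greedy_clump(idx, genotypes.dosages, r2_cut)
        f_stats = sub["statistic"].to_numpy()[keep] ** 2
        out[str(gene_id)] = InstrumentSet(
            gene_id=str(gene_id),
            snp_ids=[sub["snp_id"].iloc[j] for j in keep],
            snp_idx=idx[keep],
            p_values=sub["p_value"].to_numpy()[keep],
            f_stats=f_stats,
            selection_thresholds=thresholds,
            weak=f_stats < 10.0,
        )
    n_empty = df["gene_id"].nunique() - len(out)
    if n_empty:
        logger.info("%d genes have no significant instruments and will be skipped", n_empty)
    return out
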