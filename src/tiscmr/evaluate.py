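"""End-to-end orchestration and evaluation against simulation truth.

``analyze`` runs the method on a dataset (normalize -> PACE offsets ->
sc-eQTL mapping -> instrument selection -> MR -> gene ranking);
``run_pipeline`` wraps it around the simulator and scores the output against
ground truth (SNP-gene precision/recall, gene-level FDR/power, QQ
diagnostics); ``run_experiment`` repeats scenarios over seeded replicates
and aggregates means with standard errors.

Scoring conventions: a discovery is a SNP-gene pair with BH-adjusted
p below the threshold; precision (true discovery rate) is the fraction of
discoveries with a simulated effect (NA when there are no discoveries) and
recall the fraction of true pairs discovered.  Gene-level FDR and power are
the analogous quantities for flagged putative causal genes.  The genomic
inflation factor is the ratio of the median observed 1-df chi-square
statistic to its theoretical median.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import EqtlTable, InstrumentSet, adjust_and_clump, build_samples, map_eqtl
from .mr import MrInput, MrResult, fit_2sls, fit_2sri, fit_lasso_pleiotropy, rank_genes
from .pace import compute_offsets
from .simulate import (
    CellExpressionDataset,
    GenotypeMatrix,
    SimConfig,
    SimTruth,
    simulate_dataset,
)

__all__ = [
    "desk_config",
    "score_eqtl",
    "score_genes",
    "qq_data",
    "analyze",
    "run_pipeline",
    "run_experiment",
    "EvalReport",
    "ESTIMATORS",
]

logger = logging.getLogger("tiscmr.evaluate")

ESTIMATORS = (
    "avg_linear", "pace_linear", "avg_linear_lasso", "pace_linear_lasso",
    "avg_logit", "pace_logit", "avg_logit_lasso", "pace_logit_lasso",
)


def desk_config(**overrides: Any) -> SimConfig:
    """Reduced-scale study design: 200 individuals, 50 genes, 2 000 SNPs.

    Same qualitative contrasts as the full design at a fraction of the cost;
    the full scale remains available through :class:`SimConfig` defaults.
    """
    base = dict(
        n_individuals=200, n_snps=2000, n_genes=50,
        cells_per_individual_range=(80, 140), n_causal_genes=10,
        n_pleiotropic_snps=50,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _pair_sets(table: EqtlTable, threshold: float) -> set[tuple[str, str]]:
    df = table.df
    sig = df[df["fdr_adjusted_p"] < threshold]
    return set(zip(sig["snp_id"], sig["gene_id"]))


def _truth_pair_ids(truth: SimTruth, genotypes: GenotypeMatrix,
                    gene_ids: list[str]) -> set[tuple[str, str]]:
    return {
        (genotypes.snp_ids[p], gene_ids[g])
        for (p, g) in truth.true_snp_gene_pairs
    }


def score_eqtl(
    table: EqtlTable,
    truth: SimTruth,
    genotypes: GenotypeMatrix,
    gene_ids: list[str],
    threshold: float = 0.05,
    proxy_r2: float | None = None,
) -> dict[str, float]:
    """Precision (TDR) and recall of true SNP-gene pair detection.

    Requires ``fdr_adjusted_p`` (run :func:`tiscmr.eqtl.adjust_and_clump`
    first).  Precision is NaN when nothing is discovered.  With
    ``proxy_r2`` set, a discovered SNP in LD (dosage r^2 above the cutoff)
    with any true SNP of the same gene also counts as a true discovery
    (``precision_proxy``); with independent simulated loci the two
    conventions coincide.
    """
    if "fdr_adjusted_p" not in table.df:
        raise ValueError("table lacks fdr_adjusted_p; run adjust_and_clump first")
    truth_pairs = _truth_pair_ids(truth, genotypes, gene_ids)
    disc = _pair_sets(table, threshold)
    n_true_disc = len(disc & truth_pairs)
    precision = n_true_disc / len(disc) if disc else np.nan
    recall = n_true_disc / len(truth_pairs) if truth_pairs else np.nan
    out = {"precision": precision, "recall": recall,
           "n_discoveries": float(len(disc))}
    if proxy_r2 is not None and disc:
        snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        Zf = genotypes.dosages.astype(float)
        n_proxy_true = 0
        for snp, gene in disc:
            if (snp, gene) in truth_pairs:
                n_proxy_true += 1
                continue
            g = gene_pos[gene]
            true_snps = truth.effects.assignments[g]
            if true_snps.size == 0:
                continue
            z = Zf[:, snp_pos[snp]]
            if z.std() == 0:
                continue
            r = np.corrcoef(np.column_stack([z[:, None], Zf[:, true_snps]]).T)[0, 1:]
            if np.nanmax(r**2) > proxy_r2:
                n_proxy_true += 1
        out["precision_proxy"] = n_proxy_true / len(disc)
    return out


def score_genes(
    ranked: pd.DataFrame, truth: SimTruth, gene_ids: list[str], alpha: float = 0.05
) -> dict[str, float]:
    """Gene-level FDR and power of causal-gene detection."""
    causal = {gene_ids[g] for g in np.atleast_1d(truth.causal_genes)}
    if ranked.empty:
        return {"fdr": 0.0, "power": 0.0 if causal else np.nan, "n_flagged": 0.0}
    flagged = set(ranked.loc[ranked["flagged_causal"], "gene_id"])
    true_flags = len(flagged & causal)
    fdr = (len(flagged) - true_flags) / max(1, len(flagged))
    power = true_flags / len(causal) if causal else np.nan
    return {"fdr": fdr, "power": power, "n_flagged": float(len(flagged))}


def qq_data(pvalues: np.ndarray) -> dict[str, Any]:
    """QQ series (-log10 expected vs observed) and genomic inflation factor."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    clamped = p <= 0
    if clamped.any():
        logger.warning("%d zero p-values clamped to machine minimum", int(clamped.sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    observed = -np.log10(np.sort(p))                 # i-th smallest p
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    chi2 = stats.chi2.isf(p, df=1)
    inflation = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    return {
        "expected": expected, "observed": observed,
        "inflation_factor": inflation, "n": m,
        "clamped": bool(clamped.any()),
    }


def null_pair_pvalues(table: EqtlTable, truth: SimTruth,
                      genotypes: GenotypeMatrix, gene_ids: list[str]) -> np.ndarray:
    """p-values of pairs with no simulated effect (for calibration checks)."""
    truth_pairs = _truth_pair_ids(truth, genotypes, gene_ids)
    df = table.df
    is_true = [
        (s, g) in truth_pairs for s, g in zip(df["snp_id"], df["gene_id"])
    ]
    p = df.loc[~np.asarray(is_true), "p_value"].to_numpy()
    return p[np.isfinite(p)]


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

def _parse_estimator(tag: str) -> tuple[str, str, bool]:
    """tag -> (exposure source, base estimator, lasso?)."""
    if tag not in ESTIMATORS:
        raise ValueError(f"unknown estimator {tag!r}")
    parts = tag.split("_")
    source = parts[0]                                   # avg | pace
    base = "2sls" if parts[1] == "linear" else "2sri"
    return source, base, tag.endswith("_lasso")


def analyze(
    genotypes: GenotypeMatrix,
    cells: CellExpressionDataset,
    phenotype: np.ndarray,
    strategies: Iterable[str] = ("avg_eqtl", "cum_eqtl"),
    estimators: Iterable[str] = ("pace_linear",),
    n_intervals: int | None = None,
    t_max: float | None = None,
    fve_threshold: float = 0.99,
    fdr_cut: float = 0.05,
    r2_cut: float = 0.1,
    instruments_from: str = "cum_eqtl",
    mr_alpha: float = 0.05,
    boot_reps: int = 0,
    seed: int = 0,
) -> dict[str, Any]:
    """Offsets -> eQTL mapping -> instruments -> MR on one dataset.

    Returns a dict with the offsets matrix, per-strategy adjusted eQTL
    tables, instrument sets (from ``instruments_from``), per-estimator
    MR result lists and ranked gene tables.
    """
    strategies = list(dict.fromkeys(list(strategies) + [instruments_from]))
    estimators = list(estimators)
    rng = np.random.default_rng(seed)
    offsets = compute_offsets(
        cells, n_intervals=n_intervals, fve_threshold=fve_threshold, t_max=t_max
    )
    tables: dict[str, EqtlTable] = {}
    instrument_sets: dict[str, dict[str, InstrumentSet]] = {}
    for strat in strategies:
        design = build_samples(
            strat, cells=cells, genotypes=genotypes, offsets=offsets,
            n_intervals=n_intervals, t_max=t_max,
        )
        table = map_eqtl(design, genotypes)
        instrument_sets[strat] = adjust_and_clump(
            table, genotypes, fdr_cut=fdr_cut, r2_cut=r2_cut
        )
        tables[strat] = table

    ivs = instrument_sets[instruments_from]
    avg_design = None
    if any(_parse_estimator(t)[0] == "avg" for t in estimators):
        avg_design = build_samples("avg_eqtl", cells=cells, genotypes=genotypes)
        avg_resp = avg_design.response.reindex(genotypes.individual_ids)

    y = np.asarray(phenotype, dtype=float)
    offsets_aligned = offsets.reindex(genotypes.individual_ids)
    mr_results: dict[str, list[MrResult]] = {t: [] for t in estimators}
    for gene_id, iv in ivs.items():
        Z = genotypes.dosages[:, iv.snp_idx].astype(float)
        if Z.shape[1] >= len(y) - 2:
            logger.warning("gene %s: more instruments than df allow; skipped", gene_id)
            continue
        for tag in estimators:
            source, base, lasso = _parse_estimator(tag)
            if source == "pace":
                if gene_id not in offsets_aligned.columns:
                    continue
                expo = offsets_aligned[gene_id].to_numpy()
            else:
                if gene_id not in avg_resp.columns:
                    continue
                expo = avg_resp[gene_id].to_numpy()
            inp = MrInput(gene_id, expo, y, Z, snp_ids=iv.snp_ids)
            try:
                if lasso:
                    res = fit_lasso_pleiotropy(
                        inp, estimator=base, boot_reps=boot_reps,
                        rng=np.random.default_rng(rng.integers(2**31)), tag=tag,
                    )
                elif base == "2sls":
                    res = fit_2sls(inp, tag=tag)
                else:
                    res = fit_2sri(inp, tag=tag)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("gene %s estimator %s failed: %s", gene_id, tag, exc)
                continue
            mr_results[tag].append(res)

    ranked = {tag: rank_genes(res, alpha=mr_alpha) for tag, res in mr_results.items()}
    return {
        "offsets": offsets,
        "eqtl_tables": tables,
        "instrument_sets": instrument_sets,
        "mr_results": mr_results,
        "ranked": ranked,
    }


def run_pipeline(
    config: SimConfig,
    seed: int | None = None,
    strategies: Iterable[str] = ("avg_eqtl", "cum_eqtl"),
    estimators: Iterable[str] = (),
    eqtl_threshold: float = 0.05,
    mr_alpha: float = 0.05,
    boot_reps: int = 0,
    n_intervals: int | None = None,
) -> dict[str, Any]:
    """Simulate one dataset, run the method, score against the truth."""
    if seed is not None:
        config = replace(config, rng_seed=int(seed))
    genotypes, cells, truth = simulate_dataset(config)
    result = analyze(
        genotypes, cells, truth.phenotypes,
        strategies=strategies, estimators=estimators,
        n_intervals=n_intervals, t_max=config.trajectory_length,
        fdr_cut=eqtl_threshold, mr_alpha=mr_alpha, boot_reps=boot_reps,
        seed=config.rng_seed + 1,
    )
    gene_ids = cells.gene_ids
    scores = {
        strat: score_eqtl(tab, truth, genotypes, gene_ids, threshold=eqtl_threshold)
        for strat, tab in result["eqtl_tables"].items()
    }
    inflation = {}
    for strat, tab in result["eqtl_tables"].items():
        p_null = null_pair_pvalues(tab, truth, genotypes, gene_ids)
        if p_null.size >= 10:
            inflation[strat] = qq_data(p_null)["inflation_factor"]
    gene_scores = {
        tag: score_genes(rk, truth, gene_ids, alpha=mr_alpha)
        for tag, rk in result["ranked"].items()
    }
    result.update({
        "truth": truth, "genotypes": genotypes, "cells": cells,
        "eqtl_scores": scores, "inflation": inflation,
        "gene_scores": gene_scores, "seed": config.rng_seed,
    })
    return result


# ---------------------------------------------------------------------------
# replicated scenario grid
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Aggregated per-scenario evaluation across replicates."""

    scenario: dict[str, Any]
    n_replicates: int
    per_replicate: list[dict[str, Any]] = field(default_factory=list)
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def aggregate(self) -> None:
        keys: dict[str, list[float]] = {}
        for rep in self.per_replicate:
            for k, v in rep.items():
                if isinstance(v, (int, float)) and k != "seed":
                    keys.setdefault(k, []).append(float(v))
        self.summary = {}
        for k, vals in keys.items():
            arr = np.array(vals, dtype=float)
            ok = np.isfinite(arr)
            n = int(ok.sum())
            mean = float(arr[ok].mean()) if n else np.nan
            se = float(arr[ok].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            self.summary[k] = {"mean": mean, "se": se, "n": n}

    def to_json(self, **kwargs: Any) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps(
            {"scenario": self.scenario, "n_replicates": self.n_replicates,
             "summary": self.summary, "per_replicate": self.per_replicate},
            default=default, **kwargs,
        )


def _flatten_replicate(res: dict[str, Any]) -> dict[str, Any]:
    flat: dict[str, Any] = {"seed": res["seed"]}
    for strat, sc in res["eqtl_scores"].items():
        for k, v in sc.items():
            flat[f"{strat}_{k}"] = v
    for strat, infl in res["inflation"].items():
        flat[f"{strat}_inflation"] = infl
    for tag, sc in res["gene_scores"].items():
        for k, v in sc.items():
            flat[f"{tag}_{k}"] = v
    return flat


def run_experiment(
    scenarios: list[dict[str, Any]],
    n_replicates: int = 10,
    seed: int = 0,
    base_config: SimConfig | None = None,
    strategies: Iterable[str] = ("avg_eqtl", "cum_eqtl"),
    estimators: Iterable[str] = (),
    boot_reps: int = 0,
) -> list[EvalReport]:
    """Replicate each scenario and aggregate evaluation metrics.

    ``scenarios`` are dicts of :class:`SimConfig` field overrides (plus an
    optional ``name``).  Replicate seeds come from a splittable seed
    sequence so each scenario is independently reproducible.
    """
    if base_config is None:
        base_config = desk_config()
    reports = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(scenarios))
    for scen, ss in zip(scenarios, children):
        overrides = {k: v for k, v in scen.items() if k != "name"}
        config = replace(base_config, **overrides)
        rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_replicates)]
        report = EvalReport(scenario=dict(scen), n_replicates=n_replicates)
        for r_seed in rep_seeds:
            try:
                res = run_pipeline(
                    config, seed=r_seed, strategies=strategies,
                    estimators=estimators, boot_reps=boot_reps,
                )
                report.per_replicate.append(_flatten_replicate(res))
            except Exception as exc:  # noqa: BLE001 - record, mark partial
                logger.error("replicate seed %d failed: %s", r_seed, exc)
                report.per_replicate.append({"seed": r_seed, "failed": True})
                report.scenario["partial"] = True
        report.aggregate()
        reports.append(report)
    return reports
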