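# tiscmr — trajectory-informed dynamic single-cell Mendelian randomization

`tiscmr` prioritizes genes whose expression causally influences an
individual-level phenotype (disease status, a quantitative trait) from
population-scale single-cell RNA-seq with matched genotypes. Its premise is
that gene effects on phenotypes are **cumulative over cell development**
rather than instantaneous: a gene's exposure for individual *i* is not a
snapshot average but the integral of that individual's expression deviation
along a pseudotime trajectory,

```
x_ij = mu(t_ij) + sum_k xi_ik phi_k(t_ij) + eps_ij          (sparse FPCA)
xtilde_i = ∫ (xhat_i(t) − mu(t)) dt = sum_k xi_ik ∫ phi_k   (cumulative offset)
```

estimated by the PACE conditional-expectation algorithm, which handles the
sparse, irregular sampling produced when each donor's cells cover only part
of the trajectory. Treating `xtilde_i` as the exposure, SNPs mapped as
sc-eQTLs (FDR < 0.05, LD-clumped at r² > 0.1) serve as instruments in a
one-sample Mendelian randomization per gene:

```
stage 1:  xtilde_i = a0 + a' Z_i + e_i
stage 2:  y_i = b0 + beta * xhat_tilde_i + e_y          (2SLS, quantitative y)
          logit E[y_i] = b0 + beta * xtilde_i + b_e ehat_i   (2SRI, binary y)
```

with robust (sandwich / Terza two-stage) Wald tests, optional L1-penalized
direct instrument effects to absorb horizontal pleiotropy (penalty by
10-fold cross-validation, inference by bootstrap percentile CI), and
Benjamini-Hochberg ranking across genes. A full simulator of dynamic
single-cell transcriptomes with genotype-dependent, optionally
time-varying eQTL effects and known causal genes supports end-to-end
evaluation: precision/recall of SNP-gene detection, QQ calibration of five
eQTL strategies, and FDR/power of causal-gene discovery.

Who it is for: statistical geneticists and single-cell analysts with
(a) a genotype dosage matrix, (b) a cell × gene expression matrix with
per-cell donor IDs and pseudotimes (from any trajectory-inference tool),
and (c) per-donor phenotypes.

## Worked example

Simulate a reduced cohort (200 donors, 2 000 SNPs, 50 genes of which 10
causal, cells sampled unevenly along a length-20 trajectory,
time-varying eQTL effects), then run the full pipeline and score it
against the simulation truth:

```python
import tiscmr as tm

cfg = tm.desk_config(sampling_mode="uneven", eqtl_effect_mode="time_varying")
res = tm.run_pipeline(cfg, seed=11,
                      strategies=("avg_eqtl", "cum_eqtl"),
                      estimators=("avg_linear", "pace_linear"))

for strat, sc in res["eqtl_scores"].items():
    print(f"{strat}: precision={sc['precision']:.3f} recall={sc['recall']:.3f}")
for tag, sc in res["gene_scores"].items():
    print(f"{tag}: power={sc['power']:.2f} fdr={sc['fdr']:.2f}")
```

Output from this exact call:

```
avg_eqtl: precision=0.932 recall=0.040
cum_eqtl: precision=0.971 recall=0.066
avg_linear: power=0.20 fdr=0.00
pace_linear: power=0.20 fdr=0.00
```

Reading it: at comparable (here higher) precision, the PACE
time-cumulative eQTL strategy recovers two-thirds more true SNP-gene
pairs than per-donor averaging when cells are unevenly distributed along
the trajectory (recall 0.066 vs 0.040); both MR estimators flag 2 of the
10 truly causal genes at the BH-0.05 rule with no false discoveries on
this single replicate — the power separation between `pace_linear` and
`avg_linear` emerges across replicates (see the benchmark batteries in
`tests/test_acceptance.py` and `scripts/acceptance.py`).

On real data the same stages run from the shell:

```bash
tiscmr simulate --config sim.yaml --out data/ --seed 42   # or bring your own
tiscmr offsets  --expr data/expression --out offsets.tsv
tiscmr eqtl     --strategy cum_eqtl --geno data/genotypes.tsv \
                --expr data/expression --offsets offsets.tsv \
                --out eqtl.tsv --iv-out iv.json
tiscmr mr       --estimator pace_linear_lasso --geno data/genotypes.tsv \
                --offsets offsets.tsv --instruments iv.json \
                --pheno data/phenotypes.tsv --out mr.tsv --boot 999 --seed 7
tiscmr bench    --config grid.yaml --out results/ --reps 10 --seed 1
```

Expression is MatrixMarket + `genes.tsv`/`cells.tsv` (columns `cell_id`,
`individual_id`, `pseudotime`, `depth`); genotypes a dosage TSV or VCF;
phenotypes a two-column TSV. See `docs/methods.md` for the model, the
estimators, every tunable default, and the simulator's scope.

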