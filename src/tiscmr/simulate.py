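"""Simulation of population-level dynamic single-cell transcriptomes.

The generator produces, for a cohort of ``N`` individuals, (i) a genotype
dosage matrix of independent loci, (ii) single-cell expression counts for
``G`` genes where each cell sits at a pseudotime position on a 1-D
differentiation trajectory of length ``T``, and (iii) per-individual
phenotypes causally driven by the time-integrated expression of a subset of
genes, with optional horizontal pleiotropy.

Gene expression along pseudotime is built from ``K`` nonnegative "expression
program" basis functions generated by reflected Gaussian random walks.  The
relative mean of gene ``g`` is ``mu_g_rel(t) = sum_k w_k(t) h_kg`` with
gamma-distributed nonnegative loadings, scaled by a lognormal per-gene factor
``phi_g``.  Genotype regulation enters multiplicatively: the per-individual
latent mean is ``mu_ng(t) = mu_g(t) * (1 + lambda_ng(t))`` where
``lambda_ng(t)`` is Gaussian around the summed dosage-weighted eQTL effects
``sum_p Z_np * delta_pg(t)``; effects are either constant in pseudotime or
proportional to ``sqrt(2)*|sin t|``.  Observed counts are negative binomial
with a quadratic mean-variance relation and lognormal per-cell depths.

Phenotypes integrate the latent means against a gene-level effect curve
``gamma_g(t)`` over the trajectory (constant, cosine, windowed, or windowed
cosine regimes), add dosage-weighted pleiotropic SNP effects and a standard
normal confounder, and pass through an identity (quantitative) or logistic
(binary) link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "ExpressionProgramBasis",
    "EqtlEffectSpec",
    "CellExpressionDataset",
    "SimTruth",
    "simulate_genotypes",
    "simulate_program_basis",
    "simulate_eqtl_effects",
    "latent_mean_expression",
    "sample_cells",
    "simulate_phenotypes",
    "simulate_dataset",
]

logger = logging.getLogger("tiscmr.simulate")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the population-scale dynamic single-cell generator.

    Defaults reproduce the full-scale study design: 10 000 SNPs, 100 genes,
    500 individuals, 80-140 cells per individual, 15-25 regulating SNPs per
    gene, 20 causal genes, 100 pleiotropic SNPs, trajectory length 20.
    """

    n_individuals: int = 500
    n_snps: int = 10_000
    n_genes: int = 100
    cells_per_individual_range: tuple[int, int] = (80, 140)
    n_programs: int = 10
    trajectory_length: float = 20.0
    snps_per_gene_range: tuple[int, int] = (15, 25)
    n_causal_genes: int = 20
    n_pleiotropic_snps: int = 100
    eqtl_effect_mode: Literal["constant", "time_varying"] = "constant"
    sampling_mode: Literal["complete", "uneven"] = "complete"
    outcome_type: Literal["quantitative", "binary"] = "quantitative"
    gene_effect_regime: Literal["Y1", "Y2", "Y3", "Y4"] = "Y1"
    #: pseudotime window in which expression affects the outcome (Y3/Y4 only)
    effect_window: tuple[float, float] | None = None
    #: sd of the Gaussian noise around the summed genetic effect (lambda)
    eqtl_noise_sd: float = 0.1
    #: allele-frequency range for simulated SNPs (kept off 0/1 to avoid
    #: monomorphic loci)
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    #: per-step sd of the reflected Gaussian random walks generating programs
    program_step_sd: float = 0.1
    #: number of equally spaced grid points for latent-function evaluation
    n_grid: int = 201
    #: number of Gaussian-mixture components for uneven pseudotime sampling
    n_mixture_components: int = 5
    #: sd of quantitative phenotype noise; None => sd of the linear predictor
    #: (the genetic + expression signal then explains ~50% of variance)
    pheno_noise_sd: float | None = None
    #: sd to which the centered linear predictor is standardized before the
    #: inverse-logit for binary outcomes; keeps prevalence near 0.5 and
    #: outcome probabilities away from 0/1
    logit_scale: float = 2.0
    gamma_mean: float = 0.5
    gamma_sd: float = 0.05
    theta_mean: float = 0.5
    theta_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_snps, self.n_genes, self.n_programs) < 1:
            raise ValueError("all counts must be >= 1")
        for lo, hi in (self.cells_per_individual_range, self.snps_per_gene_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < min <= max")
        if self.trajectory_length <= 0:
            raise ValueError("trajectory_length must be positive")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        if self.effect_window is not None:
            lo, hi = self.effect_window
            if not (0 <= lo < hi <= self.trajectory_length):
                raise ValueError("effect_window must be a subinterval of [0, T]")
        if self.n_programs > self.n_genes:
            logger.warning(
                "n_programs (%d) exceeds n_genes (%d): over-parameterized basis",
                self.n_programs, self.n_genes,
            )

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.trajectory_length, self.n_grid)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP allele frequencies."""

    dosages: np.ndarray            # (N, P) values in {0, 1, 2}
    snp_ids: list[str]
    allele_freqs: np.ndarray       # (P,)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not self.individual_ids:
            self.individual_ids = [f"I{i:04d}" for i in range(self.dosages.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ExpressionProgramBasis:
    """Nonnegative random-walk expression programs and gene loadings."""

    grid: np.ndarray               # (n_grid,)
    w: np.ndarray                  # (K, n_grid), w_k(t) >= 0
    h: np.ndarray                  # (K, G), loadings >= 0
    phi: np.ndarray                # (G,), per-gene scale > 0

    def relative_mean(self, times: np.ndarray | None = None) -> np.ndarray:
        """``mu_g_rel(t) = sum_k w_k(t) h_kg`` -> (G, len(times))."""
        w = self.w if times is None else self._interp_w(times)
        return self.h.T @ w

    def absolute_mean(self, times: np.ndarray | None = None) -> np.ndarray:
        """``mu_g(t) = phi_g * mu_g_rel(t)`` -> (G, len(times))."""
        return self.phi[:, None] * self.relative_mean(times)

    def _interp_w(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return np.vstack([np.interp(times, self.grid, wk) for wk in self.w])


@dataclass
class EqtlEffectSpec:
    """Per-gene SNP assignments and base effect sizes delta_pg."""

    assignments: list[np.ndarray]  # per gene: indices of regulating SNPs
    deltas: list[np.ndarray]       # per gene: delta_pg > 0, aligned
    mode: Literal["constant", "time_varying"]

    def time_factor(self, times: np.ndarray) -> np.ndarray:
        """Multiplier applied to delta_pg at pseudotime t."""
        times = np.asarray(times, dtype=float)
        if self.mode == "constant":
            return np.ones_like(times)
        return np.sqrt(2.0) * np.abs(np.sin(times))

    def true_pairs(self) -> set[tuple[int, int]]:
        """All (snp, gene) pairs with a nonzero simulated effect."""
        return {
            (int(p), g)
            for g, idx in enumerate(self.assignments)
            for p in idx
        }

    def genetic_base(self, dosages: np.ndarray) -> np.ndarray:
        """Dosage-weighted summed effect ``sum_p Z_np delta_pg`` -> (N, G)."""
        n = dosages.shape[0]
        base = np.empty((n, len(self.assignments)))
        for g, (idx, dl) in enumerate(zip(self.assignments, self.deltas)):
            base[:, g] = dosages[:, idx] @ dl
        return base


@dataclass
class CellExpressionDataset:
    """Observed single-cell counts with per-cell metadata.

    ``cell_meta`` columns: cell_id, individual_id, individual_index,
    pseudotime, depth.
    """

    counts: np.ndarray             # (n_cells, G) nonnegative ints
    cell_meta: pd.DataFrame
    gene_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``mu_ng`` and ``lambda_ng`` are tabulated on ``grid``; continuous-time
    evaluation goes through :meth:`latent_mean_at`.
    """

    grid: np.ndarray               # (n_grid,)
    mu_ng: np.ndarray              # (N, G, n_grid) latent means, clipped >= 0
    lambda_ng: np.ndarray          # (N, G, n_grid) realized total effects
    basis: ExpressionProgramBasis
    effects: EqtlEffectSpec
    lambda_noise: np.ndarray       # (N, G) time-constant Gaussian noise draw
    genetic_base: np.ndarray       # (N, G) sum_p Z_np delta_pg
    alpha_g: np.ndarray | None = None   # NB quadratic dispersion, per gene
    beta_g: np.ndarray | None = None    # NB linear dispersion, per gene
    causal_genes: np.ndarray | None = None
    gamma: np.ndarray | None = None     # per causal gene effect size
    pleiotropic_snps: np.ndarray | None = None
    theta: np.ndarray | None = None     # per pleiotropic SNP effect
    confounder: np.ndarray | None = None    # U_n
    phenotypes: np.ndarray | None = None    # Y_n
    linear_predictor: np.ndarray | None = None

    @property
    def true_snp_gene_pairs(self) -> set[tuple[int, int]]:
        return self.effects.true_pairs()

    def latent_mean_at(self, individual_idx: np.ndarray, times: np.ndarray) -> np.ndarray:
        """``mu_ng(t)`` for paired (individual, pseudotime) queries -> (n, G)."""
        individual_idx = np.asarray(individual_idx)
        times = np.asarray(times, dtype=float)
        mu_abs = self.basis.absolute_mean(times)          # (G, n)
        f = self.effects.time_factor(times)               # (n,)
        lam = self.genetic_base[individual_idx] * f[:, None] + self.lambda_noise[individual_idx]
        return np.clip(mu_abs.T * (1.0 + lam), 0.0, None)


# ---------------------------------------------------------------------------
# generator steps
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Draw independent biallelic dosages, column p ~ Binomial(2, pi_p)."""
    lo, hi = config.allele_freq_range
    pi = rng.uniform(lo, hi, size=config.n_snps)
    dosages = rng.binomial(2, pi, size=(config.n_individuals, config.n_snps)).astype(np.int8)
    snp_ids = [f"snp{p:05d}" for p in range(config.n_snps)]
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids, allele_freqs=pi)


def simulate_program_basis(config: SimConfig, rng: np.random.Generator) -> ExpressionProgramBasis:
    """Reflected Gaussian random-walk programs, gamma loadings, lognormal scales.

    Each program starts at 1.0 and takes ``N(0, program_step_sd^2)`` steps on
    the pseudotime grid; reflection at zero keeps programs nonnegative.
    Loadings ``h_kg ~ Gamma(1/K, 1)`` and scales ``log(phi_g) ~ N(0.8, 1)``.
    """
    K, G = config.n_programs, config.n_genes
    steps = rng.normal(0.0, config.program_step_sd, size=(K, config.n_grid - 1))
    walks = np.concatenate([np.ones((K, 1)), steps], axis=1).cumsum(axis=1)
    w = np.abs(walks)
    h = rng.gamma(shape=1.0 / K, scale=1.0, size=(K, G))
    phi = np.exp(rng.normal(0.8, 1.0, size=G))
    return ExpressionProgramBasis(grid=config.grid, w=w, h=h, phi=phi)


def simulate_eqtl_effects(
    config: SimConfig, genotypes: GenotypeMatrix, rng: np.random.Generator
) -> EqtlEffectSpec:
    """Assign P_g ~ UniformInt regulating SNPs per gene, delta ~ Gamma(3.6, 1/12)."""
    lo, hi = config.snps_per_gene_range
    if hi > genotypes.n_snps:
        raise ValueError("snps_per_gene_range max exceeds number of SNPs")
    assignments, deltas = [], []
    for _ in range(config.n_genes):
        p_g = int(rng.integers(lo, hi + 1))
        idx = rng.choice(genotypes.n_snps, size=p_g, replace=False)
        idx.sort()
        assignments.append(idx)
        deltas.append(rng.gamma(shape=3.6, scale=1.0 / 12.0, size=p_g))
    return EqtlEffectSpec(assignments=assignments, deltas=deltas, mode=config.eqtl_effect_mode)


def latent_mean_expression(
    basis: ExpressionProgramBasis,
    effects: EqtlEffectSpec,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimTruth:
    """Realize per-individual latent means ``mu_ng(t)`` on the grid.

    ``lambda_ng(t) = base_ng * f(t) + e_ng`` with a single time-constant
    Gaussian draw ``e_ng ~ N(0, sigma^2)`` per (individual, gene); the latent
    mean ``mu_g(t)*(1 + lambda_ng(t))`` is clipped at zero.
    """
    grid = config.grid
    base = effects.genetic_base(genotypes.dosages)                    # (N, G)
    noise = rng.normal(0.0, config.eqtl_noise_sd, size=base.shape)
    f = effects.time_factor(grid)                                     # (n_grid,)
    lam = base[:, :, None] * f[None, None, :] + noise[:, :, None]
    mu_abs = basis.absolute_mean()                                    # (G, n_grid)
    mu = np.clip(mu_abs[None, :, :] * (1.0 + lam), 0.0, None)
    return SimTruth(
        grid=grid, mu_ng=mu, lambda_ng=lam, basis=basis, effects=effects,
        lambda_noise=noise, genetic_base=base,
    )


def _sample_pseudotimes(
    n: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cell positions on [0, T]: uniform (complete) or per-individual GMM (uneven)."""
    T = config.trajectory_length
    if config.sampling_mode == "complete":
        return rng.uniform(0.0, T, size=n)
    k = config.n_mixture_components
    means = rng.uniform(0.0, T, size=k)
    sds = np.sqrt(rng.uniform(0.5, 2.5, size=k))
    comp = rng.integers(0, k, size=n)
    t = rng.normal(means[comp], sds[comp])
    # resample draws falling outside the trajectory (truncation)
    bad = (t < 0.0) | (t > T)
    while bad.any():
        comp_b = rng.integers(0, k, size=int(bad.sum()))
        t[bad] = rng.normal(means[comp_b], sds[comp_b])
        bad = (t < 0.0) | (t > T)
    return t


def sample_cells(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> CellExpressionDataset:
    """Draw observed counts ``x_nmg ~ NegBin(s_nm mu_ng(t), alpha m^2 + beta m)``.

    Depths ``log s ~ N(log 1, log(0.7)^2)``; per-gene dispersions
    ``log alpha ~ N(log 0.4, log(2)^2)``, ``log beta ~ N(log 2, log(2)^2)``.
    Entries whose quadratic variance does not exceed the mean fall back to
    Poisson draws.
    """
    N = truth.mu_ng.shape[0]
    G = truth.mu_ng.shape[1]
    lo, hi = config.cells_per_individual_range
    n_cells_per_ind = rng.integers(lo, hi + 1, size=N)
    ind_idx = np.repeat(np.arange(N), n_cells_per_ind)
    times = np.concatenate([
        _sample_pseudotimes(int(m), config, rng) for m in n_cells_per_ind
    ])
    depth = np.exp(rng.normal(np.log(1.0), abs(np.log(0.7)), size=ind_idx.size))
    alpha_g = np.exp(rng.normal(np.log(0.4), np.log(2.0), size=G))
    beta_g = np.exp(rng.normal(np.log(2.0), np.log(2.0), size=G))

    mu_cells = truth.latent_mean_at(ind_idx, times)                  # (C, G)
    counts = _draw_counts(depth[:, None] * mu_cells, alpha_g[None, :],
                          beta_g[None, :], rng)

    truth.alpha_g = alpha_g
    truth.beta_g = beta_g
    meta = pd.DataFrame({
        "cell_id": [f"C{i:06d}" for i in range(ind_idx.size)],
        "individual_id": [f"I{i:04d}" for i in ind_idx],
        "individual_index": ind_idx,
        "pseudotime": times,
        "depth": depth,
    })
    gene_ids = [f"G{g:04d}" for g in range(G)]
    return CellExpressionDataset(counts=counts, cell_meta=meta, gene_ids=gene_ids)


def _draw_counts(
    m: np.ndarray, alpha: np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with variance ``alpha m^2 + beta m``.

    Parameterized through ``r = m^2/(v - m)`` and ``q = r/(r + m)``; entries
    whose stated variance does not exceed the mean fall back to Poisson.
    """
    m = np.asarray(m, dtype=float)
    v = alpha * m**2 + beta * m
    v = np.broadcast_to(v, m.shape)
    counts = np.zeros(m.shape, dtype=np.int64)
    pos = m > 0
    nb = pos & (v > m)
    if nb.any():
        r = m[nb] ** 2 / (v[nb] - m[nb])
        counts[nb] = rng.negative_binomial(r, r / (r + m[nb]))
    po = pos & ~nb
    if po.any():
        logger.warning(
            "NB variance <= mean for %d cell/gene entries; Poisson fallback",
            int(po.sum()),
        )
        counts[po] = rng.poisson(m[po])
    return counts


def _gamma_curve(gamma_g: float, regime: str, grid: np.ndarray,
                 window: tuple[float, float] | None) -> np.ndarray:
    """Gene-level effect curve gamma_g(t) on the grid."""
    if regime == "Y1":
        return np.full_like(grid, gamma_g)
    if regime == "Y2":
        return gamma_g * np.cos(grid)
    if window is None:
        raise ValueError(f"effect_window is required for regime {regime}")
    ind = ((grid >= window[0]) & (grid <= window[1])).astype(float)
    if regime == "Y3":
        return gamma_g * ind
    if regime == "Y4":
        return gamma_g * ind * np.cos(grid)
    raise ValueError(f"unknown gene_effect_regime {regime!r}")


def simulate_phenotypes(
    truth: SimTruth,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimTruth:
    """Complete the truth with causal genes, pleiotropy, confounder and Y.

    The linear predictor integrates (trapezoid rule) each causal gene's
    latent mean against its effect curve, adds dosage-weighted pleiotropic
    effects and ``U_n ~ N(0,1)``.  Quantitative outcomes add Gaussian noise;
    binary outcomes standardize the centered predictor to sd ``logit_scale``
    and draw Bernoulli through the inverse logit.
    """
    N, G, _ = truth.mu_ng.shape
    causal = rng.choice(G, size=config.n_causal_genes, replace=False)
    causal.sort()
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=config.n_causal_genes)
    pleio = rng.choice(genotypes.n_snps, size=config.n_pleiotropic_snps, replace=False)
    pleio.sort()
    theta = rng.normal(config.theta_mean, config.theta_sd, size=config.n_pleiotropic_snps)
    U = rng.normal(0.0, 1.0, size=N)

    eta = U + genotypes.dosages[:, pleio].astype(float) @ theta
    for g, gam in zip(causal, gamma):
        curve = _gamma_curve(gam, config.gene_effect_regime, truth.grid, config.effect_window)
        eta += np.trapezoid(truth.mu_ng[:, g, :] * curve[None, :], truth.grid, axis=1)

    eta_c = eta - eta.mean()
    if config.outcome_type == "quantitative":
        sd = config.pheno_noise_sd
        if sd is None:
            sd = float(eta_c.std()) or 1.0
        y = eta_c + rng.normal(0.0, sd, size=N)
    else:
        scale = float(eta_c.std()) or 1.0
        z = eta_c / scale * config.logit_scale
        p = 1.0 / (1.0 + np.exp(-z))
        y = rng.binomial(1, p).astype(float)

    truth.causal_genes = causal
    truth.gamma = gamma
    truth.pleiotropic_snps = pleio
    truth.theta = theta
    truth.confounder = U
    truth.linear_predictor = eta
    truth.phenotypes = y
    return truth


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, CellExpressionDataset, SimTruth]:
    """Run the full generator: genotypes -> latent means -> cells -> phenotypes."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    genotypes = simulate_genotypes(config, rng)
    basis = simulate_program_basis(config, rng)
    effects = simulate_eqtl_effects(config, genotypes, rng)
    truth = latent_mean_expression(basis, effects, genotypes, config, rng)
    cells = sample_cells(truth, config, rng)
    truth = simulate_phenotypes(truth, genotypes, config, rng)
    return genotypes, cells, truth
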