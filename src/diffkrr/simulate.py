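"""Synthetic marker and phenotype generation.

Two genotype regimes mirror the data structures the kernels are built for:
outbred biallelic SNPs sampled under Hardy-Weinberg equilibrium (genotype ~
Binomial(2, p_j) at each locus, independent loci), and fully inbred lines
(no heterozygotes; binary presence/absence codes).  Phenotypes combine an
additive QTL component with an optional pairwise-epistatic component built
from products of centered genotype pairs; both are rescaled empirically so
the realized heritability and the additive/epistatic variance split hit
their targets.  Missing genotypes are imputed by sampling from the observed
per-locus genotype frequencies -- deliberately simple, matching how the
kernels expect complete data rather than attempting LD-aware imputation.

Linkage disequilibrium, pedigree structure and selection are out of scope;
loci are independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import MISSING_CODE, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "impute_missing",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    ``architecture`` fixes the epistasis share unless 'mixed':
    'additive' -> 0, 'epistatic' -> 1, 'mixed' -> ``epistasis_fraction``.
    ``h2`` is the target ratio var(genetic)/var(phenotype) (narrow-sense for
    additive architectures, broad-sense otherwise).  The default MAF floor
    of 0.05 keeps desk-scale relationship matrices well conditioned.
    """

    n: int = 400
    p: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    architecture: str = "additive"
    n_qtl: int = 50
    h2: float = 0.5
    epistasis_fraction: float = 0.0
    inbred: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.architecture not in ("additive", "epistatic", "mixed"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 < self.n_qtl <= self.p:
            raise ValueError("need 0 < n_qtl <= p")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 <= self.epistasis_fraction <= 1.0:
            raise ValueError("epistasis_fraction must lie in [0, 1]")

    @property
    def effective_epistasis_fraction(self) -> float:
        if self.architecture == "additive":
            return 0.0
        if self.architecture == "epistatic":
            return 1.0
        return self.epistasis_fraction


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    true_g: np.ndarray
    qtl_effects: pd.DataFrame
    realized_h2: float
    config: SimulationConfig


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """HWE outbred SNPs or fully inbred binary lines, loci independent.

    Per-locus allele frequency ~ Uniform(maf_low, maf_high).  Outbred:
    genotype ~ Binomial(2, p_j), snp012 coding.  Inbred: genotype 2 with
    probability p_j else 0 (no heterozygotes), binary coding.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.p)
    if cfg.inbred:
        codes = 2 * (rng.random((cfg.n, cfg.p)) < freqs[None, :]).astype(np.int64)
        coding = "binary"
    else:
        codes = rng.binomial(2, freqs[None, :], size=(cfg.n, cfg.p)).astype(np.int64)
        coding = "snp012"
    return GenotypeMatrix(codes=codes, coding=coding)


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimulationConfig, seed: int | None = None
) -> SimulatedDataset:
    """Additive + pairwise-epistatic phenotypes at controlled heritability.

    Additive effects are standard normal draws on ``n_qtl`` sampled QTL;
    the epistatic component puts normal effects on products of centered
    genotypes for disjoint QTL pairs.  Components are standardized
    empirically, mixed as sqrt(1-f)*additive + sqrt(f)*epistatic, scaled to
    variance h2, and unit-total-variance Gaussian noise is added, so the
    phenotype has variance ~1 and var(true_g)/var(y) ~ h2.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n, p = g.n_individuals, g.n_markers
    z = g.dosages().astype(float)
    z = z - z.mean(axis=0, keepdims=True)

    qtl = np.sort(rng.choice(p, size=cfg.n_qtl, replace=False))
    frac = cfg.effective_epistasis_fraction

    add_effects = rng.standard_normal(cfg.n_qtl)
    g_add = z[:, qtl] @ add_effects
    if np.std(g_add) == 0.0:
        raise ValueError("degenerate genotypes: additive component has zero variance")
    g_add = g_add / np.std(g_add)

    frames = []
    if frac < 1.0:
        frames.append(
            pd.DataFrame({"locus_a": qtl, "locus_b": -1, "effect": add_effects, "type": "additive"})
        )
    if frac > 0.0:
        if cfg.n_qtl < 2:
            raise ValueError("epistasis needs at least two QTL")
        pair_a, pair_b = qtl[0::2], qtl[1::2]
        m = min(pair_a.size, pair_b.size)
        pair_a, pair_b = pair_a[:m], pair_b[:m]
        epi_effects = rng.standard_normal(m)
        g_epi = (z[:, pair_a] * z[:, pair_b]) @ epi_effects
        if np.std(g_epi) == 0.0:
            raise ValueError("degenerate genotypes: epistatic component has zero variance")
        g_epi = g_epi / np.std(g_epi)
        frames.append(
            pd.DataFrame(
                {"locus_a": pair_a, "locus_b": pair_b, "effect": epi_effects, "type": "epistatic"}
            )
        )
        true_g = np.sqrt(1.0 - frac) * g_add + np.sqrt(frac) * g_epi
    else:
        true_g = g_add
    effects = pd.concat(frames, ignore_index=True)

    sd = np.std(true_g)
    if sd == 0.0:
        raise ValueError("total genetic variance is zero; h2 target unattainable")
    true_g = true_g * (np.sqrt(cfg.h2) / sd)
    noise = rng.standard_normal(n) * np.sqrt(1.0 - cfg.h2)
    y = true_g + noise
    realized = float(np.var(true_g) / np.var(y))
    return SimulatedDataset(
        genotypes=g,
        phenotypes=y,
        true_g=true_g,
        qtl_effects=effects,
        realized_h2=realized,
        config=cfg,
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Genotypes and phenotypes in one call (genotype seed = cfg.seed,
    phenotype seed = cfg.seed + 1)."""
    return simulate_phenotypes(simulate_genotypes(cfg), cfg)


def impute_missing(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing codes by sampling the observed genotype frequencies per locus.

    Each missing entry is drawn independently from the empirical
    distribution of the observed codes at its locus; a fully missing locus
    is an error.  A matrix without missing values is returned unchanged.
    """
    if not g.has_missing:
        return g
    codes = g.codes.copy()
    rng = np.random.default_rng(seed)
    for j in range(codes.shape[1]):
        col = codes[:, j]
        miss = col == MISSING_CODE
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise ValueError(f"locus {g.marker_ids[j]} has no observed genotypes to sample from")
        codes[miss, j] = rng.choice(observed, size=int(miss.sum()), replace=True)
    return GenotypeMatrix(
        codes=codes,
        coding=g.coding,
        marker_ids=list(g.marker_ids),
        individual_ids=list(g.individual_ids),
    )
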