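# diffkrr

Whole-genome prediction of quantitative traits with **diffusion (heat)
kernels on genotype graphs** and **Bayesian kernel ridge regression**.

## Who this is for

Animal and plant breeders, and quantitative geneticists, who predict
phenotypes (or breeding values) from dense marker panels and want kernels
that respect the *discrete* geometry of genotypes instead of embedding
0/1/2 codes in Euclidean space. The package implements five kernel
families, an RKHS regression engine with Gibbs sampling, cross-validated
evaluation, and a synthetic-data generator for controlled experiments.

## The model

Phenotypes are regressed on an n x n kernel **K** built from markers:

    y = 1 mu + K alpha + eps,   alpha ~ N(0, K^-1 sigma_a^2),  eps ~ N(0, I sigma_e^2)

which is kernel ridge regression: the posterior mode of alpha minimizes
`||y - K alpha||^2 + lambda alpha' K alpha` with `lambda = sigma_e^2 / sigma_a^2`.
Through the eigendecomposition `K = Lambda Psi Lambda'` the model becomes
`y = 1 mu + Lambda delta + eps` with independent `delta_j ~ N(0, psi_j sigma_a^2)`,
so all Gibbs conditionals are conjugate (normal draws plus two
scaled-inverse-chi-square draws per sweep; priors default to df 3, scale 1).

**Kernels.** A biallelic SNP genotype lives on the path graph `0 - 1 - 2`
(one mutational step between neighbours); p loci live on the p-fold
Cartesian product of that path (the *SNP grid*, 3^p vertices). The heat
kernel `exp(theta * H)` on this graph — H = -L(Gamma), the negated graph
Laplacian — has a closed form that depends only on per-pair counts: with
n1 loci differing by 1, n2 differing by 2, and m11 shared heterozygous
loci, and `D = e^(-3 theta) + 3 e^(-theta) + 2`,

    K_snpgrid(x, x') = [(2 - 2e^(-3θ))/D]^n1 · [(e^(-3θ) - 3e^(-θ) + 2)/D]^n2 · [(4e^(-3θ) + 2)/D]^m11

For binary markers (inbred lines, X-chromosome dosages) the graph is the
p-cube and the kernel collapses to `tanh(theta)^d` with d the Hamming
distance. Also provided: the Gaussian kernel `exp(-theta * ||x - x'||^2)`,
and the VanRaden additive genomic relationship matrices G1 (centered) and
G2 (standardized), with 0.95*K + 0.05*I shrinkage for numerically
indefinite G matrices. Per-chromosome-block kernels combine by Hadamard
product, which exactly reproduces the whole-genome kernel for the
diffusion and Gaussian families.

## Worked example

```python
import numpy as np
from diffkrr import (SimulationConfig, simulate_dataset, theta_grid,
                     cross_validate, make_split, MCMCConfig)

ds = simulate_dataset(SimulationConfig(n=200, p=500, architecture="additive",
                                       h2=0.6, n_qtl=30, seed=42))
g, y = ds.genotypes, ds.phenotypes
theta = theta_grid(g, "snpgrid", target_means=(0.5,), seed=42)[0]
split = make_split(g.individual_ids, k=5, seed=42)
summary, per_fold = cross_validate(
    g, y, [("snpgrid", theta), ("g1", None)], split,
    cfg=MCMCConfig(n_iter=4000, burn_in=1000, thin=3, seed=42))
print(summary.round(3).to_string(index=False))
```

prints

```
 kernel  theta  mean_diag  mean_offdiag  correlation   mse
snpgrid  6.669      0.707         0.500        0.231 0.992
     g1    NaN      0.999        -0.005        0.243 0.987
```

Read: the SNP-grid bandwidth that puts the average off-diagonal kernel
entry at 0.5 is theta = 6.67; its diagonal mean of 0.71 (< 1) reflects
the heterozygosity of the sample, whereas G1's diagonal sits at ~1 and
its off-diagonal at ~0 for unrelated individuals. Under a purely additive
architecture the spatial kernel and the additive relationship matrix give
essentially the same out-of-fold predictive correlation — additive signal
gives the diffusion kernel no edge over G1, and neither is expected here
(the gap between r ~ 0.24 and sqrt(h2) ~ 0.77 is what unrelated
individuals and p > n cost you).

The same pipeline is scriptable from the shell:

```bash
diffkrr simulate --n 200 --p 500 --h2 0.6 --n-qtl 30 --seed 42 --out-prefix sim
diffkrr kernel --geno sim.geno.tsv --family snpgrid --theta 10.39 --out K.tsv
diffkrr fit --kernel K.tsv --pheno sim.pheno.tsv --out-prefix post
diffkrr diffuse-demo --rate 0.1 --steps 15   # step-wise diffusion trace
```

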