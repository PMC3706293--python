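# Methods

## Model

The regression engine treats genomic prediction as Bayesian kernel ridge
regression in a reproducing kernel Hilbert space. Given an n x n symmetric
positive (semi-)definite kernel **K** among genotyped individuals,

    y = 1 mu + K alpha + eps,
    alpha ~ N(0, K^-1 sigma_a^2),   eps ~ N(0, I sigma_e^2),

whose posterior mode for fixed variances is the ridge solution
`alpha_hat = (K + lambda I)^-1 (y - mu 1)`, `lambda = sigma_e^2/sigma_a^2`.
Sampling works in the eigenbasis: with `K = Lambda Psi Lambda'` and
`delta = Psi Lambda' alpha`, the model is `y = 1 mu + Lambda delta + eps`
with `delta_j ~ N(0, psi_j sigma_a^2)` independent. Because `Lambda` has
orthonormal columns, the full conditional of the whole `delta` vector is a
diagonal Gaussian, so one Gibbs sweep is: (1) impute any unobserved
responses from `N(mu + (Lambda delta)_i, sigma_e^2)`; (2) draw `mu` (flat
prior) from `N(mean(y - Lambda delta), sigma_e^2/n)`; (3) draw all
`delta_j`; (4, 5) draw `sigma_a^2` and `sigma_e^2` from their
scaled-inverse-chi-square conditionals. One seeded generator per chain,
draws consumed in exactly that order, so runs are bit-reproducible.

The intercept deserves a note: the training model can be written without
`mu`, but the prediction equation `y_test = 1 mu_train + K_test,train
alpha_train` requires one. We sample a flat-prior intercept by default;
`include_intercept=False` is available for fitting pre-centered responses,
and in that configuration the fixed-variance posterior mean of `alpha` is
exactly the ridge solution — the identity used by the agreement test.

Unobserved (test-set) responses are handled inside the sampler: the full
train+test kernel is built once, test responses are marked missing, and
each sweep imputes them from the current predictive distribution. The
reported prediction is the average of `mu + g_i` over retained sweeps,
which has the same mean as averaging full predictive draws but lower
Monte Carlo variance. The two prediction routes (per-sweep imputation on
the full kernel vs. `predict()` from a train-only fit with a rectangular
cross-kernel) agree within Monte Carlo error and are tested against each
other.

## Kernels

*SNP grid.* Genotypes 0/1/2 at one locus sit on the path graph 0-1-2: the
heterozygote is one mutational step from either homozygote, two steps
separate the homozygotes. p loci form the Cartesian product of p paths,
and the heat kernel on a Cartesian product is the Kronecker product of the
factor heat kernels, so the 3^p-vertex graph never needs to be formed. Per
locus the factor depends only on whether the pair of genotypes differ by
one, differ by two, or are both heterozygous; with
`D = e^(-3t) + 3e^(-t) + 2` the three normalized factors are

    A = (2 - 2e^(-3t))/D      (differ by 1)
    B = (e^(-3t) - 3e^(-t) + 2)/D   (differ by 2)
    C = (4e^(-3t) + 2)/D      (both heterozygous)

all in (0, 1) for t > 0. Entries are `A^n1 B^n2 C^m11`, accumulated as
`n1 log A + n2 log B + m11 log C` and exponentiated — with tens of
thousands of markers the raw product underflows double precision, the log
form cannot. The pair counts for all pairs come from three dense
indicator-matrix products (het x het', hom0 x hom2' + hom2 x hom0', and
the match count), O(n^2 p) through BLAS with no per-pair loop.

Normalizing each factor by D makes matched non-heterozygous loci
contribute exactly 1, so only `q = n1 + n2 + m11` loci enter the product.
A consequence worth spelling out: the diagonal is `C^(het count)`, which
is below 1 for heterozygous individuals — the kernel smooths on
heterozygosity as well as on Manhattan distance. This also means entries
of pairs sharing heterozygous loci are *not* monotone in the bandwidth
(C equals 1 at t = 0, dips to ~0.70 around t = 1, and returns to 1); only
the mismatch factors A and B increase monotonically toward 1. The
monotonicity property test is therefore restricted to A and B and to the
hypercube kernel.

*Hypercube.* Binary markers (inbred lines, hemizygous X dosages) live on
the two-vertex path; the p-fold product is the p-cube and the normalized
heat kernel is `tanh(t)^d` with d the Hamming distance. Diagonal exactly 1.
Accepted input alphabets {0,1}, {0,2}, {-1,1} are mapped to Hamming
coordinates.

*Gaussian.* `exp(-t ||x - x'||^2)` on the raw integer codes, squared
distances by the inner-product expansion with negative round-off clipped.
Centering the codes would not change pairwise distances, so raw codes are
used.

*G1 / G2.* VanRaden's additive relationship matrices from centered
(`Z Z' / 2 sum p_j (1 - p_j)`) or per-locus standardized (`W W' / p`)
dosages. Allele frequencies default to in-data estimates, which makes the
matrices positive *semi*-definite; monomorphic loci are dropped with a
warning because the G2 standardization would divide by zero. External
base-population frequencies can be supplied instead (and are required for
rectangular cross relationship matrices, where train and test must share
frequencies). For fully inbred lines with in-data frequencies the mean
diagonal of both G1 and G2 is exactly 2 — per locus the average squared
centered dosage is `4 p(1-p)` against a `2 p(1-p)` denominator term — a
useful end-to-end identity that the acceptance suite checks to 1e-10.

*Shrinkage and combination.* `shrink_kernel` maps K to
`w K + (1-w) I` (default w = 0.95), moving every eigenvalue to
`w lambda + (1-w)`; it is the standard fix when in-data frequencies leave
G slightly indefinite. `hadamard_combine` multiplies per-block kernels
elementwise; for the diffusion and Gaussian families this *exactly* equals
the kernel on the concatenated markers (they factor over loci), and PSD is
preserved by the Schur product theorem. The exponential kernel on the
unsquared Euclidean distance does not factor — kept in the test suite as
the standard counterexample. Blocks may carry different bandwidths (e.g.
autosomes vs. allosomes); the default is a shared bandwidth.

PSD validation passes at `lambda_min >= -1e-8 * lambda_max`; failures get
a shrink hint rather than silent repair.

## Bandwidth selection

Sampling the bandwidth inside MCMC would require rebuilding the kernel
every sweep, so bandwidths are chosen on a grid. The grid is constructed
by inverting the mean *off-diagonal* kernel entry: each target mean
similarity in (0, 1) (defaults evenly spaced 0.13 to 0.99) is mapped to a
bandwidth by Brent's method on a seeded subsample of up to 100
individuals. Off-diagonals rather than all entries because the diagonal
is structurally distinct (heterozygosity for the SNP grid, exactly 1 for
hypercube/Gaussian). The mean is increasing in theta for diffusion
kernels and decreasing for the Gaussian; unattainable targets are capped
with a warning.

## Evaluation

`make_split` provides seeded k-fold plans (fold sizes within one of each
other) and group holdouts (e.g. late birth years as the test set).
Predictive ability is Pearson correlation and mean squared error
(`sum (pred - obs)^2 / n`, not n-1) on *pooled* out-of-fold predictions;
per-fold values are retained. Within a kernel family the bandwidth with
the best correlation is expected to also have the smallest MSE; a
violation triggers a warning, not a failure, since weak signal
legitimately decouples the two. Besides the Gibbs engine,
`cross_validate(engine="ridge")` offers a deterministic closed-form path
at fixed lambda — useful for fast exploration and for invariance tests
where MCMC noise would obscure exact properties.

## Synthetic data

The generator produces the two marker regimes the kernels target:
outbred biallelic SNPs under Hardy-Weinberg equilibrium (per-locus allele
frequency Uniform(maf_low, maf_high), genotype Binomial(2, p_j),
independent loci) and fully inbred binary lines (code 2 with probability
p_j, no heterozygotes). The MAF floor defaults to 0.05, which keeps
desk-scale relationship matrices well conditioned. Phenotypes combine an
additive component (normal effects on `n_qtl` sampled QTL, default 50)
with an optional pairwise-epistatic component (normal effects on products
of centered genotypes over disjoint consecutive QTL pairs — the minimal
non-additive structure). Components are standardized empirically, mixed
as `sqrt(1-f)` / `sqrt(f)`, scaled so the genetic variance hits the
heritability target, and unit-total-variance Gaussian noise is added.
Missing genotypes are imputed by sampling the observed per-locus genotype
frequencies — deliberately simple; LD-aware imputation is out of scope.

**What the generator does not emulate — and what that means for the
tests.** Loci are independent and individuals unrelated: no linkage
disequilibrium, no pedigree or population structure, no selection. The
consequences are asymmetric. Additive-architecture results transfer well
(additive signal is visible to every kernel through marker similarity).
Non-additive results do not: with independent loci and unrelated
individuals, a pairwise-product signal is nearly orthogonal to every
isotropic marker kernel — an oracle kernel built from the true centred
pair products predicts the epistatic signal at r ~ 0.6, while the SNP
grid, Gaussian, and G1 kernels all sit near r ~ 0, because the causal
quadratic directions are a vanishing fraction of the ~p^2/2-dimensional
quadratic feature space that an isotropic kernel weights uniformly. In
real inbred-line panels, relatedness and LD concentrate genetic variance
(including its non-additive part) along the kernel's leading
eigendirections, which is where spatial-distance kernels earn their
advantage over additive relationship matrices. The acceptance test
asserting that advantage under the generator's independence assumptions
is therefore expected to fail, and is kept failing rather than weakened:
it documents precisely which feature of real data (relatedness/LD, not
epistasis per se) the advantage rides on.

## Numerical choices

- Heat kernels via symmetric eigendecomposition (`eigh`), exact for the
  tiny graphs involved; eigenvalue identity `eig(exp(tH)) = exp(t eig(H))`
  asserted in tests.
- Kernel eigendecomposition truncates eigenvalues below `1e-10 *
  lambda_max` and errors (with a shrink hint) below `-1e-8 * lambda_max`;
  retained rank is reported for semi-definite inputs.
- MCMC desk-scale default 12000 iterations / 4000 burn-in / thin 4
  (2000 retained draws); fidelity-scale 100000/60000/10 available via
  configuration. Effective sample size (initial positive sequence) and a
  Geweke z-score are computed for the variance chains; ESS below 100
  triggers a warning.
- Cross-validated acceptance experiments run at reduced budgets chosen as
  the package's desk-scale defaults: 5-fold CV, chains of 2000/500/3, and
  a three-point bandwidth grid targeting mean similarities
  {0.13, 0.474, 0.818} (sharp / middle / smooth, spanning the range used
  for the full grids). The variance-recovery experiment uses the full
  desk-scale chain at n = 400 with 20 replicates.
- Diffusion rates above 1/max-degree warn (the update loses its
  probabilistic reading) but are not errors; the linear recursion is
  defined for any rate.

## Known limitations

- Kernels are dense; the intended scale is n up to a few thousand.
- The bandwidth is fixed per fit (grid search outside MCMC); no
  multiple-kernel learning.
- `alpha_hat` is identified only within the span of the retained
  eigenvectors — irrelevant for prediction, relevant if coefficients are
  inspected directly.
- Gaussian likelihood only; binary or censored responses are out of
  scope.
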