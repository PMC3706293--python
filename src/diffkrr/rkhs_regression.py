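"""Bayesian kernel ridge regression via an eigendecomposition reparameterization.

The RKHS model y = 1*mu + K*alpha + eps with alpha ~ N(0, K^{-1} sigma_a^2)
is rewritten through K = Lambda Psi Lambda' as

    y = 1*mu + Lambda*delta + eps,   delta_j ~ N(0, psi_j sigma_a^2),
    eps ~ N(0, I sigma_e^2),

where delta = Psi Lambda' alpha.  Because Lambda is orthonormal, all delta_j
are conditionally independent given the variances, so the Gibbs sampler
reduces to vectorized normal draws plus two scaled-inverse-chi-square draws
per sweep.  With the variances fixed, the posterior mean of alpha is the
kernel ridge solution (K + lambda*I)^{-1} y with lambda = sigma_e^2/sigma_a^2.

Unobserved responses (the test set) can be carried along as missing values:
each sweep imputes them from the current predictive distribution, so one fit
on the full train+test kernel yields predictions directly.

Sampling order within a sweep (one generator per chain): (1) missing
responses, (2) mu, (3) delta, (4) sigma_a^2, (5) sigma_e^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

__all__ = [
    "EigenKernel",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "eigendecompose_kernel",
    "gibbs_fit",
    "fit_with_missing",
    "predict",
    "ridge_solve",
    "effective_sample_size",
    "geweke_z",
]


@dataclass(frozen=True)
class EigenKernel:
    """Retained spectrum of a PSD kernel: K ~= Lambda diag(Psi) Lambda'.

    Eigenvalues below truncation_tol * lambda_max are dropped (they carry no
    signal and would destabilize the delta update); the retained rank r may
    be < n for semi-definite kernels such as G built from in-data allele
    frequencies.
    """

    eigenvectors: np.ndarray  # n x r, orthonormal columns
    eigenvalues: np.ndarray  # length r, positive, descending
    truncation_tol: float
    family: str | None = None
    theta: float | None = None
    individual_ids: list | None = None

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def rank(self) -> int:
        return self.eigenvectors.shape[1]

    def reconstruct(self) -> np.ndarray:
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-inverse-chi-square hyperparameters for the two variances.

    Defaults (3 degrees of freedom, scale 1 for both) are weakly informative
    for responses on roughly unit scale.
    """

    df_e: float = 3.0
    scale_e: float = 1.0
    df_alpha: float = 3.0
    scale_alpha: float = 1.0

    def __post_init__(self):
        if min(self.df_e, self.scale_e, self.df_alpha, self.scale_alpha) <= 0:
            raise ValueError("prior degrees of freedom and scales must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  Desk-scale defaults (12000/4000/4 -> 2000 draws) keep
    a single fit around a second at n = 400; fidelity-scale runs
    (100000/60000/10 -> 4000 draws) are available for final analyses."""

    n_iter: int = 12_000
    burn_in: int = 4_000
    thin: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_retained < 100:
            raise ValueError("config retains fewer than 100 samples; lengthen the chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws and derived posterior summaries."""

    mu: np.ndarray  # (S,)
    sigma2_e: np.ndarray  # (S,)
    sigma2_alpha: np.ndarray  # (S,)
    delta: np.ndarray  # (S, r)
    eigen: EigenKernel
    missing_index: np.ndarray | None = None  # positions of imputed responses
    imputed_mean: np.ndarray | None = None  # posterior predictive means there

    @property
    def n_samples(self) -> int:
        return self.mu.shape[0]

    @property
    def delta_mean(self) -> np.ndarray:
        return self.delta.mean(axis=0)

    @property
    def alpha_hat(self) -> np.ndarray:
        """Posterior-mean regression coefficients, alpha = Lambda Psi^{-1} delta.

        Identified only within the span of the retained eigenvectors.
        """
        return self.eigen.eigenvectors @ (self.delta_mean / self.eigen.eigenvalues)

    @property
    def g_hat(self) -> np.ndarray:
        """Posterior-mean genetic values Lambda * delta_bar (= K alpha_hat)."""
        return self.eigen.eigenvectors @ self.delta_mean

    @property
    def mu_mean(self) -> float:
        return float(self.mu.mean())

    def summary(self) -> pd.DataFrame:
        lam = self.sigma2_e / self.sigma2_alpha
        rows = {}
        for name, draws in (
            ("mu", self.mu),
            ("sigma2_alpha", self.sigma2_alpha),
            ("sigma2_e", self.sigma2_e),
            ("lambda", lam),
        ):
            rows[name] = {
                "mean": float(np.mean(draws)),
                "sd": float(np.std(draws, ddof=1)),
                "q05": float(np.quantile(draws, 0.05)),
                "q95": float(np.quantile(draws, 0.95)),
                "ess": effective_sample_size(draws),
            }
        return pd.DataFrame(rows).T

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        draws = {"mu": self.mu, "sigma2_e": self.sigma2_e, "sigma2_alpha": self.sigma2_alpha}[name]
        a = (1.0 - level) / 2.0
        return float(np.quantile(draws, a)), float(np.quantile(draws, 1.0 - a))


# ---------------------------------------------------------------------------
# chain diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations (Geyer)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0.0:
        return float(n)
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    x = np.asarray(x, dtype=float)
    n = x.size
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)) :]
    va = np.var(a, ddof=1) / a.size
    vb = np.var(b, ddof=1) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


# ---------------------------------------------------------------------------
# eigendecomposition
# ---------------------------------------------------------------------------

def eigendecompose_kernel(
    k: KernelMatrix, tol: float = 1e-10, psd_tol: float = 1e-8
) -> EigenKernel:
    """Spectral factorization of a PSD kernel with truncation of null directions.

    Raises when an eigenvalue falls below -psd_tol * lambda_max (the kernel is
    genuinely indefinite; shrink it toward the identity first) and warns when
    the retained rank is below n (semi-definite input).
    """
    if not k.is_square:
        raise ValueError("only square kernels can be eigendecomposed")
    v = (k.values + k.values.T) / 2.0
    w, vec = np.linalg.eigh(v)
    lmax = float(w[-1])
    if lmax <= 0:
        raise ValueError("kernel has no positive eigenvalue")
    if w[0] < -psd_tol * lmax:
        raise ValueError(
            f"kernel is not PSD (lambda_min = {w[0]:.3e}); apply shrink_kernel before fitting"
        )
    keep = w > tol * lmax
    w, vec = w[keep][::-1], vec[:, keep][:, ::-1]
    if w.size < k.n:
        warnings.warn(
            f"kernel is semi-definite: retained rank {w.size} < n = {k.n}",
            stacklevel=2,
        )
    return EigenKernel(
        eigenvectors=vec,
        eigenvalues=w,
        truncation_tol=tol,
        family=k.family,
        theta=k.theta,
        individual_ids=list(k.row_ids),
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def gibbs_fit(
    y: np.ndarray,
    ek: EigenKernel,
    prior: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    fixed_variances: tuple[float, float] | None = None,
    include_intercept: bool = True,
    ess_warn: float = 100.0,
) -> PosteriorSamples:
    """Gibbs sampling for y = 1*mu + Lambda*delta + eps.

    All conditionals are conjugate: mu and each delta_j are normal (the
    orthonormal basis makes the delta draws independent given the variances)
    and both variances are scaled-inverse-chi-square.  ``fixed_variances``
    = (sigma2_alpha, sigma2_e) freezes the variances, giving draws from the
    ridge posterior with known lambda; ``include_intercept=False`` drops mu
    (the training model without an intercept), in which case y should be
    centered by the caller.

    Missing responses may be flagged with NaN; they are imputed each sweep
    from the predictive distribution (see :func:`fit_with_missing`).
    """
    prior = prior or PriorSpec()
    cfg = cfg or MCMCConfig()
    y = np.asarray(y, dtype=float).copy()
    n = ek.n
    if y.shape != (n,):
        raise ValueError(f"response has length {y.shape[0]} but kernel has n = {n}")
    miss = np.isnan(y)
    obs = ~miss
    if not np.any(obs):
        raise ValueError("all responses are missing")
    if np.sum(obs) < 3:
        raise ValueError("need at least 3 observed responses")
    if not np.all(np.isfinite(y[obs])):
        raise ValueError("responses must be finite or NaN (missing)")

    lam = ek.eigenvectors
    psi = ek.eigenvalues
    r = ek.rank
    rng = np.random.default_rng(cfg.seed)

    mu = float(np.mean(y[obs])) if include_intercept else 0.0
    delta = np.zeros(r)
    g = lam @ delta
    if fixed_variances is not None:
        s2a, s2e = map(float, fixed_variances)
        if s2a <= 0 or s2e <= 0:
            raise ValueError("fixed variances must be positive")
    else:
        s2e = float(np.var(y[obs])) or 1.0
        s2a = 1.0

    n_miss = int(np.sum(miss))
    S = cfg.n_retained
    out_mu = np.empty(S)
    out_s2e = np.empty(S)
    out_s2a = np.empty(S)
    out_delta = np.empty((S, r))
    imputed_sum = np.zeros(n_miss) if n_miss else None

    s = 0
    for it in range(cfg.n_iter):
        if n_miss:
            pred_miss = mu + g[miss]
            y[miss] = pred_miss + rng.standard_normal(n_miss) * np.sqrt(s2e)
        if include_intercept:
            resid_mean = float(np.mean(y - g))
            mu = rng.normal(resid_mean, np.sqrt(s2e / n))
        e = y - mu
        proj = lam.T @ e
        v = 1.0 / (1.0 / s2e + 1.0 / (psi * s2a))
        delta = v * proj / s2e + rng.standard_normal(r) * np.sqrt(v)
        g = lam @ delta
        if fixed_variances is None:
            ssa = float(np.sum(delta * delta / psi))
            s2a = (ssa + prior.df_alpha * prior.scale_alpha) / rng.chisquare(r + prior.df_alpha)
            resid = y - mu - g
            sse = float(resid @ resid)
            s2e = (sse + prior.df_e * prior.scale_e) / rng.chisquare(n + prior.df_e)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out_mu[s] = mu
            out_s2e[s] = s2e
            out_s2a[s] = s2a
            out_delta[s] = delta
            if n_miss:
                imputed_sum += mu + g[miss]
            s += 1

    post = PosteriorSamples(
        mu=out_mu,
        sigma2_e=out_s2e,
        sigma2_alpha=out_s2a,
        delta=out_delta,
        eigen=ek,
        missing_index=np.flatnonzero(miss) if n_miss else None,
        imputed_mean=imputed_sum / S if n_miss else None,
    )
    if fixed_variances is None:
        for name, draws in (("sigma2_alpha", out_s2a), ("sigma2_e", out_s2e)):
            ess = effective_sample_size(draws)
            if ess < ess_warn:
                warnings.warn(
                    f"effective sample size for {name} is {ess:.0f} (< {ess_warn:.0f}); "
                    "consider a longer chain",
                    stacklevel=2,
                )
    return post


def fit_with_missing(
    y_with_missing: np.ndarray,
    ek_full: EigenKernel,
    prior: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    fixed_variances: tuple[float, float] | None = None,
) -> tuple[PosteriorSamples, np.ndarray | None]:
    """Fit on a full (train + test) kernel, imputing NaN responses each sweep.

    Returns the posterior and the predictive means for the missing entries
    (None when nothing is missing, in which case this reduces exactly to
    :func:`gibbs_fit` with the same seed).
    """
    y = np.asarray(y_with_missing, dtype=float)
    post = gibbs_fit(y, ek_full, prior=prior, cfg=cfg, fixed_variances=fixed_variances)
    return post, post.imputed_mean


def predict(post: PosteriorSamples, k_test_train: KernelMatrix) -> np.ndarray:
    """Point predictions 1*mu_hat + K_test,train * alpha_hat for new individuals.

    The cross-kernel must match the training kernel's family and bandwidth;
    a mismatch is a hard error because mixing bandwidths across train and
    test silently corrupts predictions.
    """
    ek = post.eigen
    if k_test_train.values.shape[1] != ek.n:
        raise ValueError(
            f"cross-kernel has {k_test_train.values.shape[1]} columns but training n = {ek.n}"
        )
    if ek.family is not None and k_test_train.family not in (ek.family, "combined"):
        raise ValueError(
            f"cross-kernel family {k_test_train.family!r} does not match training family {ek.family!r}"
        )
    if (
        ek.theta is not None
        and k_test_train.theta is not None
        and not np.isclose(ek.theta, k_test_train.theta)
    ):
        raise ValueError(
            f"cross-kernel bandwidth {k_test_train.theta} does not match training bandwidth {ek.theta}"
        )
    return post.mu_mean + k_test_train.values @ post.alpha_hat


def ridge_solve(ek: EigenKernel, y_centered: np.ndarray, lam: float) -> np.ndarray:
    """Fixed-variance posterior mode: g_hat = Lambda diag(psi/(psi+lam)) Lambda' y.

    The deterministic kernel ridge path (lambda = sigma_e^2 / sigma_a^2),
    used by the fast cross-validation engine and for shrinkage diagnostics.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    proj = ek.eigenvectors.T @ np.asarray(y_centered, dtype=float)
    return ek.eigenvectors @ (proj * ek.eigenvalues / (ek.eigenvalues + lam))
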