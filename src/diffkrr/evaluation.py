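"""Predictive-ability assessment: splits, metrics, bandwidth grids, cross-validation.

Predictive ability is measured as Pearson's correlation between predicted
and observed responses and as mean squared prediction error (sum of squared
errors over n, not n-1), computed on pooled out-of-fold predictions;
per-fold values are also retained.  Bandwidths are chosen on a grid built by
inverting the mean off-diagonal kernel entry: a target mean similarity in
(0, 1) is mapped to theta by bisection on a seeded subsample of individuals,
which mirrors choosing bandwidths that span weak to near-perfect prior
correlation among individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kernels import GenotypeMatrix, KernelMatrix, build_kernel, validate_kernel, shrink_kernel
from .rkhs_regression import (
    MCMCConfig,
    PriorSpec,
    eigendecompose_kernel,
    gibbs_fit,
)

__all__ = [
    "SplitPlan",
    "make_split",
    "pearson",
    "mse",
    "theta_grid",
    "cross_validate",
]


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of individuals to disjoint, exhaustive folds.

    For ``k_fold`` the fold sizes differ by at most one; for
    ``holdout_by_group`` there is a single fold containing the individuals
    whose group label is in the test set (e.g. late birth years).
    """

    fold_assignments: np.ndarray  # fold id per individual; -1 = always train
    scheme: str
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.fold_assignments.shape[0]

    @property
    def n_folds(self) -> int:
        return int(self.fold_assignments.max()) + 1

    def folds(self):
        """Yield (train_indices, test_indices) per fold."""
        for f in range(self.n_folds):
            test = np.flatnonzero(self.fold_assignments == f)
            train = np.flatnonzero(self.fold_assignments != f)
            yield train, test

    def permuted(self, perm: np.ndarray) -> "SplitPlan":
        """The same plan after reordering individuals by ``perm``."""
        return SplitPlan(self.fold_assignments[np.asarray(perm)], self.scheme, self.seed)


def make_split(
    ids,
    scheme: str = "k_fold",
    k: int = 10,
    group_labels=None,
    test_groups=None,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic split plan given a seed.

    ``k_fold``: randomly assign n individuals to k disjoint subsets of
    near-equal size.  ``holdout_by_group``: individuals whose label is in
    ``test_groups`` form the single test fold (birth-year-style holdout).
    """
    n = len(ids)
    if scheme == "k_fold":
        if k < 2 or k > n:
            raise ValueError("need 2 <= k <= n folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            assign[chunk] = f
        return SplitPlan(fold_assignments=assign, scheme=scheme, seed=seed)
    if scheme == "holdout_by_group":
        if group_labels is None or test_groups is None:
            raise ValueError("holdout_by_group needs group_labels and test_groups")
        labels = np.asarray(group_labels)
        if labels.shape[0] != n:
            raise ValueError("group_labels length mismatch")
        unknown = set(test_groups) - set(labels.tolist())
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        assign = np.where(np.isin(labels, list(test_groups)), 0, -1)
        if not np.any(assign == 0) or np.all(assign == 0):
            raise ValueError("holdout must leave both a training and a testing set")
        return SplitPlan(fold_assignments=assign, scheme=scheme, seed=seed)
    raise ValueError(f"unknown scheme {scheme!r}")


def pearson(a, b) -> float:
    """Pearson correlation; raises on constant input where it is undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson needs two equal-length vectors of size >= 2")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("correlation is undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def mse(pred, obs) -> float:
    """Mean squared prediction error, sum((pred-obs)^2)/n."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("mse needs two equal-length non-empty vectors")
    d = pred - obs
    return float(d @ d / d.size)


# ---------------------------------------------------------------------------
# bandwidth grid
# ---------------------------------------------------------------------------

#: six target mean off-diagonal kernel values evenly spaced from 0.13 to 0.99
DEFAULT_TARGET_MEANS = tuple(np.round(np.linspace(0.13, 0.99, 6), 3))


def theta_grid(
    g: GenotypeMatrix,
    family: str,
    target_means=DEFAULT_TARGET_MEANS,
    subsample_size: int = 100,
    seed: int = 0,
    theta_cap: float = 1e6,
) -> np.ndarray:
    """Bandwidths whose mean off-diagonal kernel entry hits each target.

    Solved by bisection on a seeded subsample of individuals.  The mean is
    increasing in theta for the diffusion families and decreasing for the
    Gaussian; an unattainable target (mean bounded away from it at the cap)
    yields the capped theta with a warning.
    """
    targets = np.asarray(target_means, dtype=float)
    if np.any(targets <= 0) or np.any(targets >= 1) or np.any(np.diff(targets) <= 0):
        raise ValueError("target means must be strictly increasing inside (0, 1)")
    if family not in ("snpgrid", "hypercube", "gaussian"):
        raise ValueError("theta_grid applies to bandwidth kernels only")
    n = g.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    if n > subsample_size:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=subsample_size, replace=False))
        sub = GenotypeMatrix(
            codes=g.codes[idx],
            coding=g.coding,
            marker_ids=list(g.marker_ids),
            individual_ids=[g.individual_ids[i] for i in idx],
        )
    else:
        sub = g

    def mean_offdiag(theta: float) -> float:
        return build_kernel(sub, family, theta=theta).mean_offdiagonal()

    increasing = family != "gaussian"
    thetas = []
    for target in targets:
        lo, hi = 1e-8, 1.0
        f = (lambda t: mean_offdiag(t) - target) if increasing else (
            lambda t: target - mean_offdiag(t)
        )
        # f is increasing in theta under either orientation; expand the bracket
        while f(hi) < 0 and hi < theta_cap:
            hi *= 4.0
        if f(hi) < 0:
            warnings.warn(
                f"target mean {target} unattainable for family {family}; capping theta at {theta_cap:g}",
                stacklevel=2,
            )
            thetas.append(theta_cap if increasing else 1e-8)
            continue
        thetas.append(float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)))
    out = np.asarray(thetas)
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fit_predict_fold(K, ek, y, train, test, engine, prior, cfg, lam, fold_seed):
    if engine == "gibbs":
        y_miss = y.astype(float).copy()
        y_miss[test] = np.nan
        fold_cfg = MCMCConfig(
            n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin, seed=fold_seed
        )
        post = gibbs_fit(y_miss, ek, prior=prior, cfg=fold_cfg)
        return post.imputed_mean
    # deterministic ridge path: solve on the training block only
    Ktt = K[np.ix_(train, train)]
    Kxt = K[np.ix_(test, train)]
    ybar = float(np.mean(y[train]))
    alpha = np.linalg.solve(Ktt + lam * np.eye(train.size), y[train] - ybar)
    return ybar + Kxt @ alpha


def cross_validate(
    g: GenotypeMatrix,
    y: np.ndarray,
    kernels,
    split: SplitPlan,
    prior: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    engine: str = "gibbs",
    ridge_lambda: float = 1.0,
    shrink_if_needed: bool = True,
    psd_tol: float = 1e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Out-of-sample evaluation of kernel specifications.

    ``kernels`` is a sequence of (family, theta) pairs (theta None for
    g1/g2).  For each specification the full kernel is built once and
    eigendecomposed once; each fold is then fitted with the held-out
    responses treated as missing (engine ``gibbs``) or by the closed-form
    ridge path at fixed lambda (engine ``ridge``, deterministic and fast).
    Relationship matrices failing the PSD check are shrunk 0.95 toward the
    identity first.

    Returns (summary, per_fold): the summary has one row per specification
    with pooled correlation and MSE plus the mean diagonal/off-diagonal
    kernel entries; per_fold holds the same metrics fold by fold.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n_individuals or split.n != y.shape[0]:
        raise ValueError("genotypes, responses and split plan must agree in length")
    if engine not in ("gibbs", "ridge"):
        raise ValueError("engine must be 'gibbs' or 'ridge'")
    prior = prior or PriorSpec()
    cfg = cfg or MCMCConfig()

    summary_rows = []
    fold_rows = []
    for spec_idx, (family, theta) in enumerate(kernels):
        km = build_kernel(g, family, theta=theta)
        report = validate_kernel(km, tol=psd_tol)
        if not report.is_psd and shrink_if_needed:
            warnings.warn(
                f"{family} kernel not PSD (lambda_min={report.lambda_min:.2e}); "
                "shrinking 0.95 toward the identity",
                stacklevel=2,
            )
            km = shrink_kernel(km, 0.95)
        K = km.values
        ek = eigendecompose_kernel(km) if engine == "gibbs" else None

        preds = np.full(y.shape, np.nan)
        for fold_id, (train, test) in enumerate(split.folds()):
            fold_seed = (cfg.seed or 0) * 10_000 + spec_idx * 100 + fold_id
            preds[test] = _fit_predict_fold(
                K, ek, y, train, test, engine, prior, cfg, ridge_lambda, fold_seed
            )
            fold_rows.append(
                {
                    "kernel": family,
                    "theta": theta,
                    "fold": fold_id,
                    "correlation": pearson(preds[test], y[test]) if test.size > 2 else np.nan,
                    "mse": mse(preds[test], y[test]),
                }
            )
        evaluated = ~np.isnan(preds)
        summary_rows.append(
            {
                "kernel": family,
                "theta": theta,
                "mean_diag": km.mean_diagonal(),
                "mean_offdiag": km.mean_offdiagonal(),
                "correlation": pearson(preds[evaluated], y[evaluated]),
                "mse": mse(preds[evaluated], y[evaluated]),
            }
        )

    summary = pd.DataFrame(summary_rows)
    per_fold = pd.DataFrame(fold_rows)
    _warn_if_inconsistent(summary)
    return summary, per_fold


def _warn_if_inconsistent(summary: pd.DataFrame):
    """Soft check: within a family, the best-correlation theta should also
    have the smallest MSE.  A violation is reported, not raised -- with weak
    signal the two criteria can legitimately disagree."""
    for family, grp in summary.groupby("kernel"):
        if len(grp) < 2:
            continue
        best_corr = grp["correlation"].idxmax()
        best_mse = grp["mse"].idxmin()
        if best_corr != best_mse:
            warnings.warn(
                f"for kernel {family!r} the theta with highest correlation is not the theta "
                "with smallest MSE",
                stacklevel=3,
            )
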