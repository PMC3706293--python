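"""Kernel construction on marker data.

Five kernel families are provided:

* ``snpgrid`` -- heat kernel on the p-fold Cartesian product of the path
  graph 0-1-2, evaluated through its closed form: each locus contributes a
  factor depending only on whether the two genotypes differ by 1, differ by
  2, or are both heterozygous, so only the per-pair counts (n1, n2, m11)
  are needed.  Each factor is normalized by D = exp(-3*theta) +
  3*exp(-theta) + 2, hence matched non-heterozygous loci contribute exactly
  1 and the diagonal reflects heterozygosity (it is < 1 for heterozygous
  individuals -- the kernel smooths on heterozygosity as well as distance).
* ``hypercube`` -- heat kernel on the p-fold product of the two-vertex path,
  for binary markers; closed form tanh(theta)**d with d the Hamming
  distance, so the diagonal is exactly 1.
* ``gaussian`` -- exp(-theta * squared Euclidean distance) on the raw codes.
* ``g1`` / ``g2`` -- VanRaden additive genomic relationship matrices from
  centered (G1) or standardized (G2) allele dosages.

Pair counts are obtained from products of per-genotype indicator matrices
(three dense multiplications), never per-pair loops, and the diffusion
closed forms accumulate counts times log-factors so they cannot underflow
even at p ~ 4e4 markers and large bandwidths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PairSummary",
    "KernelMatrix",
    "KernelReport",
    "AlleleFrequencies",
    "pair_summary",
    "snpgrid_kernel_entry",
    "snpgrid_kernel",
    "hypercube_kernel",
    "gaussian_kernel",
    "estimate_allele_frequencies",
    "vanraden_g1",
    "vanraden_g2",
    "shrink_kernel",
    "hadamard_combine",
    "validate_kernel",
    "build_kernel",
]

#: accepted two-symbol alphabets for binary markers, mapped to Hamming {0,1}
_BINARY_ALPHABETS = ((0, 1), (0, 2), (-1, 1))

MISSING_CODE = -9


@dataclass
class GenotypeMatrix:
    """n x p integer marker codes with an explicit coding declaration.

    coding ``snp012`` counts copies of one allele (0/1/2, heterozygote = 1);
    coding ``binary`` is any of the two-symbol alphabets {0,1}, {0,2} or
    {-1,1} (X-chromosome dosages of sires, DArT presence/absence, fully
    inbred lines).  Missing values are only tolerated when
    ``allow_missing=True`` (sentinel :data:`MISSING_CODE`); they must be
    resolved by :func:`diffkrr.simulate.impute_missing` before any kernel is
    built.
    """

    codes: np.ndarray
    coding: str = "snp012"
    marker_ids: list | None = None
    individual_ids: list | None = None
    allow_missing: bool = False

    def __post_init__(self):
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D individuals x markers array")
        if not np.issubdtype(codes.dtype, np.integer):
            as_int = codes.astype(np.int64)
            if not np.array_equal(as_int, codes):
                raise ValueError("genotype codes must be integers")
            codes = as_int
        self.codes = codes
        if self.coding not in ("snp012", "binary"):
            raise ValueError(f"unknown coding {self.coding!r}")
        observed = codes[codes != MISSING_CODE] if self.allow_missing else codes
        values = set(np.unique(observed).tolist())
        if self.coding == "snp012":
            if not values <= {0, 1, 2}:
                raise ValueError(f"snp012 codes must be in {{0,1,2}}, found {sorted(values)}")
            self._alphabet = (0, 1, 2)
        else:
            for alphabet in _BINARY_ALPHABETS:
                if values <= set(alphabet):
                    self._alphabet = alphabet
                    break
            else:
                raise ValueError(
                    f"binary codes must use one of {_BINARY_ALPHABETS}, found {sorted(values)}"
                )
        if self.marker_ids is None:
            self.marker_ids = [f"m{j}" for j in range(codes.shape[1])]
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i}" for i in range(codes.shape[0])]
        if len(self.marker_ids) != codes.shape[1]:
            raise ValueError("marker_ids length mismatch")
        if len(self.individual_ids) != codes.shape[0]:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return self.allow_missing and bool(np.any(self.codes == MISSING_CODE))

    def hamming_codes(self) -> np.ndarray:
        """Binary codes mapped onto {0, 1} Hamming coordinates."""
        if self.coding != "binary":
            raise ValueError("hamming_codes is only defined for binary coding")
        lo, hi = self._alphabet
        return (self.codes == hi).astype(np.int64)

    def dosages(self) -> np.ndarray:
        """Allele dosages in {0, 1, 2} for relationship-matrix construction.

        Binary alphabets map their two symbols to dosages 0 and 2 (absence /
        presence of the counted allele on a fully homozygous background).
        """
        if self.coding == "snp012":
            return self.codes
        return 2 * self.hamming_codes()


@dataclass(frozen=True)
class PairSummary:
    """Per-pair counts indexing the diffusion closed forms.

    n1/n2: loci where the two genotype vectors differ by 1 / by 2;
    m11: loci where both are heterozygous; d: Hamming distance (binary
    coding).  Only q = n1 + n2 + m11 loci enter the SNP-grid product --
    matched non-heterozygous loci contribute a factor of exactly 1.
    """

    n1: int = 0
    n2: int = 0
    m11: int = 0
    d: int | None = None

    @property
    def q(self) -> int:
        return self.n1 + self.n2 + self.m11


@dataclass
class KernelMatrix:
    """Kernel values with provenance (family, bandwidth, marker block).

    Square kernels are symmetric PSD similarity matrices among one set of
    individuals; rectangular cross-kernels (test rows x train columns) carry
    the same provenance so prediction can refuse mismatched train/test
    kernels.
    """

    values: np.ndarray
    family: str
    theta: float | None = None
    block_id: str | None = None
    shrink_weight: float | None = None
    row_ids: list | None = None
    col_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kernel values must be 2-D")
        n, m = self.values.shape
        if self.row_ids is None:
            self.row_ids = [f"ind{i}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = list(self.row_ids) if n == m else [f"ind{j}" for j in range(m)]
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise ValueError("id length mismatch with kernel dimensions")

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def provenance_matches(self, other: "KernelMatrix") -> bool:
        same_theta = (
            (self.theta is None and other.theta is None)
            or (
                self.theta is not None
                and other.theta is not None
                and np.isclose(self.theta, other.theta)
            )
        )
        return self.family == other.family and same_theta

    def mean_diagonal(self) -> float:
        return float(np.mean(np.diag(self.values)))

    def mean_offdiagonal(self) -> float:
        v = self.values
        n = v.shape[0]
        if not self.is_square or n < 2:
            raise ValueError("mean_offdiagonal requires a square kernel with n >= 2")
        return float((v.sum() - np.trace(v)) / (n * (n - 1)))


@dataclass(frozen=True)
class AlleleFrequencies:
    """Frequencies of the counted allele, strictly inside (0, 1).

    Monomorphic loci have no variance to standardize and must be excluded
    before construction (``estimate_allele_frequencies`` does this and
    reports which loci were kept).
    """

    freqs: np.ndarray
    kept: np.ndarray | None = None  # indices of retained loci in the source matrix

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1:
            raise ValueError("freqs must be a vector")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# pair summaries and closed-form diffusion kernels
# ---------------------------------------------------------------------------

def pair_summary(x, y, coding: str = "snp012") -> PairSummary:
    """Counts (n1, n2, m11) for snp012 coding, Hamming distance for binary."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("genotype vectors must have equal length")
    if coding == "snp012":
        if not (set(np.unique(x)) <= {0, 1, 2} and set(np.unique(y)) <= {0, 1, 2}):
            raise ValueError("snp012 codes must be in {0,1,2}")
        diff = np.abs(x - y)
        return PairSummary(
            n1=int(np.sum(diff == 1)),
            n2=int(np.sum(diff == 2)),
            m11=int(np.sum((x == 1) & (y == 1))),
        )
    if coding == "binary":
        return PairSummary(d=int(np.sum(x != y)))
    raise ValueError(f"unknown coding {coding!r}")


def _snpgrid_log_factors(theta: float) -> tuple[float, float, float]:
    """log of the per-locus factors (A for n1, B for n2, C for m11).

    A = (2 - 2e^{-3t})/D, B = (e^{-3t} - 3e^{-t} + 2)/D, C = (4e^{-3t} + 2)/D
    with D = e^{-3t} + 3e^{-t} + 2 the normalizing constant; all three lie in
    (0, 1) for theta > 0.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    e3 = np.exp(-3.0 * theta)
    e1 = np.exp(-theta)
    log_d = np.log(e3 + 3.0 * e1 + 2.0)
    with np.errstate(divide="ignore"):  # B underflows to 0 at tiny theta; log -> -inf is correct
        log_a = np.log(2.0 - 2.0 * e3) - log_d
        log_b = np.log(e3 - 3.0 * e1 + 2.0) - log_d
    log_c = np.log(4.0 * e3 + 2.0) - log_d
    return log_a, log_b, log_c


def snpgrid_kernel_entry(s: PairSummary, theta: float) -> float:
    """Single SNP-grid kernel evaluation from pair counts.

    Accumulates n1*log A + n2*log B + m11*log C and exponentiates, which is
    exact and underflow-safe at any marker count.
    """
    log_a, log_b, log_c = _snpgrid_log_factors(theta)
    return float(np.exp(s.n1 * log_a + s.n2 * log_b + s.m11 * log_c))


def _pair_count_matrices(x: np.ndarray, y: np.ndarray):
    """All-pairs (n1, n2, m11) via indicator-matrix products."""
    p = x.shape[1]
    hx, h0x, h2x = (x == 1).astype(float), (x == 0).astype(float), (x == 2).astype(float)
    hy, h0y, h2y = (y == 1).astype(float), (y == 0).astype(float), (y == 2).astype(float)
    m11 = hx @ hy.T
    n2 = h0x @ h2y.T + h2x @ h0y.T
    matches = h0x @ h0y.T + hx @ hy.T + h2x @ h2y.T
    n1 = p - matches - n2
    return n1, n2, m11


def snpgrid_kernel(
    g: GenotypeMatrix, theta: float, g2: GenotypeMatrix | None = None, block_id: str | None = None
) -> KernelMatrix:
    """SNP-grid diffusion kernel on snp012 genotypes.

    With ``g2`` given, returns the rectangular cross-kernel with rows indexed
    by ``g`` and columns by ``g2`` (same bandwidth, for prediction).
    """
    if g.coding != "snp012":
        raise ValueError("snpgrid_kernel requires snp012 coding; use hypercube_kernel for binary markers")
    if g2 is not None and g2.coding != "snp012":
        raise ValueError("cross-kernel genotype matrix must also use snp012 coding")
    _require_complete(g, g2)
    log_a, log_b, log_c = _snpgrid_log_factors(theta)
    other = g if g2 is None else g2
    n1, n2, m11 = _pair_count_matrices(g.codes, other.codes)
    K = np.exp(n1 * log_a + n2 * log_b + m11 * log_c)
    if g2 is None:
        K = (K + K.T) / 2.0
    return KernelMatrix(
        values=K,
        family="snpgrid",
        theta=float(theta),
        block_id=block_id,
        row_ids=list(g.individual_ids),
        col_ids=list(other.individual_ids),
    )


def hypercube_kernel(
    g: GenotypeMatrix, theta: float, g2: GenotypeMatrix | None = None, block_id: str | None = None
) -> KernelMatrix:
    """Hypercube diffusion kernel tanh(theta)**d on binary markers.

    The per-locus heat-kernel ratio (1 - e^{-2 theta}) / (1 + e^{-2 theta})
    equals tanh(theta); normalization makes the diagonal exactly 1.
    """
    if g.coding != "binary":
        raise ValueError("hypercube_kernel requires binary coding; use snpgrid_kernel for snp012")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if g2 is not None and g2.coding != "binary":
        raise ValueError("cross-kernel genotype matrix must also use binary coding")
    _require_complete(g, g2)
    x = g.hamming_codes().astype(float)
    y = x if g2 is None else g2.hamming_codes().astype(float)
    p = x.shape[1]
    d = p - (x @ y.T + (1.0 - x) @ (1.0 - y).T)
    d = np.round(d)
    K = np.tanh(theta) ** d
    if g2 is None:
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(
        values=K,
        family="hypercube",
        theta=float(theta),
        block_id=block_id,
        row_ids=list(g.individual_ids),
        col_ids=list((g if g2 is None else g2).individual_ids),
    )


def gaussian_kernel(
    g: GenotypeMatrix, theta: float, g2: GenotypeMatrix | None = None, block_id: str | None = None
) -> KernelMatrix:
    """Gaussian kernel exp(-theta * ||x_i - x_j||^2) on the raw integer codes.

    Squared distances come from the inner-product expansion; tiny negative
    values from cancellation are clipped to zero so the diagonal is exactly 1.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    _require_complete(g, g2)
    x = g.codes.astype(float)
    y = x if g2 is None else g2.codes.astype(float)
    sx = np.einsum("ij,ij->i", x, x)
    sy = np.einsum("ij,ij->i", y, y)
    sq = sx[:, None] + sy[None, :] - 2.0 * (x @ y.T)
    np.clip(sq, 0.0, None, out=sq)
    K = np.exp(-theta * sq)
    if g2 is None:
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(
        values=K,
        family="gaussian",
        theta=float(theta),
        block_id=block_id,
        row_ids=list(g.individual_ids),
        col_ids=list((g if g2 is None else g2).individual_ids),
    )


def _require_complete(g: GenotypeMatrix, g2: GenotypeMatrix | None = None):
    for gm in (g, g2):
        if gm is not None and gm.has_missing:
            raise ValueError("genotypes contain missing values; run impute_missing first")


# ---------------------------------------------------------------------------
# additive genomic relationship kernels
# ---------------------------------------------------------------------------

def estimate_allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """In-data allele frequencies p_j = mean dosage / 2, dropping monomorphic loci.

    Using frequencies estimated from the data at hand yields positive
    semi-definite (not strictly definite) G matrices; monomorphic loci would
    put a zero in the G2 standardization and are excluded with a warning.
    """
    _require_complete(g)
    dos = g.dosages()
    p = dos.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    if not np.all(keep):
        warnings.warn(
            f"dropping {int(np.sum(~keep))} monomorphic loci from relationship-matrix construction",
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("all loci are monomorphic; no relationship matrix can be built")
    return AlleleFrequencies(freqs=p[keep], kept=np.flatnonzero(keep))


def _centered_dosages(g: GenotypeMatrix, f: AlleleFrequencies) -> np.ndarray:
    dos = g.dosages()
    if f.kept is not None:
        dos = dos[:, f.kept]
    if dos.shape[1] != f.freqs.shape[0]:
        raise ValueError("allele-frequency vector does not match marker count")
    return dos - 2.0 * f.freqs[None, :]


def vanraden_g1(
    g: GenotypeMatrix, f: AlleleFrequencies | None = None, g2: GenotypeMatrix | None = None
) -> KernelMatrix:
    """VanRaden G1 = Z Z' / (2 * sum p_j (1 - p_j)) from centered dosages."""
    _require_complete(g, g2)
    if f is None:
        if g2 is not None:
            raise ValueError("cross relationship matrices need explicitly supplied frequencies")
        f = estimate_allele_frequencies(g)
    z = _centered_dosages(g, f)
    z2 = z if g2 is None else _centered_dosages(g2, f)
    denom = 2.0 * np.sum(f.freqs * (1.0 - f.freqs))
    K = (z @ z2.T) / denom
    if g2 is None:
        K = (K + K.T) / 2.0
    return KernelMatrix(
        values=K,
        family="g1",
        row_ids=list(g.individual_ids),
        col_ids=list((g if g2 is None else g2).individual_ids),
    )


def vanraden_g2(
    g: GenotypeMatrix, f: AlleleFrequencies | None = None, g2: GenotypeMatrix | None = None
) -> KernelMatrix:
    """VanRaden G2 = W W' / p with per-locus standardized dosages w_j = z_j / sqrt(2 p_j (1-p_j))."""
    _require_complete(g, g2)
    if f is None:
        if g2 is not None:
            raise ValueError("cross relationship matrices need explicitly supplied frequencies")
        f = estimate_allele_frequencies(g)
    scale = np.sqrt(2.0 * f.freqs * (1.0 - f.freqs))
    w = _centered_dosages(g, f) / scale[None, :]
    w2 = w if g2 is None else _centered_dosages(g2, f) / scale[None, :]
    K = (w @ w2.T) / f.freqs.shape[0]
    if g2 is None:
        K = (K + K.T) / 2.0
    return KernelMatrix(
        values=K,
        family="g2",
        row_ids=list(g.individual_ids),
        col_ids=list((g if g2 is None else g2).individual_ids),
    )


# ---------------------------------------------------------------------------
# shrinkage, combination, validation
# ---------------------------------------------------------------------------

def shrink_kernel(k: KernelMatrix, weight: float = 0.95) -> KernelMatrix:
    """Shrink toward the identity: weight * K + (1 - weight) * I.

    Every eigenvalue moves to weight * lambda + (1 - weight), so a slightly
    indefinite relationship matrix becomes a valid kernel (the fix used when
    in-data allele frequencies make G numerically non-PSD).
    """
    if not 0.0 < weight <= 1.0:
        raise ValueError("weight must lie in (0, 1]")
    if not k.is_square:
        raise ValueError("only square kernels can be shrunk")
    v = weight * k.values + (1.0 - weight) * np.eye(k.n)
    return KernelMatrix(
        values=v,
        family=k.family,
        theta=k.theta,
        block_id=k.block_id,
        shrink_weight=weight if k.shrink_weight is None else weight * k.shrink_weight,
        row_ids=list(k.row_ids),
        col_ids=list(k.col_ids),
    )


def hadamard_combine(ks: list[KernelMatrix]) -> KernelMatrix:
    """Elementwise (Hadamard) product of per-block kernels.

    For the diffusion and Gaussian families this reproduces the kernel built
    on the concatenated markers, because those kernels factor over loci; PSD
    is preserved by the Schur product theorem.  Blocks may carry different
    bandwidths (e.g. autosomes vs allosomes), in which case the combined
    theta is left unset.
    """
    if not ks:
        raise ValueError("need at least one kernel to combine")
    first = ks[0]
    v = first.values.copy()
    for k in ks[1:]:
        if k.values.shape != first.values.shape:
            raise ValueError("kernels must have identical dimensions")
        if k.row_ids != first.row_ids or k.col_ids != first.col_ids:
            raise ValueError("kernels must index the same individuals in the same order")
        v *= k.values
    thetas = {k.theta for k in ks}
    blocks = [k.block_id for k in ks if k.block_id is not None]
    return KernelMatrix(
        values=v,
        family="combined" if len(ks) > 1 else first.family,
        theta=thetas.pop() if len(thetas) == 1 else None,
        block_id="#".join(blocks) if blocks else None,
        row_ids=list(first.row_ids),
        col_ids=list(first.col_ids),
    )


@dataclass(frozen=True)
class KernelReport:
    symmetry_residual: float
    lambda_min: float
    lambda_max: float
    is_psd: bool
    hint: str | None = None


def validate_kernel(k: KernelMatrix, tol: float = 1e-8) -> KernelReport:
    """Symmetry and positive-semi-definiteness check.

    Passes when lambda_min >= -tol * lambda_max; otherwise the report
    suggests shrinking toward the identity.
    """
    if not k.is_square:
        raise ValueError("only square kernels can be validated")
    v = k.values
    sym = float(np.max(np.abs(v - v.T))) if k.n else 0.0
    w = np.linalg.eigvalsh((v + v.T) / 2.0)
    lmin, lmax = float(w[0]), float(w[-1])
    ok = lmin >= -tol * max(lmax, 1.0)
    return KernelReport(
        symmetry_residual=sym,
        lambda_min=lmin,
        lambda_max=lmax,
        is_psd=ok,
        hint=None if ok else "kernel is not PSD at this tolerance; consider shrink_kernel(k, 0.95)",
    )


def build_kernel(
    g: GenotypeMatrix,
    family: str,
    theta: float | None = None,
    g2: GenotypeMatrix | None = None,
    f: AlleleFrequencies | None = None,
    block_id: str | None = None,
) -> KernelMatrix:
    """Dispatch on kernel family name (snpgrid | hypercube | gaussian | g1 | g2)."""
    family = family.lower()
    if family in ("snpgrid", "hypercube", "gaussian"):
        if theta is None:
            raise ValueError(f"{family} kernel requires a bandwidth theta")
        fn = {"snpgrid": snpgrid_kernel, "hypercube": hypercube_kernel, "gaussian": gaussian_kernel}[family]
        return fn(g, theta, g2=g2, block_id=block_id)
    if family == "g1":
        return vanraden_g1(g, f=f, g2=g2)
    if family == "g2":
        return vanraden_g2(g, f=f, g2=g2)
    raise ValueError(f"unknown kernel family {family!r}")
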