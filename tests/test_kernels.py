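"""Closed-form kernels against brute-force graph oracles, G matrices, combination."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffkrr import (
    GenotypeMatrix,
    PairSummary,
    estimate_allele_frequencies,
    gaussian_kernel,
    hadamard_combine,
    heat_kernel_exact,
    hypercube_kernel,
    pair_summary,
    path_graph_laplacian,
    shrink_kernel,
    simulate_genotypes,
    snpgrid_kernel,
    snpgrid_kernel_entry,
    validate_kernel,
    vanraden_g1,
    vanraden_g2,
    SimulationConfig,
)


def tensor_heat_oracle(codes: np.ndarray, theta: float, levels: int) -> np.ndarray:
    """Brute-force normalized tensor-product heat kernel at observed pairs.

    Per-locus factor = exp(theta*H_path)[x_i, x_j] normalized by the
    matched-homozygote entry, multiplied over loci.  Independent of the
    count-based closed form it checks.
    """
    Kp = heat_kernel_exact(path_graph_laplacian(levels), theta).values
    norm = Kp[0, 0]  # matched non-heterozygous genotype
    n, p = codes.shape
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            v = 1.0
            for l in range(p):
                v *= Kp[codes[i, l], codes[j, l]] / norm
            out[i, j] = v
    return out


class TestPairSummary:
    def test_counts_by_definition(self):
        s = pair_summary([0, 1, 2], [1, 1, 0])
        assert (s.n1, s.n2, s.m11) == (1, 1, 1)

    def test_self_pair_counts_shared_heterozygotes(self):
        s = pair_summary([1, 1, 0, 2], [1, 1, 0, 2])
        assert (s.n1, s.n2, s.m11) == (0, 0, 2)

    def test_binary_hamming_distance(self):
        s = pair_summary([0, 1, 1, 0], [0, 0, 1, 1], coding="binary")
        assert s.d == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pair_summary([0, 1], [0, 1, 2])

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.lists(st.integers(0, 2), min_size=1, max_size=30),
        y=st.lists(st.integers(0, 2), min_size=1, max_size=30),
    )
    def test_count_invariants(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        s = pair_summary(x, y)
        assert s.n1 >= 0 and s.n2 >= 0 and s.m11 >= 0
        assert s.n1 + s.n2 <= n
        assert s.m11 <= n - s.n1 - s.n2
        # symmetric in the two individuals
        t = pair_summary(y, x)
        assert (s.n1, s.n2, s.m11) == (t.n1, t.n2, t.m11)


class TestSnpgridKernel:
    def test_entry_with_no_informative_loci_is_one(self):
        assert snpgrid_kernel_entry(PairSummary(0, 0, 0), theta=2.0) == 1.0

    def test_entry_single_mismatch_matches_heat_kernel_ratio(self):
        # one locus differing by 1 at theta=1: A = (2-2e^-3)/(e^-3+3e^-1+2)
        val = snpgrid_kernel_entry(PairSummary(n1=1), theta=1.0)
        expected = (2 - 2 * np.exp(-3)) / (np.exp(-3) + 3 * np.exp(-1) + 2)
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.60266, abs=1e-5)

    def test_heterozygosity_factor_tends_to_one(self):
        assert snpgrid_kernel_entry(PairSummary(m11=3), theta=60.0) == pytest.approx(1.0, abs=1e-12)

    def test_underflow_safe_at_genome_scale(self):
        # 4e4 informative loci would underflow a naive product of factors < 1
        v = snpgrid_kernel_entry(PairSummary(n1=20_000, n2=10_000, m11=10_000), theta=0.05)
        assert v == 0.0 or v > 0.0  # finite, no overflow/NaN
        assert np.isfinite(v)

    def test_matrix_matches_tensor_product_oracle(self, small_snp_genotypes):
        g = small_snp_genotypes
        for theta in (0.5, 2.0):
            K = snpgrid_kernel(g, theta).values
            oracle = tensor_heat_oracle(g.codes, theta, levels=3)
            assert np.max(np.abs(K - oracle)) < 1e-10

    def test_identical_homozygous_individuals_give_one(self):
        g = GenotypeMatrix(codes=np.array([[0, 2, 2, 0], [0, 2, 2, 0]]))
        K = snpgrid_kernel(g, 1.5).values
        assert K[0, 1] == pytest.approx(1.0, abs=1e-14)

    def test_diagonal_dominates_rows(self):
        g = simulate_genotypes(SimulationConfig(n=60, p=300, n_qtl=2, seed=5))
        K = snpgrid_kernel(g, 8.0).values
        assert np.all(np.argmax(K, axis=1) == np.arange(60))
        assert K.diagonal().mean() > (K.sum() - np.trace(K)) / (60 * 59)

    def test_coding_invariance_allele_swap(self, small_snp_genotypes):
        g = small_snp_genotypes
        swapped = GenotypeMatrix(codes=2 - g.codes)
        assert np.allclose(
            snpgrid_kernel(g, 1.3).values, snpgrid_kernel(swapped, 1.3).values, atol=1e-14
        )

    def test_binary_coding_rejected(self, small_binary_genotypes):
        with pytest.raises(ValueError, match="hypercube"):
            snpgrid_kernel(small_binary_genotypes, 1.0)

    def test_distance_factors_monotone_in_theta(self):
        # the per-locus mismatch factors A (differ by 1) and B (differ by 2)
        # increase toward 1 with theta: larger bandwidth, stronger prior
        # correlation.  The shared-heterozygote factor C is deliberately
        # excluded: C(0) = 1, dips below 1 and returns to 1, so entries of
        # pairs sharing heterozygotes are not monotone in theta.
        thetas = [0.2, 0.5, 1.0, 3.0, 10.0]
        for counts in (PairSummary(n1=1), PairSummary(n2=1), PairSummary(n1=3, n2=2)):
            vals = [snpgrid_kernel_entry(counts, t) for t in thetas]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            assert vals[-1] < 1.0

    def test_hypercube_entries_monotone_in_theta(self, small_binary_genotypes):
        thetas = [0.2, 0.5, 1.0, 3.0]
        Ks = [hypercube_kernel(small_binary_genotypes, t).values for t in thetas]
        for a, b in zip(Ks, Ks[1:]):
            assert np.all(b - a >= -1e-12)


class TestHypercubeKernel:
    def test_diagonal_exactly_one(self, small_binary_genotypes):
        K = hypercube_kernel(small_binary_genotypes, 3.0).values
        assert np.all(np.diag(K) == 1.0)

    def test_entries_are_tanh_powers_of_hamming_distance(self, small_binary_genotypes):
        g = small_binary_genotypes
        K = hypercube_kernel(g, 3.0).values
        x = g.hamming_codes()
        for i in range(g.n_individuals):
            for j in range(g.n_individuals):
                d = np.sum(x[i] != x[j])
                assert K[i, j] == pytest.approx(np.tanh(3.0) ** d, abs=1e-12)

    def test_matches_tensor_product_oracle(self, small_binary_genotypes):
        g = small_binary_genotypes
        K = hypercube_kernel(g, 0.8).values
        oracle = tensor_heat_oracle(g.hamming_codes(), 0.8, levels=2)
        assert np.max(np.abs(K - oracle)) < 1e-10

    def test_single_distance_value(self):
        g = GenotypeMatrix(codes=np.array([[0, 0, 0], [1, 0, 0]]), coding="binary")
        K = hypercube_kernel(g, 3.0).values
        assert K[0, 1] == pytest.approx(np.tanh(3.0), abs=1e-12)
        assert K[0, 1] == pytest.approx(0.99505, abs=1e-5)

    def test_small_theta_limit_vanishes(self):
        g = GenotypeMatrix(codes=np.array([[0, 1], [1, 1]]), coding="binary")
        assert hypercube_kernel(g, 1e-9).values[0, 1] < 1e-8

    def test_snp_coding_rejected(self, small_snp_genotypes):
        with pytest.raises(ValueError, match="snpgrid"):
            hypercube_kernel(small_snp_genotypes, 1.0)

    def test_alphabet_mapping_equivalence(self):
        # {0,2} and {-1,1} alphabets give the same kernel
        codes02 = np.array([[0, 2, 2], [2, 2, 0], [0, 0, 0]])
        codes11 = np.where(codes02 == 2, 1, -1)
        K1 = hypercube_kernel(GenotypeMatrix(codes=codes02, coding="binary"), 2.0).values
        K2 = hypercube_kernel(GenotypeMatrix(codes=codes11, coding="binary"), 2.0).values
        assert np.allclose(K1, K2, atol=1e-14)


class TestGaussianKernel:
    def test_hand_computed_entry(self):
        g = GenotypeMatrix(codes=np.array([[0, 2], [2, 2]]))
        K = gaussian_kernel(g, 0.25).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_identical_rows_give_one(self):
        g = GenotypeMatrix(codes=np.array([[1, 2, 0], [1, 2, 0]]))
        assert gaussian_kernel(g, 0.7).values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_sharp_and_global_limits(self):
        # p large enough that no two individuals share a genotype vector
        g = simulate_genotypes(SimulationConfig(n=20, p=100, n_qtl=2, seed=14))
        assert np.unique(g.codes, axis=0).shape[0] == 20
        sharp = gaussian_kernel(g, 1e4).values
        assert np.allclose(sharp, np.eye(20), atol=1e-10)
        global_ = gaussian_kernel(g, 1e-9).values
        assert np.all(global_ > 0.999)

    def test_monotone_nonincreasing_in_theta(self, small_snp_genotypes):
        Ks = [gaussian_kernel(small_snp_genotypes, t).values for t in (0.01, 0.1, 1.0)]
        for a, b in zip(Ks, Ks[1:]):
            off = ~np.eye(20, dtype=bool)
            assert np.all(b[off] <= a[off] + 1e-12)

    def test_brute_force_distances(self, small_snp_genotypes, rng):
        g = small_snp_genotypes
        K = gaussian_kernel(g, 0.3).values
        i, j = 3, 7
        d2 = float(np.sum((g.codes[i] - g.codes[j]) ** 2))
        assert K[i, j] == pytest.approx(np.exp(-0.3 * d2), abs=1e-12)


class TestRelationshipMatrices:
    def test_inbred_mean_diagonal_is_two(self):
        g = simulate_genotypes(
            SimulationConfig(n=500, p=1000, n_qtl=2, maf_low=0.1, inbred=True, seed=3)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g1 = vanraden_g1(g)
            g2 = vanraden_g2(g)
        assert g1.mean_diagonal() == pytest.approx(2.0, abs=1e-10)
        assert g2.mean_diagonal() == pytest.approx(2.0, abs=1e-10)

    def test_hwe_outbred_centering(self, hwe_genotypes):
        g1 = vanraden_g1(hwe_genotypes)
        assert abs(g1.mean_diagonal() - 1.0) < 0.05
        assert abs(g1.mean_offdiagonal()) < 0.01

    def test_duplicated_individual_gives_constant_matrix(self):
        row = np.array([[0, 1, 2, 1, 0, 2]])
        g = GenotypeMatrix(codes=np.repeat(row, 5, axis=0))
        extra = GenotypeMatrix(codes=np.vstack([np.repeat(row, 5, axis=0), [[2, 1, 0, 1, 2, 0]]]))
        f = estimate_allele_frequencies(extra)
        sub = GenotypeMatrix(codes=np.repeat(row, 5, axis=0))
        K = vanraden_g1(sub, f=f).values
        assert np.allclose(K, K[0, 0])
        K2 = vanraden_g2(sub, f=f).values
        assert np.allclose(K2, K2[0, 0])

    def test_monomorphic_loci_dropped_with_warning(self):
        codes = np.array([[0, 2, 2], [0, 0, 2], [0, 2, 2]])  # first locus all 0, last all 2
        g = GenotypeMatrix(codes=codes)
        with pytest.warns(UserWarning, match="monomorphic"):
            f = estimate_allele_frequencies(g)
        assert f.freqs.shape == (1,)

    def test_g2_diag_close_to_g1_scaling(self, hwe_genotypes):
        g1 = vanraden_g1(hwe_genotypes)
        g2 = vanraden_g2(hwe_genotypes)
        # both scalings target a mean diagonal near 1 under HWE
        assert abs(g2.mean_diagonal() - g1.mean_diagonal()) < 0.1


class TestShrinkCombineValidate:
    def test_shrink_identity_fixed_point(self):
        from diffkrr.kernels import KernelMatrix

        k = KernelMatrix(values=np.eye(4), family="g1")
        assert np.allclose(shrink_kernel(k, 0.95).values, np.eye(4))

    def test_shrink_lifts_minimum_eigenvalue(self):
        from diffkrr.kernels import KernelMatrix

        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        vals = np.array([1.0, 0.8, 0.5, 0.3, 0.1, -0.01])
        k = KernelMatrix(values=(q * vals) @ q.T, family="g1")
        shrunk = shrink_kernel(k, 0.95)
        assert np.linalg.eigvalsh(shrunk.values).min() >= 0.0405 - 1e-12

    def test_shrink_weight_one_is_noop(self, small_snp_genotypes):
        k = snpgrid_kernel(small_snp_genotypes, 1.0)
        assert np.array_equal(shrink_kernel(k, 1.0).values, k.values)

    def test_hadamard_with_ones_is_identity_op(self, small_snp_genotypes):
        from diffkrr.kernels import KernelMatrix

        k = snpgrid_kernel(small_snp_genotypes, 1.0)
        ones = KernelMatrix(values=np.ones((20, 20)), family="combined", row_ids=k.row_ids)
        combined = hadamard_combine([k, ones])
        assert np.allclose(combined.values, k.values)

    @pytest.mark.parametrize("family_fn,coding", [
        (snpgrid_kernel, "snp012"),
        (hypercube_kernel, "binary"),
        (gaussian_kernel, "snp012"),
    ])
    def test_block_decomposition(self, family_fn, coding):
        cfg = SimulationConfig(n=15, p=12, n_qtl=2, inbred=(coding == "binary"), seed=21)
        g = simulate_genotypes(cfg)
        theta = 0.9
        whole = family_fn(g, theta).values
        parts = []
        for sl in (slice(0, 5), slice(5, 12)):
            sub = GenotypeMatrix(
                codes=g.codes[:, sl],
                coding=g.coding,
                individual_ids=list(g.individual_ids),
            )
            parts.append(family_fn(sub, theta))
        combined = hadamard_combine(parts).values
        assert np.max(np.abs(combined - whole)) < 1e-10

    def test_exponential_euclidean_kernel_violates_decomposition(self):
        # exp(-theta*||x-x'||) does NOT factor over marker blocks
        g = simulate_genotypes(SimulationConfig(n=10, p=6, n_qtl=2, seed=22))
        x = g.codes.astype(float)

        def expkernel(block):
            d = np.sqrt(
                np.maximum(
                    0,
                    (block**2).sum(1)[:, None] + (block**2).sum(1)[None, :] - 2 * block @ block.T,
                )
            )
            return np.exp(-0.5 * d)

        whole = expkernel(x)
        combined = expkernel(x[:, :3]) * expkernel(x[:, 3:])
        assert np.max(np.abs(whole - combined)) > 1e-3

    def test_validate_identity(self):
        from diffkrr.kernels import KernelMatrix

        rep = validate_kernel(KernelMatrix(values=np.eye(3), family="g1"))
        assert rep.is_psd and rep.lambda_min == pytest.approx(1.0)

    def test_validate_flags_indefinite_and_hints_shrink(self):
        from diffkrr.kernels import KernelMatrix

        v = np.diag([1.0, 1.0, -1e-3])
        rep = validate_kernel(KernelMatrix(values=v, family="g1"), tol=1e-8)
        assert not rep.is_psd
        assert "shrink" in rep.hint

    def test_snpgrid_kernel_is_psd(self, small_snp_genotypes):
        rep = validate_kernel(snpgrid_kernel(small_snp_genotypes, 1.0), tol=1e-8)
        assert rep.is_psd

    def test_dimension_mismatch_rejected(self, small_snp_genotypes):
        from diffkrr.kernels import KernelMatrix

        k = snpgrid_kernel(small_snp_genotypes, 1.0)
        other = KernelMatrix(values=np.eye(5), family="g1")
        with pytest.raises(ValueError):
            hadamard_combine([k, other])
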