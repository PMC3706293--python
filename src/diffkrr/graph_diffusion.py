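"""Exact diffusion machinery on genotype graphs.

Ordered genotype codes sit on path graphs: 0-1-2 for a biallelic SNP (one
mutational step separates the heterozygote from either homozygote) and 0-2
for a binary presence/absence marker.  Cartesian products of path graphs give
the SNP grid and the hypercube, whose heat kernels admit the closed forms
implemented in :mod:`diffkrr.kernels`.  This module builds the graphs
explicitly -- Laplacians, Cartesian products, step-wise diffusion, and matrix
exponentials -- so it serves both as a didactic API (``diffkrr diffuse-demo``)
and as the brute-force oracle against which the closed forms are checked.

Everything here is dense and intended for small graphs (|V| up to a few
hundred); the closed forms cover the whole-genome scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import KernelMatrix

__all__ = [
    "GraphLaplacian",
    "DiffusionState",
    "path_graph_laplacian",
    "complete_graph_laplacian",
    "cartesian_product_laplacian",
    "diffusion_step",
    "heat_kernel_exact",
]


class InvalidGraphError(ValueError):
    """Raised when a graph cannot be constructed or a matrix is not a Laplacian."""


@dataclass(frozen=True)
class GraphLaplacian:
    """Graph Laplacian L(Gamma) = degree matrix - adjacency matrix.

    The negated Laplacian H = -L drives diffusion (dk/dt = H k).  The stored
    ``matrix`` is H when ``negated`` is True, L otherwise; the ``L`` and ``H``
    properties always return the right sign, so callers never have to track
    the convention themselves.

    vertex_labels are ints for elementary graphs and coordinate tuples for
    Cartesian products, ordered lexicographically with the last coordinate
    varying fastest (Kronecker-product order).
    """

    vertex_labels: tuple
    matrix: np.ndarray
    negated: bool = True

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidGraphError("Laplacian must be square")
        if len(self.vertex_labels) != m.shape[0]:
            raise InvalidGraphError("vertex_labels length must match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidGraphError("Laplacian must be symmetric")
        if not np.allclose(m.sum(axis=1), 0.0, atol=1e-12):
            raise InvalidGraphError("Laplacian rows must sum to zero")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> np.ndarray:
        return -self.matrix if self.negated else self.matrix

    @property
    def H(self) -> np.ndarray:
        return self.matrix if self.negated else -self.matrix

    @property
    def max_degree(self) -> float:
        return float(np.max(np.diag(self.L)))


@dataclass
class DiffusionState:
    """Influence vector k(t, .) over graph vertices at discrete time t.

    ``rate`` is the per-edge diffusion rate (distinct from the regression
    coefficients of the ridge model).  When initialised from an indicator the
    values stay a probability vector for rate <= 1/max-degree.
    """

    values: np.ndarray
    time: int = 0
    rate: float = 0.1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @classmethod
    def indicator(cls, gl: GraphLaplacian, label, rate: float = 0.1) -> "DiffusionState":
        """Unit mass on one vertex: the time-0 diffusion."""
        idx = gl.vertex_labels.index(label)
        v = np.zeros(gl.n_vertices)
        v[idx] = 1.0
        return cls(values=v, time=0, rate=rate)


def path_graph_laplacian(levels: int) -> GraphLaplacian:
    """Laplacian of the path graph 0-1-...-(levels-1).

    levels=3 is the single-SNP genotype graph (aa-Aa-AA); levels=2 the
    binary-marker graph.
    """
    if levels < 2:
        raise InvalidGraphError("a path graph needs at least 2 vertices")
    L = np.zeros((levels, levels))
    for i in range(levels - 1):
        L[i, i + 1] = L[i + 1, i] = -1.0
    np.fill_diagonal(L, -L.sum(axis=1))
    return GraphLaplacian(vertex_labels=tuple(range(levels)), matrix=-L, negated=True)


def complete_graph_laplacian(levels: int) -> GraphLaplacian:
    """Laplacian of the complete graph K_levels (every genotype pair adjacent).

    The Hamming graph on one locus; provided for comparison with the path
    graph, which the SNP-grid kernel is actually built on.
    """
    if levels < 2:
        raise InvalidGraphError("a complete graph needs at least 2 vertices")
    L = -np.ones((levels, levels))
    np.fill_diagonal(L, levels - 1.0)
    return GraphLaplacian(vertex_labels=tuple(range(levels)), matrix=-L, negated=True)


def _as_tuple(label) -> tuple:
    return label if isinstance(label, tuple) else (label,)


def cartesian_product_laplacian(a: GraphLaplacian, b: GraphLaplacian) -> GraphLaplacian:
    """Laplacian of the Cartesian product Gamma_a x Gamma_b.

    Vertices are coordinate tuples; two vertices are adjacent iff they agree
    in all coordinates but one, where they are adjacent in the corresponding
    factor.  Algebraically L = L_a (x) I + I (x) L_b, so the labels are
    ordered with the b-coordinate varying fastest to match ``np.kron``.
    """
    La, Lb = a.L, b.L
    L = np.kron(La, np.eye(b.n_vertices)) + np.kron(np.eye(a.n_vertices), Lb)
    labels = tuple(
        _as_tuple(la) + _as_tuple(lb)
        for la, lb in itertools.product(a.vertex_labels, b.vertex_labels)
    )
    return GraphLaplacian(vertex_labels=labels, matrix=-L, negated=True)


def diffusion_step(state: DiffusionState, gl: GraphLaplacian, n_steps: int = 1) -> DiffusionState:
    """Advance the discrete diffusion k(t) = (I + rate*H) k(t-1) by n_steps.

    Mass (the vector sum) is conserved exactly because H has zero row sums.
    Rates above 1/max-degree remain well defined but lose the probabilistic
    reading (I + rate*H acquires negative entries); a warning is emitted.
    """
    if state.values.shape[0] != gl.n_vertices:
        raise ValueError(
            f"state has {state.values.shape[0]} entries but graph has {gl.n_vertices} vertices"
        )
    if gl.max_degree > 0 and state.rate > 1.0 / gl.max_degree + 1e-12:
        warnings.warn(
            f"diffusion rate {state.rate} exceeds 1/max-degree = {1.0 / gl.max_degree:.4g}; "
            "the update is defined but no longer a probability redistribution",
            stacklevel=2,
        )
    step = np.eye(gl.n_vertices) + state.rate * gl.H
    v = state.values
    for _ in range(n_steps):
        v = step @ v
    return DiffusionState(values=v, time=state.time + n_steps, rate=state.rate)


def heat_kernel_exact(gl: GraphLaplacian, theta: float) -> KernelMatrix:
    """Heat kernel exp(theta * H) via symmetric eigendecomposition.

    H = V diag(w) V' gives exp(theta*H) = V diag(exp(theta*w)) V', exact up to
    the eigensolver.  The result is symmetric positive definite and its rows
    sum to 1 (H has zero row sums, so the all-ones vector is a 0-eigenvector).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    H = gl.H
    if not np.allclose(H, H.T, atol=1e-12):
        raise ValueError("H must be symmetric")
    w, V = scipy.linalg.eigh(H)
    K = (V * np.exp(theta * w)) @ V.T
    K = (K + K.T) / 2.0
    return KernelMatrix(
        values=K,
        family="heat",
        theta=float(theta),
        row_ids=[str(l) for l in gl.vertex_labels],
        col_ids=[str(l) for l in gl.vertex_labels],
    )
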