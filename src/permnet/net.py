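"""Symmetric weighted-network primitives.

A weighted undirected network on ``n`` nodes is represented by a
:class:`DyadMatrix`: a symmetric ``n x n`` float matrix whose off-diagonal
entry ``w[i, j]`` is the weight of the unordered dyad ``{i, j}``. The
diagonal carries no information — self-dyads do not exist — and is stored
as zero; no analysis operation reads it.

Node indices are 0-based throughout the library. The CSV readers/writers in
:mod:`permnet.io` translate to and from 1-based user-facing node ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "DyadMatrix",
    "as_permutation",
    "strengths",
    "relabel",
    "dyad_pairs",
    "dyad_vector",
    "from_dyad_vector",
]


@dataclass(frozen=True)
class DyadMatrix:
    """Symmetric real matrix over unordered node pairs.

    Parameters
    ----------
    values
        Square array of shape ``(n, n)`` with ``n >= 2``. Must be symmetric
        and finite. The diagonal is forced to zero on construction.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError(f"expected a square matrix, got shape {w.shape}")
        if w.shape[0] < 2:
            raise InvalidInputError("a dyadic network needs at least 2 nodes")
        if not np.all(np.isfinite(w)):
            raise InvalidInputError("matrix contains non-finite entries")
        if not np.allclose(w, w.T, rtol=0.0, atol=1e-9):
            raise InvalidInputError("matrix is not symmetric")
        w = (w + w.T) / 2.0  # exact symmetry
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "values", w)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DyadMatrix):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.values, other.values)


def as_permutation(perm, n: int) -> np.ndarray:
    """Validate ``perm`` as a bijection of ``0..n-1`` and return it as an
    integer array."""
    p = np.asarray(perm, dtype=np.intp)
    if p.shape != (n,):
        raise InvalidInputError(f"permutation has length {p.size}, expected {n}")
    seen = np.zeros(n, dtype=bool)
    if p.min(initial=0) < 0 or p.max(initial=0) >= n:
        raise InvalidInputError("permutation entries out of range")
    seen[p] = True
    if not seen.all():
        raise InvalidInputError("mapping is not a bijection on node indices")
    return p


def strengths(net: DyadMatrix) -> np.ndarray:
    """Node strengths: the sum of each node's edge weights.

    The diagonal is zero by construction, so a plain row sum implements
    ``v(i) = sum_{j != i} w(i, j)``. Total strength equals twice the total
    edge weight over unordered pairs.
    """
    return net.values.sum(axis=1)


def relabel(net: DyadMatrix, perm) -> DyadMatrix:
    """Relabel nodes: node ``i`` of the input becomes node ``perm[i]``.

    The output satisfies ``w'(perm[i], perm[j]) = w(i, j)``, i.e. all of a
    node's connections move together — the operation underlying QAP.
    """
    p = as_permutation(perm, net.n)
    out = np.empty_like(net.values)
    out[np.ix_(p, p)] = net.values
    return DyadMatrix(out)


def dyad_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the ``n(n-1)/2`` unordered dyads, lexicographic
    in ``(i, j)`` with ``i < j``."""
    return np.triu_indices(n, k=1)


def dyad_vector(net: DyadMatrix) -> np.ndarray:
    """Vectorise a matrix over its unordered dyads in the fixed lexicographic
    order of :func:`dyad_pairs`."""
    return net.values[dyad_pairs(net.n)]


def from_dyad_vector(n: int, vec) -> DyadMatrix:
    """Reconstruct a :class:`DyadMatrix` from a dyad vector (inverse of
    :func:`dyad_vector`)."""
    v = np.asarray(vec, dtype=float)
    m = n * (n - 1) // 2
    if v.shape != (m,):
        raise InvalidInputError(f"dyad vector has length {v.size}, expected {m}")
    w = np.zeros((n, n))
    i, j = dyad_pairs(n)
    w[i, j] = v
    w[j, i] = v
    return DyadMatrix(w)
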