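"""Regression and permutation inference for nodal and dyadic network data.

Four procedures are provided, mirroring the methods commonly compared in
animal social network analysis:

``ols_nodal``
    Simple linear regression of a node-level response on a node-level
    predictor, with parametric (t-test) p-values.
``node_label_permutation_test``
    The same slope statistic, with a null distribution built by uniformly
    permuting node labels of the response.
``dyadic_ols``
    No-intercept least squares over mean-centred dyad vectors — the "naive"
    linear model for matrix-on-matrix regression.
``qap_test``
    The quadratic assignment procedure: the dyadic slope, with a null built
    by relabelling the nodes of the predictor matrix so that all of a node's
    edges are permuted together.
``mmlm_fit``
    A multimembership linear model ``y_ij = beta * x_ij + u_i + u_j + eps``
    in which every dyad receives the effects of both of its member nodes;
    solved as an exact linear least-squares problem.

Permutation p-values use the add-one estimator
``p = (1 + #{|b*| >= |b_obs|}) / (n_perm + 1)``, which counts the observed
statistic as a member of its own null and guarantees ``p > 0``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InvalidInputError
from .net import DyadMatrix, dyad_pairs, dyad_vector

__all__ = [
    "FitResult",
    "MMLMFit",
    "ols_nodal",
    "node_label_permutation_test",
    "dyadic_ols",
    "qap_test",
    "mmlm_fit",
    "exact_perm_null",
    "perm_pvalue_two_sided",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one regression / permutation test.

    ``null_sample`` is present exactly for permutation methods and holds the
    permuted slope statistics used to compute ``p``.
    """

    beta: float
    se: float
    stat: float
    p: float
    method: str
    null_sample: np.ndarray | None = None


@dataclass(frozen=True)
class MMLMFit:
    """Multimembership linear-model fit.

    ``node_effects`` is the fitted vector ``u`` (one entry per node);
    ``sigma2`` the residual variance estimate; ``dof`` the residual degrees
    of freedom ``n(n-1)/2 - (n + 1)``.
    """

    beta: float
    node_effects: np.ndarray
    sigma2: float
    se_beta: float
    stat: float
    p: float
    dof: int
    rss: float
    method: str = "MMLM"


def _as_vector(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return a


def perm_pvalue_two_sided(null_sample: np.ndarray, observed: float) -> float:
    """Add-one two-sided permutation p-value on the |statistic| ordering."""
    null_sample = np.asarray(null_sample, dtype=float)
    k = int(np.count_nonzero(np.abs(null_sample) >= abs(observed) - 1e-12))
    return (1 + k) / (null_sample.size + 1)


def ols_nodal(response, predictor) -> FitResult:
    """Simple linear regression (with intercept) of one node vector on
    another; two-sided t-test on the slope."""
    y = _as_vector(response, "response")
    x = _as_vector(predictor, "predictor")
    if y.size != x.size:
        raise InvalidInputError("response and predictor lengths differ")
    n = y.size
    if n < 3:
        raise InvalidInputError("need at least 3 nodes for nodal regression")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateDesignError("predictor is constant")
    yc = y - y.mean()
    beta = float(xc @ yc) / sxx
    rss = float(yc @ yc) - beta * beta * sxx
    dof = n - 2
    sigma2 = max(rss, 0.0) / dof
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        stat = math.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        stat = beta / se
        p = 2.0 * float(stats.t.sf(abs(stat), dof))
    return FitResult(beta=beta, se=se, stat=stat, p=p, method="LM-nodal")


def _permutation_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """(n_perm, n) array of independent uniform permutations of 0..n-1."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def node_label_permutation_test(
    response, predictor, n_perm: int = 10_000, rng: np.random.Generator | None = None
) -> FitResult:
    """Node-label permutation test with the regression slope as statistic.

    The response labels are permuted uniformly at random ``n_perm`` times;
    each permuted slope is recorded and the two-sided p-value compares the
    observed slope with that null on the |slope| ordering.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    obs = ols_nodal(response, predictor)
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    perms = _permutation_indices(rng, n_perm, y.size)
    # slope of permuted y on x: (xc . y_perm) / sxx  (centring of y is inert)
    null = (y[perms] @ xc) / sxx
    p = perm_pvalue_two_sided(null, obs.beta)
    return FitResult(
        beta=obs.beta, se=obs.se, stat=obs.beta, p=p,
        method="PERM-nodal", null_sample=null,
    )


def _dyad_slope_parts(x: DyadMatrix, y: DyadMatrix) -> tuple[np.ndarray, np.ndarray]:
    if x.n != y.n:
        raise InvalidInputError("x and y have different node counts")
    xv = dyad_vector(x)
    yv = dyad_vector(y)
    return xv - xv.mean(), yv - yv.mean()


def dyadic_ols(x: DyadMatrix, y: DyadMatrix) -> FitResult:
    """No-intercept least squares of the mean-centred dyad vectors.

    Each unordered dyad contributes one observation (``n(n-1)/2`` rows).
    Centring both vectors makes this identical to an intercept-including
    simple regression; the t-test uses ``n(n-1)/2 - 2`` degrees of freedom.
    """
    xc, yc = _dyad_slope_parts(x, y)
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateDesignError("predictor matrix is constant across dyads")
    m = xc.size
    beta = float(xc @ yc) / sxx
    rss = float(yc @ yc) - beta * beta * sxx
    dof = m - 2
    sigma2 = max(rss, 0.0) / dof
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        stat = math.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        stat = beta / se
        p = 2.0 * float(stats.t.sf(abs(stat), dof))
    return FitResult(beta=beta, se=se, stat=stat, p=p, method="LM-dyadic")


def qap_test(
    x: DyadMatrix, y: DyadMatrix, n_perm: int = 1000, rng: np.random.Generator | None = None
) -> FitResult:
    """Quadratic assignment procedure for dyadic regression.

    The predictor matrix is relabelled by ``n_perm`` uniform random node
    permutations — moving all of a node's edges at once — and the dyadic
    slope is recomputed for each. QAP reports the unadjusted slope estimate
    (identical to :func:`dyadic_ols`); only the p-value differs.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    obs = dyadic_ols(x, y)
    n = x.n
    iu, ju = dyad_pairs(n)
    xv_mat = x.values
    yv = dyad_vector(y)
    yc = yv - yv.mean()
    perms = _permutation_indices(rng, n_perm, n)
    # relabelled predictor dyad vectors: entry (i,j) of x after relabelling by
    # perm equals x[inv(perm)[i], inv(perm)[j]]; gathering rows/cols of x by
    # inv(perm) is the same as gathering by any uniform permutation, so perms
    # are used directly.
    xp = xv_mat[perms[:, iu], perms[:, ju]]  # (n_perm, m)
    xpc = xp - xp.mean(axis=1, keepdims=True)
    null = (xpc @ yc) / np.einsum("ij,ij->i", xpc, xpc)
    p = perm_pvalue_two_sided(null, obs.beta)
    return FitResult(
        beta=obs.beta, se=obs.se, stat=obs.beta, p=p,
        method="QAP", null_sample=null,
    )


def mmlm_design(x: DyadMatrix) -> np.ndarray:
    """Design matrix for the multimembership model: the dyad vector of ``x``
    followed by ``n`` node-incidence columns (each dyad row has a 1 in the
    columns of both its member nodes)."""
    n = x.n
    iu, ju = dyad_pairs(n)
    m = iu.size
    a = np.zeros((m, n + 1))
    a[:, 0] = dyad_vector(x)
    rows = np.arange(m)
    a[rows, 1 + iu] = 1.0
    a[rows, 1 + ju] = 1.0
    return a


def mmlm_fit(x: DyadMatrix, y: DyadMatrix) -> MMLMFit:
    """Fit ``y_ij = beta * x_ij + u_i + u_j + eps_ij`` by least squares.

    The objective is quadratic, so the exact minimiser is obtained from a
    dense least-squares solve; ``se_beta`` and the p-value come from a Wald
    t-test with ``n(n-1)/2 - (n+1)`` residual degrees of freedom.
    """
    if x.n != y.n:
        raise InvalidInputError("x and y have different node counts")
    n = x.n
    if n < 4:
        raise InvalidInputError("multimembership model needs at least 4 nodes")
    a = mmlm_design(x)
    yv = dyad_vector(y)
    coef, _, rank, _ = np.linalg.lstsq(a, yv, rcond=None)
    if rank < n + 1:
        # identify offending columns for the error message
        names = ["x"] + [f"u[{i}]" for i in range(n)]
        _, r = np.linalg.qr(a)
        bad = [names[k] for k in range(n + 1) if abs(r[k, k]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise DegenerateDesignError(
            f"design matrix is rank deficient (rank {rank} < {n + 1}); "
            f"dependent columns: {bad or 'unknown'}"
        )
    resid = yv - a @ coef
    rss = float(resid @ resid)
    m = yv.size
    dof = m - (n + 1)
    sigma2 = rss / dof
    xtx_inv_00 = float(np.linalg.inv(a.T @ a)[0, 0])
    se_beta = math.sqrt(sigma2 * xtx_inv_00)
    beta = float(coef[0])
    if se_beta == 0.0:
        stat = math.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        stat = beta / se_beta
        p = 2.0 * float(stats.t.sf(abs(stat), dof))
    return MMLMFit(
        beta=beta, node_effects=coef[1:], sigma2=sigma2, se_beta=se_beta,
        stat=stat, p=p, dof=dof, rss=rss,
    )


def exact_perm_null(statistic: Callable[[np.ndarray], float], size: int) -> np.ndarray:
    """Exhaustively enumerate the permutation null of ``statistic``.

    ``statistic`` receives each of the ``size!`` permutations of
    ``0..size-1`` (including the identity) exactly once. Only tractable for
    ``size <= 7`` (5040 permutations); larger sizes are refused.
    """
    if size > 7:
        raise InvalidInputError("exact enumeration limited to size <= 7")
    if size < 1:
        raise InvalidInputError("size must be >= 1")
    return np.array(
        [statistic(np.array(p, dtype=np.intp)) for p in itertools.permutations(range(size))]
    )


def exact_pvalue_two_sided(null: np.ndarray, observed: float) -> float:
    """Exact two-sided p: proportion of the full enumeration (which contains
    the identity, hence the observed statistic) at least as extreme as
    ``observed``."""
    null = np.asarray(null, dtype=float)
    return float(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12)) / null.size
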