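"""Synthetic data-generating processes for the four study designs.

Each simulator returns a fully specified sample with every latent variable
retained, so tests can check the construction directly:

``simulate_trait_strength``
    A gregariousness-driven sampling model: each of ``n`` individuals gets a
    Poisson gregariousness score; in each sampling period a pair interacts
    with probability proportional to their combined gregariousness. Edge
    weights are interaction rates (counts / periods). A binary sex trait is
    assigned either at random (null) or with probability increasing in
    gregariousness (effect).
``simulate_nodal_clique``
    Two latent cliques; edges exist with probability 0.8 within and 0.4
    between cliques, with U(0,1) weights. The nodal covariate is a linear
    combination of node strength, a per-clique U(0,1) value and U(0,1)
    noise — clique size confounds strength and covariate under the null.
``simulate_dyadic_node``
    Symmetric matrices built from node effects:
    ``x_ij = r_i + r_j + x'_ij`` and
    ``y_ij = b' * x_ij + (1 - b') * (s_i + s_j + y'_ij)``,
    all components i.i.d. U(0,1) (dyad noise drawn once per unordered pair).
``simulate_dyadic_clique``
    As above, plus overlapping 4-node cliques. Each clique carries a U(0,1)
    value; a node's clique load is the sum of the values of the cliques it
    belongs to, and the loads of both member nodes are added (scaled by
    ``clique_scale``) to the predictor and to the response structure. The
    shared load creates a real x-y association under the null that is
    invisible to naive OLS standard errors, is only partially captured by
    node relabelling (the load is shared *across* the two matrices), and is
    absorbed exactly by multimembership node effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError
from .net import DyadMatrix, dyad_pairs, from_dyad_vector, strengths

__all__ = [
    "TraitSimConfig",
    "NodalCliqueSimConfig",
    "DyadicNodeSimConfig",
    "DyadicCliqueSimConfig",
    "NodalSample",
    "DyadicSample",
    "simulate_trait_strength",
    "simulate_nodal_clique",
    "simulate_dyadic_node",
    "simulate_dyadic_clique",
]


def _default_interaction_scale(lam: float) -> float:
    # keeps (g_i + g_j) * scale inside [0, 1] except with negligible
    # probability (~1e-11 per dyad at lam = 5)
    return 1.0 / (2.0 * (lam + 6.0 * np.sqrt(lam)))


@dataclass(frozen=True)
class TraitSimConfig:
    """Configuration of the trait-based gregariousness simulation."""

    n: int = 20
    lam: float = 5.0
    periods: int = 60
    interaction_scale: float | None = None
    effect: bool = False
    sex_effect_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.lam <= 0:
            raise ConfigurationError("Poisson mean must be positive")
        if self.periods < 0:
            raise ConfigurationError("periods must be >= 0")
        if not 0.0 <= self.sex_effect_strength <= 1.0:
            raise ConfigurationError("sex_effect_strength must lie in [0, 1]")

    @property
    def scale(self) -> float:
        return (
            self.interaction_scale
            if self.interaction_scale is not None
            else _default_interaction_scale(self.lam)
        )


@dataclass(frozen=True)
class NodalCliqueSimConfig:
    """Configuration of the two-clique nodal simulation."""

    n: int = 20
    p_within: float = 0.8
    p_between: float = 0.4
    beta_strength: float = 0.0  # 0.05 for the effect case
    clique_coeff: float = 1.0
    noise_coeff: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ConfigurationError("require 0 <= p_between <= p_within <= 1")


@dataclass(frozen=True)
class DyadicNodeSimConfig:
    """Configuration of the node-dependence dyadic simulation."""

    n: int = 20
    beta_prime: float = 0.0  # 0.20 for the effect case

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if not 0.0 <= self.beta_prime <= 1.0:
            raise ConfigurationError("beta_prime must lie in [0, 1]")


@dataclass(frozen=True)
class DyadicCliqueSimConfig:
    """Configuration of the clique-dependence dyadic simulation."""

    n: int = 20
    clique_size: int = 4
    n_cliques: int = 10
    beta_prime: float = 0.0
    shared_clique_values: bool = True
    clique_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.clique_size != 4:
            raise ConfigurationError("clique_size is fixed at 4")
        if self.clique_size > self.n:
            raise ConfigurationError("clique_size cannot exceed n")
        if self.n_cliques < 0:
            raise ConfigurationError("n_cliques must be >= 0")
        if not 0.0 <= self.beta_prime <= 1.0:
            raise ConfigurationError("beta_prime must lie in [0, 1]")


@dataclass(frozen=True)
class NodalSample:
    """One nodal dataset: a network plus node-level variables.

    ``strength`` always equals ``strengths(net)`` exactly; ``trait`` is the
    covariate entering the nodal regression (0/1 sex, or the continuous
    clique-confounded covariate)."""

    net: DyadMatrix
    strength: np.ndarray
    trait: np.ndarray
    gregariousness: np.ndarray | None = None
    clique_label: np.ndarray | None = None
    clique_values: np.ndarray | None = None


@dataclass(frozen=True)
class DyadicSample:
    """One dyadic dataset: predictor and response matrices plus latents."""

    x: DyadMatrix
    y: DyadMatrix
    beta_prime: float
    r: np.ndarray | None = None
    s: np.ndarray | None = None
    cliques: tuple[frozenset, ...] = field(default_factory=tuple)
    clique_values: np.ndarray | None = None


def simulate_trait_strength(cfg: TraitSimConfig, rng: np.random.Generator) -> NodalSample:
    """Simulate one gregariousness-driven sampling network with a sex trait."""
    n = cfg.n
    g = rng.poisson(cfg.lam, size=n).astype(float)
    iu, ju = dyad_pairs(n)
    p = (g[iu] + g[ju]) * cfg.scale
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ConfigurationError(
            "interaction probability outside [0, 1]; reduce interaction_scale"
        )
    if cfg.periods == 0:
        w = np.zeros_like(p)
    else:
        counts = rng.binomial(cfg.periods, p)
        w = counts / cfg.periods
    net = from_dyad_vector(n, w)
    if cfg.effect:
        # rank-based assignment keeps probabilities inside [0, 1] for any
        # gregariousness distribution; strength controls the slope
        ranks = rankdata(g) / (n + 1)
        prob = 0.5 + cfg.sex_effect_strength * (ranks - 0.5)
        sex = (rng.random(n) < prob).astype(float)
    else:
        sex = (rng.random(n) < 0.5).astype(float)
    return NodalSample(net=net, strength=strengths(net), trait=sex, gregariousness=g)


def simulate_nodal_clique(cfg: NodalCliqueSimConfig, rng: np.random.Generator) -> NodalSample:
    """Simulate one two-clique network with a clique-confounded covariate."""
    n = cfg.n
    labels = rng.integers(0, 2, size=n)
    iu, ju = dyad_pairs(n)
    same = labels[iu] == labels[ju]
    p_edge = np.where(same, cfg.p_within, cfg.p_between)
    present = rng.random(iu.size) < p_edge
    w = np.where(present, rng.uniform(size=iu.size), 0.0)
    net = from_dyad_vector(n, w)
    s = strengths(net)
    v = rng.uniform(size=2)
    eps = rng.uniform(size=n)
    covariate = cfg.beta_strength * s + cfg.clique_coeff * v[labels] + cfg.noise_coeff * eps
    return NodalSample(
        net=net, strength=s, trait=covariate,
        clique_label=labels, clique_values=v,
    )


def simulate_dyadic_node(cfg: DyadicNodeSimConfig, rng: np.random.Generator) -> DyadicSample:
    """Simulate one predictor/response matrix pair with node dependence."""
    n = cfg.n
    b = cfg.beta_prime
    r = rng.uniform(size=n)
    s = rng.uniform(size=n)
    iu, ju = dyad_pairs(n)
    xp = rng.uniform(size=iu.size)
    yp = rng.uniform(size=iu.size)
    xv = r[iu] + r[ju] + xp
    yv = b * xv + (1.0 - b) * (s[iu] + s[ju] + yp)
    return DyadicSample(
        x=from_dyad_vector(n, xv), y=from_dyad_vector(n, yv),
        beta_prime=b, r=r, s=s,
    )


def simulate_dyadic_clique(cfg: DyadicCliqueSimConfig, rng: np.random.Generator) -> DyadicSample:
    """Simulate one matrix pair with overlapping 4-node clique dependence.

    Each clique's U(0,1) value loads onto its member nodes; node loads enter
    both the predictor and the response structure through the two member
    nodes of every dyad, scaled by ``clique_scale``. With
    ``shared_clique_values`` the same values drive both matrices (the
    confound of interest); otherwise the response cliques draw independent
    values and x and y are independent under ``beta_prime = 0``.
    """
    n = cfg.n
    b = cfg.beta_prime
    r = rng.uniform(size=n)
    s = rng.uniform(size=n)
    iu, ju = dyad_pairs(n)
    m = iu.size
    xp = rng.uniform(size=m)
    yp = rng.uniform(size=m)
    hx = np.zeros(n)
    hy = np.zeros(n)
    cliques = []
    cvals = np.empty(cfg.n_cliques)
    for k in range(cfg.n_cliques):
        members = rng.choice(n, size=cfg.clique_size, replace=False)
        cliques.append(frozenset(int(i) for i in members))
        cval = rng.uniform()
        cvals[k] = cval
        hx[members] += cval
        hy[members] += cval if cfg.shared_clique_values else rng.uniform()
    cx = cfg.clique_scale * (hx[iu] + hx[ju])
    cy = cfg.clique_scale * (hy[iu] + hy[ju])
    xv = r[iu] + r[ju] + xp + cx
    yv = b * xv + (1.0 - b) * (s[iu] + s[ju] + yp + cy)
    return DyadicSample(
        x=from_dyad_vector(n, xv), y=from_dyad_vector(n, yv),
        beta_prime=b, r=r, s=s, cliques=tuple(cliques), clique_values=cvals,
    )
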