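"""Monte-Carlo experiment harness: type-I-error / power studies and
effect-size summaries.

A :class:`ScenarioSpec` names one of the four simulation scenarios, whether
an effect is present, the replicate and permutation counts, and the master
seed. :func:`run_scenario` simulates each replicate once and applies every
method appropriate to the scenario to the same sample:

* nodal scenarios (``trait``, ``nodal-clique``): LM-nodal + PERM-nodal;
* dyadic scenarios (``dyadic-node``, ``dyadic-clique``): LM-dyadic + QAP +
  MMLM.

Randomness is organised so each replicate is independently reproducible:
replicate ``k`` of scenario ``s`` under master seed ``S`` uses the
numpy ``SeedSequence(S, spawn_key=(scenario_code, k))``, split into one
stream for simulation and one for permutation resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .regress import dyadic_ols, mmlm_fit, node_label_permutation_test, ols_nodal, qap_test
from .simulate import (
    DyadicCliqueSimConfig,
    DyadicNodeSimConfig,
    NodalCliqueSimConfig,
    TraitSimConfig,
    simulate_dyadic_clique,
    simulate_dyadic_node,
    simulate_nodal_clique,
    simulate_trait_strength,
)

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "ExperimentResult",
    "make_spec",
    "run_scenario",
    "positive_rate",
    "summarize_effects",
    "pvalue_histogram",
]

SCENARIOS = ("trait", "nodal-clique", "dyadic-node", "dyadic-clique")
_SCENARIO_CODE = {name: k for k, name in enumerate(SCENARIOS)}
NODAL_SCENARIOS = ("trait", "nodal-clique")
DYADIC_SCENARIOS = ("dyadic-node", "dyadic-clique")

# effect sizes used throughout the studies
_EFFECT_BETA_STRENGTH = 0.05
_EFFECT_BETA_PRIME = 0.20


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation study."""

    scenario: str
    effect: bool
    sim_cfg: object
    n_reps: int = 1000
    n_perm: int = 10_000  # 1000 for dyadic scenarios (QAP)
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidInputError(f"unknown scenario {self.scenario!r}")
        if self.n_reps < 1:
            raise InvalidInputError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must lie in (0, 1)")


def make_spec(
    scenario: str,
    effect: bool,
    master_seed: int,
    n_reps: int = 1000,
    n_perm: int | None = None,
    alpha: float = 0.05,
    **cfg_overrides,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` with the study-default simulator config.

    ``effect`` switches on the scenario's effect parameter (trait-linked sex,
    strength coefficient 0.05, or beta-prime 0.20). ``n_perm`` defaults to
    10,000 for nodal scenarios and 1000 for dyadic (QAP) scenarios.
    """
    if scenario == "trait":
        cfg = TraitSimConfig(effect=effect, **cfg_overrides)
    elif scenario == "nodal-clique":
        cfg = NodalCliqueSimConfig(
            beta_strength=_EFFECT_BETA_STRENGTH if effect else 0.0, **cfg_overrides
        )
    elif scenario == "dyadic-node":
        cfg = DyadicNodeSimConfig(
            beta_prime=_EFFECT_BETA_PRIME if effect else 0.0, **cfg_overrides
        )
    elif scenario == "dyadic-clique":
        cfg = DyadicCliqueSimConfig(
            beta_prime=_EFFECT_BETA_PRIME if effect else 0.0, **cfg_overrides
        )
    else:
        raise InvalidInputError(f"unknown scenario {scenario!r}")
    if n_perm is None:
        n_perm = 10_000 if scenario in NODAL_SCENARIOS else 1000
    return ScenarioSpec(
        scenario=scenario, effect=effect, sim_cfg=cfg,
        n_reps=n_reps, n_perm=n_perm, alpha=alpha, master_seed=master_seed,
    )


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate records plus per-method summary statistics."""

    spec: ScenarioSpec
    records: pd.DataFrame  # columns: rep, method, beta, p
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.summary is None:
            object.__setattr__(self, "summary", summarize_records(
                self.records, alpha=self.spec.alpha,
                true_sign=+1 if self.spec.effect else 0,
            ))

    def rates(self) -> Mapping[str, float]:
        """Positive rate (share of p < alpha) per method."""
        return dict(zip(self.summary["method"], self.summary["positive_rate"]))


def _replicate_rngs(spec: ScenarioSpec, rep: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(
        spec.master_seed, spawn_key=(_SCENARIO_CODE[spec.scenario], rep)
    )
    sim_ss, perm_ss = ss.spawn(2)
    return np.random.default_rng(sim_ss), np.random.default_rng(perm_ss)


def _run_replicate(spec: ScenarioSpec, rep: int) -> list[tuple[str, float, float]]:
    sim_rng, perm_rng = _replicate_rngs(spec, rep)
    out: list[tuple[str, float, float]] = []
    if spec.scenario in NODAL_SCENARIOS:
        if spec.scenario == "trait":
            sample = simulate_trait_strength(spec.sim_cfg, sim_rng)
            response, predictor = sample.strength, sample.trait
        else:
            sample = simulate_nodal_clique(spec.sim_cfg, sim_rng)
            response, predictor = sample.trait, sample.strength
        lm = ols_nodal(response, predictor)
        perm = node_label_permutation_test(response, predictor, spec.n_perm, perm_rng)
        out.append((lm.method, lm.beta, lm.p))
        out.append((perm.method, perm.beta, perm.p))
    else:
        if spec.scenario == "dyadic-node":
            sample = simulate_dyadic_node(spec.sim_cfg, sim_rng)
        else:
            sample = simulate_dyadic_clique(spec.sim_cfg, sim_rng)
        lm = dyadic_ols(sample.x, sample.y)
        qap = qap_test(sample.x, sample.y, spec.n_perm, perm_rng)
        mm = mmlm_fit(sample.x, sample.y)
        out.append((lm.method, lm.beta, lm.p))
        out.append((qap.method, qap.beta, qap.p))
        out.append((mm.method, mm.beta, mm.p))
    return out


def run_scenario(spec: ScenarioSpec) -> ExperimentResult:
    """Run one full Monte-Carlo study; returns records and summaries."""
    rows = []
    for rep in range(spec.n_reps):
        try:
            for method, beta, p in _run_replicate(spec, rep):
                rows.append((rep, method, beta, p))
        except Exception as exc:
            raise type(exc)(f"replicate {rep}: {exc}") from exc
    records = pd.DataFrame(rows, columns=["rep", "method", "beta", "p"])
    return ExperimentResult(spec=spec, records=records)


def positive_rate(pvals, alpha: float = 0.05) -> float:
    """Share of p-values below ``alpha`` (a TPR when an effect is present,
    an FPR under the null)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return float(np.count_nonzero(p < alpha)) / p.size


def summarize_effects(
    betas, pvals, true_sign: int = +1, alpha: float = 0.05
) -> dict[str, float]:
    """Distribution summary of effect-size estimates.

    Returns the median, the equal-tailed 95% empirical interval
    (linear-interpolation quantiles), the share of estimates with sign
    opposite ``true_sign``, and the share that are both wrong-signed and
    significant at ``alpha``. With ``true_sign = 0`` the sign rates are
    reported as NaN (no true direction exists under the null).
    """
    b = np.asarray(betas, dtype=float)
    p = np.asarray(pvals, dtype=float)
    if b.size != p.size:
        raise InvalidInputError("betas and pvals lengths differ")
    if b.size < 2:
        raise InvalidInputError("need at least 2 estimates to summarise")
    q025, med, q975 = np.quantile(b, [0.025, 0.5, 0.975])
    if true_sign == 0:
        wrong = wrong_sig = float("nan")
    else:
        bad = np.sign(b) == -np.sign(true_sign)
        wrong = float(np.count_nonzero(bad)) / b.size
        wrong_sig = float(np.count_nonzero(bad & (p < alpha))) / b.size
    return {
        "median": float(med),
        "q025": float(q025),
        "q975": float(q975),
        "wrong_sign_rate": wrong,
        "wrong_sign_sig_rate": wrong_sig,
    }


def summarize_records(
    records: pd.DataFrame, alpha: float = 0.05, true_sign: int = +1
) -> pd.DataFrame:
    """Per-method summary table recomputed purely from the records."""
    nan_summary = dict.fromkeys(
        ("median", "q025", "q975", "wrong_sign_rate", "wrong_sign_sig_rate"), float("nan")
    )
    rows = []
    for method, grp in records.groupby("method", sort=False):
        eff = (
            summarize_effects(grp["beta"], grp["p"], true_sign=true_sign, alpha=alpha)
            if len(grp) >= 2
            else nan_summary  # a single replicate has no distribution to summarise
        )
        rows.append({
            "method": method,
            "positive_rate": positive_rate(grp["p"], alpha),
            **eff,
        })
    return pd.DataFrame(rows)


def pvalue_histogram(pvals, n_bins: int = 20) -> np.ndarray:
    """Counts of p-values over ``n_bins`` equal-width bins on [0, 1]."""
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    counts, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return counts
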