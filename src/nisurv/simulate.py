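"""Monte Carlo verification of the design's operating characteristics.

Each simulated trial follows the planning model exactly: entry times are
uniform over the accrual period, latent event times exponential with the
true hazard, latent dropout times exponential with a dropout hazard (or
uniform over the study window, flag-switchable), and administrative
censoring falls at ``accrual + followup - entry``.  The observed time is
the minimum of the three; the event flag records whether the event came
first.

Replicate r draws from an RNG stream derived from ``(seed, r)``, so
replicates are order-independent and reproducible individually.

``operating_characteristics`` runs the gatekept dual test on every
replicate and reports rejection rates with Monte Carlo standard errors
``sqrt(p(1-p)/R)``.  Trials with zero events cannot reject (the hazard
MLE is degenerate) and are tallied separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analysis import Conclusion, TrialData, dual_test, fit_exponential
from .design import event_probability
from .hazards import NonInferiorityMargin, SurvivalSummary

__all__ = [
    "SimulationConfig",
    "OperatingCharacteristics",
    "simulate_trial",
    "operating_characteristics",
    "power_curve",
    "dropout_hazard_for_fraction",
]


def dropout_hazard_for_fraction(
    fraction: float, event_hazard: float, accrual: float, followup: float
) -> float:
    """Dropout hazard giving an expected dropout fraction by study end.

    A patient counts as a dropout when their exponential dropout time
    precedes both the event and administrative censoring.  That
    probability is ``lam_d/(lam_e+lam_d) * P_any(lam_e+lam_d)`` with
    ``P_any`` the any-cause observed-event probability under the accrual
    and follow-up windows; the rate is found by root bracketing.
    """
    if fraction == 0:
        return 0.0
    if not 0 < fraction < 1:
        raise ValueError(f"dropout fraction must be in [0, 1), got {fraction}")

    def realized(lam_d: float) -> float:
        total = event_hazard + lam_d
        return lam_d / total * event_probability(total, accrual, followup)

    hi = 1.0
    while realized(hi) < fraction:
        hi *= 2
        if hi > 1e6:
            raise ValueError("dropout fraction unattainable")
    return float(brentq(lambda x: realized(x) - fraction, 1e-12, hi, xtol=1e-12))


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario plus the decision rule applied to each trial."""

    true_hazard: float
    n_patients: int
    accrual: float
    followup: float
    control: SurvivalSummary
    nim: NonInferiorityMargin | float
    alpha: float
    dropout_hazard: float = 0.0
    dropout_model: Literal["exponential", "uniform"] = "exponential"
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_hazard > 0:
            raise ValueError("true hazard must be positive")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.dropout_hazard < 0:
            raise ValueError("dropout hazard must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def simulate_trial(config: SimulationConfig, replicate_index: int = 0) -> TrialData:
    """Simulate one trial; deterministic given ``(config.seed, replicate_index)``."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(replicate_index,))
    )
    n = config.n_patients
    entry = rng.uniform(0.0, config.accrual, size=n) if config.accrual > 0 else np.zeros(n)
    event_time = rng.exponential(1.0 / config.true_hazard, size=n)
    if config.dropout_hazard > 0:
        if config.dropout_model == "exponential":
            dropout_time = rng.exponential(1.0 / config.dropout_hazard, size=n)
        else:
            dropout_time = rng.uniform(
                0.0, config.accrual + config.followup, size=n
            )
    else:
        dropout_time = np.full(n, np.inf)
    admin_time = config.accrual + config.followup - entry
    observed = np.minimum(np.minimum(event_time, dropout_time), admin_time)
    # strictly positive observed times (zero-probability tie guard)
    observed = np.maximum(observed, np.finfo(float).tiny)
    flag = (event_time <= np.minimum(dropout_time, admin_time)).astype(int)
    return TrialData(time=observed, event=flag, entry=entry)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical size/power of the dual decision over simulated trials."""

    replicates: int
    reject_ni_rate: float
    reject_sup_rate: float
    reject_ni_se: float
    reject_sup_se: float
    conclusion_freqs: dict[str, float]
    mean_events: float
    mean_event_fraction: float
    zero_event_trials: int
    config: SimulationConfig = field(compare=False)

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "reject_ni_rate": self.reject_ni_rate,
            "reject_sup_rate": self.reject_sup_rate,
            "reject_ni_se": self.reject_ni_se,
            "reject_sup_se": self.reject_sup_se,
            "conclusion_freqs": dict(self.conclusion_freqs),
            "mean_events": self.mean_events,
            "mean_event_fraction": self.mean_event_fraction,
            "zero_event_trials": self.zero_event_trials,
        }


def operating_characteristics(config: SimulationConfig) -> OperatingCharacteristics:
    """Run the dual test on every replicate and tally the decisions."""
    counts = {c.value: 0 for c in Conclusion}
    reject_ni = 0
    reject_sup = 0
    zero_events = 0
    total_events = 0
    for r in range(config.replicates):
        trial = simulate_trial(config, r)
        d = int(trial.event.sum())
        total_events += d
        if d == 0:
            zero_events += 1
            counts[Conclusion.INCONCLUSIVE.value] += 1
            continue
        outcome = fit_exponential(trial)
        decision = dual_test(outcome, config.control, config.nim, config.alpha)
        counts[decision.conclusion.value] += 1
        if decision.conclusion is not Conclusion.INCONCLUSIVE:
            reject_ni += 1
        if decision.conclusion is Conclusion.SUPERIOR:
            reject_sup += 1
    R = config.replicates
    p_ni = reject_ni / R
    p_sup = reject_sup / R
    return OperatingCharacteristics(
        replicates=R,
        reject_ni_rate=p_ni,
        reject_sup_rate=p_sup,
        reject_ni_se=math.sqrt(p_ni * (1 - p_ni) / R),
        reject_sup_se=math.sqrt(p_sup * (1 - p_sup) / R),
        conclusion_freqs={k: v / R for k, v in counts.items()},
        mean_events=total_events / R,
        mean_event_fraction=total_events / (R * config.n_patients),
        zero_event_trials=zero_events,
        config=config,
    )


def power_curve(configs: list[SimulationConfig]) -> pd.DataFrame:
    """Operating characteristics over a grid of scenarios, one row each."""
    if not configs:
        raise ValueError("need at least one configuration")
    rows = []
    for cfg in configs:
        oc = operating_characteristics(cfg)
        rows.append(
            {
                "true_hazard": cfg.true_hazard,
                "true_median": math.inf
                if cfg.true_hazard == 0
                else math.log(2) / cfg.true_hazard,
                "n_patients": cfg.n_patients,
                "replicates": cfg.replicates,
                **{
                    k: v
                    for k, v in oc.to_dict().items()
                    if k not in ("conclusion_freqs", "replicates")
                },
                **{f"freq_{k}": v for k, v in oc.conclusion_freqs.items()},
            }
        )
    return pd.DataFrame(rows)


def scenario_at_true_median(
    config: SimulationConfig, true_median: float
) -> SimulationConfig:
    """The same scenario with the true hazard re-anchored at a median."""
    return replace(config, true_hazard=math.log(2) / true_median)
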