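"""Final analysis of a single-arm time-to-event trial.

The parametric path fits the exponential model by maximum likelihood with
right censoring — the hazard estimate is events over total exposure — and
tests each null hazard with the asymptotic normal statistic for the
log-hazard,

    z = sqrt(d) * (ln(lam_null) - ln(lam_hat)),    p = 1 - Phi(z),

whose variance 1/d is the inverse Fisher information given d events.  A
small p favors the treatment (observed hazard below the null).

The dual decision is hierarchical (gatekept): the non-inferiority null
(control hazard times the margin) is tested first; only when it is
rejected is the superiority null (the control hazard itself) tested, at
the same unadjusted alpha.  Because the non-inferiority null hazard is at
least the superiority null hazard, p_NI <= p_sup always, so the gate
controls the overall one-sided type I error without alpha splitting.

The nonparametric path estimates the Kaplan–Meier median with a
Brookmeyer–Crowley-style confidence interval (log-minus-log Greenwood
interval for S(t), inverted at 0.5) and compares its lower bound against
median thresholds for the two nulls.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.stats import norm

from .hazards import LN2, NonInferiorityMargin, SurvivalSummary, shifted_null

__all__ = [
    "TrialData",
    "TrialOutcome",
    "HypothesisResult",
    "Conclusion",
    "DualDecision",
    "KMDecision",
    "fit_exponential",
    "one_sided_exponential_test",
    "dual_test",
    "effect_sizes",
    "km_decision",
    "decide_from_median_ci",
]


@dataclass(frozen=True)
class TrialData:
    """Patient-level observations: observed time, event flag, optional entry.

    ``time`` is months from entry to event or censoring (> 0);
    ``event`` is 1 for an observed event, 0 for censoring.  ``entry``
    (months from study start) is kept for validation and simulation
    provenance only — the exponential likelihood depends only on exposure
    and event counts.
    """

    time: np.ndarray
    event: np.ndarray
    entry: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.all(time > 0):
            raise ValueError("all observed times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        if self.entry is not None:
            entry = np.asarray(self.entry, dtype=float)
            object.__setattr__(self, "entry", entry)
            if entry.shape != time.shape:
                raise ValueError("entry must match time in length")
            if not np.all(entry >= 0):
                raise ValueError("entry times must be non-negative")

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_records(
        cls,
        times: Sequence[float],
        events: Sequence[int],
        entries: Sequence[float] | None = None,
    ) -> "TrialData":
        return cls(
            time=np.asarray(times, dtype=float),
            event=np.asarray(events, dtype=int),
            entry=None if entries is None else np.asarray(entries, dtype=float),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialData":
        """Build from a table with columns ``time`` and ``event``
        (optional ``entry_time``)."""
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        bad = df.index[~df["event"].isin([0, 1])]
        if len(bad):
            raise ValueError(f"event flags outside {{0,1}} at rows {list(bad)}")
        entries = df["entry_time"].to_numpy() if "entry_time" in df.columns else None
        return cls.from_records(df["time"].to_numpy(), df["event"].to_numpy(), entries)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        """Read a patient CSV: header ``patient_id,time,event[,entry_time]``."""
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": np.arange(1, len(self) + 1),
                "time": self.time,
                "event": self.event,
            }
        )
        if self.entry is not None:
            df["entry_time"] = self.entry
        return df

    def validate_against_study(self, accrual: float, followup: float) -> None:
        """Check no observation outruns its administrative censoring window."""
        if self.entry is None:
            return
        limit = accrual + followup - self.entry
        if np.any(self.time > limit + 1e-9):
            raise ValueError(
                "observed time exceeds study duration minus entry for some patients"
            )


@dataclass(frozen=True)
class TrialOutcome:
    """Exponential MLE summary of a trial: d events over T patient-months."""

    n: int
    events: int
    total_exposure: float
    hazard_hat: float
    median_hat: float


@dataclass(frozen=True)
class HypothesisResult:
    """A one-sided test of ``H0: hazard >= null_hazard`` plus effect sizes.

    Effect sizes are the signed differences of the estimate from the null
    on both scales: ``median_hat - null_median`` and
    ``hazard_hat - null_hazard``.
    """

    null_hazard: float
    null_median: float
    z_value: float
    p_value: float
    effect_size_median: float
    effect_size_hazard: float


class Conclusion(enum.Enum):
    SUPERIOR = "superior"
    NON_INFERIOR_ONLY = "non_inferior_only"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class DualDecision:
    """Ranked outcome of the gatekept non-inferiority-then-superiority test."""

    ni_result: HypothesisResult
    sup_result: HypothesisResult | None
    conclusion: Conclusion
    alpha: float


@dataclass(frozen=True)
class KMDecision:
    """Outcome of the nonparametric median-CI decision rule."""

    median: float
    ci_lower: float
    ci_upper: float
    confidence: float
    ni_threshold: float
    sup_threshold: float
    conclusion: Conclusion
    diagnostic: str = ""


def fit_exponential(data: TrialData) -> TrialOutcome:
    """Exponential MLE with right censoring: ``lam_hat = d / sum(time)``.

    Raises when no events were observed — the hazard MLE is then zero and
    the log-hazard test undefined; use the Kaplan–Meier path instead.
    """
    d = int(data.event.sum())
    if d < 1:
        raise ValueError(
            "no events observed: the exponential hazard cannot be estimated; "
            "use the nonparametric (Kaplan-Meier) decision path"
        )
    exposure = float(data.time.sum())
    lam = d / exposure
    return TrialOutcome(
        n=len(data),
        events=d,
        total_exposure=exposure,
        hazard_hat=lam,
        median_hat=LN2 / lam,
    )


def one_sided_exponential_test(
    outcome: TrialOutcome, null_hazard: float
) -> HypothesisResult:
    """Test ``H0: hazard >= null_hazard`` against the one-sided alternative.

    ``z = sqrt(d) (ln null - ln lam_hat)`` is standard normal under the
    boundary null; ``p = 1 - Phi(z)`` is small when the observed hazard
    falls below the null.  ``p = 0.5`` exactly at ``lam_hat = null``.
    """
    if outcome.events < 1:
        raise ValueError("at least one event is required")
    if not null_hazard > 0:
        raise ValueError(f"null hazard must be positive, got {null_hazard}")
    z = math.sqrt(outcome.events) * (
        math.log(null_hazard) - math.log(outcome.hazard_hat)
    )
    null_median = LN2 / null_hazard
    return HypothesisResult(
        null_hazard=null_hazard,
        null_median=null_median,
        z_value=z,
        p_value=float(norm.sf(z)),
        effect_size_median=outcome.median_hat - null_median,
        effect_size_hazard=outcome.hazard_hat - null_hazard,
    )


def dual_test(
    outcome: TrialOutcome,
    control: SurvivalSummary,
    nim: NonInferiorityMargin | float,
    alpha: float,
) -> DualDecision:
    """Gatekept dual test: non-inferiority first, then superiority.

    Both tests run at the same unadjusted ``alpha``.  Superiority can only
    be declared after non-inferiority is; the ranked conclusion is
    ``superior > non_inferior_only > inconclusive``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ni_null = shifted_null(control, nim)
    ni = one_sided_exponential_test(outcome, ni_null.hazard)
    if ni.p_value >= alpha:
        return DualDecision(
            ni_result=ni, sup_result=None,
            conclusion=Conclusion.INCONCLUSIVE, alpha=alpha,
        )
    sup = one_sided_exponential_test(outcome, control.hazard)
    conclusion = (
        Conclusion.SUPERIOR if sup.p_value < alpha else Conclusion.NON_INFERIOR_ONLY
    )
    return DualDecision(
        ni_result=ni, sup_result=sup, conclusion=conclusion, alpha=alpha
    )


def effect_sizes(
    outcome: TrialOutcome,
    control: SurvivalSummary,
    nim: NonInferiorityMargin | float,
) -> dict[str, dict[str, float]]:
    """Signed effect sizes versus both nulls, on the median and hazard scales.

    With a margin above 1 the non-inferiority null is the easier target,
    so whenever the observed median reaches the control median the
    non-inferiority effects exceed the superiority effects in absolute
    value on both scales.
    """
    ni_null = shifted_null(control, nim)
    return {
        "superiority": {
            "median": outcome.median_hat - control.median,
            "hazard": outcome.hazard_hat - control.hazard,
        },
        "non_inferiority": {
            "median": outcome.median_hat - ni_null.median,
            "hazard": outcome.hazard_hat - ni_null.hazard,
        },
    }


def decide_from_median_ci(
    ci_lower: float, ni_threshold: float, sup_threshold: float
) -> Conclusion:
    """Rank a median-CI lower bound against the two median thresholds."""
    if ni_threshold > sup_threshold:
        raise ValueError("non-inferiority threshold must not exceed superiority's")
    if not math.isfinite(ci_lower):
        return Conclusion.INCONCLUSIVE
    if ci_lower > sup_threshold:
        return Conclusion.SUPERIOR
    if ci_lower > ni_threshold:
        return Conclusion.NON_INFERIOR_ONLY
    return Conclusion.INCONCLUSIVE


def km_decision(
    data: TrialData,
    sup_threshold: float,
    ni_threshold: float,
    confidence: float = 0.90,
) -> KMDecision:
    """Nonparametric decision: Kaplan–Meier median CI versus thresholds.

    Non-inferiority is achieved when the two-sided CI lower bound for the
    median exceeds ``ni_threshold``; superiority when it also exceeds
    ``sup_threshold``.  The CI is the log-minus-log (exponential
    Greenwood) interval for S(t) inverted at the median.  When the lower
    bound is undefined (the interval never crosses one half within
    follow-up) the decision is inconclusive with a diagnostic.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if ni_threshold > sup_threshold:
        raise ValueError("non-inferiority threshold must not exceed superiority's")
    kmf = KaplanMeierFitter(alpha=1 - confidence)
    kmf.fit(data.time, event_observed=data.event)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lower, upper = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    diagnostic = ""
    if not math.isfinite(lower):
        diagnostic = (
            "median CI lower bound undefined: the survival CI never crosses "
            "0.5 within follow-up"
        )
    conclusion = decide_from_median_ci(lower, ni_threshold, sup_threshold)
    return KMDecision(
        median=median,
        ci_lower=lower,
        ci_upper=upper,
        confidence=confidence,
        ni_threshold=ni_threshold,
        sup_threshold=sup_threshold,
        conclusion=conclusion,
        diagnostic=diagnostic,
    )
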