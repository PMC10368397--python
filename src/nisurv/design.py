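"""Sample-size chain for a single-arm exponential time-to-event design.

The planning chain runs:

1. required events ``d = (z_{1-a} + z_{1-b})^2 / ln(HR)^2`` for the
   one-sample exponential MLE test of hazard ratio ``HR`` between the
   alternative and the control hazard (``z_{1-a/2}`` when two-sided);
2. the probability that an enrolled patient yields an observed event under
   uniform accrual over ``ap`` months with a minimum follow-up of ``fp``
   months after the last enrollment (administrative censoring at
   ``ap + fp`` from study start),
   ``P = 1 - exp(-lam*fp) * (1 - exp(-lam*ap)) / (lam*ap)``;
3. required patients ``d / P``, inflated by ``1/(1 - dropout_rate)`` and
   rounded up.

``analytic_power`` inverts step 1, giving the power of the test at a fixed
event count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .hazards import NonInferiorityMargin, SurvivalSummary, shifted_null

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "z_quantile",
    "required_events",
    "event_probability",
    "required_patients",
    "analytic_power",
    "design_summary",
]

Sided = Literal["one", "two"]


def z_quantile(p: float) -> float:
    """Standard normal inverse CDF."""
    if not 0 < p < 1:
        raise ValueError(f"quantile probability must be in (0, 1), got {p}")
    return float(norm.ppf(p))


def _alpha_quantile(alpha: float, sided: Sided) -> float:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sided == "one":
        return z_quantile(1 - alpha)
    if sided == "two":
        return z_quantile(1 - alpha / 2)
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def required_events(
    hr: float, alpha: float, power: float, sided: Sided = "one"
) -> tuple[float, int]:
    """Events needed to detect hazard ratio ``hr`` with the one-sample test.

    Returns ``(events_exact, events)`` where ``events`` is the ceiling.
    Symmetric in ``hr`` and ``1/hr`` (only ``ln(hr)^2`` enters).
    """
    if not hr > 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    if hr == 1:
        raise ValueError("hazard ratio of 1 gives a degenerate design")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")
    z_a = _alpha_quantile(alpha, sided)
    z_b = z_quantile(power)
    exact = (z_a + z_b) ** 2 / math.log(hr) ** 2
    return exact, math.ceil(exact)


def event_probability(hazard: float, accrual: float, followup: float) -> float:
    """Probability an enrolled patient has an observed event by study end.

    Entry uniform on ``[0, accrual]``; event exponential(``hazard``);
    administrative censoring at ``accrual + followup - entry``.  The
    ``accrual -> 0`` limit is ``1 - exp(-hazard * followup)``.
    """
    if not hazard > 0:
        raise ValueError(f"hazard must be positive, got {hazard}")
    if not followup > 0:
        raise ValueError(f"follow-up must be positive, got {followup}")
    if accrual < 0:
        raise ValueError(f"accrual must be non-negative, got {accrual}")
    x = hazard * accrual
    # (1 - e^-x)/x -> 1 as x -> 0; expm1 keeps the small-x branch accurate
    frac = -math.expm1(-x) / x if x > 0 else 1.0
    return 1.0 - math.exp(-hazard * followup) * frac


def required_patients(
    events: int, event_probability: float, dropout_rate: float = 0.0
) -> tuple[float, float, int]:
    """Patients needed to expect ``events`` events, inflated for dropout.

    Returns ``(patients_exact, patients_inflated, patients)``:
    ``events / P``, that divided by ``1 - dropout_rate``, and the ceiling
    of the inflated count.
    """
    if events < 1:
        raise ValueError(f"events must be >= 1, got {events}")
    if not 0 < event_probability <= 1:
        raise ValueError(
            f"event probability must be in (0, 1], got {event_probability}"
        )
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {dropout_rate}")
    exact = events / event_probability
    inflated = exact / (1.0 - dropout_rate)
    return exact, inflated, math.ceil(inflated)


def analytic_power(
    events: float, hr: float, alpha: float, sided: Sided = "one"
) -> float:
    """Power of the one-sample test at a fixed event count.

    ``Phi(sqrt(d) * |ln(hr)| - z_alpha)``; inverse-consistent with
    :func:`required_events` evaluated at ``events_exact``.
    """
    if not events > 0:
        raise ValueError(f"events must be positive, got {events}")
    if not hr > 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    if hr == 1:
        raise ValueError("hazard ratio of 1 gives a degenerate design")
    z_a = _alpha_quantile(alpha, sided)
    return float(norm.cdf(math.sqrt(events) * abs(math.log(hr)) - z_a))


@dataclass(frozen=True)
class DesignSpec:
    """All planning inputs for the single-arm design.

    ``control`` carries the historical null (hazard ``lam0``),
    ``alternative`` the effect the study is powered to detect (``lam1``).
    Times are months.  The optional ``nim`` adds the shifted
    non-inferiority null to the design report.
    """

    alpha: float
    power: float
    control: SurvivalSummary
    alternative: SurvivalSummary
    accrual: float
    followup: float
    sided: Sided = "one"
    dropout_rate: float = 0.0
    nim: NonInferiorityMargin | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.accrual < 0:
            raise ValueError("accrual period must be non-negative")
        if not self.followup > 0:
            raise ValueError("follow-up period must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.alternative.hazard == self.control.hazard:
            raise ValueError(
                "alternative hazard equals control hazard: degenerate design"
            )

    @property
    def hr(self) -> float:
        """Planning hazard ratio ``lam1 / lam0`` (= control/alternative median)."""
        return self.alternative.hazard / self.control.hazard


@dataclass(frozen=True)
class SampleSizeResult:
    """The events -> event probability -> patients chain, plus both nulls."""

    hr: float
    events_exact: float
    events: int
    event_probability: float
    patients_exact: float
    patients_inflated: float
    patients: int
    superiority_null: SurvivalSummary
    non_inferiority_null: SurvivalSummary | None = None

    def to_dict(self) -> dict:
        out = {
            "hr": self.hr,
            "events_exact": self.events_exact,
            "events": self.events,
            "event_probability": self.event_probability,
            "patients_exact": self.patients_exact,
            "patients_inflated": self.patients_inflated,
            "patients": self.patients,
            "superiority_null": {
                "median": self.superiority_null.median,
                "hazard": self.superiority_null.hazard,
            },
        }
        if self.non_inferiority_null is not None:
            out["non_inferiority_null"] = {
                "median": self.non_inferiority_null.median,
                "hazard": self.non_inferiority_null.hazard,
            }
        return out


def design_summary(
    spec: DesignSpec,
    event_probability_hazard: Literal["alternative", "control"] = "alternative",
) -> SampleSizeResult:
    """Run the full sizing chain for a design.

    The event probability is evaluated at the alternative hazard by
    default (the study is sized under the alternative); pass
    ``event_probability_hazard='control'`` to size conservatively at the
    null hazard instead.
    """
    events_exact, events = required_events(
        spec.hr, spec.alpha, spec.power, spec.sided
    )
    lam = (
        spec.alternative.hazard
        if event_probability_hazard == "alternative"
        else spec.control.hazard
    )
    p_event = event_probability(lam, spec.accrual, spec.followup)
    patients_exact, patients_inflated, patients = required_patients(
        events, p_event, spec.dropout_rate
    )
    ni_null = shifted_null(spec.control, spec.nim) if spec.nim is not None else None
    return SampleSizeResult(
        hr=spec.hr,
        events_exact=events_exact,
        events=events,
        event_probability=p_event,
        patients_exact=patients_exact,
        patients_inflated=patients_inflated,
        patients=patients,
        superiority_null=spec.control,
        non_inferiority_null=ni_null,
    )
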