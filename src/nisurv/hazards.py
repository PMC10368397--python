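"""Constant-hazard survival summaries and the fixed-margin non-inferiority margin.

Everything in this package rests on the exponential survival model, under
which a time-to-event distribution is pinned down by a single constant
hazard rate ``lam`` (per month).  The three interchangeable anchors are

* median survival ``m``:            ``lam = ln(2) / m``
* survival fraction ``S`` at a landmark time ``t``:  ``lam = -ln(S) / t``
* the hazard itself.

The non-inferiority margin (NIM) is derived with the fixed-margin method:
take the lower confidence bound ``L`` of the historical active-vs-placebo
hazard ratio (oriented so ``L >= 1`` means the active control beats
placebo) and discount it to retain a fraction ``f`` of that historical
effect on the log scale::

    NIM = L ** (1 - f)

A NIM of 1 tolerates no loss of effect; larger values tolerate more.  The
non-inferiority null is the control distribution shifted by the margin:
hazard multiplied by the NIM, median divided by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SurvivalSummary",
    "HistoricalEffect",
    "NonInferiorityMargin",
    "hazard_from_median",
    "median_from_hazard",
    "hazard_from_landmark",
    "fixed_margin_nim",
    "shifted_null",
]

LN2 = math.log(2.0)


def hazard_from_median(median: float) -> float:
    """Constant hazard implied by a median survival time: ``ln(2)/median``."""
    if not median > 0:
        raise ValueError(f"median must be positive, got {median}")
    return LN2 / median


def median_from_hazard(hazard: float) -> float:
    """Median survival implied by a constant hazard; ``inf`` for zero hazard."""
    if hazard < 0:
        raise ValueError(f"hazard must be non-negative, got {hazard}")
    if hazard == 0:
        return math.inf
    return LN2 / hazard


def hazard_from_landmark(rate: float, landmark: float) -> float:
    """Constant hazard implied by survival fraction ``rate`` at time ``landmark``.

    ``-ln(rate)/landmark``; a rate of 1 (no events by the landmark) gives a
    zero hazard.
    """
    if not 0 < rate <= 1:
        raise ValueError(f"landmark survival rate must be in (0, 1], got {rate}")
    if not landmark > 0:
        raise ValueError(f"landmark time must be positive, got {landmark}")
    return -math.log(rate) / landmark


@dataclass(frozen=True)
class SurvivalSummary:
    """A survival-scale anchor and its implied constant hazard.

    Construct through :meth:`from_median`, :meth:`from_landmark` or
    :meth:`from_hazard` — exactly one anchor is supplied and the others are
    derived.  Times are in months, hazards per month.
    """

    hazard: float
    median: float
    landmark_rate: float | None = None
    landmark_time: float | None = None

    def __post_init__(self) -> None:
        if self.hazard < 0:
            raise ValueError("hazard must be non-negative")
        if self.hazard > 0 and not math.isclose(
            self.median, LN2 / self.hazard, rel_tol=1e-12
        ):
            raise ValueError("median and hazard are inconsistent")

    @classmethod
    def from_median(cls, median: float) -> "SurvivalSummary":
        return cls(hazard=hazard_from_median(median), median=float(median))

    @classmethod
    def from_landmark(cls, rate: float, landmark: float) -> "SurvivalSummary":
        lam = hazard_from_landmark(rate, landmark)
        return cls(
            hazard=lam,
            median=median_from_hazard(lam),
            landmark_rate=float(rate),
            landmark_time=float(landmark),
        )

    @classmethod
    def from_hazard(cls, hazard: float) -> "SurvivalSummary":
        return cls(hazard=float(hazard), median=median_from_hazard(hazard))

    def survival_at(self, t: float) -> float:
        """Exponential survival probability ``exp(-hazard * t)``."""
        return math.exp(-self.hazard * t)


@dataclass(frozen=True)
class HistoricalEffect:
    """Historical active-control-vs-placebo hazard ratio with its CI.

    Stored in the *loss* direction: ``hr_point >= 1`` means the active
    control reduced the hazard relative to placebo (the ratio is
    placebo-hazard over control-hazard, equivalently control-median over
    placebo-median under exponentiality).  ``retention`` is the fraction of
    this historical effect the new treatment must retain.
    """

    hr_point: float
    ci_lower: float
    ci_upper: float
    retention: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.ci_lower <= self.hr_point <= self.ci_upper:
            raise ValueError(
                "require 1 <= ci_lower <= hr_point <= ci_upper "
                f"(got {self.ci_lower}, {self.hr_point}, {self.ci_upper}); "
                "the historical effect must favor the active control"
            )
        if not 0 <= self.retention <= 1:
            raise ValueError(f"retention must be in [0, 1], got {self.retention}")

    @classmethod
    def from_benefit_ratio(
        cls,
        hr_point: float,
        ci_lower: float,
        ci_upper: float,
        retention: float = 0.5,
    ) -> "HistoricalEffect":
        """Build from the benefit-direction ratio (< 1, active over placebo).

        Point and bounds are inverted and the bounds swapped.
        """
        if not 0 < ci_lower <= hr_point <= ci_upper:
            raise ValueError("require 0 < ci_lower <= hr_point <= ci_upper")
        return cls(
            hr_point=1.0 / hr_point,
            ci_lower=1.0 / ci_upper,
            ci_upper=1.0 / ci_lower,
            retention=retention,
        )


@dataclass(frozen=True)
class NonInferiorityMargin:
    """A hazard-ratio multiplier >= 1: the largest clinically acceptable loss."""

    value: float
    source: HistoricalEffect | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.value >= 1:
            raise ValueError(f"non-inferiority margin must be >= 1, got {self.value}")
        if self.source is not None and self.value > self.source.ci_lower + 1e-12:
            raise ValueError("margin exceeds the historical CI lower bound")

    def __float__(self) -> float:
        return self.value


def fixed_margin_nim(effect: HistoricalEffect) -> NonInferiorityMargin:
    """Fixed-margin method: ``NIM = ci_lower ** (1 - retention)``.

    Retention 1 gives a unit margin (no acceptable loss); retention 0
    allows the full lower-bound effect.  Monotone non-increasing in the
    retention fraction.
    """
    return NonInferiorityMargin(
        value=effect.ci_lower ** (1.0 - effect.retention), source=effect
    )


def shifted_null(
    control: SurvivalSummary, nim: NonInferiorityMargin | float
) -> SurvivalSummary:
    """The non-inferiority null: control hazard scaled up by the margin.

    Equivalently the control median divided by the margin — the two scales
    stay mutually consistent because both are exponential summaries.
    """
    m = float(nim)
    if m < 1:
        raise ValueError(f"non-inferiority margin must be >= 1, got {m}")
    return SurvivalSummary.from_hazard(control.hazard * m)
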