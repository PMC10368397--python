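"""JSON and plain-text report assembly for the command-line interface.

JSON reports carry full double precision and a stable ``schema_version``;
text reports round hazards to three significant figures and patient counts
to one decimal for readability.
"""

from __future__ import annotations

import json
import math
from typing import Any

from .analysis import DualDecision, HypothesisResult, KMDecision, TrialOutcome
from .design import DesignSpec, SampleSizeResult
from .hazards import NonInferiorityMargin, SurvivalSummary

SCHEMA_VERSION = 1


def _sig3(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 2)


def survival_summary_dict(s: SurvivalSummary) -> dict[str, Any]:
    d: dict[str, Any] = {"median": s.median, "hazard": s.hazard}
    if s.landmark_rate is not None:
        d["landmark_rate"] = s.landmark_rate
        d["landmark_time"] = s.landmark_time
    return d


def margin_report(
    nim: NonInferiorityMargin,
    control: SurvivalSummary | None,
    ni_null: SurvivalSummary | None,
) -> dict[str, Any]:
    rep: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "nim": nim.value}
    if nim.source is not None:
        rep["historical_effect"] = {
            "hr_point": nim.source.hr_point,
            "ci_lower": nim.source.ci_lower,
            "ci_upper": nim.source.ci_upper,
            "retention": nim.source.retention,
        }
    if control is not None and ni_null is not None:
        rep["superiority_null"] = survival_summary_dict(control)
        rep["non_inferiority_null"] = survival_summary_dict(ni_null)
    return rep


def design_report(spec: DesignSpec, result: SampleSizeResult) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "inputs": {
            "alpha": spec.alpha,
            "sided": spec.sided,
            "power": spec.power,
            "control": survival_summary_dict(spec.control),
            "alternative": survival_summary_dict(spec.alternative),
            "accrual": spec.accrual,
            "followup": spec.followup,
            "dropout_rate": spec.dropout_rate,
            "nim": None if spec.nim is None else spec.nim.value,
        },
        "result": result.to_dict(),
    }


def design_text(result: SampleSizeResult) -> str:
    lines = [
        f"hazard ratio (alternative/control): {result.hr:.3f}",
        f"required events: {result.events_exact:.2f} -> {result.events}",
        f"event probability: {_sig3(result.event_probability)}",
        f"patients before dropout: {result.patients_exact:.1f}",
        f"patients after dropout inflation: "
        f"{result.patients_inflated:.1f} -> {result.patients}",
        f"superiority null: median {result.superiority_null.median:.4g} mo, "
        f"hazard {_sig3(result.superiority_null.hazard)}/mo",
    ]
    if result.non_inferiority_null is not None:
        lines.append(
            f"non-inferiority null: median "
            f"{result.non_inferiority_null.median:.4g} mo, "
            f"hazard {_sig3(result.non_inferiority_null.hazard)}/mo"
        )
    return "\n".join(lines)


def _hypothesis_dict(h: HypothesisResult) -> dict[str, Any]:
    return {
        "null_hazard": h.null_hazard,
        "null_median": h.null_median,
        "z_value": h.z_value,
        "p_value": h.p_value,
        "effect_size_median": h.effect_size_median,
        "effect_size_hazard": h.effect_size_hazard,
    }


def analysis_report(
    outcome: TrialOutcome, decision: DualDecision, inputs: dict[str, Any]
) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "inputs": inputs,
        "outcome": {
            "n": outcome.n,
            "events": outcome.events,
            "total_exposure": outcome.total_exposure,
            "hazard_hat": outcome.hazard_hat,
            "median_hat": outcome.median_hat,
        },
        "non_inferiority": _hypothesis_dict(decision.ni_result),
        "superiority": None
        if decision.sup_result is None
        else _hypothesis_dict(decision.sup_result),
        "conclusion": decision.conclusion.value,
        "alpha": decision.alpha,
    }


def km_report(decision: KMDecision, inputs: dict[str, Any]) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "inputs": inputs,
        "km_median": decision.median,
        "ci_lower": decision.ci_lower,
        "ci_upper": decision.ci_upper,
        "confidence": decision.confidence,
        "ni_threshold": decision.ni_threshold,
        "sup_threshold": decision.sup_threshold,
        "conclusion": decision.conclusion.value,
        "diagnostic": decision.diagnostic,
    }


def dumps(report: dict[str, Any]) -> str:
    def default(o: Any):
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        raise TypeError(type(o))

    return json.dumps(_jsonable(report), indent=2, default=default)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return None
    return obj
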