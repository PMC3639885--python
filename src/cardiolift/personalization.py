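"""Expert-concordance evaluation and personal-threshold recovery.

``concordance`` compares automated at-risk flags against the expert's,
reporting the true-positive rate (share of expert at-risk records the
classifier also flags) and false-positive rate (share of expert not-at-risk
records it flags).

``recover_threshold`` automates the manual cutoff-adjustment step: given
labeled measurements, it finds the single inclusive-at-risk threshold that
maximizes agreement with the labels.  On perfectly separable data the
boundary is the observed at-risk extreme (the minimum at-risk value for an
"at risk if >=" rule, the maximum for "at risk if <="), matching the
convention that personalized models place their cutoff exactly on an
observed at-risk value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .guidelines import ClassificationResult, RiskModel, lift
from .records import PatientRecord
from .units import UnitRegistry

__all__ = [
    "ConcordanceReport",
    "ThresholdFit",
    "concordance",
    "evaluate_model_set",
    "recover_threshold",
]


@dataclass(frozen=True)
class ConcordanceReport:
    model: str
    n_expert_at_risk: int
    n_expert_not_at_risk: int
    tp_rate_percent: Optional[float]  # None when the denominator is zero
    fp_rate_percent: Optional[float]
    discordant_ids: tuple[str, ...]
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        for rate in (self.tp_rate_percent, self.fp_rate_percent):
            assert rate is None or 0.0 <= rate <= 100.0


def concordance(records: Sequence[PatientRecord], model: RiskModel,
                flag_key: Optional[str] = None,
                registry: Optional[UnitRegistry] = None,
                include_unclassified: bool = False) -> ConcordanceReport:
    """Compare the model's automated flags against the expert flags stored
    on the records (under ``flag_key``, defaulting to the model's own).

    Rates are computed over records having both an expert flag and a
    classifiable value; records the model leaves unclassified (guideline
    gaps, missing inputs) are counted in ``n_unclassified`` and excluded
    from the denominators unless ``include_unclassified`` (in which case
    they count as not-flagged)."""
    key = flag_key or model.flag_key
    if key is None:
        raise ValueError(f"model {model.name!r} has no expert-flag key")
    tp = fp = n_pos = n_neg = n_unclassified = 0
    discordant: list[str] = []
    for record in records:
        expert = record.expert_flags.get(key)
        if expert is None:
            continue
        _, results = lift(record, [model], registry=registry)
        result = results[model.name]
        if result.status != "classified":
            n_unclassified += 1
            if not include_unclassified:
                continue
            auto = 0
        else:
            auto = result.at_risk
        if expert == 1:
            n_pos += 1
            tp += auto
        else:
            n_neg += 1
            fp += auto
        if auto != expert:
            discordant.append(record.record_id)
    return ConcordanceReport(
        model=model.name,
        n_expert_at_risk=n_pos,
        n_expert_not_at_risk=n_neg,
        tp_rate_percent=100.0 * tp / n_pos if n_pos else None,
        fp_rate_percent=100.0 * fp / n_neg if n_neg else None,
        discordant_ids=tuple(discordant),
        n_unclassified=n_unclassified,
    )


def evaluate_model_set(records: Sequence[PatientRecord],
                       model_set: dict[str, RiskModel],
                       registry: Optional[UnitRegistry] = None,
                       ) -> dict[str, ConcordanceReport]:
    """Concordance report per expert-flag key (SBP, DBP, CHOL, ...)."""
    return {key: concordance(records, model, flag_key=key, registry=registry)
            for key, model in model_set.items()}


@dataclass(frozen=True)
class ThresholdFit:
    direction: str  # at_risk_if_ge | at_risk_if_le
    boundary: float
    gap_interval: tuple[float, float]
    concordance_percent: float
    separable: bool

    def __post_init__(self) -> None:
        lo, hi = self.gap_interval
        assert lo <= self.boundary <= hi


def _accuracy_ge(values, labels, threshold: float) -> int:
    return sum(1 for v, y in zip(values, labels)
               if (1 if v >= threshold else 0) == y)


def _accuracy_le(values, labels, threshold: float) -> int:
    return sum(1 for v, y in zip(values, labels)
               if (1 if v <= threshold else 0) == y)


def recover_threshold(values: Sequence[float], labels: Sequence[int],
                      direction: str) -> ThresholdFit:
    """Recover the inclusive-at-risk threshold best matching the labels.

    ``direction`` is ``"at_risk_if_ge"`` (label 1 for values >= boundary) or
    ``"at_risk_if_le"``.  Separable data returns the observed at-risk
    extreme with 100% concordance; otherwise the boundary maximizing
    concordance, ties broken toward the smaller at-risk set."""
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("values must be finite")
    if direction not in ("at_risk_if_ge", "at_risk_if_le"):
        raise ValueError(f"unknown direction {direction!r}")
    labels = [int(y) for y in labels]
    if set(labels) != {0, 1}:
        raise ValueError("both labels must be present to recover a boundary")

    pos = sorted(v for v, y in zip(values, labels) if y == 1)
    neg = sorted(v for v, y in zip(values, labels) if y == 0)
    n = len(values)
    ge = direction == "at_risk_if_ge"
    accuracy = _accuracy_ge if ge else _accuracy_le

    # perfect separation: at-risk side strictly beyond every safe value
    if ge and pos[0] > neg[-1]:
        boundary = pos[0]
        gap = (neg[-1], pos[0])
        return ThresholdFit(direction, boundary, gap, 100.0, True)
    if not ge and pos[-1] < neg[0]:
        boundary = pos[-1]
        gap = (pos[-1], neg[0])
        return ThresholdFit(direction, boundary, gap, 100.0, True)

    # non-separable: scan candidate thresholds (observed values plus one
    # sentinel beyond each end so the all-0 / all-1 rules are reachable)
    uniq = sorted(set(values))
    if ge:
        candidates = uniq + [uniq[-1] + 1.0]
        # ties toward the smaller at-risk set = larger threshold
        best = max(candidates,
                   key=lambda t: (accuracy(values, labels, t), t))
    else:
        candidates = [uniq[0] - 1.0] + uniq
        best = max(candidates,
                   key=lambda t: (accuracy(values, labels, t), -t))
    correct = accuracy(values, labels, best)
    # gap interval around the chosen boundary: nearest observed values on
    # the safe and risk sides of it
    if ge:
        below = [v for v in uniq if v < best]
        lo = below[-1] if below else best
        gap = (lo, best)
    else:
        above = [v for v in uniq if v > best]
        hi = above[0] if above else best
        gap = (best, hi)
    return ThresholdFit(direction, best, gap, 100.0 * correct / n, False)
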