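"""Synthetic cohort generation with a simulated expert labeler.

The original cohort behind the legacy spreadsheet is not deposited, so this
module fabricates cohorts with the same structure: the nine core
measurements drawn from truncated physiologic distributions, sex,
smoker/diabetic/treatment booleans, per-attribute expert binary flags
produced by a rule-following labeler (optionally deviating from its rules
with a configurable flip probability), and a ternary overall label from the
point-score quantization.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .derivations import DerivationError, framingham_for_record
from .guidelines import RiskModel, builtin_models, lift, resolve_model_set
from .records import (Attribute, FLAG_KEYS, MeasurementClass, PatientRecord)
from .units import Quantity, UnitRegistry, builtin_units

__all__ = ["DistributionSpec", "CohortSpec", "simulate_cohort",
           "expert_label"]


@dataclass(frozen=True)
class DistributionSpec:
    """A truncated draw for one measurement: ``normal`` (mean, sd) or
    ``uniform`` (low, high), clipped to ``(lower, upper)`` and rounded to
    ``grid`` when given."""

    family: str  # normal | uniform
    params: tuple[float, float]
    lower: float
    upper: float
    grid: Optional[float] = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.lower >= self.upper or self.lower < 0:
            raise ValueError("truncation range must be positive and ordered")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "uniform":
            draws = rng.uniform(self.lower, self.upper, size=n)
        else:
            mean, sd = self.params
            a = (self.lower - mean) / sd
            b = (self.upper - mean) / sd
            draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                        random_state=rng)
        if self.integer:
            draws = np.floor(draws)
        elif self.grid:
            draws = np.round(draws / self.grid) * self.grid
        return draws


def _default_distributions() -> dict[MeasurementClass, DistributionSpec]:
    MC = MeasurementClass
    return {
        MC.SBP: DistributionSpec("normal", (130, 20), 90, 220, integer=True),
        MC.DBP: DistributionSpec("normal", (80, 12), 60, 120, grid=0.1),
        MC.CHOL: DistributionSpec("normal", (210, 40), 100, 400,
                                  integer=True),
        MC.HDL: DistributionSpec("normal", (48, 12), 20, 100, integer=True),
        MC.TG: DistributionSpec("normal", (140, 60), 40, 400, integer=True),
        MC.HEIGHT: DistributionSpec("normal", (1.72, 0.10), 1.4, 2.1,
                                    grid=0.0001),
        MC.MASS: DistributionSpec("normal", (80, 15), 40, 160, grid=0.0001),
        MC.GLUCOSE: DistributionSpec("normal", (100, 20), 50, 300,
                                     integer=True),
        MC.AGE: DistributionSpec("uniform", (30, 86), 30, 86, integer=True),
    }


@dataclass
class CohortSpec:
    n: int
    seed: int = 0
    distributions: dict[MeasurementClass, DistributionSpec] = field(
        default_factory=_default_distributions)
    sex_fraction_male: float = 0.7
    smoker_prob: float = 0.3
    diabetic_prob: float = 0.1
    treated_prob: float = 0.0
    label_model_set: str = "modified"
    deviation_rate: float = 0.0
    ternary_deviation_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.sex_fraction_male, self.smoker_prob,
                  self.diabetic_prob, self.treated_prob, self.deviation_rate,
                  self.ternary_deviation_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")


def expert_label(record: PatientRecord,
                 model_set: dict[str, RiskModel],
                 rng: Optional[np.random.Generator] = None,
                 deviation_rate: float = 0.0,
                 ternary_deviation_rate: float = 0.0,
                 registry: Optional[UnitRegistry] = None,
                 ) -> PatientRecord:
    """Return a copy of ``record`` with expert flags and ternary label.

    Binary flags come from lifting and classifying under ``model_set``
    (LDL/BMI derived on the fly), each flipped independently with
    probability ``deviation_rate``.  The ternary label maps the point-score
    category {low, medium, high} to {1, 2, 3} (male records with complete
    inputs only); with probability ``ternary_deviation_rate`` it is bumped
    one category up or down.  Attributes whose inputs are insufficient
    leave their flag absent."""
    if deviation_rate or ternary_deviation_rate:
        if rng is None:
            raise ValueError("deviations require an rng")
    registry = registry or builtin_units()
    labeled = record.copy()
    _, results = lift(record, list(model_set.values()), registry=registry)
    for key, model in model_set.items():
        result = results[model.name]
        if result.status != "classified":
            continue
        flag = result.at_risk
        if deviation_rate and rng.random() < deviation_rate:
            flag = 1 - flag
        labeled.expert_flags[key] = flag
    try:
        fres = framingham_for_record(record, registry=registry)
        ternary = {"low": 1, "medium": 2, "high": 3}[fres.category]
        if ternary_deviation_rate and rng.random() < ternary_deviation_rate:
            ternary = min(3, max(1, ternary + rng.choice([-1, 1])))
        labeled.expert_ternary = int(ternary)
    except DerivationError:
        labeled.expert_ternary = None
    return labeled


def simulate_cohort(spec: CohortSpec,
                    registry: Optional[UnitRegistry] = None,
                    ) -> list[PatientRecord]:
    """Generate ``spec.n`` labeled records, reproducibly from ``spec.seed``.

    Measurements are drawn in the legacy units (pressures mmHg, lipids and
    glucose mg/dl, height m, weight kg, age years); expert labels are
    computed before missingness is applied, so a measurement can be missing
    while its expert flag survives (as in a partially transcribed sheet)."""
    registry = registry or builtin_units()
    rng = np.random.default_rng(spec.seed)
    model_set = resolve_model_set(spec.label_model_set)
    units = {
        MeasurementClass.SBP: registry["millimeter-of-mercury-column"],
        MeasurementClass.DBP: registry["millimeter-of-mercury-column"],
        MeasurementClass.CHOL: registry["milligram-per-deciliter"],
        MeasurementClass.HDL: registry["milligram-per-deciliter"],
        MeasurementClass.TG: registry["milligram-per-deciliter"],
        MeasurementClass.GLUCOSE: registry["milligram-per-deciliter"],
        MeasurementClass.HEIGHT: registry["meter"],
        MeasurementClass.MASS: registry["kilogram"],
        MeasurementClass.AGE: registry["year"],
    }
    order = sorted(spec.distributions, key=lambda m: m.name)
    draws = {m: spec.distributions[m].sample(rng, spec.n) for m in order}
    sexes = rng.random(spec.n) < spec.sex_fraction_male
    smokers = rng.random(spec.n) < spec.smoker_prob
    diabetics = rng.random(spec.n) < spec.diabetic_prob
    treated = rng.random(spec.n) < spec.treated_prob

    records: list[PatientRecord] = []
    for i in range(spec.n):
        record = PatientRecord(
            record_id=f"s{i + 1}",
            smoker=bool(smokers[i]),
            diabetic=bool(diabetics[i]),
            bp_treated=bool(treated[i]),
        )
        record.attributes[MeasurementClass.SEX] = Attribute(
            MeasurementClass.SEX,
            sex_value="male" if sexes[i] else "female")
        for mclass in order:
            record.attributes[mclass] = Attribute(
                mclass,
                measurement=Quantity(float(draws[mclass][i]), units[mclass]))
        record = expert_label(
            record, model_set, rng=rng,
            deviation_rate=spec.deviation_rate,
            ternary_deviation_rate=spec.ternary_deviation_rate,
            registry=registry)
        if spec.missing_rate:
            for mclass in order:
                if rng.random() < spec.missing_rate:
                    del record.attributes[mclass]
        records.append(record)
    return records
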