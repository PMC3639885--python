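"""Algorithmic derivations lifting core measurements into derived ones.

* body-mass index from height and mass,
* LDL cholesterol via the Friedewald approximation C - H - k*T, where the
  constant k depends on the concentration system the inputs are expressed
  in (0.20 for mg/dl, 0.45 for mmol/l),
* the men's general-cardiovascular-disease point score, its 10-year risk
  percentage lookup, and the low/medium/high ternary quantization
  (low <= 9 points, medium 10-19, high >= 20).

Each derivation is exposed both as a plain function over quantities and as
a record-in/record-out transformation that attaches the derived attribute
with its unit, leaving the original attributes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import Attribute, MeasurementClass, PatientRecord, get_quantity
from .units import Quantity, Unit, UnitRegistry, builtin_units

__all__ = [
    "DerivationError",
    "derive_bmi",
    "derive_ldl",
    "friedewald",
    "friedewald_constant",
    "FraminghamProfile",
    "FraminghamResult",
    "RiskPercent",
    "framingham_points",
    "framingham_percent",
    "framingham_category",
    "framingham_for_record",
    "FRIEDEWALD_K",
    "TG_GUARD_MG_DL",
]


class DerivationError(ValueError):
    """Missing or implausible inputs for a derivation."""


# ---------------------------------------------------------------------------
# BMI
# ---------------------------------------------------------------------------

def derive_bmi(record: PatientRecord,
               registry: Optional[UnitRegistry] = None) -> PatientRecord:
    """Attach a BodyMassIndex attribute: mass[kg] / height[m]^2, in
    kilogram-per-meter-squared."""
    registry = registry or builtin_units()
    height = get_quantity(record, MeasurementClass.HEIGHT, "meter",
                          registry=registry)
    mass = get_quantity(record, MeasurementClass.MASS, "kilogram",
                        registry=registry)
    if height is None or mass is None:
        missing = [name for name, q in
                   (("Height", height), ("Mass", mass)) if q is None]
        raise DerivationError(
            f"record {record.record_id}: BMI needs {', '.join(missing)}")
    if height.value <= 0:
        raise DerivationError(
            f"record {record.record_id}: non-positive height")
    bmi = mass.value / height.value ** 2
    unit = registry["kilogram-per-meter-squared"]
    return record.with_attribute(
        Attribute(MeasurementClass.BMI, measurement=Quantity(bmi, unit)))


# ---------------------------------------------------------------------------
# Friedewald LDL
# ---------------------------------------------------------------------------

#: unit-system-dependent triglyceride coefficient
FRIEDEWALD_K = {"milligram-per-deciliter": 0.20, "millimole-per-liter": 0.45}

#: optional validity guard (not applied by default)
TG_GUARD_MG_DL = 400.0


def friedewald_constant(unit: Unit) -> float:
    """Select k from the concentration family of ``unit``: 0.20 for mass
    concentrations (mg/dl system), 0.45 for molar concentrations (mmol/l)."""
    if unit.quality == "mass-concentration":
        return 0.20
    if unit.quality == "molar-concentration":
        return 0.45
    raise DerivationError(
        f"unit {unit.name!r} is not a concentration unit")


def friedewald(chol: Quantity, hdl: Quantity, tg: Quantity,
               registry: Optional[UnitRegistry] = None,
               tg_guard: bool = False) -> tuple[Quantity, float]:
    """Estimate LDL as C - H - k*T in the unit system of ``chol``; HDL and
    triglycerides are converted into that working unit first.  Returns the
    LDL quantity and the constant k it selected (0.20 for a mass
    concentration working unit, 0.45 for a molar one)."""
    registry = registry or builtin_units()
    working_unit = chol.unit
    k = friedewald_constant(working_unit)
    hdl = registry.convert(hdl, working_unit, analyte="hdl")
    tg = registry.convert(tg, working_unit, analyte="triglyceride")
    if tg_guard:
        tg_mgdl = registry.convert(tg, "milligram-per-deciliter",
                                   analyte="triglyceride")
        if tg_mgdl.value > TG_GUARD_MG_DL:
            raise DerivationError(
                f"triglycerides above {TG_GUARD_MG_DL:g} mg/dl invalidate "
                f"the LDL estimate")
    ldl = chol.value - hdl.value - k * tg.value
    if ldl < 0:
        raise DerivationError(
            f"implausible inputs give negative LDL ({ldl:.3g})")
    return Quantity(ldl, working_unit), k


def derive_ldl(record: PatientRecord,
               registry: Optional[UnitRegistry] = None,
               tg_guard: bool = False) -> PatientRecord:
    """Attach an LDL attribute computed via :func:`friedewald` in the unit
    system of the record's total-cholesterol measurement; k is selected
    automatically from that unit's concentration family."""
    registry = registry or builtin_units()
    chol_attr = record.attributes.get(MeasurementClass.CHOL)
    if chol_attr is None:
        raise DerivationError(
            f"record {record.record_id}: LDL needs total cholesterol")
    hdl = get_quantity(record, MeasurementClass.HDL, registry=registry)
    tg = get_quantity(record, MeasurementClass.TG, registry=registry)
    if hdl is None or tg is None:
        missing = [name for name, q in (("HDL", hdl), ("TG", tg)) if q is None]
        raise DerivationError(
            f"record {record.record_id}: LDL needs {', '.join(missing)}")
    try:
        ldl, _ = friedewald(chol_attr.measurement, hdl, tg,
                            registry=registry, tg_guard=tg_guard)
    except DerivationError as exc:
        raise DerivationError(f"record {record.record_id}: {exc}") from None
    return record.with_attribute(
        Attribute(MeasurementClass.LDL, measurement=ldl))


# ---------------------------------------------------------------------------
# Framingham general-CVD points (men)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FraminghamProfile:
    """Inputs for the men's general-CVD point score."""

    age: float
    hdl: Quantity
    total_cholesterol: Quantity
    sbp: Quantity
    bp_treated: bool = False
    smoker: bool = False
    diabetic: bool = False
    sex: str = "male"

    def __post_init__(self) -> None:
        if self.sex != "male":
            raise DerivationError("only the men's scoring table is supported")
        if self.age < 30:
            raise DerivationError(
                f"age {self.age} below the lowest scored band (30)")


@dataclass(frozen=True)
class RiskPercent:
    """A 10-year risk percentage, possibly an open-ended bound.

    ``relation`` is ``'eq'`` for an exact table value, ``'lt'`` for the
    below-range bound, ``'ge'`` for the top open-ended bound."""

    percent: float
    relation: str = "eq"

    def __str__(self) -> str:
        sym = {"eq": "", "lt": "<", "ge": "≥"}[self.relation]
        return f"{sym}{self.percent:g}%"


@dataclass(frozen=True)
class FraminghamResult:
    per_factor_points: dict[str, int]
    total_points: int
    ten_year_risk: RiskPercent
    category: str  # low | medium | high

    def __post_init__(self) -> None:
        assert self.total_points == sum(self.per_factor_points.values())


# per-factor bands: (lower bound inclusive, points); lookup takes the last
# band whose lower bound the value reaches. Values below the first bound of
# an open-bottom factor fall into the "<" band listed first with -inf.
_NEG_INF = float("-inf")

_AGE_POINTS = [(30, 0), (35, 2), (40, 5), (45, 6), (50, 8), (55, 10),
               (60, 11), (65, 12), (70, 14), (75, 15)]
_HDL_POINTS = [(_NEG_INF, 2), (35, 1), (45, 0), (50, -1), (60, -2)]
_CHOL_POINTS = [(_NEG_INF, 0), (160, 1), (200, 2), (240, 3), (280, 4)]
_SBP_UNTREATED = [(_NEG_INF, -2), (120, 0), (130, 1), (140, 2), (160, 3)]
_SBP_TREATED = [(_NEG_INF, 0), (120, 2), (130, 3), (140, 4), (160, 5)]
_SMOKER_POINTS = {False: 0, True: 4}
_DIABETIC_POINTS = {False: 0, True: 3}


def _band_lookup(bands: list[tuple[float, int]], value: float) -> int:
    points = bands[0][1]
    for lower, pts in bands:
        if value >= lower:
            points = pts
    return points


def framingham_points(profile: FraminghamProfile,
                      registry: Optional[UnitRegistry] = None,
                      ) -> FraminghamResult:
    """Per-factor point lookup for men.  HDL and total cholesterol are taken
    in mg/dl, systolic pressure in mmHg (converted internally); fractional
    ages are truncated to whole years before the band lookup."""
    registry = registry or builtin_units()
    hdl = registry.convert(profile.hdl, "milligram-per-deciliter",
                           analyte="hdl").value
    chol = registry.convert(profile.total_cholesterol,
                            "milligram-per-deciliter",
                            analyte="total-cholesterol").value
    sbp = registry.convert(profile.sbp,
                           "millimeter-of-mercury-column").value
    sbp_bands = _SBP_TREATED if profile.bp_treated else _SBP_UNTREATED
    per_factor = {
        "age": _band_lookup(_AGE_POINTS, int(profile.age)),
        "hdl": _band_lookup(_HDL_POINTS, hdl),
        "total_cholesterol": _band_lookup(_CHOL_POINTS, chol),
        "sbp": _band_lookup(sbp_bands, sbp),
        "smoker": _SMOKER_POINTS[profile.smoker],
        "diabetic": _DIABETIC_POINTS[profile.diabetic],
    }
    total = sum(per_factor.values())
    return FraminghamResult(
        per_factor_points=per_factor,
        total_points=total,
        ten_year_risk=framingham_percent(total),
        category=framingham_category(total),
    )


_PERCENT_TABLE = [
    (9, 1.0), (10, 1.0), (11, 1.0), (12, 1.0),
    (13, 2.0), (14, 2.0), (15, 3.0), (16, 4.0), (17, 5.0), (18, 6.0),
    (19, 8.0), (20, 11.0), (21, 14.0), (22, 17.0), (23, 22.0), (24, 27.0),
]


def framingham_percent(total_points: int) -> RiskPercent:
    """10-year general-CVD risk for a total point score: below 9 points the
    published risk is an open bound (<1%), 25 points and above it is >=30%,
    in between an exact percentage."""
    if total_points < 9:
        return RiskPercent(1.0, "lt")
    if total_points >= 25:
        return RiskPercent(30.0, "ge")
    percent = dict(_PERCENT_TABLE)[total_points]
    return RiskPercent(percent, "eq")


def framingham_category(total_points: int) -> str:
    """Ternary quantization: low <= 9, medium 10-19, high >= 20."""
    if total_points <= 9:
        return "low"
    if total_points <= 19:
        return "medium"
    return "high"


def framingham_for_record(record: PatientRecord,
                          registry: Optional[UnitRegistry] = None,
                          ) -> FraminghamResult:
    """Build a profile from a record (male, with age, cholesterol, HDL and
    systolic pressure present) and score it.  Unset smoker/diabetic/treated
    booleans default to false."""
    registry = registry or builtin_units()
    if record.sex != "male":
        raise DerivationError(
            f"record {record.record_id}: scoring requires a male record")
    age = get_quantity(record, MeasurementClass.AGE, "year",
                       registry=registry)
    hdl = get_quantity(record, MeasurementClass.HDL, registry=registry)
    chol = get_quantity(record, MeasurementClass.CHOL, registry=registry)
    sbp = get_quantity(record, MeasurementClass.SBP, registry=registry)
    missing = [name for name, q in (("Age", age), ("HDL", hdl),
                                    ("TotalCholesterol", chol), ("SBP", sbp))
               if q is None]
    if missing:
        raise DerivationError(
            f"record {record.record_id}: scoring needs "
            f"{', '.join(missing)}")
    profile = FraminghamProfile(
        age=age.value, hdl=hdl, total_cholesterol=chol, sbp=sbp,
        bp_treated=bool(record.bp_treated), smoker=bool(record.smoker),
        diabetic=bool(record.diabetic))
    return framingham_points(profile, registry=registry)
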