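"""Declarative band-based risk models and the lifting classifier.

A :class:`RiskModel` is an ordered list of value bands over one measurement
class, expressed in a canonical unit; each band carries a label and a 0/1
at-risk flag.  The shipped registry contains:

* the original per-attribute binary models (at-risk iff SBP >= 140 mmHg,
  DBP >= 90 mmHg, cholesterol >= 5.0 mmol/L, HDL <= 1.03 mmol/L,
  triglycerides >= 2.26 mmol/L, BMI >= 25 kg/m2, LDL >= 160 mg/dl),
* the clinician-personalized ("modified") set (cholesterol >= 5.2,
  HDL <= 0.89, triglycerides >= 2.63, BMI >= 26; pressures and LDL as in
  the original set),
* the published multi-band guideline models, including the cholesterol
  model whose printed bands leave an uncovered gap between 5.0 and
  5.2 mmol/L — :func:`validate_model` enumerates such gaps, and
  :func:`classify_binary` reports values falling into one as an explicit
  ``"unclassified: gap"`` outcome rather than silently defaulting.

:func:`lift` resolves the derivation dependency graph (BMI from height and
mass, LDL from the lipid panel, the point score from its profile inputs)
before classifying, recording every derivation and conversion performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .derivations import (DerivationError, derive_bmi, derive_ldl,
                          framingham_for_record)
from .records import MeasurementClass, PatientRecord, get_quantity
from .units import (IncompatibleUnitsError, Quantity, Unit, UnitRegistry,
                    builtin_units)

__all__ = [
    "Band",
    "RiskModel",
    "ClassificationResult",
    "ModelError",
    "builtin_models",
    "load_models",
    "models_to_config",
    "classify_binary",
    "classify_bp_stage",
    "lift",
    "validate_model",
    "MODEL_SETS",
    "FRAMINGHAM_TARGET",
]

_INF = float("inf")

#: pseudo-model name accepted by :func:`lift`
FRAMINGHAM_TARGET = "framingham"


class ModelError(ValueError):
    """Bad model definition or unresolvable model reference."""


@dataclass(frozen=True)
class Band:
    lower: float
    upper: float
    label: str
    at_risk: int
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.at_risk not in (0, 1):
            raise ModelError(f"band {self.label!r}: at_risk must be 0/1")
        if self.lower > self.upper:
            raise ModelError(f"band {self.label!r}: lower > upper")
        if self.lower == self.upper and not (
                self.lower_inclusive and self.upper_inclusive):
            raise ModelError(f"band {self.label!r}: degenerate open band")

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_inclusive
                                       and value == self.lower)
        below = value < self.upper or (self.upper_inclusive
                                       and value == self.upper)
        return above and below


@dataclass(frozen=True)
class RiskModel:
    name: str
    mclass: MeasurementClass
    canonical_unit: str
    bands: tuple[Band, ...]
    analyte: Optional[str] = None
    sex_overrides: Optional[Mapping[str, tuple[Band, ...]]] = None
    flag_key: Optional[str] = None  # expert-flag column this model maps to

    def bands_for(self, sex: Optional[str]) -> tuple[Band, ...]:
        if self.sex_overrides and sex in self.sex_overrides:
            return tuple(self.sex_overrides[sex])
        return self.bands

    def match(self, value: float, sex: Optional[str] = None) -> Optional[Band]:
        for band in self.bands_for(sex):
            if band.contains(value):
                return band
        return None


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    model: str
    status: str  # classified | unclassified: gap | insufficient data | below-range
    band_label: Optional[str] = None
    at_risk: Optional[int] = None
    value: Optional[float] = None
    unit: Optional[str] = None
    derivations_performed: tuple[str, ...] = ()
    conversions_performed: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# builtin model registry
# ---------------------------------------------------------------------------

def _binary(name: str, mclass: MeasurementClass, unit: str, threshold: float,
            direction: str, flag_key: str,
            analyte: Optional[str] = None) -> RiskModel:
    """Two-band partition with the at-risk side closed at the threshold."""
    if direction == "ge":
        bands = (
            Band(-_INF, threshold, "not at risk", 0, upper_inclusive=False),
            Band(threshold, _INF, "at risk", 1, lower_inclusive=True),
        )
    elif direction == "le":
        bands = (
            Band(-_INF, threshold, "at risk", 1, upper_inclusive=True),
            Band(threshold, _INF, "not at risk", 0, lower_inclusive=False),
        )
    else:  # pragma: no cover
        raise ModelError(direction)
    return RiskModel(name=name, mclass=mclass, canonical_unit=unit,
                     bands=bands, analyte=analyte, flag_key=flag_key)


def _bands(rows: Sequence[tuple]) -> tuple[Band, ...]:
    return tuple(Band(*row) for row in rows)


def builtin_models() -> dict[str, RiskModel]:
    """All shipped models, keyed by name (fresh dict, shared frozen models)."""
    return dict(_builtin_models_cached())


def _builtin_models_cached() -> dict[str, RiskModel]:
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is not None:
        return _BUILTIN_CACHE
    models: dict[str, RiskModel] = {}

    def add(model: RiskModel) -> None:
        models[model.name] = model

    MC = MeasurementClass
    mmhg = "millimeter-of-mercury-column"
    mmol = "millimole-per-liter"
    mgdl = "milligram-per-deciliter"
    kgm2 = "kilogram-per-meter-squared"

    # original binary set
    add(_binary("sbp", MC.SBP, mmhg, 140.0, "ge", "SBP"))
    add(_binary("dbp", MC.DBP, mmhg, 90.0, "ge", "DBP"))
    add(_binary("chol", MC.CHOL, mmol, 5.0, "ge", "CHOL",
                analyte="total-cholesterol"))
    add(_binary("hdl", MC.HDL, mmol, 1.03, "le", "HDL", analyte="hdl"))
    add(_binary("tg", MC.TG, mmol, 2.26, "ge", "TG", analyte="triglyceride"))
    add(_binary("bmi", MC.BMI, kgm2, 25.0, "ge", "BMI"))
    add(_binary("ldl", MC.LDL, mgdl, 160.0, "ge", "LDL", analyte="ldl"))

    # clinician-personalized ("modified") set
    add(_binary("chol_modified", MC.CHOL, mmol, 5.2, "ge", "CHOL",
                analyte="total-cholesterol"))
    add(_binary("hdl_modified", MC.HDL, mmol, 0.89, "le", "HDL",
                analyte="hdl"))
    add(_binary("tg_modified", MC.TG, mmol, 2.63, "ge", "TG",
                analyte="triglyceride"))
    add(_binary("bmi_modified", MC.BMI, kgm2, 26.0, "ge", "BMI"))

    # published multi-band guideline models
    add(RiskModel(
        name="aha_sbp_stage", mclass=MC.SBP, canonical_unit=mmhg,
        flag_key="SBP",
        bands=_bands([
            (90.0, 120.0, "Normal", 0),
            (120.0, 140.0, "Pre-hypertension", 0),
            (140.0, 160.0, "Stage 1", 1),
            (160.0, _INF, "Stage 2", 1),
        ])))
    add(RiskModel(
        name="aha_dbp_stage", mclass=MC.DBP, canonical_unit=mmhg,
        flag_key="DBP",
        bands=_bands([
            (60.0, 80.0, "Normal", 0),
            (80.0, 90.0, "Pre-hypertension", 0),
            (90.0, 100.0, "Stage 1", 1),
            (100.0, _INF, "Stage 2", 1),
        ])))
    # cholesterol guideline as printed in mmol/L: an uncovered gap remains
    # between 5.0 and 5.2
    add(RiskModel(
        name="aha_chol_mmol", mclass=MC.CHOL, canonical_unit=mmol,
        analyte="total-cholesterol", flag_key="CHOL",
        bands=(
            Band(-_INF, 5.0, "Desirable", 0, upper_inclusive=False),
            Band(5.2, 6.2, "Borderline high risk", 1, lower_inclusive=True,
                 upper_inclusive=True),
            Band(6.2, _INF, "High risk", 1, lower_inclusive=False),
        )))
    add(RiskModel(
        name="aha_hdl", mclass=MC.HDL, canonical_unit=mgdl, analyte="hdl",
        flag_key="HDL",
        bands=(
            Band(-_INF, 40.0, "Low HDL, heightened risk", 1,
                 upper_inclusive=False),
            Band(40.0, 60.0, "Medium HDL", 0, upper_inclusive=False),
            Band(60.0, _INF, "High HDL, optimal", 0),
        ),
        sex_overrides={"female": (
            Band(-_INF, 50.0, "Low HDL, heightened risk", 1,
                 upper_inclusive=False),
            Band(50.0, 60.0, "Medium HDL", 0, upper_inclusive=False),
            Band(60.0, _INF, "High HDL, optimal", 0),
        )}))
    add(RiskModel(
        name="aha_tg", mclass=MC.TG, canonical_unit=mgdl,
        analyte="triglyceride", flag_key="TG",
        bands=_bands([
            (-_INF, 150.0, "Normal", 0),
            (150.0, 200.0, "Borderline high", 0),
            (200.0, 500.0, "High", 1),
            (500.0, _INF, "Very high", 1),
        ])))
    add(RiskModel(
        name="aha_bmi", mclass=MC.BMI, canonical_unit=kgm2, flag_key="BMI",
        bands=_bands([
            (-_INF, 18.5, "Underweight", 0),
            (18.5, 25.0, "Healthy weight", 0),
            (25.0, 30.0, "Overweight", 1),
            (30.0, 40.0, "Obese", 1),
            (40.0, _INF, "Morbidly obese", 1),
        ])))
    add(RiskModel(
        name="aha_ldl", mclass=MC.LDL, canonical_unit=mgdl, analyte="ldl",
        flag_key="LDL",
        bands=_bands([
            (-_INF, 130.0, "Desirable", 0),
            (130.0, 160.0, "Borderline high risk", 0),
            (160.0, _INF, "High risk", 1),
        ])))
    _BUILTIN_CACHE = models
    return models


_BUILTIN_CACHE: Optional[dict[str, RiskModel]] = None


#: named model sets: expert-flag key -> model name
MODEL_SETS: dict[str, dict[str, str]] = {
    "original": {"SBP": "sbp", "DBP": "dbp", "CHOL": "chol", "HDL": "hdl",
                 "TG": "tg", "BMI": "bmi", "LDL": "ldl"},
    "modified": {"SBP": "sbp", "DBP": "dbp", "CHOL": "chol_modified",
                 "HDL": "hdl_modified", "TG": "tg_modified",
                 "BMI": "bmi_modified", "LDL": "ldl"},
    "aha": {"SBP": "aha_sbp_stage", "DBP": "aha_dbp_stage",
            "CHOL": "aha_chol_mmol", "HDL": "aha_hdl", "TG": "aha_tg",
            "BMI": "aha_bmi", "LDL": "aha_ldl"},
}


def resolve_model_set(name_or_path: str,
                      models: Optional[dict[str, RiskModel]] = None,
                      ) -> dict[str, RiskModel]:
    """Resolve a named set ('original', 'modified', 'aha') or a YAML model
    file into flag-key -> model mappings."""
    models = models or builtin_models()
    if name_or_path in MODEL_SETS:
        return {key: models[mname]
                for key, mname in MODEL_SETS[name_or_path].items()}
    loaded = load_models(open(name_or_path).read())
    out = {}
    for model in loaded.values():
        if model.flag_key is None:
            raise ModelError(f"model {model.name!r} lacks a flag_key")
        out[model.flag_key] = model
    return out


# -- model config (de)serialization -----------------------------------------

def _band_to_dict(band: Band) -> dict:
    return {
        "lower": None if band.lower == -_INF else band.lower,
        "upper": None if band.upper == _INF else band.upper,
        "lower_inclusive": band.lower_inclusive,
        "upper_inclusive": band.upper_inclusive,
        "label": band.label,
        "at_risk": band.at_risk,
    }


def _band_from_dict(d: Mapping) -> Band:
    return Band(
        lower=-_INF if d.get("lower") is None else float(d["lower"]),
        upper=_INF if d.get("upper") is None else float(d["upper"]),
        label=str(d["label"]),
        at_risk=int(d["at_risk"]),
        lower_inclusive=bool(d.get("lower_inclusive", True)),
        upper_inclusive=bool(d.get("upper_inclusive", False)),
    )


def models_to_config(models: Iterable[RiskModel]) -> str:
    """Serialize models to YAML."""
    entries = []
    for model in models:
        entry = {
            "name": model.name,
            "measurement_class": model.mclass.value,
            "unit": model.canonical_unit,
            "analyte": model.analyte,
            "flag_key": model.flag_key,
            "bands": [_band_to_dict(b) for b in model.bands],
        }
        if model.sex_overrides:
            entry["sex_overrides"] = {
                sex: [_band_to_dict(b) for b in bands]
                for sex, bands in model.sex_overrides.items()}
        entries.append(entry)
    return yaml.safe_dump({"models": entries}, sort_keys=False)


def load_models(text: str) -> dict[str, RiskModel]:
    """Parse models from the YAML config format."""
    config = yaml.safe_load(text)
    by_value = {m.value: m for m in MeasurementClass}
    models = {}
    for entry in config["models"]:
        mclass = by_value.get(entry["measurement_class"])
        if mclass is None:
            raise ModelError(
                f"unknown measurement class {entry['measurement_class']!r}")
        overrides = None
        if entry.get("sex_overrides"):
            overrides = {sex: tuple(_band_from_dict(b) for b in bands)
                         for sex, bands in entry["sex_overrides"].items()}
        model = RiskModel(
            name=entry["name"], mclass=mclass,
            canonical_unit=entry["unit"], analyte=entry.get("analyte"),
            flag_key=entry.get("flag_key"),
            bands=tuple(_band_from_dict(b) for b in entry["bands"]),
            sex_overrides=overrides)
        models[model.name] = model
    return models


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_binary(record: PatientRecord, model: RiskModel,
                    registry: Optional[UnitRegistry] = None,
                    ) -> ClassificationResult:
    """Convert the record's value for the model's measurement class into the
    model's canonical unit and match it to a band.  The stored measurement
    is never mutated.  A value landing in an uncovered gap yields status
    ``"unclassified: gap"``."""
    registry = registry or builtin_units()
    attr = record.attributes.get(model.mclass)
    if attr is None or attr.measurement is None:
        return ClassificationResult(record.record_id, model.name,
                                    status="insufficient data")
    conversions = []
    q = attr.measurement
    target = registry[model.canonical_unit]
    if q.unit != target:
        converted = registry.convert(q, target, analyte=model.analyte)
        conversions.append(
            f"{q.value:g} {q.unit.name} -> {converted.value:g} {target.name}")
        q = converted
    band = model.match(q.value, sex=record.sex)
    if band is None:
        return ClassificationResult(
            record.record_id, model.name, status="unclassified: gap",
            value=q.value, unit=target.name,
            conversions_performed=tuple(conversions))
    return ClassificationResult(
        record.record_id, model.name, status="classified",
        band_label=band.label, at_risk=band.at_risk, value=q.value,
        unit=target.name, conversions_performed=tuple(conversions))


_STAGE_SEVERITY = ["Normal", "Pre-hypertension", "Stage 1", "Stage 2"]
_STAGE_AT_RISK = {"Normal": 0, "Pre-hypertension": 0, "Stage 1": 1,
                  "Stage 2": 1, "Isolated systolic hypertension": 1}


def classify_bp_stage(record: PatientRecord,
                      registry: Optional[UnitRegistry] = None,
                      ) -> ClassificationResult:
    """Joint blood-pressure staging: isolated systolic hypertension iff
    SBP >= 140 with DBP < 90; otherwise the more severe of the systolic and
    diastolic stages.  Pressures below the tables' lower bounds (SBP < 90,
    DBP < 60) give a ``below-range`` outcome."""
    registry = registry or builtin_units()
    mmhg = registry["millimeter-of-mercury-column"]
    sbp = get_quantity(record, MeasurementClass.SBP, mmhg, registry=registry)
    dbp = get_quantity(record, MeasurementClass.DBP, mmhg, registry=registry)
    if sbp is None or dbp is None:
        return ClassificationResult(record.record_id, "bp_stage",
                                    status="insufficient data")
    if sbp.value < 90 or dbp.value < 60:
        return ClassificationResult(record.record_id, "bp_stage",
                                    status="below-range")
    if sbp.value >= 140 and dbp.value < 90:
        label = "Isolated systolic hypertension"
    else:
        models = builtin_models()
        s_band = models["aha_sbp_stage"].match(sbp.value)
        d_band = models["aha_dbp_stage"].match(dbp.value)
        label = max((s_band.label, d_band.label),
                    key=_STAGE_SEVERITY.index)
    return ClassificationResult(
        record.record_id, "bp_stage", status="classified", band_label=label,
        at_risk=_STAGE_AT_RISK[label], value=sbp.value, unit=mmhg.name)


# ---------------------------------------------------------------------------
# lifting
# ---------------------------------------------------------------------------

#: derivation dependency graph: derived class -> (deriver, required classes)
_DERIVERS = {
    MeasurementClass.BMI: (derive_bmi, (MeasurementClass.HEIGHT,
                                        MeasurementClass.MASS)),
    MeasurementClass.LDL: (derive_ldl, (MeasurementClass.CHOL,
                                        MeasurementClass.HDL,
                                        MeasurementClass.TG)),
}


def lift(record: PatientRecord,
         targets: Sequence[Union[str, RiskModel]],
         models: Optional[dict[str, RiskModel]] = None,
         registry: Optional[UnitRegistry] = None,
         ) -> tuple[PatientRecord, dict[str, ClassificationResult]]:
    """Derive whatever missing derivable attributes the targets need (each
    at most once), then classify each target.  ``targets`` may name binary
    models, ``"bp_stage"``, or ``"framingham"``.  Returns the augmented
    record and per-target results; an underivable missing attribute yields
    an ``insufficient data`` result for that target only.  Lifting an
    already-lifted record performs no further derivations."""
    registry = registry or builtin_units()
    models = models or builtin_models()
    derivations: list[str] = []
    augmented = record.copy()

    def ensure(mclass: MeasurementClass) -> bool:
        nonlocal augmented
        if mclass in augmented.attributes:
            return True
        deriver = _DERIVERS.get(mclass)
        if deriver is None:
            return False
        func, needs = deriver
        if not all(n in augmented.attributes for n in needs):
            return False
        augmented = func(augmented, registry=registry)
        derivations.append(mclass.value)
        return True

    results: dict[str, ClassificationResult] = {}
    for target in targets:
        if isinstance(target, RiskModel):
            name, model = target.name, target
        elif target == FRAMINGHAM_TARGET:
            name, model = FRAMINGHAM_TARGET, None
        elif target == "bp_stage":
            name, model = "bp_stage", None
        else:
            model = models.get(target)
            if model is None:
                raise ModelError(f"unknown model {target!r}")
            name = target

        mark = len(derivations)  # provenance is per-target

        if name == FRAMINGHAM_TARGET:
            try:
                fres = framingham_for_record(augmented, registry=registry)
            except DerivationError:
                results[name] = ClassificationResult(
                    record.record_id, name, status="insufficient data")
                continue
            derivations.append(MeasurementClass.FRAMINGHAM.value)
            results[name] = ClassificationResult(
                record.record_id, name, status="classified",
                band_label=fres.category,
                at_risk=int(fres.category != "low"),
                value=float(fres.total_points), unit="points",
                derivations_performed=tuple(derivations[mark:]))
            continue
        if name == "bp_stage":
            results[name] = classify_bp_stage(augmented, registry=registry)
            continue

        if model.mclass not in augmented.attributes:
            try:
                ok = ensure(model.mclass)
            except DerivationError:
                ok = False
            if not ok:
                results[name] = ClassificationResult(
                    record.record_id, name, status="insufficient data")
                continue
        result = classify_binary(augmented, model, registry=registry)
        results[name] = replace(
            result, derivations_performed=tuple(derivations[mark:]))
    return augmented, results


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: RiskModel, sex: Optional[str] = None,
                   ) -> dict[str, list[tuple[float, float]]]:
    """Enumerate uncovered gaps and overlapping band pairs.

    Gaps are maximal open intervals between consecutive covered stretches
    (intervals of zero width count when both adjoining endpoints are
    exclusive).  Coverage is assessed over (-inf, +inf); a model whose bands
    do not reach the infinities reports boundary gaps too."""
    bands = sorted(model.bands_for(sex), key=lambda b: (b.lower, b.upper))
    gaps: list[tuple[float, float]] = []
    overlaps: list[tuple[float, float]] = []

    for i, a in enumerate(bands):
        for b in bands[i + 1:]:
            lo = max(a.lower, b.lower)
            hi = min(a.upper, b.upper)
            if lo < hi:
                overlaps.append((lo, hi))
            elif lo == hi:
                a_inc = (a.upper_inclusive if a.upper == lo
                         else a.lower_inclusive)
                b_inc = (b.lower_inclusive if b.lower == lo
                         else b.upper_inclusive)
                if a_inc and b_inc:
                    overlaps.append((lo, hi))

    cursor = -_INF
    cursor_closed = True  # whether `cursor` itself is covered/irrelevant
    for band in bands:
        if band.lower > cursor or (band.lower == cursor
                                   and not cursor_closed
                                   and not band.lower_inclusive):
            if band.lower > cursor:
                gaps.append((cursor, band.lower))
            else:
                gaps.append((cursor, cursor))
        if band.upper > cursor or (band.upper == cursor
                                   and band.upper_inclusive):
            cursor = band.upper
            cursor_closed = band.upper_inclusive
        elif band.upper == cursor:
            cursor_closed = cursor_closed or band.upper_inclusive
    if cursor < _INF:
        gaps.append((cursor, _INF))
    return {"gaps": gaps, "overlaps": overlaps}
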