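"""Patient-record data model plus legacy-spreadsheet and Turtle RDF I/O.

A :class:`PatientRecord` is one clinical encounter: at most one
:class:`Attribute` per measurement class, optional expert binary risk flags
per attribute, an optional ternary overall risk label, and optional
smoker/diabetic/blood-pressure-treatment booleans.

Measurement classes split into *grounding* classes (directly observed) and
*derived* classes (computed: LDL, BMI, overall risk score).

The RDF layer writes records as a graph in Turtle: a record node linked by
``sio:hasAttribute`` to attribute nodes, each linked by
``sio:hasMeasurement`` to a measurement node carrying ``sio:hasUnit`` and
``sio:hasValue``.  The emitted Turtle is a constrained one-triple-per-line
subset that :func:`read_rdf` parses back losslessly.
"""

from __future__ import annotations

import csv
import enum
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, TextIO, Union

from .units import Quantity, Unit, UnitRegistry, builtin_units

__all__ = [
    "MeasurementClass",
    "Attribute",
    "PatientRecord",
    "RecordError",
    "DERIVED_CLASSES",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_UNIT_ASSUMPTIONS",
    "FLAG_KEYS",
    "read_legacy_table",
    "write_legacy_table",
    "write_rdf",
    "read_rdf",
    "get_quantity",
]


class MeasurementClass(enum.Enum):
    AGE = "Age"
    SEX = "Sex"
    MASS = "Mass"
    HEIGHT = "Height"
    SBP = "SystolicBloodPressure"
    DBP = "DiastolicBloodPressure"
    GLUCOSE = "BloodSugarConcentration"
    CHOL = "SerumCholesterolConcentration"
    HDL = "SerumHDLCholesterolConcentration"
    TG = "SerumTriglycerideConcentration"
    LDL = "SerumLDLCholesterolConcentration"
    BMI = "BodyMassIndex"
    FRAMINGHAM = "GeneralCVDFraminghamRiskScore"

    @property
    def grounding(self) -> bool:
        return self not in DERIVED_CLASSES


#: classes whose members are computed, never directly tied to the dataset
DERIVED_CLASSES = frozenset({
    MeasurementClass.LDL,
    MeasurementClass.BMI,
    MeasurementClass.FRAMINGHAM,
})

#: expert-flag keys in the legacy sheet, in printed column order
FLAG_KEYS = ("TG", "HDL", "LDL", "CHOL", "BMI", "DBP", "SBP")

_FLAG_TO_CLASS = {
    "TG": MeasurementClass.TG,
    "HDL": MeasurementClass.HDL,
    "LDL": MeasurementClass.LDL,
    "CHOL": MeasurementClass.CHOL,
    "BMI": MeasurementClass.BMI,
    "DBP": MeasurementClass.DBP,
    "SBP": MeasurementClass.SBP,
}


class RecordError(ValueError):
    """Malformed input row or graph; carries row/node context."""


@dataclass(frozen=True)
class Attribute:
    """One measurement attached to a record.

    Sex is categorical (``sex_value``); every other class carries a
    :class:`~cardiolift.units.Quantity`.  Exactly one of the two is set."""

    mclass: MeasurementClass
    measurement: Optional[Quantity] = None
    sex_value: Optional[str] = None  # "male" | "female"

    def __post_init__(self) -> None:
        if (self.measurement is None) == (self.sex_value is None):
            raise RecordError(
                f"attribute {self.mclass.value}: exactly one of measurement/"
                f"sex_value must be set"
            )
        if self.mclass is MeasurementClass.SEX:
            if self.sex_value not in ("male", "female"):
                raise RecordError(f"invalid sex value {self.sex_value!r}")
        elif self.measurement is None:
            raise RecordError(f"{self.mclass.value} requires a measurement")


@dataclass
class PatientRecord:
    """One encounter's attributes plus optional expert annotations."""

    record_id: str
    attributes: dict[MeasurementClass, Attribute] = field(default_factory=dict)
    expert_flags: dict[str, int] = field(default_factory=dict)
    expert_ternary: Optional[int] = None
    smoker: Optional[bool] = None
    diabetic: Optional[bool] = None
    bp_treated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.expert_ternary is not None and self.expert_ternary not in (1, 2, 3):
            raise RecordError(
                f"record {self.record_id}: ternary label must be 1, 2 or 3"
            )
        for key, flag in self.expert_flags.items():
            if flag not in (0, 1):
                raise RecordError(
                    f"record {self.record_id}: flag {key} must be 0/1"
                )

    def with_attribute(self, attribute: Attribute) -> "PatientRecord":
        """Copy of this record with ``attribute`` added/replaced."""
        attrs = dict(self.attributes)
        attrs[attribute.mclass] = attribute
        return replace(self, attributes=attrs)

    @property
    def sex(self) -> Optional[str]:
        attr = self.attributes.get(MeasurementClass.SEX)
        return attr.sex_value if attr else None

    def copy(self) -> "PatientRecord":
        return replace(self, attributes=dict(self.attributes),
                       expert_flags=dict(self.expert_flags))


# ---------------------------------------------------------------------------
# legacy spreadsheet dialect
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP: dict[str, MeasurementClass] = {
    "SBP": MeasurementClass.SBP,
    "DBP": MeasurementClass.DBP,
    "TOTALCHOL": MeasurementClass.CHOL,
    "HDL": MeasurementClass.HDL,
    "TG": MeasurementClass.TG,
    "AGE": MeasurementClass.AGE,
    "GENDER": MeasurementClass.SEX,
    "HEIGHT": MeasurementClass.HEIGHT,
    "WEIGHT": MeasurementClass.MASS,
    "GLUCOSE": MeasurementClass.GLUCOSE,
    "LDL": MeasurementClass.LDL,
    "BMI": MeasurementClass.BMI,
}

_DEFAULT_UNIT_NAMES: dict[MeasurementClass, str] = {
    MeasurementClass.AGE: "year",
    MeasurementClass.MASS: "kilogram",
    MeasurementClass.HEIGHT: "meter",
    MeasurementClass.SBP: "millimeter-of-mercury-column",
    MeasurementClass.DBP: "millimeter-of-mercury-column",
    MeasurementClass.GLUCOSE: "milligram-per-deciliter",
    MeasurementClass.CHOL: "milligram-per-deciliter",
    MeasurementClass.HDL: "milligram-per-deciliter",
    MeasurementClass.TG: "milligram-per-deciliter",
    MeasurementClass.LDL: "milligram-per-deciliter",
    MeasurementClass.BMI: "kilogram-per-meter-squared",
}


def DEFAULT_UNIT_ASSUMPTIONS(registry: UnitRegistry) -> dict[MeasurementClass, Unit]:
    """Shipped unit assumptions for the legacy sheet: height in meters,
    weight in kilograms, pressures in mmHg, lipids/glucose in mg/dl."""
    return {m: registry[name] for m, name in _DEFAULT_UNIT_NAMES.items()}


_GR_RE = re.compile(r"^(?P<key>[A-Z]+)\s*GR$")
_TRUTHY = {"1", "Y", "YES", "TRUE", "T"}
_FALSY = {"0", "N", "NO", "FALSE", "F"}


def _parse_bool(cell: str, row_index: int, column: str) -> Optional[bool]:
    token = cell.strip().upper()
    if not token:
        return None
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise RecordError(f"row {row_index}: bad boolean {cell!r} in {column}")


def read_legacy_table(
    stream: Union[str, TextIO],
    column_map: Optional[Mapping[str, MeasurementClass]] = None,
    unit_assumptions: Optional[Mapping[MeasurementClass, Unit]] = None,
    registry: Optional[UnitRegistry] = None,
) -> list[PatientRecord]:
    """Read the legacy spreadsheet dialect (comma or tab separated, header
    row required).  ``*_GR`` columns become expert flags, ``RISK GR`` the
    ternary label; optional ``SMOKER``/``DIABETIC``/``BPTREATED`` columns
    become booleans.  Missing cells yield absent attributes.  Malformed
    cells raise :class:`RecordError` naming the row."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    registry = registry or builtin_units()
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    units = dict(unit_assumptions or DEFAULT_UNIT_ASSUMPTIONS(registry))

    text = stream.read()
    if not text.strip():
        return []
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    header = [h.strip() for h in next(reader)]

    flag_cols: dict[int, str] = {}
    ternary_col: Optional[int] = None
    bool_cols: dict[int, str] = {}
    value_cols: dict[int, MeasurementClass] = {}
    id_col: Optional[int] = None
    for i, name in enumerate(header):
        upper = name.upper()
        if upper in ("RISK GR", "RISKGR", "RISK_GR"):
            ternary_col = i
            continue
        gr = _GR_RE.match(upper.replace("_", " "))
        if gr:
            flag_cols[i] = gr.group("key")
            continue
        if upper in ("SMOKER", "DIABETIC", "BPTREATED", "BP_TREATED"):
            bool_cols[i] = "bp_treated" if "TREATED" in upper else upper.lower()
            continue
        if upper in ("ID", "RECORD_ID", "RECORDID"):
            id_col = i
            continue
        if name in column_map:
            value_cols[i] = column_map[name]
        elif upper in column_map:
            value_cols[i] = column_map[upper]
        else:
            raise RecordError(f"unmapped column header {name!r}")

    records: list[PatientRecord] = []
    for row_index, row in enumerate(reader, start=1):
        if not any(cell.strip() for cell in row):
            continue
        record = PatientRecord(
            record_id=row[id_col].strip() if id_col is not None
            else f"r{row_index}")
        for i, mclass in value_cols.items():
            cell = row[i].strip() if i < len(row) else ""
            if not cell:
                continue
            if mclass is MeasurementClass.SEX:
                code = cell.upper()
                if code in ("M", "MALE"):
                    sex = "male"
                elif code in ("F", "FEMALE"):
                    sex = "female"
                else:
                    raise RecordError(
                        f"row {row_index}: unknown gender code {cell!r}")
                attr = Attribute(mclass, sex_value=sex)
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise RecordError(
                        f"row {row_index}: unparseable numeric {cell!r} "
                        f"in column {header[i]!r}") from None
                attr = Attribute(mclass, measurement=Quantity(value, units[mclass]))
            record.attributes[mclass] = attr
        for i, key in flag_cols.items():
            cell = row[i].strip() if i < len(row) else ""
            if not cell:
                continue
            if cell not in ("0", "1"):
                raise RecordError(
                    f"row {row_index}: flag {header[i]!r} must be 0/1, "
                    f"got {cell!r}")
            record.expert_flags[key] = int(cell)
        if ternary_col is not None and ternary_col < len(row):
            cell = row[ternary_col].strip()
            if cell:
                if cell not in ("1", "2", "3"):
                    raise RecordError(
                        f"row {row_index}: ternary label must be 1/2/3, "
                        f"got {cell!r}")
                record.expert_ternary = int(cell)
        for i, attr_name in bool_cols.items():
            cell = row[i] if i < len(row) else ""
            parsed = _parse_bool(cell, row_index, header[i])
            if parsed is not None:
                setattr(record, attr_name, parsed)
        records.append(record)
    return records


_LEGACY_ORDER = [
    ("SBP", MeasurementClass.SBP), ("DBP", MeasurementClass.DBP),
    ("TOTALCHOL", MeasurementClass.CHOL), ("HDL", MeasurementClass.HDL),
    ("TG", MeasurementClass.TG), ("AGE", MeasurementClass.AGE),
    ("GENDER", MeasurementClass.SEX), ("HEIGHT", MeasurementClass.HEIGHT),
    ("WEIGHT", MeasurementClass.MASS),
]


def write_legacy_table(records: Iterable[PatientRecord],
                       include_extras: bool = True) -> str:
    """Serialize records back to the legacy CSV dialect (shipped units)."""
    records = list(records)
    header = [name for name, _ in _LEGACY_ORDER]
    extras = []
    if include_extras:
        extras = ["SMOKER", "DIABETIC", "BPTREATED"]
    header = ["ID"] + header + extras + [f"{k} GR" for k in FLAG_KEYS] + ["RISK GR"]
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(header)
    for record in records:
        row: list[str] = [record.record_id]
        for _, mclass in _LEGACY_ORDER:
            attr = record.attributes.get(mclass)
            if attr is None:
                row.append("")
            elif mclass is MeasurementClass.SEX:
                row.append("M" if attr.sex_value == "male" else "F")
            else:
                row.append(repr(attr.measurement.value))
        if include_extras:
            for flag in (record.smoker, record.diabetic, record.bp_treated):
                row.append("" if flag is None else str(int(flag)))
        for key in FLAG_KEYS:
            flag = record.expert_flags.get(key)
            row.append("" if flag is None else str(flag))
        row.append("" if record.expert_ternary is None
                   else str(record.expert_ternary))
        writer.writerow(row)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Turtle RDF (constrained subset, self-contained)
# ---------------------------------------------------------------------------

PREFIXES = {
    "cardio": "http://example.org/cardiolift/cardio#",
    "sio": "http://semanticscience.org/resource/",
    "muo": "http://purl.oclc.org/NET/muo/muo#",
    "unit": "http://example.org/cardiolift/unit#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
}

_BOOL_PREDS = {"smoker": "cardio:isSmoker", "diabetic": "cardio:isDiabetic",
               "bp_treated": "cardio:isBPTreated"}


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def write_rdf(records: Iterable[PatientRecord]) -> str:
    """Serialize records to Turtle: record -> hasAttribute -> attribute ->
    hasMeasurement -> measurement{hasUnit, hasValue}."""
    lines = [f"@prefix {p}: <{iri}> ." for p, iri in PREFIXES.items()]
    lines.append("")
    for rec in records:
        rid = rec.record_id
        subj = f"cardio:record_{rid}"
        lines.append(f"{subj} rdf:type cardio:PatientRecord .")
        lines.append(f'{subj} cardio:recordID "{_ttl_escape(rid)}" .')
        for mclass in sorted(rec.attributes, key=lambda m: m.name):
            attr = rec.attributes[mclass]
            anode = f"cardio:attr_{rid}_{mclass.value}"
            lines.append(f"{subj} sio:hasAttribute {anode} .")
            lines.append(f"{anode} rdf:type cardio:{mclass.value} .")
            if mclass is MeasurementClass.SEX:
                lines.append(
                    f'{anode} cardio:hasSexValue "{attr.sex_value}" .')
            else:
                mnode = f"cardio:meas_{rid}_{mclass.value}"
                q = attr.measurement
                lines.append(f"{anode} sio:hasMeasurement {mnode} .")
                lines.append(f"{mnode} rdf:type sio:Measurement .")
                lines.append(f"{mnode} sio:hasUnit unit:{q.unit.name} .")
                lines.append(
                    f'{mnode} sio:hasValue "{q.value!r}"^^xsd:double .')
        for key, flag in sorted(rec.expert_flags.items()):
            lines.append(
                f'{subj} cardio:hasExpertFlag_{key} '
                f'"{flag}"^^xsd:integer .')
        if rec.expert_ternary is not None:
            lines.append(
                f'{subj} cardio:hasExpertTernaryRisk '
                f'"{rec.expert_ternary}"^^xsd:integer .')
        for attr_name, pred in _BOOL_PREDS.items():
            val = getattr(rec, attr_name)
            if val is not None:
                lines.append(
                    f'{subj} {pred} "{"true" if val else "false"}"'
                    f'^^xsd:boolean .')
    return "\n".join(lines) + "\n"


_TRIPLE_RE = re.compile(
    r"^(?P<s>\S+)\s+(?P<p>\S+)\s+(?P<o>.+?)\s*\.$")
_LITERAL_RE = re.compile(
    r'^"(?P<lex>(?:[^"\\]|\\.)*)"(?:\^\^(?P<dtype>\S+))?$')


def _parse_triples(text: str) -> list[tuple[str, str, str]]:
    triples = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("@prefix"):
            continue
        match = _TRIPLE_RE.match(line)
        if not match:
            raise RecordError(f"turtle line {lineno}: cannot parse {raw!r}")
        triples.append((match.group("s"), match.group("p"), match.group("o")))
    return triples


def _literal(obj: str) -> str:
    match = _LITERAL_RE.match(obj)
    if not match:
        raise RecordError(f"expected literal, got {obj!r}")
    return match.group("lex").replace('\\"', '"').replace("\\\\", "\\")


def read_rdf(text: str,
             registry: Optional[UnitRegistry] = None) -> list[PatientRecord]:
    """Parse Turtle produced by :func:`write_rdf` back into records."""
    registry = registry or builtin_units()
    triples = _parse_triples(text)
    by_subject: dict[str, list[tuple[str, str]]] = {}
    for s, p, o in triples:
        by_subject.setdefault(s, []).append((p, o))

    class_by_name = {m.value: m for m in MeasurementClass}
    records = []
    for subj, props in by_subject.items():
        if ("rdf:type", "cardio:PatientRecord") not in props:
            continue
        rid = None
        for p, o in props:
            if p == "cardio:recordID":
                rid = _literal(o)
        if rid is None:
            raise RecordError(f"record node {subj} lacks cardio:recordID")
        rec = PatientRecord(record_id=rid)
        for p, o in props:
            if p == "sio:hasAttribute":
                rec.attributes.update(
                    _parse_attribute(o, by_subject, class_by_name, registry))
            elif p.startswith("cardio:hasExpertFlag_"):
                rec.expert_flags[p.removeprefix("cardio:hasExpertFlag_")] = \
                    int(_literal(o))
            elif p == "cardio:hasExpertTernaryRisk":
                rec.expert_ternary = int(_literal(o))
            elif p == "cardio:isSmoker":
                rec.smoker = _literal(o) == "true"
            elif p == "cardio:isDiabetic":
                rec.diabetic = _literal(o) == "true"
            elif p == "cardio:isBPTreated":
                rec.bp_treated = _literal(o) == "true"
        records.append(rec)
    records.sort(key=lambda r: r.record_id)
    return records


def _parse_attribute(node: str, by_subject, class_by_name, registry):
    props = by_subject.get(node, [])
    mclass = None
    for p, o in props:
        if p == "rdf:type" and o.startswith("cardio:"):
            name = o.removeprefix("cardio:")
            if name not in class_by_name:
                raise RecordError(
                    f"attribute node {node}: unknown measurement class "
                    f"{name!r}")
            mclass = class_by_name[name]
    if mclass is None:
        raise RecordError(f"attribute node {node} lacks a measurement class")
    if mclass is MeasurementClass.SEX:
        for p, o in props:
            if p == "cardio:hasSexValue":
                return {mclass: Attribute(mclass, sex_value=_literal(o))}
        raise RecordError(f"sex attribute node {node} lacks a value")
    for p, o in props:
        if p == "sio:hasMeasurement":
            mprops = by_subject.get(o, [])
            unit = value = None
            for mp, mo in mprops:
                if mp == "sio:hasUnit":
                    unit_name = mo.removeprefix("unit:")
                    unit = registry.get(unit_name)
                    if unit is None:
                        raise RecordError(
                            f"measurement node {o}: unknown unit "
                            f"{unit_name!r}")
                elif mp == "sio:hasValue":
                    value = float(_literal(mo))
            if unit is None:
                raise RecordError(f"measurement node {o} lacks sio:hasUnit")
            if value is None:
                raise RecordError(f"measurement node {o} lacks sio:hasValue")
            return {mclass: Attribute(mclass,
                                      measurement=Quantity(value, unit))}
    raise RecordError(f"attribute node {node} lacks sio:hasMeasurement")


# ---------------------------------------------------------------------------


def get_quantity(record: PatientRecord, mclass: MeasurementClass,
                 target_unit: Optional[Union[Unit, str]] = None,
                 analyte: Optional[str] = None,
                 registry: Optional[UnitRegistry] = None,
                 ) -> Optional[Quantity]:
    """The record's quantity for ``mclass``, converted to ``target_unit``
    when given.  Returns ``None`` (not an error) when the attribute is
    absent.  Conversion errors propagate."""
    attr = record.attributes.get(mclass)
    if attr is None or attr.measurement is None:
        return None
    if target_unit is None:
        return attr.measurement
    registry = registry or builtin_units()
    return registry.convert(attr.measurement, target_unit, analyte=analyte)
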