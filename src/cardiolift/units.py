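"""Compositional unit-of-measure registry with analyte-aware conversion.

Units are built the way modular unit ontologies build them: a small set of
*base* units (gram, meter, liter, mole, pascal, ...), *simple derived* units
obtained from exactly one base unit via a decimal prefix and/or an integer
dimensional exponent (millimeter, kilogram, meter-squared), and *complex
derived* units combining two or more components with signed exponents
(kilogram-per-meter-squared, milligram-per-deciliter).

Conversion between two units is possible when they reduce to the same base
signature (pure prefix rescaling), when an explicit rule links their base
units (e.g. millimeter-of-mercury-column to pascal), or — for clinical
concentrations — when an analyte-specific molar-mass rule bridges a mass
concentration to a molar concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Unit",
    "Quantity",
    "ConversionRule",
    "UnitRegistry",
    "UnitError",
    "IncompatibleUnitsError",
    "builtin_units",
    "CHOLESTEROL_ANALYTES",
    "MOLAR_MASS_G_PER_MOL",
]

#: physical-quality tags used by the registry
QUALITIES = (
    "pressure",
    "mass",
    "length",
    "volume",
    "amount",
    "time",
    "area-density",
    "mass-concentration",
    "molar-concentration",
    "dimensionless",
)

#: analytes whose species share the cholesterol molar mass
CHOLESTEROL_ANALYTES = frozenset({"total-cholesterol", "hdl", "ldl"})

#: effective molar masses (g/mol) used for mass<->molar concentration
#: bridging; chosen so that mg/dl -> mmol/L divides by 38.67 (cholesterol
#: species), 88.57 (triglyceride) and 18.016 (glucose)
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "total-cholesterol": 386.7,
    "hdl": 386.7,
    "ldl": 386.7,
    "triglyceride": 885.7,
    "glucose": 180.16,
}


class UnitError(ValueError):
    """Invalid unit construction or lookup."""


class IncompatibleUnitsError(UnitError):
    """No conversion path exists between the two units."""


def _canon(name: str) -> str:
    return name.strip().lower().replace(" ", "-")


@dataclass(frozen=True)
class Unit:
    """A named unit of measure.

    ``derives_from`` is a tuple of ``(Unit, exponent)`` pairs: empty for a
    base unit, a single pair for a simple derived unit, two or more pairs
    for a complex derived unit.  ``prefix_factor`` is the decimal scale of a
    simple derived unit relative to its base (1.0 when there is no prefix).
    """

    name: str
    kind: str  # base | simple_derived | complex_derived
    derives_from: tuple[tuple["Unit", int], ...] = ()
    prefix_factor: float = 1.0
    quality: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.kind not in ("base", "simple_derived", "complex_derived"):
            raise UnitError(f"unknown unit kind {self.kind!r}")
        if self.kind == "base":
            if self.derives_from or self.prefix_factor != 1.0:
                raise UnitError(
                    f"base unit {self.name!r} must have no components and "
                    f"prefix factor 1.0"
                )
        elif self.kind == "simple_derived":
            if len(self.derives_from) != 1:
                raise UnitError(
                    f"simple derived unit {self.name!r} must derive from "
                    f"exactly one unit"
                )
        else:
            if len(self.derives_from) < 2:
                raise UnitError(
                    f"complex derived unit {self.name!r} needs >= 2 components"
                )
        if self.prefix_factor <= 0:
            raise UnitError(f"non-positive prefix factor for {self.name!r}")

    # -- reduction to base signature -------------------------------------

    def reduce(self) -> tuple[float, tuple[tuple[str, int], ...]]:
        """Return ``(scale, signature)``: one of this unit equals ``scale``
        times the product of base units raised to the signature exponents."""
        if self.kind == "base":
            return 1.0, ((self.name, 1),)
        scale = 1.0
        sig: dict[str, int] = {}
        for component, exponent in self.derives_from:
            sub_scale, sub_sig = component.reduce()
            scale *= (self.prefix_factor * sub_scale) ** exponent \
                if self.kind == "simple_derived" else (sub_scale) ** exponent
            for base_name, base_exp in sub_sig:
                sig[base_name] = sig.get(base_name, 0) + base_exp * exponent
        signature = tuple(sorted((n, e) for n, e in sig.items() if e != 0))
        return scale, signature

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Unit({self.name!r})"


@dataclass(frozen=True)
class Quantity:
    """A finite numeric value bound to a registered unit."""

    value: float
    unit: Unit

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite quantity value {self.value!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Quantity({self.value}, {self.unit.name!r})"


@dataclass(frozen=True)
class ConversionRule:
    """An explicit multiplicative link ``from_unit -> to_unit``.

    ``analyte`` restricts the rule to conversions made with that analyte tag
    (used for mass-concentration <-> molar-concentration bridging)."""

    from_unit: Unit
    to_unit: Unit
    factor: float
    analyte: Optional[str] = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise UnitError("conversion factor must be positive")


# signature -> quality for composite units
_SIGNATURE_QUALITY: dict[tuple[tuple[str, int], ...], str] = {
    (("gram", 1),): "mass",
    (("meter", 1),): "length",
    (("liter", 1),): "volume",
    (("mole", 1),): "amount",
    (("pascal", 1),): "pressure",
    (("gram", 1), ("meter", -2)): "area-density",
    (("gram", 1), ("liter", -1)): "mass-concentration",
    (("liter", -1), ("mole", 1)): "molar-concentration",
    (): "dimensionless",
}


class UnitRegistry:
    """Interning registry of units, aliases and conversion rules."""

    def __init__(self) -> None:
        self._units: dict[str, Unit] = {}
        self._aliases: dict[str, str] = {}
        self._rules: list[ConversionRule] = []
        # cache: simple-derived construction triples -> unit
        self._simple_cache: dict[tuple[str, float, int], Unit] = {}
        self._complex_cache: dict[tuple[tuple[str, int], ...], Unit] = {}

    # -- registration ----------------------------------------------------

    def add(self, unit: Unit, aliases: Iterable[str] = ()) -> Unit:
        key = _canon(unit.name)
        existing = self._units.get(key)
        if existing is not None:
            if existing != unit:
                raise UnitError(f"unit name {unit.name!r} already registered")
            unit = existing
        else:
            self._units[key] = unit
        for alias in aliases:
            self._aliases[_canon(alias)] = key
        return unit

    def alias(self, alias: str, target: str) -> None:
        self._aliases[_canon(alias)] = _canon(target)

    def add_rule(self, rule: ConversionRule, register_inverse: bool = True) -> None:
        self._rules.append(rule)
        if register_inverse:
            self._rules.append(
                ConversionRule(rule.to_unit, rule.from_unit, 1.0 / rule.factor,
                               rule.analyte)
            )

    def base(self, name: str, quality: str, aliases: Iterable[str] = ()) -> Unit:
        return self.add(Unit(name=name, kind="base", quality=quality),
                        aliases=aliases)

    def make_simple_derived(self, base: Unit, prefix_factor: float,
                            exponent: int, name: Optional[str] = None,
                            aliases: Iterable[str] = ()) -> Unit:
        """Derive a unit from one base unit via a prefix and/or exponent.

        Registering the same ``(base, prefix, exponent)`` triple twice
        returns the identical unit object."""
        if base.kind != "base":
            raise UnitError(f"{base.name!r} is not a base unit")
        if prefix_factor <= 0:
            raise UnitError("prefix factor must be positive")
        if exponent == 0:
            raise UnitError("exponent must be non-zero")
        cache_key = (base.name, float(prefix_factor), int(exponent))
        cached = self._simple_cache.get(cache_key)
        if cached is not None:
            return cached
        if name is None:
            name = f"{base.name}^{exponent}x{prefix_factor:g}"
        unit = Unit(
            name=name,
            kind="simple_derived",
            derives_from=((base, exponent),),
            prefix_factor=float(prefix_factor),
            quality=self._quality_of(((base, exponent),), prefix_factor),
        )
        unit = self.add(unit, aliases=aliases)
        self._simple_cache[cache_key] = unit
        return unit

    def make_complex_derived(self, components: Sequence[tuple[Unit, int]],
                             name: Optional[str] = None,
                             aliases: Iterable[str] = ()) -> Unit:
        """Combine >= 2 component units into a complex derived unit.

        The component list is order-insensitive: the same multiset of
        components returns the identical registered unit."""
        if len(components) < 2:
            raise UnitError("complex derived unit needs >= 2 components")
        comp = tuple(sorted(((u, int(e)) for u, e in components),
                            key=lambda p: (p[0].name, p[1])))
        cache_key = tuple((u.name, e) for u, e in comp)
        cached = self._complex_cache.get(cache_key)
        if cached is not None:
            return cached
        if name is None:
            name = "-".join(
                f"{u.name}{'' if e == 1 else f'^{e}'}" for u, e in comp
            )
        unit = Unit(
            name=name,
            kind="complex_derived",
            derives_from=comp,
            quality=self._quality_of(comp, 1.0),
        )
        unit = self.add(unit, aliases=aliases)
        self._complex_cache[cache_key] = unit
        return unit

    def _quality_of(self, components: tuple[tuple[Unit, int], ...],
                    prefix_factor: float) -> str:
        probe = Unit(name="__probe__",
                     kind="simple_derived" if len(components) == 1
                     else "complex_derived",
                     derives_from=components,
                     prefix_factor=prefix_factor)
        _, signature = probe.reduce()
        if signature in _SIGNATURE_QUALITY:
            return _SIGNATURE_QUALITY[signature]
        if len(signature) == 1 and signature[0][1] == 1:
            base = self._units.get(_canon(signature[0][0]))
            if base is not None:
                return base.quality
        return "dimensionless" if not signature else "derived"

    # -- lookup ----------------------------------------------------------

    def get(self, name: str) -> Optional[Unit]:
        key = _canon(name)
        key = self._aliases.get(key, key)
        return self._units.get(key)

    def __getitem__(self, name: str) -> Unit:
        unit = self.get(name)
        if unit is None:
            raise UnitError(f"unknown unit {name!r}")
        return unit

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    def names(self) -> list[str]:
        return sorted(self._units)

    # -- conversion ------------------------------------------------------

    def conversion_factor(self, source: Unit, target: Unit,
                          analyte: Optional[str] = None) -> float:
        """Multiplicative factor turning a value in ``source`` into
        ``target``, composed across prefix rescalings and explicit rules."""
        if source == target:
            return 1.0
        # BFS over (unit) nodes; edge = same-signature rescale or rule
        src_scale, src_sig = source.reduce()
        tgt_scale, tgt_sig = target.reduce()
        if src_sig == tgt_sig:
            return src_scale / tgt_scale
        # graph search through explicit rules
        frontier: list[tuple[Unit, float]] = [(source, 1.0)]
        seen = {source.name}
        while frontier:
            unit, factor = frontier.pop(0)
            u_scale, u_sig = unit.reduce()
            for rule in self._rules:
                if rule.analyte is not None and rule.analyte != analyte:
                    continue
                r_scale, r_sig = rule.from_unit.reduce()
                if r_sig != u_sig:
                    continue
                # rescale onto the rule's from_unit, apply rule
                step = factor * (u_scale / r_scale) * rule.factor
                nxt = rule.to_unit
                n_scale, n_sig = nxt.reduce()
                if n_sig == tgt_sig:
                    return step * (n_scale / tgt_scale)
                if nxt.name not in seen:
                    seen.add(nxt.name)
                    frontier.append((nxt, step))
        if (source.quality in ("mass-concentration", "molar-concentration")
                and target.quality in ("mass-concentration",
                                       "molar-concentration")
                and source.quality != target.quality and analyte is None):
            raise IncompatibleUnitsError(
                f"converting {source.name!r} -> {target.name!r} requires an "
                f"analyte tag (mass/molar concentration bridge)"
            )
        raise IncompatibleUnitsError(
            f"no conversion path from {source.name!r} ({source.quality}) to "
            f"{target.name!r} ({target.quality})"
        )

    def convert(self, q: Quantity, target: Unit | str,
                analyte: Optional[str] = None) -> Quantity:
        if isinstance(target, str):
            target = self[target]
        factor = self.conversion_factor(q.unit, target, analyte=analyte)
        return Quantity(q.value * factor, target)

    # -- (de)serialization ----------------------------------------------

    def to_config(self) -> dict:
        units = []
        for unit in self._units.values():
            units.append({
                "name": unit.name,
                "kind": unit.kind,
                "quality": unit.quality,
                "prefix_factor": unit.prefix_factor,
                "derives_from": [[u.name, e] for u, e in unit.derives_from],
            })
        rules = [{
            "from": r.from_unit.name, "to": r.to_unit.name,
            "factor": r.factor, "analyte": r.analyte,
        } for r in self._rules]
        aliases = dict(self._aliases)
        return {"units": units, "rules": rules, "aliases": aliases}

    @classmethod
    def from_config(cls, config: Mapping) -> "UnitRegistry":
        reg = cls()
        pending = list(config["units"])
        # topological fill: bases first, then whatever's resolvable
        while pending:
            progressed = False
            rest = []
            for entry in pending:
                deps = [d[0] for d in entry["derives_from"]]
                if all(reg.get(d) for d in deps):
                    comps = tuple((reg[d], int(e))
                                  for d, e in entry["derives_from"])
                    unit = Unit(name=entry["name"], kind=entry["kind"],
                                derives_from=comps,
                                prefix_factor=float(entry["prefix_factor"]),
                                quality=entry["quality"])
                    reg.add(unit)
                    progressed = True
                else:
                    rest.append(entry)
            if not progressed:
                raise UnitError("unresolvable unit dependencies in config")
            pending = rest
        for alias, target in config.get("aliases", {}).items():
            reg.alias(alias, target)
        for rule in config.get("rules", []):
            reg.add_rule(ConversionRule(reg[rule["from"]], reg[rule["to"]],
                                        float(rule["factor"]),
                                        rule.get("analyte")),
                         register_inverse=False)
        return reg

    def to_turtle(self) -> str:
        """Emit the unit definitions as Turtle triples in the style of a
        modular measurement-unit ontology."""
        lines = [
            "@prefix muo: <http://purl.oclc.org/NET/muo/muo#> .",
            "@prefix unit: <http://example.org/cardiolift/unit#> .",
            "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
            "",
        ]
        kind_class = {
            "base": "muo:BaseUnit",
            "simple_derived": "muo:SimpleDerivedUnit",
            "complex_derived": "muo:ComplexDerivedUnit",
        }
        for unit in self._units.values():
            subj = f"unit:{unit.name}"
            lines.append(f"{subj} a {kind_class[unit.kind]} .")
            for comp, exponent in unit.derives_from:
                lines.append(f"{subj} muo:derivesFrom unit:{comp.name} .")
                if exponent != 1:
                    lines.append(
                        f'{subj} muo:dimensionalSize "{exponent}"^^xsd:float .'
                    )
            if unit.prefix_factor != 1.0:
                lines.append(
                    f'{subj} muo:prefixFactor '
                    f'"{unit.prefix_factor!r}"^^xsd:double .'
                )
        return "\n".join(lines) + "\n"


def builtin_units() -> UnitRegistry:
    """Registry pre-loaded with the units needed for the clinical records:
    gram/kilogram/milligram, meter/millimeter, liter/deciliter,
    mole/millimole, pascal/kilopascal, millimeter-of-mercury-column, year,
    kilogram-per-meter-squared, milligram-per-deciliter,
    millimole-per-liter — plus the analyte bridging rules."""
    reg = UnitRegistry()
    gram = reg.base("gram", "mass", aliases=["g"])
    meter = reg.base("meter", "length", aliases=["m"])
    liter = reg.base("liter", "volume", aliases=["l", "L"])
    mole = reg.base("mole", "amount", aliases=["mol"])
    pascal = reg.base("pascal", "pressure", aliases=["Pa"])
    # mercury-column pressure is its own base, linked by an explicit rule
    mmhg = reg.base("millimeter-of-mercury-column", "pressure",
                    aliases=["mmHg", "milli-meter-of-mercury-column",
                             "millimeter-of mercury-column"])
    reg.base("year", "time", aliases=["y", "years"])

    kilogram = reg.make_simple_derived(gram, 1000.0, 1, name="kilogram",
                                       aliases=["kg"])
    milligram = reg.make_simple_derived(gram, 0.001, 1, name="milligram",
                                        aliases=["mg"])
    reg.make_simple_derived(meter, 0.001, 1, name="millimeter",
                            aliases=["mm"])
    reg.make_simple_derived(meter, 0.01, 1, name="centimeter",
                            aliases=["cm"])
    deciliter = reg.make_simple_derived(liter, 0.1, 1, name="deciliter",
                                        aliases=["dl", "dL"])
    millimole = reg.make_simple_derived(mole, 0.001, 1, name="millimole",
                                        aliases=["mmol"])
    kilopascal = reg.make_simple_derived(pascal, 1000.0, 1, name="kilopascal",
                                         aliases=["kPa"])
    meter_sq = reg.make_simple_derived(meter, 1.0, 2, name="meter-squared",
                                       aliases=["m2", "m^2"])

    reg.make_complex_derived([(kilogram, 1), (meter, -2)],
                             name="kilogram-per-meter-squared",
                             aliases=["kg/m2", "kg/m^2",
                                      "kilogram-per-meter-square"])
    reg.make_complex_derived([(milligram, 1), (deciliter, -1)],
                             name="milligram-per-deciliter",
                             aliases=["mg/dl", "mg/dL",
                                      "milli-gram-per-deci-liter"])
    mmol_l = reg.make_complex_derived([(millimole, 1), (liter, -1)],
                                      name="millimole-per-liter",
                                      aliases=["mmol/l", "mmol/L",
                                               "mili-mole-per-liter",
                                               "milli-mole-per-liter"])
    g_l = reg.make_complex_derived([(gram, 1), (liter, -1)],
                                   name="gram-per-liter", aliases=["g/l"])
    mol_l = reg.make_complex_derived([(mole, 1), (liter, -1)],
                                     name="mole-per-liter", aliases=["mol/l"])

    # pressure bridge: 1 mmHg = 0.133322 kPa = 133.322 Pa
    reg.add_rule(ConversionRule(mmhg, pascal, 133.322))

    # analyte bridges: (g/L) / (g/mol) = mol/L
    for analyte, molar_mass in MOLAR_MASS_G_PER_MOL.items():
        reg.add_rule(ConversionRule(g_l, mol_l, 1.0 / molar_mass,
                                    analyte=analyte))
    # silence "unused" lints without dropping the handles
    del mmol_l
    return reg
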