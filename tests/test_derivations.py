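import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiolift.derivations import (DerivationError, FraminghamProfile,
                                    derive_bmi, derive_ldl,
                                    framingham_category, framingham_percent,
                                    framingham_points, friedewald,
                                    friedewald_constant)
from cardiolift.records import Attribute, MeasurementClass, PatientRecord
from cardiolift.units import Quantity, builtin_units

MC = MeasurementClass


def _record(registry, **kwargs):
    rec = PatientRecord(record_id="t")
    unit_map = {
        "height": ("meter", MC.HEIGHT), "mass": ("kilogram", MC.MASS),
        "height_cm": ("centimeter", MC.HEIGHT),
        "chol": ("mg/dl", MC.CHOL), "hdl": ("mg/dl", MC.HDL),
        "tg": ("mg/dl", MC.TG),
        "chol_mmol": ("mmol/L", MC.CHOL), "hdl_mmol": ("mmol/L", MC.HDL),
        "tg_mmol": ("mmol/L", MC.TG),
    }
    for key, value in kwargs.items():
        unit_name, mclass = unit_map[key]
        rec.attributes[mclass] = Attribute(
            mclass, measurement=Quantity(value, registry[unit_name]))
    return rec


class TestBmi:
    def test_hand_oracle(self, registry):
        rec = _record(registry, height=1.8288, mass=78.1818)
        out = derive_bmi(rec, registry=registry)
        expected = 78.1818 / 1.8288 ** 2  # independent hand computation
        bmi = out.attributes[MC.BMI].measurement
        assert bmi.value == pytest.approx(expected, rel=1e-12)
        assert bmi.value == pytest.approx(23.38, abs=0.005)
        assert bmi.unit.name == "kilogram-per-meter-squared"

    def test_unit_height(self, registry):
        rec = _record(registry, height=1.0, mass=42.0)
        out = derive_bmi(rec, registry=registry)
        assert out.attributes[MC.BMI].measurement.value == 42.0

    def test_cm_input_matches_meter_input(self, registry):
        in_m = derive_bmi(_record(registry, height=1.75, mass=70.0),
                          registry=registry)
        in_cm = derive_bmi(_record(registry, height_cm=175.0, mass=70.0),
                           registry=registry)
        a = in_m.attributes[MC.BMI].measurement.value
        b = in_cm.attributes[MC.BMI].measurement.value
        assert abs(a - b) / a < 1e-6

    def test_originals_untouched(self, registry):
        rec = _record(registry, height=1.75, mass=70.0)
        out = derive_bmi(rec, registry=registry)
        assert out.attributes[MC.HEIGHT].measurement.value == 1.75
        assert MC.BMI not in rec.attributes  # input record not mutated

    def test_missing_input(self, registry):
        with pytest.raises(DerivationError, match="Mass"):
            derive_bmi(_record(registry, height=1.75), registry=registry)

    def test_non_positive_height(self, registry):
        with pytest.raises(DerivationError, match="height"):
            derive_bmi(_record(registry, height=0.0, mass=70.0),
                       registry=registry)


class TestFriedewald:
    def test_hand_oracle_mgdl(self, registry):
        rec = _record(registry, chol=227.0, hdl=55.0, tg=84.0)
        out = derive_ldl(rec, registry=registry)
        ldl = out.attributes[MC.LDL].measurement
        assert ldl.value == pytest.approx(227 - 55 - 0.2 * 84)  # = 155.2
        assert ldl.value == pytest.approx(155.2)
        assert ldl.unit.name == "milligram-per-deciliter"

    def test_degenerate_zero(self, registry):
        rec = _record(registry, chol=180.0, hdl=180.0, tg=0.0)
        out = derive_ldl(rec, registry=registry)
        assert out.attributes[MC.LDL].measurement.value == 0.0

    def test_constant_selection(self, registry):
        assert friedewald_constant(registry["mg/dl"]) == 0.20
        assert friedewald_constant(registry["mmol/L"]) == 0.45
        with pytest.raises(DerivationError):
            friedewald_constant(registry["meter"])

    def test_constant_exposed_by_friedewald(self, registry):
        _, k = friedewald(Quantity(5.87, registry["mmol/L"]),
                          Quantity(1.42, registry["mmol/L"]),
                          Quantity(0.95, registry["mmol/L"]),
                          registry=registry)
        assert k == 0.45
        _, k = friedewald(Quantity(227.0, registry["mg/dl"]),
                          Quantity(55.0, registry["mg/dl"]),
                          Quantity(84.0, registry["mg/dl"]),
                          registry=registry)
        assert k == 0.20

    def test_within_family_unit_invariance(self, registry):
        """Same values in mg/dl vs g/L agree to 1e-6 relative: both select
        k = 0.20."""
        rec_mgdl = _record(registry, chol=227.0, hdl=55.0, tg=84.0)
        rec_gl = PatientRecord(record_id="t")
        gl = registry["gram-per-liter"]
        for mclass, v in [(MC.CHOL, 2.27), (MC.HDL, 0.55), (MC.TG, 0.84)]:
            rec_gl.attributes[mclass] = Attribute(
                mclass, measurement=Quantity(v, gl))
        a = derive_ldl(rec_mgdl, registry=registry) \
            .attributes[MC.LDL].measurement
        b = derive_ldl(rec_gl, registry=registry) \
            .attributes[MC.LDL].measurement
        b_in_mgdl = registry.convert(b, "mg/dl", analyte="ldl")
        assert abs(a.value - b_in_mgdl.value) / a.value < 1e-6

    def test_cross_family_close_but_not_exact(self, registry):
        """The molar-system constant 0.45 is not an exact rescale of 0.20
        (0.20 scaled by the TG/cholesterol molar-mass ratio is ~0.458), so
        cross-family agreement is approximate, within 1%."""
        rec_mgdl = _record(registry, chol=227.0, hdl=55.0, tg=84.0)
        rec_mmol = _record(
            registry,
            chol_mmol=registry.convert(Quantity(227.0, registry["mg/dl"]),
                                       "mmol/L",
                                       analyte="total-cholesterol").value,
            hdl_mmol=registry.convert(Quantity(55.0, registry["mg/dl"]),
                                      "mmol/L", analyte="hdl").value,
            tg_mmol=registry.convert(Quantity(84.0, registry["mg/dl"]),
                                     "mmol/L", analyte="triglyceride").value)
        a = derive_ldl(rec_mgdl, registry=registry) \
            .attributes[MC.LDL].measurement
        b = derive_ldl(rec_mmol, registry=registry) \
            .attributes[MC.LDL].measurement
        a_mmol = registry.convert(a, "mmol/L", analyte="ldl")
        assert b.unit.name == "millimole-per-liter"
        assert abs(a_mmol.value - b.value) / a_mmol.value < 0.01
        assert a_mmol.value != pytest.approx(b.value, rel=1e-6)

    def test_missing_inputs(self, registry):
        with pytest.raises(DerivationError, match="TG"):
            derive_ldl(_record(registry, chol=227.0, hdl=55.0),
                       registry=registry)

    def test_negative_ldl_flagged(self, registry):
        with pytest.raises(DerivationError, match="negative"):
            derive_ldl(_record(registry, chol=100.0, hdl=90.0, tg=200.0),
                       registry=registry)

    def test_tg_guard_optional(self, registry):
        rec = _record(registry, chol=300.0, hdl=40.0, tg=450.0)
        derive_ldl(rec, registry=registry)  # guard off by default
        with pytest.raises(DerivationError, match="400"):
            derive_ldl(rec, registry=registry, tg_guard=True)


def _profile(registry, age=50, hdl=50.0, chol=180.0, sbp=125.0,
             treated=False, smoker=False, diabetic=False):
    return FraminghamProfile(
        age=age,
        hdl=Quantity(hdl, registry["mg/dl"]),
        total_cholesterol=Quantity(chol, registry["mg/dl"]),
        sbp=Quantity(sbp, registry["mmHg"]),
        bp_treated=treated, smoker=smoker, diabetic=diabetic)


class TestFraminghamPoints:
    # exhaustive band edges, frozen from the printed men's table
    AGE_CASES = [(30, 0), (34, 0), (35, 2), (39, 2), (40, 5), (44, 5),
                 (45, 6), (49, 6), (50, 8), (54, 8), (55, 10), (59, 10),
                 (60, 11), (64, 11), (65, 12), (69, 12), (70, 14), (74, 14),
                 (75, 15), (77, 15), (95, 15)]
    HDL_CASES = [(20.0, 2), (34.0, 2), (35.0, 1), (44.0, 1), (45.0, 0),
                 (49.0, 0), (50.0, -1), (59.0, -1), (60.0, -2), (62.0, -2)]
    CHOL_CASES = [(100.0, 0), (159.0, 0), (160.0, 1), (199.0, 1),
                  (200.0, 2), (239.0, 2), (240.0, 3), (279.0, 3),
                  (280.0, 4), (400.0, 4)]
    SBP_UNTREATED = [(100.0, -2), (119.0, -2), (120.0, 0), (129.0, 0),
                     (130.0, 1), (139.0, 1), (140.0, 2), (159.0, 2),
                     (160.0, 3), (220.0, 3)]
    SBP_TREATED = [(100.0, 0), (119.0, 0), (120.0, 2), (129.0, 2),
                   (130.0, 3), (139.0, 3), (140.0, 4), (159.0, 4),
                   (160.0, 5), (220.0, 5)]

    @pytest.mark.parametrize("age,points", AGE_CASES)
    def test_age_points(self, registry, age, points):
        result = framingham_points(_profile(registry, age=age),
                                   registry=registry)
        assert result.per_factor_points["age"] == points

    @pytest.mark.parametrize("hdl,points", HDL_CASES)
    def test_hdl_points(self, registry, hdl, points):
        result = framingham_points(_profile(registry, hdl=hdl),
                                   registry=registry)
        assert result.per_factor_points["hdl"] == points

    @pytest.mark.parametrize("chol,points", CHOL_CASES)
    def test_chol_points(self, registry, chol, points):
        result = framingham_points(_profile(registry, chol=chol),
                                   registry=registry)
        assert result.per_factor_points["total_cholesterol"] == points

    @pytest.mark.parametrize("sbp,points", SBP_UNTREATED)
    def test_sbp_untreated_points(self, registry, sbp, points):
        result = framingham_points(_profile(registry, sbp=sbp),
                                   registry=registry)
        assert result.per_factor_points["sbp"] == points

    @pytest.mark.parametrize("sbp,points", SBP_TREATED)
    def test_sbp_treated_points(self, registry, sbp, points):
        result = framingham_points(_profile(registry, sbp=sbp, treated=True),
                                   registry=registry)
        assert result.per_factor_points["sbp"] == points

    def test_smoker_diabetic_points(self, registry):
        base = framingham_points(_profile(registry), registry=registry)
        smoker = framingham_points(_profile(registry, smoker=True),
                                   registry=registry)
        diabetic = framingham_points(_profile(registry, diabetic=True),
                                     registry=registry)
        assert smoker.total_points - base.total_points == 4
        assert diabetic.total_points - base.total_points == 3

    def test_hand_sum_minimal_profile(self, registry):
        # 0 (age 30) + 0 (HDL 46) + 0 (chol 150) + (-2) (SBP 118) + 0 + 0
        result = framingham_points(
            _profile(registry, age=30, hdl=46.0, chol=150.0, sbp=118.0),
            registry=registry)
        assert result.total_points == -2

    def test_total_is_sum(self, registry):
        result = framingham_points(
            _profile(registry, age=77, hdl=55.0, chol=227.0, sbp=128.0),
            registry=registry)
        assert result.total_points == sum(
            result.per_factor_points.values())

    def test_age_below_30_rejected(self, registry):
        with pytest.raises(DerivationError, match="30"):
            _profile(registry, age=29)

    def test_female_rejected(self, registry):
        with pytest.raises(DerivationError, match="men"):
            FraminghamProfile(
                age=50, hdl=Quantity(50, registry["mg/dl"]),
                total_cholesterol=Quantity(180, registry["mg/dl"]),
                sbp=Quantity(120, registry["mmHg"]), sex="female")

    def test_mmol_inputs_convert_internally(self, registry):
        # non-boundary values: band edges are not robust to conversion
        # round-trip noise at the last ulp
        mgdl = framingham_points(_profile(registry, hdl=62.0, chol=245.0),
                                 registry=registry)
        mmol = framingham_points(
            FraminghamProfile(
                age=50,
                hdl=registry.convert(Quantity(62.0, registry["mg/dl"]),
                                     "mmol/L", analyte="hdl"),
                total_cholesterol=registry.convert(
                    Quantity(245.0, registry["mg/dl"]), "mmol/L",
                    analyte="total-cholesterol"),
                sbp=registry.convert(Quantity(125.0, registry["mmHg"]),
                                     "kPa")),
            registry=registry)
        assert mgdl.per_factor_points == mmol.per_factor_points

    @given(age=st.integers(30, 95), hdl=st.floats(20, 100),
           chol=st.floats(100, 400), sbp=st.floats(95, 220),
           smoker=st.booleans(), diabetic=st.booleans())
    @settings(max_examples=150, deadline=None)
    def test_monotonicity(self, age, hdl, chol, sbp, smoker, diabetic):
        registry = builtin_units()
        base = framingham_points(
            _profile(registry, age=age, hdl=hdl, chol=chol, sbp=sbp,
                     smoker=smoker, diabetic=diabetic), registry=registry)

        def total(**overrides):
            kwargs = dict(age=age, hdl=hdl, chol=chol, sbp=sbp,
                          smoker=smoker, diabetic=diabetic)
            kwargs.update(overrides)
            return framingham_points(_profile(registry, **kwargs),
                                     registry=registry).total_points

        assert total(age=min(age + 5, 95)) >= base.total_points
        assert total(chol=min(chol + 40, 400)) >= base.total_points
        assert total(sbp=min(sbp + 15, 220)) >= base.total_points
        assert total(hdl=min(hdl + 10, 100)) <= base.total_points


class TestFraminghamPercent:
    TABLE = [(9, 1.0), (10, 1.0), (11, 1.0), (12, 1.0), (13, 2.0),
             (14, 2.0), (15, 3.0), (16, 4.0), (17, 5.0), (18, 6.0),
             (19, 8.0), (20, 11.0), (21, 14.0), (22, 17.0), (23, 22.0),
             (24, 27.0)]

    @pytest.mark.parametrize("points,percent", TABLE)
    def test_exact_rows(self, points, percent):
        risk = framingham_percent(points)
        assert risk.relation == "eq"
        assert risk.percent == percent

    def test_twenty_points(self):
        assert framingham_percent(20).percent == 11.0

    def test_open_ended_top(self):
        risk = framingham_percent(25)
        assert (risk.relation, risk.percent) == ("ge", 30.0)
        assert framingham_percent(40).relation == "ge"
        assert str(risk) == "≥30%"

    def test_below_range_bound(self):
        risk = framingham_percent(0)
        assert (risk.relation, risk.percent) == ("lt", 1.0)
        assert framingham_percent(8).relation == "lt"

    def test_percent_non_decreasing_in_points(self):
        previous = 0.0
        for points in range(-5, 41):
            percent = framingham_percent(points).percent
            assert percent >= previous
            previous = percent


class TestFraminghamCategory:
    @pytest.mark.parametrize("points,category", [
        (-2, "low"), (0, "low"), (9, "low"),
        (10, "medium"), (15, "medium"), (19, "medium"),
        (20, "high"), (30, "high"),
    ])
    def test_quantization(self, points, category):
        assert framingham_category(points) == category

    def test_category_consistent_with_percent_ordering(self):
        # risk % at the category boundaries is non-decreasing
        assert framingham_percent(9).percent <= framingham_percent(10).percent
        assert framingham_percent(19).percent <= \
            framingham_percent(20).percent
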