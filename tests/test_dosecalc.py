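"""Dose-calculator algorithm: BSA readings, corrections, clamping, dilution."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aortadose.dosecalc import (
    AgentSpec,
    CalculatorConfig,
    PatientProfile,
    apply_dilution,
    calculate_dose,
    compute_bsa,
    concentration_correction,
    hr_correction,
    round_half_up,
    standard_plan,
)


def _patient(weight, height, hr, group="calculator"):
    return PatientProfile(weight=weight, height=height, heart_rate=hr, group=group)


class TestBsa:
    @pytest.mark.parametrize(
        "weight, height, mode, expected",
        [
            (80, 180, "mosteller", 2.0),  # 14400/3600 = 4, sqrt = 2 exactly
            (115, 185, "literal", 115 * 185 / 3600 * 0.5),
            (97, 175, "literal", 97 * 175 / 3600 * 0.5),
        ],
    )
    def test_both_readings(self, weight, height, mode, expected):
        assert compute_bsa(weight, height, mode) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weight, height", [(0, 170), (-5, 170), (70, 0), (70, -1)])
    def test_non_positive_inputs_rejected(self, weight, height):
        with pytest.raises(ValueError):
            compute_bsa(weight, height)

    @given(
        weight=st.floats(30, 200),
        height=st.floats(120, 220),
    )
    def test_literal_exceeds_mosteller_iff_product_over_4(self, weight, height):
        hw = height * weight / 3600
        lit = compute_bsa(weight, height, "literal")
        mos = compute_bsa(weight, height, "mosteller")
        if hw > 4:
            assert lit > mos
        elif hw < 4:
            assert lit < mos
        else:
            assert lit == pytest.approx(mos)


class TestHrCorrection:
    def test_exhaustive_against_literal_table(self, calc_config):
        """Every integer bpm 1–200 agrees with a direct transcription of the
        published correction table (55 bpm assigned to the low band)."""
        for bpm in range(1, 201):
            if bpm <= 55:
                expected = -10
            elif bpm <= 65:
                expected = 0
            elif bpm <= 75:
                expected = 10
            elif bpm <= 90:
                expected = 20
            elif bpm <= 105:
                expected = 25
            else:
                expected = 30
            assert hr_correction(bpm, calc_config) == expected, f"bpm={bpm}"

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            hr_correction(0)


class TestConcentrationCorrection:
    @pytest.mark.parametrize(
        "concentration, expected",
        [(350, 0.0), (320, 6.0), (370, -4.0), (355, -1.0), (345.0, 1.0)],
    )
    def test_linear_around_reference(self, concentration, expected):
        assert concentration_correction(concentration) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            concentration_correction(0)


class TestCalculateDose:
    def test_published_worked_example(self):
        """115 kg / 185 cm / 122 bpm at 350 mg I/ml: 163 ml pre-calculated,
        capped at the 150 ml protocol maximum."""
        plan = calculate_dose(_patient(115, 185, 122))
        assert plan.raw_dose == 163
        assert plan.final_dose == 150
        assert not plan.diluted

    def test_round_bsa_case(self):
        plan = calculate_dose(_patient(80, 180, 60))  # 2.0 m² × 45, no corrections
        assert plan.raw_dose == 90
        assert plan.final_dose == 90

    def test_small_patient_hits_floor(self):
        plan = calculate_dose(_patient(50, 150, 50))  # 46.875 − 10 = 36.875 → 37 → 40
        assert plan.raw_dose == 37
        assert plan.final_dose == 40

    def test_concentration_lowers_dose(self):
        base = calculate_dose(_patient(80, 180, 60))
        high = calculate_dose(_patient(80, 180, 60), AgentSpec(370))
        assert high.final_dose == base.final_dose - 4

    @given(
        weight=st.floats(30, 200),
        height=st.floats(120, 220),
        hr=st.integers(30, 220),
        conc=st.floats(240, 400),
    )
    def test_plan_invariants(self, weight, height, hr, conc):
        cfg = CalculatorConfig()
        plan = calculate_dose(_patient(weight, height, hr), AgentSpec(conc), cfg)
        # audit identity
        assert plan.raw_dose_unrounded == pytest.approx(
            plan.base_dose + plan.hr_correction + plan.concentration_correction, abs=1e-9
        )
        assert plan.base_dose == pytest.approx(plan.bsa * cfg.dose_per_bsa)
        assert plan.raw_dose == round_half_up(plan.raw_dose_unrounded)
        assert cfg.min_dose <= plan.clamped_dose <= cfg.max_dose
        assert plan.final_dose == plan.clamped_dose
        diluted = apply_dilution(plan, cfg)
        assert cfg.dilution_floor <= diluted.final_dose <= round_half_up(
            cfg.max_dose * cfg.dilution_factor
        )
        assert diluted.clamped_dose == plan.clamped_dose  # audit record preserved

    @given(
        weight=st.floats(30, 199),
        height=st.floats(120, 219),
        hr=st.integers(30, 219),
        conc=st.floats(240, 399),
    )
    def test_raw_dose_monotonicity(self, weight, height, hr, conc):
        ref = calculate_dose(_patient(weight, height, hr), AgentSpec(conc)).raw_dose_unrounded
        heavier = calculate_dose(_patient(weight + 1, height, hr), AgentSpec(conc))
        taller = calculate_dose(_patient(weight, height + 1, hr), AgentSpec(conc))
        faster = calculate_dose(_patient(weight, height, hr + 1), AgentSpec(conc))
        denser = calculate_dose(_patient(weight, height, hr), AgentSpec(conc + 1))
        assert heavier.raw_dose_unrounded >= ref
        assert taller.raw_dose_unrounded >= ref
        assert faster.raw_dose_unrounded >= ref
        assert denser.raw_dose_unrounded <= ref


class TestDilution:
    @pytest.mark.parametrize("clamped_source, expected", [((50, 150, 50), 20)])
    def test_floor_case(self, clamped_source, expected):
        plan = calculate_dose(_patient(*clamped_source))  # clamps to 40
        assert plan.clamped_dose == 40
        assert apply_dilution(plan).final_dose == expected

    def test_half_of_maximum(self):
        plan = calculate_dose(_patient(115, 185, 122))  # clamps to 150
        assert apply_dilution(plan).final_dose == 75

    def test_half_ml_rounds_up(self):
        # 185 cm × 125.41 kg, 60 bpm → raw 145 ml; half of 145 rounds up to 73
        plan = calculate_dose(_patient(125.41, 185, 60))
        assert plan.clamped_dose == 145
        assert apply_dilution(plan).final_dose == 73

    def test_double_dilution_rejected(self):
        plan = apply_dilution(calculate_dose(_patient(80, 180, 60)))
        with pytest.raises(ValueError, match="already diluted"):
            apply_dilution(plan)


class TestValidation:
    def test_bad_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            PatientProfile(weight=80, height=180, heart_rate=60, group="placebo")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dilution_floor": 45.0},  # floor above the minimum dose
            {"dilution_factor": 1.5},
            {"min_dose": 200.0},
            {"hr_table": ((65, 0.0), (55, -10.0), (math.inf, 30.0))},  # not increasing
            {"hr_table": ((55, 10.0), (65, 0.0), (math.inf, 30.0))},  # decreasing corr
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CalculatorConfig(**kwargs)

    def test_standard_plan_is_fixed_dose(self, calc_config):
        plan = standard_plan(calc_config)
        assert plan.final_dose == 120
        assert plan.raw_dose == plan.clamped_dose == 120
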