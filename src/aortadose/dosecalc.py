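"""Contrast-agent dose calculation for CT aortography.

Implements the injector algorithm used in the study: body surface area
(BSA) times a fixed 45 ml/m² base dose, a piecewise-constant heart-rate
correction, a linear concentration correction around a 350 mg I/ml
reference, half-up rounding to whole millilitres, clamping to the
protocol window (40–150 ml), and an optional 50% dilution arm with a
20 ml floor.

Two readings of the BSA formula are supported:

``literal``
    BSA = (height_cm × weight_kg / 3600) × 0.5 — the formula exactly as
    the injector documentation prints it.  This reading reproduces the
    documented 163 ml worked example and is the default.
``mosteller``
    BSA = sqrt(height_cm × weight_kg / 3600) — the standard Mosteller
    estimate, equivalent to reading "× 0.5" as an exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import pandas as pd

__all__ = [
    "GROUPS",
    "PatientProfile",
    "AgentSpec",
    "CalculatorConfig",
    "DosePlan",
    "compute_bsa",
    "hr_correction",
    "concentration_correction",
    "calculate_dose",
    "apply_dilution",
    "standard_plan",
    "round_half_up",
    "run_batch",
]

GROUPS = ("standard", "calculator", "calculator_diluted")

#: Heart-rate bands as (inclusive upper bound in bpm, volume correction in ml).
#: 55 bpm falls in the −10 ml band so that the table is total over all rates.
DEFAULT_HR_TABLE: tuple[tuple[float, float], ...] = (
    (55, -10.0),
    (65, 0.0),
    (75, 10.0),
    (90, 20.0),
    (105, 25.0),
    (math.inf, 30.0),
)

INJECTION_RATE_ML_S = 4.0
SALINE_FLUSH_ML = 30.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (doses are positive)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PatientProfile:
    """One subject's body and circulatory parameters plus arm assignment."""

    weight: float  # kg
    height: float  # cm
    heart_rate: int  # bpm
    group: str = "calculator"
    sex: str = "male"  # metadata only
    age: float = 65.0  # years, metadata only
    pathology: str = "aneurysm"  # metadata only
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0 or self.heart_rate <= 0:
            raise ValueError(
                "weight, height and heart_rate must be strictly positive; got "
                f"weight={self.weight}, height={self.height}, heart_rate={self.heart_rate}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class AgentSpec:
    """Contrast agent stock, identified by iodine concentration in mg I/ml."""

    concentration: float = 350.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")


@dataclass(frozen=True)
class CalculatorConfig:
    """Tunables of the dose algorithm; defaults are the study protocol."""

    dose_per_bsa: float = 45.0  # ml per m²
    hr_table: tuple[tuple[float, float], ...] = DEFAULT_HR_TABLE
    reference_concentration: float = 350.0  # mg I/ml
    concentration_step: float = 2.0  # ml per 10 mg I/ml
    min_dose: float = 40.0  # ml
    max_dose: float = 150.0  # ml
    dilution_factor: float = 0.5
    dilution_floor: float = 20.0  # ml
    bsa_mode: Literal["literal", "mosteller"] = "literal"
    standard_dose: float = 120.0  # fixed dose of the control arm, ml

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.hr_table]
        corrections = [c for _, c in self.hr_table]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("hr_table bounds must be strictly increasing")
        if any(c2 < c1 for c1, c2 in zip(corrections, corrections[1:])):
            raise ValueError("hr_table corrections must be non-decreasing")
        if not math.isinf(bounds[-1]):
            raise ValueError("hr_table must end with an unbounded band")
        if not 0 < self.dilution_factor < 1:
            raise ValueError("dilution_factor must lie in (0, 1)")
        if self.dilution_floor >= self.min_dose:
            raise ValueError("dilution_floor must be below min_dose")
        if self.min_dose >= self.max_dose:
            raise ValueError("min_dose must be below max_dose")
        if self.bsa_mode not in ("literal", "mosteller"):
            raise ValueError(f"unknown bsa_mode {self.bsa_mode!r}")


@dataclass(frozen=True)
class DosePlan:
    """Full audit trail of one dose calculation."""

    bsa: float  # m²
    base_dose: float  # ml, = bsa × dose_per_bsa
    hr_correction: float  # ml
    concentration_correction: float  # ml
    raw_dose_unrounded: float  # ml, pre-clamp
    raw_dose: int  # ml, rounded half-up, pre-clamp
    clamped_dose: int  # ml, within [min_dose, max_dose]
    final_dose: int  # ml administered (diluted value for the dilution arm)
    diluted: bool = False
    injection_rate: float = INJECTION_RATE_ML_S  # ml/s
    saline_flush: float = SALINE_FLUSH_ML  # ml


def compute_bsa(weight: float, height: float, mode: str = "literal") -> float:
    """Body surface area in m² from weight (kg) and height (cm).

    ``literal`` applies (height × weight / 3600) × 0.5; ``mosteller``
    applies sqrt(height × weight / 3600).
    """
    if weight <= 0 or height <= 0:
        raise ValueError(f"weight and height must be positive, got {weight}, {height}")
    hw = height * weight / 3600.0
    if mode == "literal":
        return hw * 0.5
    if mode == "mosteller":
        return math.sqrt(hw)
    raise ValueError(f"unknown BSA mode {mode!r}")


def hr_correction(heart_rate: float, config: CalculatorConfig | None = None) -> float:
    """Volume correction (ml) for the given heart rate (bpm)."""
    if heart_rate <= 0:
        raise ValueError(f"heart_rate must be positive, got {heart_rate}")
    cfg = config or CalculatorConfig()
    for upper, correction in cfg.hr_table:
        if heart_rate <= upper:
            return correction
    raise AssertionError("hr_table has no unbounded band")  # unreachable by config invariant


def concentration_correction(
    concentration: float, config: CalculatorConfig | None = None
) -> float:
    """Volume correction (ml) for the agent's iodine concentration.

    +2 ml per 10 mg I/ml below the 350 mg I/ml reference, −2 ml per
    10 mg I/ml above it; non-multiples of 10 scale linearly.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    cfg = config or CalculatorConfig()
    return (cfg.reference_concentration - concentration) / 10.0 * cfg.concentration_step


def calculate_dose(
    patient: PatientProfile,
    agent: AgentSpec | None = None,
    config: CalculatorConfig | None = None,
) -> DosePlan:
    """Run the full dose algorithm for one patient, recording every term.

    base = BSA × 45 ml/m²; raw = base + HR correction + concentration
    correction; rounded half-up to whole ml; clamped to [40, 150] ml.
    The returned plan is undiluted; pass it to :func:`apply_dilution`
    for the dilution arm.
    """
    agent = agent or AgentSpec()
    cfg = config or CalculatorConfig()
    bsa = compute_bsa(patient.weight, patient.height, cfg.bsa_mode)
    base = bsa * cfg.dose_per_bsa
    hr_corr = hr_correction(patient.heart_rate, cfg)
    conc_corr = concentration_correction(agent.concentration, cfg)
    raw_unrounded = base + hr_corr + conc_corr
    raw = round_half_up(raw_unrounded)
    clamped = int(min(max(raw, cfg.min_dose), cfg.max_dose))
    return DosePlan(
        bsa=bsa,
        base_dose=base,
        hr_correction=hr_corr,
        concentration_correction=conc_corr,
        raw_dose_unrounded=raw_unrounded,
        raw_dose=raw,
        clamped_dose=clamped,
        final_dose=clamped,
        diluted=False,
    )


def apply_dilution(plan: DosePlan, config: CalculatorConfig | None = None) -> DosePlan:
    """50% dilution arm: halve the clamped dose, floor at 20 ml.

    The clamped (undiluted) dose stays in the record for audit.
    """
    cfg = config or CalculatorConfig()
    if plan.diluted:
        raise ValueError("plan is already diluted; dilution may be applied only once")
    if not cfg.min_dose <= plan.final_dose <= cfg.max_dose:
        raise ValueError(
            f"final_dose {plan.final_dose} outside [{cfg.min_dose}, {cfg.max_dose}]"
        )
    diluted = max(round_half_up(plan.clamped_dose * cfg.dilution_factor), int(cfg.dilution_floor))
    return replace(plan, final_dose=diluted, diluted=True)


def standard_plan(config: CalculatorConfig | None = None) -> DosePlan:
    """Fixed-dose control arm: every patient receives the standard 120 ml."""
    cfg = config or CalculatorConfig()
    dose = int(cfg.standard_dose)
    return DosePlan(
        bsa=float("nan"),
        base_dose=cfg.standard_dose,
        hr_correction=0.0,
        concentration_correction=0.0,
        raw_dose_unrounded=cfg.standard_dose,
        raw_dose=dose,
        clamped_dose=dose,
        final_dose=dose,
        diluted=False,
    )


def plan_for(
    patient: PatientProfile,
    agent: AgentSpec | None = None,
    config: CalculatorConfig | None = None,
) -> DosePlan:
    """Dose plan appropriate to the patient's study arm."""
    cfg = config or CalculatorConfig()
    if patient.group == "standard":
        return standard_plan(cfg)
    plan = calculate_dose(patient, agent, cfg)
    if patient.group == "calculator_diluted":
        plan = apply_dilution(plan, cfg)
    return plan


BATCH_COLUMNS = ["id", "weight_kg", "height_cm", "heart_rate_bpm", "concentration_mgI_ml", "group"]


def run_batch(
    patients: pd.DataFrame, config: CalculatorConfig | None = None
) -> pd.DataFrame:
    """Vector the calculator over a patient table.

    Expects the batch CSV schema (columns ``id, weight_kg, height_cm,
    heart_rate_bpm, concentration_mgI_ml, group``) and returns the input
    plus one column per :class:`DosePlan` field.
    """
    cfg = config or CalculatorConfig()
    missing = [c for c in BATCH_COLUMNS if c not in patients.columns]
    if missing:
        raise ValueError(f"patient table is missing columns: {missing}")
    rows = []
    for rec in patients.itertuples(index=False):
        patient = PatientProfile(
            weight=rec.weight_kg,
            height=rec.height_cm,
            heart_rate=int(rec.heart_rate_bpm),
            group=rec.group,
            patient_id=str(rec.id),
        )
        plan = plan_for(patient, AgentSpec(rec.concentration_mgI_ml), cfg)
        rows.append(
            {
                "bsa_m2": plan.bsa,
                "base_dose_ml": plan.base_dose,
                "hr_correction_ml": plan.hr_correction,
                "concentration_correction_ml": plan.concentration_correction,
                "raw_dose_unrounded_ml": plan.raw_dose_unrounded,
                "raw_dose_ml": plan.raw_dose,
                "clamped_dose_ml": plan.clamped_dose,
                "final_dose_ml": plan.final_dose,
                "diluted": plan.diluted,
            }
        )
    return pd.concat([patients.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
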