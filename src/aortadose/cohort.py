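"""Synthetic study cohorts.

The real patient data are clinical records that are not deposited, so
study arms are emulated by sampling each demographic attribute from a
normal distribution truncated to the published minimum–maximum range.
Defaults reproduce the three arms' published demographics (weight,
height, heart rate; mean ± SD with range), sampled independently unless
a weight–height correlation is requested.

Sampling is inverse-CDF (uniform draws mapped through the truncated
normal quantile function), so a fixed seed gives the same cohort on
every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dosecalc import GROUPS, PatientProfile

__all__ = [
    "TruncatedNormalSpec",
    "GroupDemographics",
    "DEFAULT_DEMOGRAPHICS",
    "sample_cohort",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Mean/SD of the parent normal plus hard truncation bounds."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if not self.minimum < self.mean < self.maximum:
            raise ValueError(
                f"need minimum < mean < maximum, got {self.minimum}, {self.mean}, {self.maximum}"
            )

    @property
    def _ab(self) -> tuple[float, float]:
        return (self.minimum - self.mean) / self.sd, (self.maximum - self.mean) / self.sd

    def ppf(self, q: np.ndarray) -> np.ndarray:
        # sd == 0 degenerates to a point mass at the mean (zero-noise runs)
        if self.sd == 0:
            return np.full_like(np.asarray(q, dtype=float), self.mean)
        a, b = self._ab
        return stats.truncnorm.ppf(q, a, b, loc=self.mean, scale=self.sd)

    def theoretical_mean(self) -> float:
        """Mean of the truncated distribution (not the parent normal)."""
        if self.sd == 0:
            return self.mean
        a, b = self._ab
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def theoretical_sd(self) -> float:
        if self.sd == 0:
            return 0.0
        a, b = self._ab
        return float(stats.truncnorm.std(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class GroupDemographics:
    """Published marginals of one study arm."""

    group: str
    n: int
    weight: TruncatedNormalSpec  # kg
    height: TruncatedNormalSpec  # cm
    heart_rate: TruncatedNormalSpec  # bpm
    sex_ratio: float = 0.75  # fraction male
    pathology_mix: tuple[float, float, float] = (0.5, 0.5, 0.0)  # aneurysm/dissection/other
    age: TruncatedNormalSpec = field(
        default=TruncatedNormalSpec(65.0, 14.0, 22.0, 87.0)
    )
    weight_height_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for attr in ("weight", "height", "heart_rate"):
            if getattr(self, attr).sd == 0:
                raise ValueError(f"{attr} sd must be strictly positive for a cohort")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if abs(sum(self.pathology_mix) - 1) > 1e-9:
            raise ValueError("pathology_mix fractions must sum to 1")
        if not -1 < self.weight_height_correlation < 1:
            raise ValueError("weight_height_correlation must lie in (-1, 1)")


# Published per-arm demographics: mean ± SD (min–max); sex 11/9, 15/5, 15/5;
# pathology aneurysm/dissection/other 9/10/1, 11/9/0, 10/10/0.
DEFAULT_DEMOGRAPHICS: dict[str, GroupDemographics] = {
    "standard": GroupDemographics(
        group="standard",
        n=20,
        weight=TruncatedNormalSpec(74.6, 15.0, 50.0, 105.0),
        height=TruncatedNormalSpec(167.9, 10.0, 150.0, 186.0),
        heart_rate=TruncatedNormalSpec(66.8, 15.6, 39.0, 95.0),
        sex_ratio=11 / 20,
        pathology_mix=(9 / 20, 10 / 20, 1 / 20),
        age=TruncatedNormalSpec(65.8, 16.8, 22.0, 87.0),
    ),
    "calculator": GroupDemographics(
        group="calculator",
        n=20,
        weight=TruncatedNormalSpec(82.6, 14.0, 50.0, 115.0),
        height=TruncatedNormalSpec(172.7, 8.2, 154.0, 187.0),
        heart_rate=TruncatedNormalSpec(72.9, 18.4, 51.0, 122.0),
        sex_ratio=15 / 20,
        pathology_mix=(11 / 20, 9 / 20, 0.0),
        age=TruncatedNormalSpec(66.6, 8.7, 52.0, 82.0),
    ),
    "calculator_diluted": GroupDemographics(
        group="calculator_diluted",
        n=20,
        weight=TruncatedNormalSpec(79.9, 14.3, 60.0, 109.0),
        height=TruncatedNormalSpec(172.1, 11.0, 152.0, 186.0),
        heart_rate=TruncatedNormalSpec(66.7, 18.5, 49.0, 127.0),
        sex_ratio=15 / 20,
        pathology_mix=(10 / 20, 10 / 20, 0.0),
        age=TruncatedNormalSpec(64.1, 14.3, 25.0, 84.0),
    ),
}

_PATHOLOGIES = ("aneurysm", "dissection", "other")


def sample_cohort(
    demographics: GroupDemographics, seed: int, n: int | None = None
) -> list[PatientProfile]:
    """Draw one synthetic study arm.

    Continuous attributes come from independent truncated normals
    (inverse-CDF of uniforms); an optional weight–height Gaussian copula
    correlation can be switched on.  Heart rate is rounded to a whole
    bpm.  The draw is fully determined by ``seed``.
    """
    n = demographics.n if n is None else n
    rng = np.random.default_rng(seed)
    rho = demographics.weight_height_correlation
    if rho != 0.0:
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n, method="cholesky"
        )
        u_w, u_h = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    else:
        u_w, u_h = rng.uniform(size=n), rng.uniform(size=n)
    weights = demographics.weight.ppf(u_w)
    heights = demographics.height.ppf(u_h)
    rates = np.rint(demographics.heart_rate.ppf(rng.uniform(size=n))).astype(int)
    ages = demographics.age.ppf(rng.uniform(size=n))
    male = rng.uniform(size=n) < demographics.sex_ratio
    pathology = rng.choice(_PATHOLOGIES, size=n, p=list(demographics.pathology_mix))
    return [
        PatientProfile(
            weight=float(weights[i]),
            height=float(heights[i]),
            heart_rate=int(rates[i]),
            group=demographics.group,
            sex="male" if male[i] else "female",
            age=float(ages[i]),
            pathology=str(pathology[i]),
            patient_id=f"{demographics.group}-{i + 1:03d}",
        )
        for i in range(n)
    ]


def cohort_to_frame(
    patients: list[PatientProfile], concentration: float = 350.0
) -> pd.DataFrame:
    """Cohort as the batch CSV schema the dose calculator consumes."""
    return pd.DataFrame(
        {
            "id": [p.patient_id for p in patients],
            "weight_kg": [p.weight for p in patients],
            "height_cm": [p.height for p in patients],
            "heart_rate_bpm": [p.heart_rate for p in patients],
            "concentration_mgI_ml": concentration,
            "group": [p.group for p in patients],
            "sex": [p.sex for p in patients],
            "age": [p.age for p in patients],
            "pathology": [p.pathology for p in patients],
        }
    )
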