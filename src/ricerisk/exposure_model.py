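"""Deterministic dose and risk equations for dietary exposure to a food contaminant.

The model is the standard chronic-intake chain used in regulatory risk
assessment of a carcinogen in a staple food, stratified by age group ``j``:

.. math::

    \\mathrm{ADD}_j = \\frac{C \\times IR_j \\times ED_j \\times EF_j}{BW_j \\times AT_j},
    \\qquad AT_j = ED_j \\times 365

where ``C`` is the contaminant concentration in the raw food (mg/g),
``IR_j`` the ingestion rate (g/day), ``ED_j`` the exposure duration (years),
``EF_j`` the exposure frequency (days/year) and ``BW_j`` the body weight (kg).
Because the averaging time is defined as ``ED_j * 365`` days, the exposure
duration cancels and the dose depends only on ``IR``, ``EF`` and ``BW``.

Lifetime risk metrics weight each age group by its share of the lifetime ``LT``:

.. math::

    \\mathrm{ILCR} = \\sum_j \\mathrm{ADD}_j \\times SF \\times \\frac{ED_j}{LT},
    \\qquad
    \\mathrm{HQ} = \\sum_j \\frac{\\mathrm{ADD}_j}{RfD} \\times \\frac{ED_j}{LT}

with ``SF`` the oral cancer slope factor and ``RfD`` the oral reference dose.
For a fixed concentration these two sums satisfy the algebraic identity
``ILCR == HQ * SF * RfD`` exactly; the implementation preserves it to
floating-point precision.

Concentration datasets are carried in ng/g; the single ng/g -> mg/g
conversion lives in :data:`NG_PER_G_TO_MG_PER_G` and is applied only inside
:func:`add_coefficient`, so the unit change has exactly one auditable locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: ng/g -> mg/g; the only place concentration units are converted.
NG_PER_G_TO_MG_PER_G = 1e-6

DAYS_PER_YEAR = 365.0

#: Columns of the exposure-table CSV interface, in order.
EXPOSURE_CSV_COLUMNS = [
    "label",
    "age_start",
    "age_end",
    "exposure_duration",
    "ingestion_rate_g_day",
    "body_weight_kg",
    "exposure_frequency_d_yr",
]


@dataclass(frozen=True)
class RiskConstants:
    """Toxicological constants for oral exposure to inorganic arsenic.

    Parameters
    ----------
    slope_factor : float
        Cancer potency, per (mg/kg-day). Default 1.5 (oral iAs).
    reference_dose : float
        Chronic oral reference dose, mg/kg-day. Default 0.003 (oral iAs).
    lifetime_years : float
        Lifetime over which age-group risks are averaged. Default 70.
    """

    slope_factor: float = 1.5
    reference_dose: float = 0.003
    lifetime_years: float = 70.0

    def __post_init__(self) -> None:
        for name in ("slope_factor", "reference_dose", "lifetime_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RiskConstants.{name} must be strictly positive")


@dataclass(frozen=True)
class AgeGroupExposure:
    """Exposure factors for one age bin.

    ``exposure_duration`` must equal ``age_end - age_start``; the averaging
    time ``AT = exposure_duration * 365`` days is derived, never stored.
    """

    label: str
    age_start: float
    age_end: float
    exposure_duration: float
    ingestion_rate: float  # g raw rice / day
    body_weight: float  # kg
    exposure_frequency: float  # days / year

    def __post_init__(self) -> None:
        if self.exposure_duration <= 0:
            raise ValueError(f"{self.label!r}: exposure_duration must be > 0")
        if abs(self.exposure_duration - (self.age_end - self.age_start)) > 1e-9:
            raise ValueError(
                f"{self.label!r}: exposure_duration must equal age_end - age_start"
            )
        if not 0.0 <= self.exposure_frequency <= DAYS_PER_YEAR:
            raise ValueError(f"{self.label!r}: exposure_frequency must be in [0, 365]")
        if self.ingestion_rate < 0:
            raise ValueError(f"{self.label!r}: ingestion_rate must be >= 0")
        if self.body_weight <= 0:
            raise ValueError(f"{self.label!r}: body_weight must be > 0")


@dataclass(frozen=True)
class ExposureTable:
    """Ordered, contiguous set of age bins covering the exposed lifetime."""

    groups: tuple[AgeGroupExposure, ...]

    def __init__(self, groups: Iterable[AgeGroupExposure]):
        object.__setattr__(self, "groups", tuple(groups))
        prev_end = None
        for g in self.groups:
            if prev_end is not None and abs(g.age_start - prev_end) > 1e-9:
                raise ValueError(
                    f"age bins must be contiguous: {g.label!r} starts at "
                    f"{g.age_start}, previous bin ends at {prev_end}"
                )
            prev_end = g.age_end

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    @property
    def total_duration(self) -> float:
        """Sum of exposure durations across bins, in years."""
        return sum(g.exposure_duration for g in self.groups)

    def validate_against(self, constants: RiskConstants) -> None:
        """Check the table does not exceed the lifetime it will be averaged over."""
        if self.total_duration > constants.lifetime_years + 1e-9:
            raise ValueError(
                f"total exposure duration {self.total_duration:.3f} y exceeds "
                f"lifetime {constants.lifetime_years} y"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [g.label for g in self.groups],
                "age_start": [g.age_start for g in self.groups],
                "age_end": [g.age_end for g in self.groups],
                "exposure_duration": [g.exposure_duration for g in self.groups],
                "ingestion_rate_g_day": [g.ingestion_rate for g in self.groups],
                "body_weight_kg": [g.body_weight for g in self.groups],
                "exposure_frequency_d_yr": [g.exposure_frequency for g in self.groups],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExposureTable":
        missing = set(EXPOSURE_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"exposure table missing columns: {sorted(missing)}")
        groups = [
            AgeGroupExposure(
                label=str(row.label),
                age_start=float(row.age_start),
                age_end=float(row.age_end),
                exposure_duration=float(row.exposure_duration),
                ingestion_rate=float(row.ingestion_rate_g_day),
                body_weight=float(row.body_weight_kg),
                exposure_frequency=float(row.exposure_frequency_d_yr),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(groups)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExposureTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class AgeDose:
    """Average daily dose for one age group, mg contaminant per kg-bw per day."""

    label: str
    add: float

    def __post_init__(self) -> None:
        if self.add < 0:
            raise ValueError("average daily dose must be >= 0")


def add_coefficient(group: AgeGroupExposure) -> float:
    """Dose per unit concentration, (mg/kg-day) per (ng/g).

    The exposure duration cancels against the averaging time
    ``AT = ED * 365`` and therefore does not appear. Multiplying by a
    concentration in ng/g yields the ADD in mg/kg-day; the Monte Carlo
    engine applies this same coefficient to whole draw vectors.
    """
    return (
        NG_PER_G_TO_MG_PER_G
        * group.ingestion_rate
        * group.exposure_frequency
        / (group.body_weight * DAYS_PER_YEAR)
    )


def compute_add(concentration_ng_g: float, group: AgeGroupExposure) -> AgeDose:
    """Average daily dose for one age group at a fixed concentration.

    Parameters
    ----------
    concentration_ng_g : float
        Contaminant concentration in the raw food, ng/g. Must be >= 0.
    group : AgeGroupExposure
        Exposure factors of the age bin.

    Returns
    -------
    AgeDose
        Dose in mg/kg-day.
    """
    if concentration_ng_g < 0:
        raise ValueError("concentration must be >= 0 ng/g")
    return AgeDose(label=group.label, add=concentration_ng_g * add_coefficient(group))


def cancer_risk_term(
    dose: AgeDose, group: AgeGroupExposure, constants: RiskConstants
) -> float:
    """Incremental cancer-risk contribution of one age group.

    ``ADD_j * SF * ED_j / LT`` — the group's dose scaled by cancer potency
    and weighted by its share of the lifetime.
    """
    return (
        dose.add
        * constants.slope_factor
        * group.exposure_duration
        / constants.lifetime_years
    )


def hq_term(dose: AgeDose, group: AgeGroupExposure, constants: RiskConstants) -> float:
    """Fractional hazard quotient of one age group: ``(ADD_j / RfD) * ED_j / LT``."""
    return (
        dose.add
        / constants.reference_dose
        * group.exposure_duration
        / constants.lifetime_years
    )


def lifetime_totals(
    terms_by_group: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Sum per-group (cancer term, HQ term) pairs into lifetime (ILCR, HQ).

    An empty sequence returns ``(0.0, 0.0)``. For terms computed from a
    single fixed concentration the outputs satisfy
    ``ILCR == HQ * SF * RfD`` exactly.
    """
    ilcr = float(sum(t[0] for t in terms_by_group))
    hq = float(sum(t[1] for t in terms_by_group))
    return ilcr, hq
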