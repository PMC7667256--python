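"""Resource-use costing for the two surgical arms.

Turns per-patient resource use (operating-room minutes, consumables,
intensive-care days, postoperative imaging, ward days) into 2018 euros from
a hospital perspective, with the intraoperative-MR device cost amortized
over its life cycle and yearly case volume.  No discounting is applied: the
analysis horizon is one year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MODALITIES",
    "DEFAULT_IMAGE_COSTS",
    "DEFAULT_UNIT_COSTS",
    "UnitCosts",
    "CostBreakdown",
    "amortized_device_cost",
    "patient_cost",
    "arm_cost_summary",
    "expected_breakdown",
]

#: Imaging modalities tracked per patient (pre- and postoperative counts).
MODALITIES = ("MR-C", "MR", "PET", "XRay", "PortableXRay", "SPECT", "CT")

DEFAULT_IMAGE_COSTS: Mapping[str, float] = {
    "MR-C": 203.0,          # MR with contrast
    "MR": 138.0,
    "PET": 566.0,
    "XRay": 15.0,
    "PortableXRay": 32.0,
    "SPECT": 166.0,
    "CT": 72.0,
}


def amortized_device_cost(
    total: float, life_years: float, interventions_per_year: float
) -> float:
    """Per-intervention cost of a capital device.

    The device purchase price is spread uniformly over its life cycle and
    the yearly number of interventions that benefit from it::

        total / (life_years * interventions_per_year)

    With the defaults (1,000,000 EUR, 10 years, 120 interventions/year)
    this is 833.33 EUR per intervention.
    """
    if life_years <= 0:
        raise ValueError(f"life_years must be > 0, got {life_years}")
    if interventions_per_year <= 0:
        raise ValueError(
            f"interventions_per_year must be > 0, got {interventions_per_year}"
        )
    if total < 0:
        raise ValueError(f"device total must be >= 0, got {total}")
    return total / (life_years * interventions_per_year)


@dataclass(frozen=True)
class UnitCosts:
    """Fixed per-unit prices (EUR, 2018) plus device amortization inputs."""

    or_minute: float = 5.0
    surgical_pack: float = 1_150.0
    navigation: float = 862.0
    prosthesis: float = 272.0
    icu_day: float = 555.0
    hospital_day: float = 422.0
    image_costs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMAGE_COSTS)
    )
    device_total: float = 1_000_000.0
    device_life_years: float = 10.0
    device_interventions_per_year: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "or_minute",
            "surgical_pack",
            "navigation",
            "prosthesis",
            "icu_day",
            "hospital_day",
            "device_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.device_life_years <= 0 or self.device_interventions_per_year <= 0:
            raise ValueError("device amortization inputs must be > 0")
        missing = set(MODALITIES) - set(self.image_costs)
        if missing:
            raise ValueError(f"image_costs missing modalities: {sorted(missing)}")
        if any(self.image_costs[m] < 0 for m in MODALITIES):
            raise ValueError("image costs must be >= 0")

    @property
    def device_per_intervention(self) -> float:
        return amortized_device_cost(
            self.device_total,
            self.device_life_years,
            self.device_interventions_per_year,
        )

    def scaled(self, k: float) -> "UnitCosts":
        """All prices multiplied by ``k`` (amortization horizon unchanged)."""
        return UnitCosts(
            or_minute=self.or_minute * k,
            surgical_pack=self.surgical_pack * k,
            navigation=self.navigation * k,
            prosthesis=self.prosthesis * k,
            icu_day=self.icu_day * k,
            hospital_day=self.hospital_day * k,
            image_costs={m: c * k for m, c in self.image_costs.items()},
            device_total=self.device_total * k,
            device_life_years=self.device_life_years,
            device_interventions_per_year=self.device_interventions_per_year,
        )


DEFAULT_UNIT_COSTS = UnitCosts()


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient (or per-arm mean) cost by category, EUR."""

    operating_room: float
    icu: float
    imaging: float
    hospitalization: float
    residual: float

    @property
    def total(self) -> float:
        return (
            self.operating_room
            + self.icu
            + self.imaging
            + self.hospitalization
            + self.residual
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "operating_room": self.operating_room,
            "icu": self.icu,
            "imaging": self.imaging,
            "hospitalization": self.hospitalization,
            "residual": self.residual,
            "total": self.total,
        }


def patient_cost(patient, costs: UnitCosts, residual: float = 0.0) -> CostBreakdown:
    """Cost breakdown of a single patient record.

    The operating-room category carries surgical time, the surgical pack,
    navigation, prosthesis and the amortized device cost when each was used.
    The imaging category prices postoperative images only; preoperative
    counts stay in the record but are reported separately.  ``residual`` is
    the per-arm unattributed cost constant added verbatim.
    """
    if patient.or_minutes < 0 or patient.icu_days < 0 or patient.los_days < 0:
        raise ValueError("resource quantities must be >= 0")
    operating_room = patient.or_minutes * costs.or_minute
    if patient.used_pack:
        operating_room += costs.surgical_pack
    if patient.used_navigation:
        operating_room += costs.navigation
    if patient.used_prosthesis:
        operating_room += costs.prosthesis
    if patient.used_device:
        operating_room += costs.device_per_intervention
    icu = patient.icu_days * costs.icu_day
    imaging = 0.0
    for m in MODALITIES:
        count = patient.images_post.get(m, 0)
        if count < 0:
            raise ValueError(f"negative image count for {m}")
        imaging += count * costs.image_costs[m]
    hospitalization = patient.los_days * costs.hospital_day
    return CostBreakdown(operating_room, icu, imaging, hospitalization, residual)


def arm_cost_summary(
    cohort: Iterable, costs: UnitCosts, residual: float = 0.0
) -> CostBreakdown:
    """Per-patient mean cost breakdown over a cohort (linear in unit costs)."""
    breakdowns = [patient_cost(p, costs, residual) for p in cohort]
    if not breakdowns:
        raise ValueError("cohort is empty")
    n = len(breakdowns)
    return CostBreakdown(
        operating_room=sum(b.operating_room for b in breakdowns) / n,
        icu=sum(b.icu for b in breakdowns) / n,
        imaging=sum(b.imaging for b in breakdowns) / n,
        hospitalization=sum(b.hospitalization for b in breakdowns) / n,
        residual=residual,
    )


def expected_breakdown(
    *,
    or_minutes,
    prob_pack,
    prob_navigation,
    prob_prosthesis,
    prob_device,
    prob_icu,
    icu_days_given_admitted,
    image_post_means: Mapping[str, object],
    los_days,
    costs: UnitCosts | None = None,
    device_per_intervention=None,
    unit_or_minute=None,
    unit_pack=None,
    unit_navigation=None,
    unit_prosthesis=None,
    unit_icu_day=None,
    unit_hospital_day=None,
    unit_image_costs: Mapping[str, object] | None = None,
    residual=0.0,
) -> CostBreakdown:
    """Expected per-patient cost from arm-level mean resource use.

    This is the deterministic arm-mean counterpart of :func:`patient_cost`:
    every Bernoulli usage enters with its probability, the ICU category is
    ``prob_icu * days_given_admitted * icu_day``, and imaging prices the
    postoperative mean counts.  All arguments accept numpy arrays, which is
    how the probabilistic sensitivity analysis evaluates the model over a
    vector of parameter draws; unit-price keyword overrides let sampled
    prices replace the fixed :class:`UnitCosts` values element-wise.
    """
    c = costs if costs is not None else DEFAULT_UNIT_COSTS

    def pick(override, default):
        return default if override is None else override

    or_rate = pick(unit_or_minute, c.or_minute)
    pack = pick(unit_pack, c.surgical_pack)
    nav = pick(unit_navigation, c.navigation)
    pros = pick(unit_prosthesis, c.prosthesis)
    icu_rate = pick(unit_icu_day, c.icu_day)
    hosp_rate = pick(unit_hospital_day, c.hospital_day)
    device = pick(device_per_intervention, c.device_per_intervention)

    operating_room = (
        np.asarray(or_minutes) * or_rate
        + prob_pack * pack
        + prob_navigation * nav
        + prob_prosthesis * pros
        + prob_device * device
    )
    icu = np.asarray(prob_icu) * icu_days_given_admitted * icu_rate
    imaging = 0.0
    for m in MODALITIES:
        mean = image_post_means.get(m, 0.0)
        price = (
            unit_image_costs[m]
            if unit_image_costs is not None and m in unit_image_costs
            else c.image_costs[m]
        )
        imaging = imaging + np.asarray(mean) * price
    hospitalization = np.asarray(los_days) * hosp_rate
    return CostBreakdown(operating_room, icu, imaging, hospitalization, residual)
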