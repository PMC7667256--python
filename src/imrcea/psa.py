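"""Probabilistic sensitivity analysis (PSA) by Monte Carlo simulation.

Second-order uncertainty propagation: every varied model parameter receives
a probability distribution chosen by its nature — Gamma (moment-matched to
the published mean and SD) for times, counts, lengths of stay, costs and
effectiveness means; Beta for proportions, parameterized from the published
event counts or moment-matched where only mean and SD are given; a 20%
coefficient of variation where no SD is printed.  Parameters marked "not
varied" (surgical pack, navigation and device usage) stay fixed, and all
parameters are sampled independently.

Each draw rebuilds both arms' expected per-patient cost through the costing
model and each endpoint's effectiveness value, yielding one point
(delta effect, delta cost) on the cost-effectiveness plane per endpoint.
The south-east quadrant (more effective, less costly) is the region where
the intervention dominates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cea import ENDPOINTS, EffectParam, printed_base_case
from .cohorts import ArmProfile, default_profiles
from .costing import (
    MODALITIES,
    UnitCosts,
    amortized_device_cost,
    expected_breakdown,
)

__all__ = [
    "ParamDistribution",
    "PSAModel",
    "PSAConfig",
    "PSAResult",
    "fit_gamma",
    "fit_beta",
    "fit_beta_moments",
    "default_distributions",
    "run_psa",
    "deterministic_base",
    "quadrant_proportions",
    "export_ce_plane",
]

#: Default coefficient of variation for parameters with no printed SD.
DEFAULT_CV = 0.20


def fit_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Gamma (shape, scale): shape=(m/s)^2, scale=s^2/m."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moment matching requires mean > 0 and sd > 0")
    return (mean / sd) ** 2, sd**2 / mean


def fit_beta(events: float, non_events: float) -> tuple[float, float]:
    """Beta from observed counts (conjugate convention alpha=events)."""
    if events <= 0 or non_events <= 0:
        raise ValueError("beta requires positive event and non-event counts")
    return float(events), float(non_events)


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta moment-matched to a (mean, sd) on the [0, 1] scale."""
    if not 0 < mean < 1:
        raise ValueError("beta mean must be in (0, 1)")
    if sd <= 0 or sd**2 >= mean * (1 - mean):
        raise ValueError("beta sd must satisfy 0 < sd^2 < mean*(1-mean)")
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


@dataclass(frozen=True)
class ParamDistribution:
    """One varied (or fixed) model parameter and its sampling distribution."""

    name: str
    family: str  # "gamma" | "beta" | "fixed"
    mean: float | None = None
    sd: float | None = None
    alpha: float | None = None
    beta: float | None = None
    value: float | None = None

    @classmethod
    def gamma(cls, name: str, mean: float, sd: float) -> "ParamDistribution":
        if sd == 0.0 or mean == 0.0:  # zero-variance limit collapses to fixed
            return cls.fixed(name, mean)
        return cls(name, "gamma", mean=mean, sd=sd)

    @classmethod
    def beta_counts(cls, name: str, events: float, non_events: float) -> "ParamDistribution":
        a, b = fit_beta(events, non_events)
        return cls(name, "beta", alpha=a, beta=b)

    @classmethod
    def beta_moments(cls, name: str, mean: float, sd: float) -> "ParamDistribution":
        a, b = fit_beta_moments(mean, sd)
        return cls(name, "beta", alpha=a, beta=b)

    @classmethod
    def fixed(cls, name: str, value: float) -> "ParamDistribution":
        return cls(name, "fixed", value=float(value))

    @property
    def base_value(self) -> float:
        """The distribution's mean (the deterministic base-case value)."""
        if self.family == "gamma":
            return float(self.mean)
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta)
        return float(self.value)

    def as_fixed(self) -> "ParamDistribution":
        return ParamDistribution.fixed(self.name, self.base_value)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "gamma":
            shape, scale = fit_gamma(self.mean, self.sd)
            return rng.gamma(shape, scale, size=n)
        if self.family == "beta":
            return rng.beta(self.alpha, self.beta, size=n)
        if self.family == "fixed":
            return np.full(n, self.value)
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class PSAModel:
    """Arm profiles, unit prices and effectiveness parameters for the PSA."""

    conventional: ArmProfile
    lf_imr: ArmProfile
    unit_costs: UnitCosts
    effects: dict[str, dict[str, EffectParam]]
    device_sd: float = 200_000.0

    @classmethod
    def default(cls) -> "PSAModel":
        conv, imr = default_profiles()
        base = printed_base_case()
        return cls(
            conventional=conv,
            lf_imr=imr,
            unit_costs=UnitCosts(),
            effects=base.effects,
            device_sd=base.device_sd,
        )

    @property
    def profiles(self) -> dict[str, ArmProfile]:
        return {"conventional": self.conventional, "lf_imr": self.lf_imr}


@dataclass
class PSAConfig:
    n_draws: int = 10_000
    seed: int = 0
    cv: float = DEFAULT_CV
    #: optional full override of the distribution set (name -> distribution)
    distributions: dict[str, ParamDistribution] | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def default_distributions(
    model: PSAModel, cv: float = DEFAULT_CV
) -> dict[str, ParamDistribution]:
    """The published distribution assignments for every model parameter.

    Gamma for times, stays, image counts, unit prices and effectiveness
    means; Beta from counts for proportions; fixed for "not varied"
    parameters.  ICU days among admitted and all unit prices carry the
    ``cv`` coefficient of variation, having no printed SD.
    """
    dists: dict[str, ParamDistribution] = {}

    def add(d: ParamDistribution) -> None:
        dists[d.name] = d

    c = model.unit_costs
    for name, price in (
        ("unit.or_minute", c.or_minute),
        ("unit.surgical_pack", c.surgical_pack),
        ("unit.navigation", c.navigation),
        ("unit.prosthesis", c.prosthesis),
        ("unit.icu_day", c.icu_day),
        ("unit.hospital_day", c.hospital_day),
    ):
        add(ParamDistribution.gamma(name, price, cv * price))
    for m in MODALITIES:
        price = c.image_costs[m]
        add(ParamDistribution.gamma(f"unit.image.{m}", price, cv * price))
    add(ParamDistribution.gamma("device_total", c.device_total, model.device_sd))

    for arm, profile in model.profiles.items():
        add(ParamDistribution.gamma(f"{arm}.or_minutes", *profile.or_minutes))
        events = round(profile.prob_prosthesis * profile.n)
        if 0 < events < profile.n:
            add(ParamDistribution.beta_counts(
                f"{arm}.prob_prosthesis", events, profile.n - events))
        else:
            add(ParamDistribution.fixed(f"{arm}.prob_prosthesis",
                                        profile.prob_prosthesis))
        events = round(profile.prob_icu * profile.n)
        if 0 < events < profile.n:
            add(ParamDistribution.beta_counts(
                f"{arm}.prob_icu", events, profile.n - events))
        else:
            add(ParamDistribution.fixed(f"{arm}.prob_icu", profile.prob_icu))
        add(ParamDistribution.gamma(
            f"{arm}.icu_days",
            profile.icu_days_given_admitted,
            cv * profile.icu_days_given_admitted,
        ))
        for m in MODALITIES:
            mean, sd = profile.image_rates_post.get(m, (0.0, 0.0))
            add(ParamDistribution.gamma(f"{arm}.image_post.{m}", mean, sd))
        add(ParamDistribution.gamma(f"{arm}.los", *profile.los))

    for ep in ENDPOINTS:
        for arm in ("conventional", "lf_imr"):
            p = model.effects[ep][arm]
            name = f"{arm}.effect.{ep}"
            if ep == "rkps":
                add(ParamDistribution.beta_moments(name, p.value / 100.0, p.sd / 100.0))
            else:
                add(ParamDistribution.gamma(name, p.value, p.sd))
    return dists


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo cloud of (delta effect, delta cost) pairs per endpoint."""

    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_effect: Mapping[str, np.ndarray]
    quadrants: Mapping[str, dict[str, float]]  # endpoint -> {NE,SE,SW,NW}
    summary: dict

    def __eq__(self, other) -> bool:  # value equality for determinism checks
        if not isinstance(other, PSAResult):
            return NotImplemented
        return (
            self.n_draws == other.n_draws
            and self.seed == other.seed
            and np.array_equal(self.delta_cost, other.delta_cost)
            and set(self.delta_effect) == set(other.delta_effect)
            and all(
                np.array_equal(self.delta_effect[k], other.delta_effect[k])
                for k in self.delta_effect
            )
            and self.quadrants == other.quadrants
            and self.summary == other.summary
        )


def quadrant_proportions(
    delta_effect: Sequence[float], delta_cost: Sequence[float]
) -> dict[str, float]:
    """Fractions of draws per cost-effectiveness-plane quadrant.

    NE = (+effect, +cost), SE = (+effect, -cost; dominant), SW = (-, -),
    NW = (-effect, +cost).  Exact-zero deltas count on the positive side.
    """
    de = np.asarray(delta_effect, dtype=float)
    dc = np.asarray(delta_cost, dtype=float)
    if de.size == 0 or de.shape != dc.shape:
        raise ValueError("delta arrays must be non-empty and equal-length")
    e_pos = de >= 0
    c_pos = dc >= 0
    n = de.size
    return {
        "NE": float(np.sum(e_pos & c_pos)) / n,
        "SE": float(np.sum(e_pos & ~c_pos)) / n,
        "SW": float(np.sum(~e_pos & ~c_pos)) / n,
        "NW": float(np.sum(~e_pos & c_pos)) / n,
    }


def _arm_cost(
    model: PSAModel, arm: str, s: Mapping[str, np.ndarray]
) -> np.ndarray:
    profile = model.profiles[arm]
    c = model.unit_costs
    device = s["device_total"] / (
        c.device_life_years * c.device_interventions_per_year
    )
    bd = expected_breakdown(
        or_minutes=s[f"{arm}.or_minutes"],
        prob_pack=profile.prob_pack,
        prob_navigation=profile.prob_navigation,
        prob_prosthesis=s[f"{arm}.prob_prosthesis"],
        prob_device=profile.prob_device,
        prob_icu=s[f"{arm}.prob_icu"],
        icu_days_given_admitted=s[f"{arm}.icu_days"],
        image_post_means={m: s[f"{arm}.image_post.{m}"] for m in MODALITIES},
        los_days=s[f"{arm}.los"],
        costs=c,
        device_per_intervention=device,
        unit_or_minute=s["unit.or_minute"],
        unit_pack=s["unit.surgical_pack"],
        unit_navigation=s["unit.navigation"],
        unit_prosthesis=s["unit.prosthesis"],
        unit_icu_day=s["unit.icu_day"],
        unit_hospital_day=s["unit.hospital_day"],
        unit_image_costs={m: s[f"unit.image.{m}"] for m in MODALITIES},
        residual=profile.residual_cost,
    )
    return np.asarray(bd.total)


def run_psa(model: PSAModel, config: PSAConfig) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Deterministic given the configuration (including the seed): parameters
    are sampled in a fixed order from a single generator, the costing model
    maps each draw's resource-use means to arm costs, and the effectiveness
    draws supply the per-endpoint effect deltas (R-KPS on the percentage-
    point scale).
    """
    required = set(default_distributions(model, cv=config.cv))
    if config.distributions is not None:
        dists = config.distributions
        missing = required - set(dists)
        if missing:
            raise ValueError(
                f"missing distribution(s) for varied parameter(s): {sorted(missing)}"
            )
    else:
        dists = default_distributions(model, cv=config.cv)
    rng = np.random.default_rng(config.seed)
    samples: dict[str, np.ndarray] = {}
    for name in sorted(dists):
        samples[name] = dists[name].draw(rng, config.n_draws)

    cost_conv = _arm_cost(model, "conventional", samples)
    cost_imr = _arm_cost(model, "lf_imr", samples)
    delta_cost = cost_imr - cost_conv

    delta_effect: dict[str, np.ndarray] = {}
    for ep in ENDPOINTS:
        diff = samples[f"lf_imr.effect.{ep}"] - samples[f"conventional.effect.{ep}"]
        if ep == "rkps":
            diff = diff * 100.0  # percentage points
        delta_effect[ep] = diff

    quadrants = {
        ep: quadrant_proportions(delta_effect[ep], delta_cost) for ep in ENDPOINTS
    }
    lo, hi = 2.5, 97.5
    summary = {
        "delta_cost": {
            "mean": float(delta_cost.mean()),
            "ci95": [float(v) for v in np.percentile(delta_cost, [lo, hi])],
        },
        "delta_effect": {
            ep: {
                "mean": float(delta_effect[ep].mean()),
                "ci95": [float(v) for v in np.percentile(delta_effect[ep], [lo, hi])],
            }
            for ep in ENDPOINTS
        },
    }
    return PSAResult(
        n_draws=config.n_draws,
        seed=config.seed,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        quadrants=quadrants,
        summary=summary,
    )


def deterministic_base(model: PSAModel) -> PSAResult:
    """The zero-variance model evaluated at every parameter's mean."""
    dists = {
        name: d.as_fixed() for name, d in default_distributions(model).items()
    }
    return run_psa(model, PSAConfig(n_draws=1, seed=0, distributions=dists))


def export_ce_plane(
    result: PSAResult, endpoint: str, path, plot_path=None
) -> None:
    """CSV of (delta_effect, delta_cost) pairs; optional scatter plot.

    The plot follows the usual cost-effectiveness-plane layout: incremental
    effectiveness on the x-axis, incremental cost in euros on the y-axis,
    quadrant axes through the origin.
    """
    if endpoint not in result.delta_effect:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    de = result.delta_effect[endpoint]
    dc = result.delta_cost
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["delta_effect", "delta_cost"])
        for e_i, c_i in zip(de, dc):
            writer.writerow([repr(float(e_i)), repr(float(c_i))])
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(de, dc, s=4, alpha=0.3, edgecolors="none")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.axvline(0.0, color="black", lw=0.8)
        ax.set_xlabel(f"incremental effectiveness ({endpoint})")
        ax.set_ylabel("incremental cost (EUR)")
        ax.set_title(f"Cost-effectiveness plane: {endpoint}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
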