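"""Patient-level domain types and the synthetic two-arm cohort generator.

The study compares conventional microsurgery for glioma (historical cohort,
n = 146) against surgery guided by a low-field intraoperative MR device
(prospective cohort, n = 50).  No patient-level data are deposited, so this
module generates synthetic cohorts whose marginal distributions match the
published arm-level summaries: resource-use means/SDs, extent-of-resection
and complication proportions, Karnofsky performance status (KPS) scores,
progression-free survival censored at one year, and 1-/2-year survival.

Generative recipe
-----------------
* Continuous positive quantities (operating-room minutes, length of stay,
  ICU days among admitted, progression-free survival) are Gamma draws
  moment-matched to (mean, sd); Gamma guarantees positivity and mirrors the
  distribution family used in the probabilistic sensitivity analysis.
* Image counts are discretized Gamma draws (rounded, floored at zero).
* Binary usage/outcome indicators are Bernoulli.
* KPS scores are latent-Normal draws rounded to the nearest 10 and clipped
  to the published range; the latent location is calibrated by root-finding
  so the *discretized* mean equals the profile mean (naive round-and-clip
  would bias it).
* PFS draws are censored at 365 days: ``progression_event`` is False when
  the raw draw exceeds one year.

All randomness flows through an explicit integer seed; the same seed yields
a byte-identical cohort.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .costing import MODALITIES

__all__ = [
    "ARMS",
    "PatientRecord",
    "ArmProfile",
    "default_profiles",
    "generate_cohort",
    "classify_rkps",
    "read_cohort_csv",
    "write_cohort_csv",
    "CohortValidationError",
]

ARMS = ("conventional", "lf_imr")
EOR_LEVELS = ("GTR", "STR", "PR")
SEXES = ("female", "male")
GRADES = ("LGG", "HGG")


class CohortValidationError(ValueError):
    """A patient record violates a range or consistency rule."""


@dataclass
class PatientRecord:
    """One patient's resource use and clinical outcomes."""

    patient_id: str
    arm: str
    age: float
    sex: str
    grade: str
    pre_kps: int
    post_kps: int
    eor: str
    complication: bool
    reintervention: bool
    pfs_days: int
    progression_event: bool
    alive_1y: bool
    alive_2y: bool
    or_minutes: float
    used_pack: bool
    used_navigation: bool
    used_prosthesis: bool
    used_device: bool
    icu_admitted: bool
    icu_days: float
    images_pre: dict[str, int] = field(default_factory=dict)
    images_post: dict[str, int] = field(default_factory=dict)
    los_days: float = 0.0

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise CohortValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex must be one of {SEXES}")
        if self.grade not in GRADES:
            raise CohortValidationError(f"grade must be one of {GRADES}")
        if self.eor not in EOR_LEVELS:
            raise CohortValidationError(f"eor must be one of {EOR_LEVELS}")
        if self.pre_kps not in range(70, 101, 10):
            raise CohortValidationError(
                f"pre_kps must be a multiple of 10 in [70, 100], got {self.pre_kps}"
            )
        if self.post_kps not in range(60, 101, 10):
            raise CohortValidationError(
                f"post_kps must be a multiple of 10 in [60, 100], got {self.post_kps}"
            )
        if not 0 <= self.pfs_days <= 365:
            raise CohortValidationError(
                f"pfs_days must be in [0, 365], got {self.pfs_days}"
            )
        if self.alive_2y and not self.alive_1y:
            raise CohortValidationError("alive_2y requires alive_1y")
        if (self.icu_days > 0) != self.icu_admitted:
            raise CohortValidationError(
                "icu_days > 0 must hold exactly when icu_admitted"
            )
        if self.icu_days < 0 or self.or_minutes < 0:
            raise CohortValidationError("resource quantities must be >= 0")
        if self.los_days <= 0:
            raise CohortValidationError(f"los_days must be > 0, got {self.los_days}")
        if self.age < 0:
            raise CohortValidationError("age must be >= 0")
        for label, imgs in (("images_pre", self.images_pre),
                            ("images_post", self.images_post)):
            for m, k in imgs.items():
                if m not in MODALITIES:
                    raise CohortValidationError(f"{label}: unknown modality {m!r}")
                if k < 0:
                    raise CohortValidationError(f"{label}[{m}] must be >= 0")


@dataclass
class ArmProfile:
    """Arm-level generative parameters (also the PSA parameter means)."""

    arm: str
    n: int
    or_minutes: tuple[float, float]
    prob_pack: float
    prob_navigation: float
    prob_prosthesis: float
    prob_device: float
    prob_icu: float
    icu_days_given_admitted: float
    image_rates_pre: dict[str, tuple[float, float]]
    image_rates_post: dict[str, tuple[float, float]]
    los: tuple[float, float]
    pre_kps: tuple[float, float]
    post_kps: tuple[float, float]
    prob_gtr: float
    prob_str: float
    prob_complication: float
    pfs_mean: float
    prob_os1y: float
    prob_os2y: float
    residual_cost: float
    # generative parameters the published tables imply but do not print
    pfs_sd: float = 60.0
    icu_days_sd: float | None = None  # None -> sd equal to the mean
    age: tuple[float, float] = (54.0, 15.0)
    prob_female: float = 0.39
    prob_hgg: float = 0.69
    prob_reintervention: float = 0.0

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.n <= 0:
            raise ValueError(f"cohort size must be > 0, got {self.n}")
        probs = {
            "prob_pack": self.prob_pack,
            "prob_navigation": self.prob_navigation,
            "prob_prosthesis": self.prob_prosthesis,
            "prob_device": self.prob_device,
            "prob_icu": self.prob_icu,
            "prob_gtr": self.prob_gtr,
            "prob_str": self.prob_str,
            "prob_complication": self.prob_complication,
            "prob_os1y": self.prob_os1y,
            "prob_os2y": self.prob_os2y,
            "prob_female": self.prob_female,
            "prob_hgg": self.prob_hgg,
            "prob_reintervention": self.prob_reintervention,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.prob_gtr + self.prob_str > 1.0 + 1e-12:
            raise ValueError("prob_gtr + prob_str must be <= 1")
        if self.prob_os2y > self.prob_os1y:
            raise ValueError("prob_os2y must be <= prob_os1y")
        pairs = {
            "or_minutes": self.or_minutes,
            "los": self.los,
            "pre_kps": self.pre_kps,
            "post_kps": self.post_kps,
            "age": self.age,
        }
        for name, (m, s) in pairs.items():
            if m <= 0:
                raise ValueError(f"{name} mean must be > 0")
            if s < 0:
                raise ValueError(f"{name} sd must be >= 0")
        for rates in (self.image_rates_pre, self.image_rates_post):
            for m, (mu, s) in rates.items():
                if mu < 0 or s < 0:
                    raise ValueError(f"image rate for {m} must have mean, sd >= 0")
        if self.pfs_mean <= 0 or self.pfs_sd < 0:
            raise ValueError("pfs_mean must be > 0 and pfs_sd >= 0")
        if self.icu_days_given_admitted < 0:
            raise ValueError("icu_days_given_admitted must be >= 0")


def default_profiles() -> tuple[ArmProfile, ArmProfile]:
    """The two published arm profiles (conventional, LF-iMR).

    Resource use and unit prices follow the study's resource-use table;
    clinical outcomes follow its outcomes table.  ICU days among admitted
    patients are not printed and are calibrated from the ICU category costs:
    717 / (0.67 x 555) = 1.93 d conventional, 472 / (0.34 x 555) = 2.50 d
    LF-iMR.  The per-arm residual cost (381 / 706 EUR) reconciles the four
    printed cost categories with the printed per-patient totals
    (10,810 / 11,599 EUR), which do not otherwise sum.
    """
    conventional = ArmProfile(
        arm="conventional",
        n=146,
        or_minutes=(368.0, 75.0),
        prob_pack=1.0,
        prob_navigation=0.0,
        prob_prosthesis=0.92,
        prob_device=0.0,
        prob_icu=0.67,
        icu_days_given_admitted=717.0 / (0.67 * 555.0),
        image_rates_pre={
            "MR-C": (1.2, 0.9),
            "MR": (2.0, 1.63),
            "PET": (0.1, 0.2),
            "XRay": (1.3, 1.6),
            "PortableXRay": (0.03, 0.2),
            "SPECT": (0.0, 0.0),
            "CT": (0.5, 0.6),
        },
        image_rates_post={
            "MR-C": (3.0, 1.7),
            "MR": (3.5, 1.8),
            "PET": (0.0, 0.0),
            "XRay": (1.1, 2.9),
            "PortableXRay": (0.9, 1.2),
            "SPECT": (0.1, 0.1),
            "CT": (1.1, 2.9),
        },
        los=(11.9, 7.8),
        pre_kps=(84.0, 9.0),
        post_kps=(77.0, 18.0),
        prob_gtr=0.562,
        prob_str=0.30,
        prob_complication=0.213,
        pfs_mean=295.0,
        pfs_sd=40.0,
        prob_os1y=0.843,
        prob_os2y=0.733,
        residual_cost=381.0,
        age=(54.0, 15.0),
        prob_female=0.39,
        prob_hgg=0.719,
        prob_reintervention=0.0,
    )
    lf_imr = ArmProfile(
        arm="lf_imr",
        n=50,
        or_minutes=(415.0, 70.0),
        prob_pack=1.0,
        prob_navigation=1.0,
        prob_prosthesis=0.88,
        prob_device=1.0,
        prob_icu=0.34,
        icu_days_given_admitted=472.0 / (0.34 * 555.0),
        image_rates_pre={
            "MR-C": (1.0, 0.9),
            "MR": (1.7, 1.7),
            "PET": (0.1, 0.3),
            "XRay": (1.1, 1.2),
            "PortableXRay": (0.1, 0.5),
            "SPECT": (0.0, 0.0),
            "CT": (0.4, 0.6),
        },
        image_rates_post={
            "MR-C": (2.5, 1.7),
            "MR": (3.1, 1.6),
            "PET": (0.0, 0.0),
            "XRay": (1.7, 3.5),
            "PortableXRay": (0.3, 0.9),
            "SPECT": (0.1, 0.3),
            "CT": (0.7, 1.4),
        },
        los=(9.7, 5.4),
        pre_kps=(87.0, 8.0),
        post_kps=(84.0, 8.0),
        prob_gtr=0.70,
        prob_str=0.22,
        prob_complication=0.14,
        pfs_mean=333.0,
        pfs_sd=76.0,
        prob_os1y=0.88,
        prob_os2y=0.70,
        residual_cost=706.0,
        age=(53.0, 15.0),
        prob_female=0.40,
        prob_hgg=0.62,
        prob_reintervention=0.08,
    )
    return conventional, lf_imr


# ---------------------------------------------------------------------------
# generation helpers


def _gamma_draws(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Moment-matched Gamma draws; degenerate cases collapse to constants."""
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be >= 0")
    if mean == 0.0:
        return np.zeros(n)
    if sd == 0.0:
        return np.full(n, float(mean))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def _kps_latent_mean(target: float, sd: float, lo: int, hi: int) -> float:
    """Latent Normal location whose rounded-and-clipped mean equals ``target``.

    KPS is reported in steps of 10 on [lo, hi]; the discretization maps the
    latent draw x to clip(round(x / 10) * 10, lo, hi).  The expectation of
    that map is continuous and strictly increasing in the latent location,
    so a bracketing root-find recovers the calibrated location exactly.
    """
    if not lo <= target <= hi:
        raise ValueError(f"KPS mean {target} outside [{lo}, {hi}]")
    levels = np.arange(lo, hi + 1, 10, dtype=float)
    edges = levels[:-1] + 5.0  # bin boundaries between adjacent levels

    def discretized_mean(mu: float) -> float:
        cdf = norm.cdf(edges, loc=mu, scale=sd)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(levels @ probs)

    lo_b, hi_b = lo - 6.0 * sd - 10.0, hi + 6.0 * sd + 10.0
    return brentq(lambda mu: discretized_mean(mu) - target, lo_b, hi_b, xtol=1e-10)


def _kps_draws(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int, n: int
) -> np.ndarray:
    if sd == 0.0:
        value = int(np.clip(round(mean / 10.0) * 10, lo, hi))
        return np.full(n, value, dtype=int)
    mu = _kps_latent_mean(mean, sd, lo, hi)
    raw = rng.normal(mu, sd, size=n)
    return np.clip(np.round(raw / 10.0) * 10.0, lo, hi).astype(int)


def generate_cohort(profile: ArmProfile, seed: int) -> list[PatientRecord]:
    """Generate ``profile.n`` synthetic patients for one arm.

    Deterministic given (profile, seed).  Marginal means and proportions
    converge to the profile parameters as n grows; the one deliberate
    exception is progression-free survival, whose censoring at 365 days
    pulls the restricted mean below the uncensored profile mean.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    n = profile.n

    age = _gamma_draws(rng, *profile.age, n)
    female = rng.random(n) < profile.prob_female
    hgg = rng.random(n) < profile.prob_hgg
    pre_kps = _kps_draws(rng, *profile.pre_kps, 70, 100, n)
    post_kps = _kps_draws(rng, *profile.post_kps, 60, 100, n)

    u = rng.random(n)
    eor = np.where(
        u < profile.prob_gtr,
        "GTR",
        np.where(u < profile.prob_gtr + profile.prob_str, "STR", "PR"),
    )
    complication = rng.random(n) < profile.prob_complication
    reintervention = rng.random(n) < profile.prob_reintervention

    pfs_raw = _gamma_draws(rng, profile.pfs_mean, profile.pfs_sd, n)
    progression_event = pfs_raw <= 365.0
    pfs_days = np.rint(np.minimum(pfs_raw, 365.0)).astype(int)

    alive_1y = rng.random(n) < profile.prob_os1y
    cond_2y = profile.prob_os2y / profile.prob_os1y if profile.prob_os1y > 0 else 0.0
    alive_2y = alive_1y & (rng.random(n) < cond_2y)

    or_minutes = _gamma_draws(rng, *profile.or_minutes, n)
    used_pack = rng.random(n) < profile.prob_pack
    used_navigation = rng.random(n) < profile.prob_navigation
    used_prosthesis = rng.random(n) < profile.prob_prosthesis
    used_device = rng.random(n) < profile.prob_device

    icu_admitted = rng.random(n) < profile.prob_icu
    icu_sd = (
        profile.icu_days_sd
        if profile.icu_days_sd is not None
        else profile.icu_days_given_admitted
    )
    icu_raw = _gamma_draws(rng, profile.icu_days_given_admitted, icu_sd, n)
    icu_days = np.where(icu_admitted, icu_raw, 0.0)
    # a zero-length stay counts as not admitted (can only occur degenerately)
    icu_admitted = icu_days > 0

    images_pre = {
        m: np.rint(_gamma_draws(rng, *profile.image_rates_pre.get(m, (0.0, 0.0)), n))
        .clip(min=0)
        .astype(int)
        for m in MODALITIES
    }
    images_post = {
        m: np.rint(_gamma_draws(rng, *profile.image_rates_post.get(m, (0.0, 0.0)), n))
        .clip(min=0)
        .astype(int)
        for m in MODALITIES
    }
    los = _gamma_draws(rng, *profile.los, n)
    los = np.maximum(los, 1e-6)  # LoS is strictly positive

    cohort = []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"{profile.arm}-{i:04d}",
            arm=profile.arm,
            age=float(age[i]),
            sex="female" if female[i] else "male",
            grade="HGG" if hgg[i] else "LGG",
            pre_kps=int(pre_kps[i]),
            post_kps=int(post_kps[i]),
            eor=str(eor[i]),
            complication=bool(complication[i]),
            reintervention=bool(reintervention[i]),
            pfs_days=int(pfs_days[i]),
            progression_event=bool(progression_event[i]),
            alive_1y=bool(alive_1y[i]),
            alive_2y=bool(alive_2y[i]),
            or_minutes=float(or_minutes[i]),
            used_pack=bool(used_pack[i]),
            used_navigation=bool(used_navigation[i]),
            used_prosthesis=bool(used_prosthesis[i]),
            used_device=bool(used_device[i]),
            icu_admitted=bool(icu_admitted[i]),
            icu_days=float(icu_days[i]),
            images_pre={m: int(images_pre[m][i]) for m in MODALITIES},
            images_post={m: int(images_post[m][i]) for m in MODALITIES},
            los_days=float(los[i]),
        )
        rec.validate()
        cohort.append(rec)
    return cohort


def classify_rkps(patient: PatientRecord) -> bool:
    """Composite surgical endpoint R-KPS.

    True iff the resection was gross-total or subtotal AND the postoperative
    KPS is conserved or improved relative to the preoperative score.  A
    partial resection fails the endpoint regardless of the KPS course.
    """
    if patient.eor not in EOR_LEVELS:
        raise CohortValidationError(f"eor must be one of {EOR_LEVELS}")
    return patient.eor in ("GTR", "STR") and patient.post_kps >= patient.pre_kps


# ---------------------------------------------------------------------------
# CSV interchange

_BOOL_FIELDS = (
    "complication",
    "reintervention",
    "progression_event",
    "alive_1y",
    "alive_2y",
    "used_pack",
    "used_navigation",
    "used_prosthesis",
    "used_device",
    "icu_admitted",
)
_INT_FIELDS = ("pre_kps", "post_kps", "pfs_days")
_FLOAT_FIELDS = ("age", "or_minutes", "icu_days", "los_days")
_STR_FIELDS = ("patient_id", "arm", "sex", "grade", "eor")

CSV_COLUMNS = (
    list(_STR_FIELDS[:2])
    + ["age", "sex", "grade", "pre_kps", "post_kps", "eor"]
    + [
        "complication",
        "reintervention",
        "pfs_days",
        "progression_event",
        "alive_1y",
        "alive_2y",
        "or_minutes",
        "used_pack",
        "used_navigation",
        "used_prosthesis",
        "used_device",
        "icu_admitted",
        "icu_days",
    ]
    + [f"images_pre_{m}" for m in MODALITIES]
    + [f"images_post_{m}" for m in MODALITIES]
    + ["los_days"]
)


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    """Write one row per patient (UTF-8, comma-separated, header required)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in cohort:
            row = []
            for col in CSV_COLUMNS:
                if col.startswith("images_pre_"):
                    row.append(p.images_pre.get(col[len("images_pre_"):], 0))
                elif col.startswith("images_post_"):
                    row.append(p.images_post.get(col[len("images_post_"):], 0))
                else:
                    value = getattr(p, col)
                    row.append(repr(value) if isinstance(value, float) else value)
            writer.writerow(row)


def _parse_value(col: str, raw: str):
    if col in _BOOL_FIELDS:
        if raw not in ("True", "False"):
            raise ValueError(f"expected True/False, got {raw!r}")
        return raw == "True"
    if col in _INT_FIELDS or col.startswith("images_"):
        return int(raw)
    if col in _FLOAT_FIELDS:
        return float(raw)
    return raw


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read and validate a patient-level CSV; errors name the row and field."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file, header row required")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortValidationError(
                f"{path}: missing required column(s): {sorted(missing)}"
            )
        cohort = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            kwargs: dict = {"images_pre": {}, "images_post": {}}
            for col in CSV_COLUMNS:
                try:
                    value = _parse_value(col, row[col])
                except (TypeError, ValueError) as exc:
                    raise CohortValidationError(
                        f"{path}: row {i}, field {col!r}: {exc}"
                    ) from None
                if col.startswith("images_pre_"):
                    kwargs["images_pre"][col[len("images_pre_"):]] = value
                elif col.startswith("images_post_"):
                    kwargs["images_post"][col[len("images_post_"):]] = value
                else:
                    kwargs[col] = value
            rec = PatientRecord(**kwargs)
            try:
                rec.validate()
            except CohortValidationError as exc:
                raise CohortValidationError(f"{path}: row {i}: {exc}") from None
            cohort.append(rec)
    return cohort
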