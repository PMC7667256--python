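"""Effectiveness endpoints and supporting survival statistics.

The three effectiveness variables carried into the cost-effectiveness
analysis are the mean postoperative Karnofsky performance status (KPS), the
proportion achieving the composite R-KPS endpoint (gross-total/subtotal
resection with conserved or improved KPS), and 1-year progression-free
survival expressed as the restricted mean of PFS days censored at 365.
Overall survival at 1 and 2 years, complication and resection rates are
summarized descriptively.

The Kaplan-Meier product-limit estimator and the one-degree-of-freedom
log-rank (Mantel-Cox) test are implemented here directly; deaths before
progression count as progression events, and all p-values are two-sided.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohorts import PatientRecord, classify_rkps

__all__ = [
    "EffectivenessSummary",
    "SurvivalCurve",
    "summarize_effectiveness",
    "km_estimate",
    "logrank_test",
    "welch_t_test",
    "export_survival_csv",
    "plot_km",
]


@dataclass(frozen=True)
class EffectivenessSummary:
    mean_post_kps: float
    rkps_proportion: float
    mean_pfs_1y: float
    os_1y: float
    os_2y: float
    complication_rate: float
    gtr_rate: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_post_kps": self.mean_post_kps,
            "rkps_proportion": self.rkps_proportion,
            "mean_pfs_1y": self.mean_pfs_1y,
            "os_1y": self.os_1y,
            "os_2y": self.os_2y,
            "complication_rate": self.complication_rate,
            "gtr_rate": self.gtr_rate,
        }


def summarize_effectiveness(cohort: Sequence[PatientRecord]) -> EffectivenessSummary:
    """Arm-level effectiveness summary from patient-level records."""
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    return EffectivenessSummary(
        mean_post_kps=sum(p.post_kps for p in cohort) / n,
        rkps_proportion=sum(classify_rkps(p) for p in cohort) / n,
        mean_pfs_1y=sum(p.pfs_days for p in cohort) / n,
        os_1y=sum(p.alive_1y for p in cohort) / n,
        os_2y=sum(p.alive_2y for p in cohort) / n,
        complication_rate=sum(p.complication for p in cohort) / n,
        gtr_rate=sum(p.eor == "GTR" for p in cohort) / n,
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate tabulated at each distinct observed time."""

    times: np.ndarray       # distinct observed times, ascending
    at_risk: np.ndarray     # number at risk just before each time
    events: np.ndarray      # events at each time
    survival: np.ndarray    # S(t) at each time (right-continuous steps)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_survival_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t, e


def km_estimate(times: Iterable[float], events: Iterable[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _check_survival_input(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n_total = t.size
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    removed = 0
    for i, u in enumerate(uniq):
        mask = t == u
        at_risk[i] = n_total - removed
        d[i] = int(e[mask].sum())
        removed += int(mask.sum())
    with np.errstate(invalid="ignore"):
        factors = 1.0 - d / at_risk
    survival = np.cumprod(factors)
    return SurvivalCurve(times=uniq, at_risk=at_risk, events=d, survival=survival)


def logrank_test(
    times_a: Iterable[float],
    events_a: Iterable[bool],
    times_b: Iterable[float],
    events_b: Iterable[bool],
) -> tuple[float, float]:
    """Two-sample log-rank (Mantel-Cox) test.

    Returns the one-degree-of-freedom chi-square statistic and its two-sided
    p-value from the chi-square upper tail.  Raises if neither group has any
    event (the statistic is undefined).
    """
    ta, ea = _check_survival_input(times_a, events_a)
    tb, eb = _check_survival_input(times_b, events_b)
    if not ea.any() and not eb.any():
        raise ValueError("log-rank statistic undefined: no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])

    event_times = np.unique(t[e])
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for u in event_times:
        at_risk = t >= u
        n_i = int(at_risk.sum())
        n_a = int((at_risk & ~group).sum())
        d_i = int((e & (t == u)).sum())
        d_a = int((e & (t == u) & ~group).sum())
        observed_a += d_a
        expected_a += d_i * n_a / n_i
        if n_i > 1:
            variance += (
                d_i * (n_i - d_i) * n_a * (n_i - n_a) / (n_i**2 * (n_i - 1))
            )
    if variance == 0.0:
        return 0.0, 1.0
    chi2 = (observed_a - expected_a) ** 2 / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def welch_t_test(sample_a: Iterable[float], sample_b: Iterable[float]) -> tuple[float, float]:
    """Two-sided unequal-variance t-test (Welch-Satterthwaite df)."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def export_survival_csv(curve: SurvivalCurve, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "at_risk", "events", "survival"])
        for t, n, d, s in zip(curve.times, curve.at_risk, curve.events, curve.survival):
            writer.writerow([repr(float(t)), int(n), int(d), repr(float(s))])


def plot_km(curves: dict[str, SurvivalCurve], path, title: str = "Progression-free survival") -> None:
    """Step plot of one KM curve per labelled group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("days from surgery")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
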