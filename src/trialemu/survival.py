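"""Time-to-event summaries and superiority-trial sample-size design.

Kaplan–Meier curves and log-rank tests (via lifelines) for the 5-year
composite outcome, crude per-arm event tables, and a transparent
Schoenfeld-formula sample-size calculator with exponential-survival accrual
arithmetic and a simple crossover dilution of the hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import chi2_contingency, norm

__all__ = [
    "KMCurve",
    "SampleSizeResult",
    "km_curve",
    "log_rank",
    "crude_event_table",
    "tte_sample_size",
    "sample_size_grid",
]

OUTCOME_LABELS = {
    "death": "All-cause mortality",
    "cv_death": "Cardiovascular mortality",
    "mi": "Myocardial infarction",
    "stroke": "Stroke",
    "hf_hosp": "Heart failure hospitalization",
    "cv_hosp": "Cardiovascular hospitalization",
    "vte": "Venous thromboembolism",
    "composite": "Composite of all-cause mortality or cardiovascular hospitalization",
}


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SampleSizeResult:
    events: int
    n_total: int
    n_per_arm: int
    assumptions: dict = field(default_factory=dict)


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    Ties are handled by the simultaneous-event convention (all deaths at a
    time point share the same at-risk set).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    t = tab.index.to_numpy(dtype=float)
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].reindex(tab.index).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where((at_risk - d) > 0, d / (at_risk * (at_risk - d)), 0.0)
    gw = surv**2 * np.cumsum(term)
    return KMCurve(t, surv, at_risk, gw)


def log_rank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    ea, eb = np.asarray(events_a, dtype=int), np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def crude_event_table(
    cohort: pd.DataFrame, outcomes: tuple = tuple(OUTCOME_LABELS), arm_col: str = "arm"
) -> pd.DataFrame:
    """Per-arm 5-year event counts and percentages with chi-square p-values.

    Percentages are reported to one decimal, mirroring how crude event-rate
    tables are typically printed.
    """
    arms = sorted(cohort[arm_col].unique(), key=lambda a: a != "CABG")  # CABG first
    rows = []
    for outcome in outcomes:
        col = f"{outcome}_event"
        row = {"outcome": outcome, "label": OUTCOME_LABELS.get(outcome, outcome)}
        counts = []
        for arm in arms:
            grp = cohort.loc[cohort[arm_col] == arm, col]
            k, n = int(grp.sum()), int(len(grp))
            counts.append((k, n))
            key = "cabg" if arm == "CABG" else "pci"
            row[f"{key}_count"] = k
            row[f"{key}_n"] = n
            row[f"{key}_pct"] = round(100.0 * k / n, 1) if n else float("nan")
        if len(counts) == 2 and all(n > 0 for _, n in counts):
            table = np.array([[k, n - k] for k, n in counts])
            if table[:, 0].sum() in (0, table.sum()):
                row["p_value"] = 1.0
            else:
                row["p_value"] = float(chi2_contingency(table, correction=False)[1])
        rows.append(row)
    return pd.DataFrame(rows)


def _event_probability(lam: float, accrual_years: float, total_years: float) -> float:
    """P(event before administrative censoring) under exponential survival
    with uniform accrual over ``accrual_years`` and study end at
    ``total_years``."""
    if accrual_years == 0:
        return 1.0 - math.exp(-lam * total_years)
    a, T = accrual_years, total_years
    return 1.0 - math.exp(-lam * T) * (math.exp(lam * a) - 1.0) / (lam * a)


def tte_sample_size(
    hr: float,
    control_event_rate_5y: float = 0.70,
    accrual_years: float = 4.0,
    total_years: float = 7.0,
    crossover: float = 0.05,
    power: float = 0.90,
    alpha: float = 0.05,
    allocation: float = 0.5,
) -> SampleSizeResult:
    """Events and per-arm N for a time-to-event superiority trial.

    Required events from the Schoenfeld formula
    ``d = (z_{1-alpha/2} + z_{1-beta})^2 / (p(1-p) (ln hr_eff)^2)`` with
    allocation fraction ``p`` and a crossover-diluted hazard ratio
    ``hr_eff = exp(ln(hr) * (1 - 2*crossover))``. Per-arm N converts events
    to patients through the per-patient event probability under exponential
    survival calibrated to the control 5-year event rate, uniform accrual,
    and administrative censoring at the study end. Results round up.
    """
    if not 0 < hr < 1:
        raise ValueError("hr must be in (0, 1) for a superiority design (hr = 1: no effect)")
    for name, v in (("control_event_rate_5y", control_event_rate_5y), ("crossover", crossover)):
        if not 0 <= v < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if not 0 < allocation < 1:
        raise ValueError("allocation must be in (0, 1)")
    if total_years < accrual_years:
        raise ValueError("total_years must be >= accrual_years")

    hr_eff = math.exp(math.log(hr) * (1.0 - 2.0 * crossover))
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    p = allocation
    d = (z_a + z_b) ** 2 / (p * (1.0 - p) * math.log(hr_eff) ** 2)
    events = math.ceil(d)

    lam_c = -math.log(1.0 - control_event_rate_5y) / 5.0
    lam_t = lam_c * hr_eff
    p_c = _event_probability(lam_c, accrual_years, total_years)
    p_t = _event_probability(lam_t, accrual_years, total_years)
    p_bar = allocation * p_t + (1.0 - allocation) * p_c
    n_total = math.ceil(events / p_bar)
    n_per_arm = math.ceil(n_total * max(allocation, 1.0 - allocation))
    return SampleSizeResult(
        events,
        n_total,
        n_per_arm,
        {
            "hr": hr,
            "hr_eff": hr_eff,
            "control_event_rate_5y": control_event_rate_5y,
            "accrual_years": accrual_years,
            "total_years": total_years,
            "crossover": crossover,
            "power": power,
            "alpha": alpha,
            "allocation": allocation,
            "event_prob_control": p_c,
            "event_prob_treated": p_t,
        },
    )


def sample_size_grid(hrs, **kwargs) -> pd.DataFrame:
    """Sample-size scenarios over a grid of hazard ratios."""
    rows = []
    for hr in hrs:
        r = tte_sample_size(hr, **kwargs)
        rows.append({"hr": hr, "events": r.events, "n_total": r.n_total, "n_per_arm": r.n_per_arm})
    return pd.DataFrame(rows)
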