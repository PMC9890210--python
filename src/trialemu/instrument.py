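"""Regional-preference instrument construction and validity diagnostics.

The instrument is the regional CABG rate among revascularized heart-failure
patients (the share of CABG among CABG + complex PCI in each administrative
region). Diagnostics mirror standard practice-variation IV workflows:

* per-region rates with an unweighted mean/SD summary;
* an adjusted funnel plot — standardized surgical ratios (observed/expected
  CABG counts under a patient-level case-mix model) with 95% and 99.8%
  control limits;
* first-stage strength: F-statistic of the excluded instrument against the
  single-instrument Stock–Yogo critical value 16.38 (10% maximal-bias
  level);
* covariate balance across instrument quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from trialemu.estimators import build_design
from trialemu.matching import standardized_mean_difference

__all__ = [
    "InstrumentDiagnostics",
    "FunnelResult",
    "regional_cabg_rates",
    "attach_instrument",
    "funnel_analysis",
    "first_stage_diagnostics",
    "instrument_quartile_balance",
]

STOCK_YOGO_1INSTR_10PCT = 16.38


@dataclass
class InstrumentDiagnostics:
    region_rates: pd.DataFrame  # region, n, n_cabg, rate
    rate_mean: float
    rate_sd: float
    rate_min: float
    rate_max: float
    first_stage_f: float
    first_stage_p: float
    critical_value: float
    strong_instrument: bool
    quartile_balance: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


@dataclass
class FunnelResult:
    table: pd.DataFrame  # region, n, observed, expected, ratio, limits, flags
    z95: float = 1.959964
    z998: float = 3.090232


def regional_cabg_rates(
    cohort: pd.DataFrame, region_col: str = "region", treatment_col: str = "treatment"
) -> tuple[pd.DataFrame, dict]:
    """Per-region CABG rates and their unweighted mean/SD summary.

    The rate is CABG / (CABG + complex PCI); only revascularized patients
    appear in a cohort table, so every grouped region has a defined rate.
    """
    g = cohort.groupby(region_col)[treatment_col].agg(n="size", n_cabg="sum")
    g["rate"] = g["n_cabg"] / g["n"]
    table = g.reset_index()
    summary = {
        "mean": float(table["rate"].mean()),
        "sd": float(table["rate"].std(ddof=1)) if len(table) > 1 else 0.0,
        "min": float(table["rate"].min()),
        "max": float(table["rate"].max()),
        "n_regions": int(len(table)),
    }
    return table, summary


def attach_instrument(
    cohort: pd.DataFrame,
    region_col: str = "region",
    treatment_col: str = "treatment",
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Return the cohort with each patient's regional CABG rate attached.

    With ``leave_one_out`` the patient's own treatment is removed from their
    region's numerator and denominator (patients in single-patient regions
    get a missing instrument and are dropped from IV fits downstream).
    """
    out = cohort.copy()
    g = out.groupby(region_col)[treatment_col].transform
    n = g("size")
    s = g("sum")
    if leave_one_out:
        denom = n - 1
        rate = (s - out[treatment_col]) / denom.where(denom > 0)
    else:
        rate = s / n
    out["instrument"] = rate
    return out


def funnel_analysis(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    region_col: str = "region",
    treatment_col: str = "treatment",
) -> FunnelResult:
    """Standardized surgical ratios with binomial control limits.

    A patient-level logistic model of CABG vs complex PCI on case-mix
    covariates (no region terms) yields fitted probabilities; a region's
    expected count is their sum and its standardized ratio is
    observed/expected. Control limits around 1.0 use the normal
    approximation to the binomial variance of the expected count.
    """
    if cohort[region_col].nunique() < 2:
        raise ValueError("funnel analysis needs at least 2 regions")
    X, data = build_design(cohort, covariates)
    y = data[treatment_col].to_numpy(dtype=float)
    Xd = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    from trialemu.estimators import fit_discrete

    res = fit_discrete(sm.Logit(y, Xd))
    score_norm = float(np.max(np.abs(res.mle_retvals.get("score", np.array([np.inf])))))
    if not (res.mle_retvals.get("converged", False) or score_norm < 1e-4):
        raise RuntimeError(
            "funnel case-mix model did not converge "
            f"(max |score| = {score_norm:.3g}); model diagnostics: {res.mle_retvals}"
        )
    p = np.asarray(res.predict(Xd))
    df = pd.DataFrame(
        {"region": data[region_col].to_numpy(), "obs": y, "p": p, "v": p * (1 - p)}
    )
    g = df.groupby("region").agg(n=("obs", "size"), observed=("obs", "sum"),
                                 expected=("p", "sum"), var=("v", "sum"))
    g = g[g["expected"] > 0]
    g["ratio"] = g["observed"] / g["expected"]
    z95, z998 = 1.959964, 3.090232
    se = np.sqrt(g["var"]) / g["expected"]
    for z, tag in ((z95, "95"), (z998, "998")):
        g[f"lcl{tag}"] = 1.0 - z * se
        g[f"ucl{tag}"] = 1.0 + z * se
        g[f"inside{tag}"] = (g["ratio"] >= g[f"lcl{tag}"]) & (g["ratio"] <= g[f"ucl{tag}"])
    return FunnelResult(g.reset_index())


def first_stage_diagnostics(
    cohort: pd.DataFrame,
    instrument_col: str = "instrument",
    covariates: list[str] | None = None,
    treatment_col: str = "treatment",
    critical_value: float = STOCK_YOGO_1INSTR_10PCT,
    with_quartile_balance: bool = True,
) -> InstrumentDiagnostics:
    """First-stage strength of the excluded instrument.

    Linear first-stage regression of the treatment indicator on the
    instrument plus covariates; with a single instrument the first-stage F
    is the squared t-statistic of the instrument, compared against the
    Stock–Yogo critical value (16.38 at the 10% maximal-bias level).
    """
    z = pd.to_numeric(cohort[instrument_col], errors="coerce")
    if z.dropna().nunique() <= 1:
        raise ValueError("no regional variation: instrument is constant")
    X, data = build_design(cohort, covariates)
    zz = z.loc[data.index]
    keep = zz.notna()
    data, X, zz = data.loc[keep], X.loc[keep], zz.loc[keep]
    t = data[treatment_col].to_numpy(dtype=float)
    Xd = np.column_stack([np.ones(len(t)), zz.to_numpy(dtype=float), X.to_numpy(dtype=float)])
    res = sm.OLS(t, Xd).fit()
    f = float(res.tvalues[1] ** 2)
    p = float(res.pvalues[1])

    rates, summary = regional_cabg_rates(data, treatment_col=treatment_col)
    qb = instrument_quartile_balance(data.assign(instrument=zz)) if with_quartile_balance else None
    return InstrumentDiagnostics(
        region_rates=rates,
        rate_mean=summary["mean"],
        rate_sd=summary["sd"],
        rate_min=summary["min"],
        rate_max=summary["max"],
        first_stage_f=f,
        first_stage_p=p,
        critical_value=critical_value,
        strong_instrument=bool(f > critical_value),
        quartile_balance=qb,
        notes={"n": int(len(t)), "n_regions": summary["n_regions"]},
    )


def instrument_quartile_balance(
    cohort: pd.DataFrame,
    instrument_col: str = "instrument",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate summaries by instrument quartile with max pairwise SMDs.

    Quartiles are sample quartiles of the patient-level instrument; ties
    resolve by rank-then-patient-order so quartile sizes differ by at most
    one.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 rows for quartiles")
    covs = covariates or [
        c
        for c in ("age", "male", "imd", "diabetes", "hypertension", "lipidaemia",
                  "ckd", "prior_stroke", "prior_mi", "pvd")
        if c in cohort.columns
    ]
    z = pd.to_numeric(cohort[instrument_col], errors="coerce").to_numpy()
    order = np.lexsort((np.arange(len(z)), z))
    q = np.empty(len(z), dtype=int)
    q[order] = (np.arange(len(z)) * 4) // len(z) + 1
    df = cohort.assign(_quartile=q)
    rows = []
    for cov in covs:
        vals = pd.to_numeric(df[cov], errors="coerce")
        groups = [vals[df["_quartile"] == k].dropna() for k in (1, 2, 3, 4)]
        means = {f"q{k}_mean": float(g.mean()) for k, g in zip((1, 2, 3, 4), groups)}
        smds = [
            abs(standardized_mean_difference(groups[i], groups[j]))
            for i in range(4)
            for j in range(i + 1, 4)
            if len(groups[i]) > 1 and len(groups[j]) > 1
        ]
        rows.append(
            {"covariate": cov, **means, "max_pairwise_smd": max(smds) if smds else 0.0}
        )
    return pd.DataFrame(rows)


def plot_funnel(result: FunnelResult, path) -> None:
    """Render the funnel plot (ratio vs expected count) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table.sort_values("expected")
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(tab["expected"], tab["ratio"], s=18, alpha=0.8)
    ax.plot(tab["expected"], tab["lcl95"], "--", color="C1", label="95% limits")
    ax.plot(tab["expected"], tab["ucl95"], "--", color="C1")
    ax.plot(tab["expected"], tab["lcl998"], ":", color="C3", label="99.8% limits")
    ax.plot(tab["expected"], tab["ucl998"], ":", color="C3")
    ax.axhline(1.0, color="grey", lw=1)
    ax.set_xlabel("Expected CABG count")
    ax.set_ylabel("Standardized surgical ratio (obs/exp)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
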