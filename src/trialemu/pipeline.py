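"""End-to-end emulation runs: generate → phenotype → match → diagnose →
estimate → design, under one master seed, with a file-based report bundle.

The master seed fans out to every stochastic stage through
:mod:`trialemu._seeds`, so a full run is bit-for-bit reproducible and any
stage can be re-run in isolation with the stream it saw in the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialemu._seeds import derive_seed
from trialemu.config import SimConfig
from trialemu.estimators import (
    DEFAULT_COVARIATES,
    biprobit_iv_ate,
    metalearner_ate,
    psm_ate,
    regression_adjustment_ate,
    subgroup_ates,
)
from trialemu.instrument import attach_instrument, first_stage_diagnostics, funnel_analysis
from trialemu.matching import MatchSpec, match_to_ipd
from trialemu.phenotyping import (
    PRIMARY_AND_SECONDARY,
    PRIMARY_ONLY,
    CodeLists,
    build_cohort,
    default_code_lists,
)
from trialemu.survival import crude_event_table, km_curve, log_rank, sample_size_grid
from trialemu.synthetic import generate_hes_like, generate_trial_ipd, oracle_true_ate

__all__ = ["RunConfig", "RunReport", "StageError", "run_emulation", "write_report"]

ALL_ESTIMATORS = ("IV_BIPROBIT", "REG_ADJUST", "PSM", "S_LEARNER", "T_LEARNER", "X_LEARNER")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    code_lists: CodeLists = field(default_factory=default_code_lists)
    match_spec: MatchSpec = field(default_factory=MatchSpec)
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    dialects: list = field(default_factory=lambda: [PRIMARY_ONLY, PRIMARY_AND_SECONDARY])
    estimators: list = field(default_factory=lambda: list(ALL_ESTIMATORS))
    estimator_cohorts: list = field(default_factory=lambda: ["unmatched", "matched"])
    bootstrap: int = 200
    base_learner: dict = field(default_factory=dict)
    subgroups: list = field(default_factory=lambda: ["sex", "diabetes", "ckd"])
    subgroup_bootstrap: int = 50
    sample_size_hrs: list = field(default_factory=lambda: [0.6, 0.65, 0.7, 0.75, 0.8])
    oracle_n_mc: int = 100_000
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        if "code_lists" in kwargs:
            kwargs["code_lists"] = CodeLists(**{k: tuple(v) for k, v in kwargs["code_lists"].items()})
        if "match_spec" in kwargs:
            kwargs["match_spec"] = MatchSpec(**kwargs["match_spec"])
        return cls(**kwargs)


@dataclass
class RunReport:
    sections: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    cohorts: dict = field(default_factory=dict)  # name -> DataFrame

    def to_dict(self) -> dict:
        return _jsonable(self.sections)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # surface the failing stage by name
            raise StageError(name, exc) from exc

    return wrap


def _summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Per-arm baseline table: medians/IQRs and counts/percentages."""
    out = {}
    for arm, grp in cohort.groupby("arm"):
        s = {"n": int(len(grp))}
        for cont in ("age", "imd"):
            vals = grp[cont].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                s[cont] = {"median": float(med), "iqr": [float(q1), float(q3)]}
        for b in ("male", "diabetes", "hypertension", "lipidaemia", "ckd",
                  "prior_stroke", "prior_mi", "pvd"):
            k = int(grp[b].sum())
            s[b] = {"count": k, "pct": round(100.0 * k / len(grp), 1)}
        out[arm] = s
    return out


def run_emulation(config: RunConfig) -> RunReport:
    """Execute all enabled stages on the unmatched and matched cohorts."""
    report = RunReport()
    sim = config.sim.with_(seed=derive_seed(config.master_seed, "sim"))

    dataset = _stage("simulate")(generate_hes_like, sim)
    ipd = _stage("simulate")(generate_trial_ipd, sim)
    oracle = _stage("simulate")(oracle_true_ate, sim, config.oracle_n_mc)
    report.sections["config"] = {
        "sim": sim.to_dict(),
        "master_seed": config.master_seed,
        "estimators": list(config.estimators),
        "bootstrap": config.bootstrap,
    }
    report.sections["oracle"] = {"ate": oracle.ate, "se": oracle.se, "n_mc": oracle.n_mc}

    cohorts: dict[str, pd.DataFrame] = {}
    attritions: dict[str, dict] = {}
    for dialect in config.dialects:
        cohort, attrition = _stage("phenotype")(build_cohort, dataset, config.code_lists, dialect)
        cohort = attach_instrument(cohort)
        cohorts[dialect] = cohort
        attritions[dialect] = attrition
    report.sections["attrition"] = attritions
    primary = cohorts[config.dialects[0]]

    spec = MatchSpec(
        covariates=config.match_spec.covariates,
        caliper=config.match_spec.caliper,
        replacement=config.match_spec.replacement,
        order_seed=derive_seed(config.master_seed, "match"),
    )
    match = _stage("match")(match_to_ipd, primary, ipd, spec)
    matched_ids = match.matched["patient_id"].to_numpy()
    report.sections["matching"] = {
        "n_matched": int(len(match.matched)),
        "n_pairs": int(len(match.pairs)),
        "n_dropped_missing": int(match.n_dropped_missing),
        "balance": match.balance.assign(
            smd_before_pct=lambda d: 100 * d.smd_before, smd_after_pct=lambda d: 100 * d.smd_after
        ),
    }
    report.tables["match_pairs"] = match.pairs
    report.tables["match_balance"] = match.balance

    diag = _stage("diagnose")(
        first_stage_diagnostics, primary, "instrument", config.covariates
    )
    funnel = _stage("diagnose")(funnel_analysis, primary, config.covariates)
    report.sections["instrument"] = {
        "rate_mean": diag.rate_mean,
        "rate_sd": diag.rate_sd,
        "rate_min": diag.rate_min,
        "rate_max": diag.rate_max,
        "first_stage_f": diag.first_stage_f,
        "first_stage_p": diag.first_stage_p,
        "critical_value": diag.critical_value,
        "strong_instrument": diag.strong_instrument,
        "n_regions_outside_998": int((~funnel.table["inside998"]).sum()),
    }
    report.tables["region_rates"] = diag.region_rates
    report.tables["funnel"] = funnel.table
    report.tables["quartile_balance"] = diag.quartile_balance

    report.sections["crude_event_rates"] = {}
    report.sections["km"] = {}
    for dialect, cohort in cohorts.items():
        for label, frame in (
            ("unmatched", cohort),
            ("matched", cohort[cohort["patient_id"].isin(matched_ids)]),
        ):
            key = f"{label}_{dialect}"
            tab = _stage("events")(crude_event_table, frame)
            report.sections["crude_event_rates"][key] = tab
            report.tables[f"events_{key}"] = tab
            arms = {a: g for a, g in frame.groupby("arm")}
            if len(arms) == 2:
                (a1, g1), (a2, g2) = sorted(arms.items())
                stat, p = log_rank(
                    g1["composite_days"], g1["composite_event"],
                    g2["composite_days"], g2["composite_event"],
                )
                km = {
                    a: {
                        "s_at_horizon": km_curve(g["composite_days"], g["composite_event"]).survival_at(
                            float(g["composite_days"].max())
                        ),
                        "n": int(len(g)),
                    }
                    for a, g in arms.items()
                }
                report.sections["km"][key] = {"logrank_stat": stat, "logrank_p": p, "arms": km}

    report.sections["cohort_summaries"] = {
        "unmatched": _summarize_cohort(primary),
        "matched": _summarize_cohort(primary[primary["patient_id"].isin(matched_ids)]),
    }

    seed_est = derive_seed(config.master_seed, "estimate")
    report.sections["ates"] = {}
    for label in config.estimator_cohorts:
        frame = primary if label == "unmatched" else primary[primary["patient_id"].isin(matched_ids)]
        results = []
        for name in config.estimators:
            est = _stage(f"estimate:{name}")(
                _run_estimator, name, frame, config, seed_est
            )
            results.append(est.to_dict())
        report.sections["ates"][label] = results

    if config.subgroups:
        sub = _stage("estimate:subgroups")(
            subgroup_ates,
            primary,
            config.subgroups,
            config.covariates,
            bootstrap=config.subgroup_bootstrap,
            seed=seed_est,
        )
        report.sections["subgroups"] = sub
        report.tables["subgroups"] = sub

    grid = _stage("design")(
        sample_size_grid,
        config.sample_size_hrs,
        control_event_rate_5y=0.70,
        accrual_years=4.0,
        total_years=7.0,
        crossover=0.05,
        power=0.90,
        alpha=0.05,
    )
    report.sections["sample_size"] = grid
    report.tables["sample_size"] = grid

    report.cohorts = {f"cohort_{d}": c for d, c in cohorts.items()}
    return report


def _run_estimator(name: str, frame: pd.DataFrame, config: RunConfig, seed: int):
    covs = config.covariates
    B = config.bootstrap
    if name == "IV_BIPROBIT":
        est, _ = biprobit_iv_ate(frame, covariates=covs, bootstrap=B, seed=seed)
        return est
    if name == "REG_ADJUST":
        return regression_adjustment_ate(frame, covs, bootstrap=B, seed=seed)
    if name == "PSM":
        return psm_ate(frame, covs, bootstrap=min(B, 200), seed=seed)
    if name in ("S_LEARNER", "T_LEARNER", "X_LEARNER"):
        return metalearner_ate(
            frame, covs, kind=name[0], base_learner_config=config.base_learner,
            bootstrap=min(B, 50), seed=seed,
        )
    raise ValueError(f"unknown estimator {name!r}")


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: RunReport, out_dir, figures: bool = True) -> dict:
    """Write the JSON summary, CSV tables and figures; return a manifest.

    The manifest maps each written file to its SHA-256 checksum.
    """
    if not report.sections:
        raise ValueError("empty report: nothing to write")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files = []
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(report_path)

    for name, table in {**report.tables, **report.cohorts}.items():
        if table is None:
            continue
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        files.append(p)

    if figures:
        try:
            _write_figures(report, out, files)
        except Exception as exc:  # tables stand on their own
            import warnings

            warnings.warn(f"figure rendering skipped: {exc}", stacklevel=2)

    manifest = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest() for p in files
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_figures(report: RunReport, out: pathlib.Path, files: list) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # forest plot of ATEs
    ates = report.sections.get("ates", {})
    rows = [
        (f"{label}:{r['estimator']}", r["ate"], r["ci_low"], r["ci_high"])
        for label, results in ates.items()
        for r in results
    ]
    if rows:
        fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
        ys = np.arange(len(rows))[::-1]
        for y, (name, ate, lo, hi) in zip(ys, rows):
            ax.plot([lo, hi], [y, y], "-", color="C0")
            ax.plot([ate], [y], "s", color="C0")
        ax.axvline(0.0, color="grey", lw=1)
        ax.set_yticks(ys)
        ax.set_yticklabels([r[0] for r in rows])
        ax.set_xlabel("ATE (risk difference)")
        fig.tight_layout()
        p = out / "forest.svg"
        fig.savefig(p, metadata={"Date": None})
        plt.close(fig)
        files.append(p)

    # KM curves for the primary-dialect cohorts
    for name, cohort in report.cohorts.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        from trialemu.survival import km_curve as _km

        for arm, grp in cohort.groupby("arm"):
            km = _km(grp["composite_days"], grp["composite_event"])
            ax.step(np.r_[0, km.times], np.r_[1.0, km.survival], where="post", label=arm)
        ax.set_xlabel("Days since index revascularization")
        ax.set_ylabel("Composite event-free survival")
        ax.set_ylim(0, 1)
        ax.legend()
        fig.tight_layout()
        p = out / f"km_{name}.svg"
        fig.savefig(p, metadata={"Date": None})
        plt.close(fig)
        files.append(p)
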