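"""Synthetic HES-like data with a regional instrument and known truth.

Two generation paths share one patient-level core:

* :func:`generate_core` — a vectorised patient table (covariates, latent
  frailty, regional preference, treatment, factual and counterfactual
  outcome times). Estimator validation simulations run on this path.
* :func:`generate_hes_like` — emits episode-level admission histories
  (qualifying heart-failure admission, index revascularization with OPCS-4
  codes, follow-up admissions) and a death registry on top of the core, with
  eligibility violators injected by editing histories so the phenotyping
  engine's exclusion counts are known exactly.

The factual outcome columns of the core correspond to the primary-diagnosis
coding dialect; the episode path additionally plants cardiovascular codes in
secondary diagnosis positions of some follow-up admissions, so the wider
(primary+secondary) dialect ascertains strictly more events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from trialemu._seeds import derive_rng
from trialemu.config import (
    COMORBIDITIES,
    VIOLATOR_TYPES,
    ConfigError,
    SimConfig,
)

__all__ = [
    "SyntheticDataset",
    "OracleATE",
    "generate_core",
    "generate_hes_like",
    "generate_trial_ipd",
    "oracle_true_ate",
    "calibrate_control_rate",
    "write_dataset",
]

DAYS_PER_YEAR = 365.25

# ICD-10 / OPCS-4 vocabulary the generator writes (4-character HES style)
HF_PRIMARY = ("I500", "I501", "I509")
COMORBIDITY_CODE = {
    "diabetes": "E119",
    "hypertension": "I10",
    "lipidaemia": "E780",
    "ckd": "N183",
    "prior_stroke": "I64",
    "prior_mi": "I252",
    "pvd": "I739",
}
CABG_PROCS = ("K401", "K402", "K411", "K441", "K451")
INDEX_PRIMARY = "I251"
NOISE_PRIMARY = ("J189", "N390", "K529", "A419")
NOISE_SECONDARY_CV = ("I489", "I200", "I500")
HOSP_CAUSE_CODE = {
    "hf": ("I500", "I509"),
    "mi": ("I219", "I211"),
    "stroke": ("I639", "I619"),
    "vte": ("I260", "I801"),
    "other": ("I489", "I200", "I251"),
}
HOSP_CAUSE_PROBS = {"hf": 0.40, "mi": 0.18, "stroke": 0.08, "vte": 0.03, "other": 0.31}
CV_DEATH_CODES = ("I500", "I219", "I469", "I639")
NONCV_DEATH_CODES = ("C349", "J449", "C189")
VIOLATOR_CODE = {
    "recent_mi": "I219",
    "valve_surgery": "K251",
    "cardiogenic_shock": "R570",
    "maternal": "O800",
    "bleeding_risk": "D689",
}


class OracleATE(NamedTuple):
    """Monte-Carlo ground-truth average treatment effect with its SE."""

    ate: float
    se: float
    n_mc: int


@dataclass
class SyntheticDataset:
    """Episode/death/truth tables plus the generating configuration.

    ``patients`` is the vectorised patient-level core the episode tables were
    emitted from (factual outcomes under the primary-diagnosis dialect).
    """

    episodes: pd.DataFrame
    deaths: pd.DataFrame
    truth: pd.DataFrame
    config_echo: SimConfig
    patients: pd.DataFrame


# ---------------------------------------------------------------------------
# covariates and outcome processes
# ---------------------------------------------------------------------------

def _sample_population(config: SimConfig, rng: np.random.Generator, n: int) -> dict:
    cm = config.covariate_model
    cov = {
        "age": cm.age_mean + cm.age_sd * rng.standard_normal(n),
        "male": (rng.random(n) < cm.male_frac).astype(np.int64),
    }
    levels = list(cm.ethnicity_probs)
    probs = np.array([cm.ethnicity_probs[k] for k in levels], dtype=float)
    cov["ethnicity"] = np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=probs)]
    cov["imd_true"] = np.exp(cm.imd_log_mean + cm.imd_log_sd * rng.standard_normal(n))
    cov["imd_missing"] = rng.random(n) < cm.missing_imd_frac
    for c in COMORBIDITIES:
        cov[c] = (rng.random(n) < cm.comorbidity_prev[c]).astype(np.int64)
    return cov


def _centred(config: SimConfig, cov: dict) -> dict:
    """Centred/standardized covariates used in the generator's linear predictors."""
    cm = config.covariate_model
    z = {
        "age": (cov["age"] - cm.age_mean) / cm.age_sd,
        "male": cov["male"] - cm.male_frac,
        "imd": (np.log(cov["imd_true"]) - cm.imd_log_mean) / cm.imd_log_sd,
    }
    for c in COMORBIDITIES:
        z[c] = cov[c] - cm.comorbidity_prev[c]
    return z


def _treatment_linpred(config: SimConfig, z: dict) -> np.ndarray:
    coefs = config.treatment_model_coefs
    lp = np.full(len(z["age"]), float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "intercept" or beta == 0.0:
            continue
        if name not in z:
            raise ConfigError(f"treatment_model_coefs has unknown covariate {name!r}")
        lp += beta * z[name]
    return lp


def _outcome_linpred(config: SimConfig, z: dict) -> np.ndarray:
    om = config.outcome_model
    lp = np.zeros(len(z["age"]))
    for name, beta in om.covariate_loghr.items():
        if beta == 0.0:
            continue
        if name not in z:
            raise ConfigError(f"outcome_model.covariate_loghr has unknown covariate {name!r}")
        lp += beta * z[name]
    return lp


def _frailty_multiplier(config: SimConfig, lp_out: np.ndarray, U: np.ndarray) -> np.ndarray:
    om = config.outcome_model
    u_loghr = config.confounding_strength if om.u_loghr is None else om.u_loghr
    return np.exp(lp_out + u_loghr * U)


def _treatment_hr(config: SimConfig, z: dict, n: int) -> np.ndarray:
    """Per-patient CABG hazard ratio (allows effect modification)."""
    om = config.outcome_model
    loghr = np.full(n, om.treatment_loghr)
    for name, shift in om.treatment_loghr_modifiers.items():
        if name not in z:
            raise ConfigError(
                f"outcome_model.treatment_loghr_modifiers has unknown covariate {name!r}"
            )
        loghr = loghr + shift * z[name]
    return np.exp(loghr)


def _potential_days(
    config: SimConfig, rng: np.random.Generator, m: np.ndarray, hr: np.ndarray
) -> dict[str, np.ndarray]:
    """Death / CV-hospitalization event days under both arms (common draws).

    Hospitalization days are clamped past a nominal index length of stay
    (surgical 7 days, percutaneous 2), since a readmission cannot start
    before discharge; this never moves an event across the 5-year horizon.
    """
    om = config.outcome_model
    n = len(m)
    e_d = rng.exponential(size=n)
    e_h = rng.exponential(size=n)
    out: dict[str, np.ndarray] = {}
    for arm, label in ((0, "control"), (1, "treated")):
        scale = hr if arm else 1.0
        td = e_d / np.maximum(om.death_rate * m * scale, 1e-12)
        th = e_h / np.maximum(om.cv_hosp_rate * m * scale, 1e-12)
        dd = np.floor(td * DAYS_PER_YEAR).astype(np.int64) + 1
        dh = np.floor(th * DAYS_PER_YEAR).astype(np.int64) + 1
        dh = np.maximum(dh, (8 if arm else 3))
        out[f"death_{label}"] = dd
        out[f"hosp_{label}"] = dh
    return out


# ---------------------------------------------------------------------------
# core patient table
# ---------------------------------------------------------------------------

def generate_core(config: SimConfig) -> pd.DataFrame:
    """Vectorised patient-level table with factual and counterfactual outcomes."""
    config.validate()
    n = int(config.n_patients)
    rng = derive_rng(config.seed, "core")

    region_logit = config.region_pref_mean_logit + config.region_pref_spread * rng.standard_normal(
        config.n_regions
    )
    region = rng.integers(0, config.n_regions, size=n)
    U = rng.standard_normal(n)
    cov = _sample_population(config, rng, n)
    z = _centred(config, cov)

    logit_p = (
        config.instrument_strength * region_logit[region]
        + _treatment_linpred(config, z)
        - config.confounding_strength * U
    )
    treatment = (rng.random(n) < expit(logit_p)).astype(np.int64)
    revasc = np.where(treatment == 1, "CABG", "COMPLEX_PCI").astype(object)
    demote = (treatment == 0) & (rng.random(n) < config.simple_pci_frac)
    revasc[demote] = "SIMPLE_PCI"

    index_date = rng.integers(800, 1200, size=n)
    index_los = np.where(treatment == 1, rng.integers(6, 13, size=n), rng.integers(1, 4, size=n))

    m = _frailty_multiplier(config, _outcome_linpred(config, z), U)
    pot = _potential_days(config, rng, m, _treatment_hr(config, z, n))
    horizon = int(config.horizon_days)

    pot_treated = np.minimum(pot["death_treated"], pot["hosp_treated"])
    pot_control = np.minimum(pot["death_control"], pot["hosp_control"])
    individual_effect = (pot_treated <= horizon).astype(np.int64) - (
        pot_control <= horizon
    ).astype(np.int64)

    death_day = np.where(treatment == 1, pot["death_treated"], pot["death_control"])
    hosp_day = np.where(treatment == 1, pot["hosp_treated"], pot["hosp_control"])
    hosp_day = np.maximum(hosp_day, index_los + 1)

    cause_levels = list(HOSP_CAUSE_PROBS)
    cause_p = np.array([HOSP_CAUSE_PROBS[k] for k in cause_levels])
    hosp_cause = np.array(cause_levels, dtype=object)[rng.choice(len(cause_levels), n, p=cause_p)]
    death_cv = rng.random(n) < config.outcome_model.cv_death_frac

    death_event = death_day <= horizon
    hosp_event = (hosp_day <= horizon) & (hosp_day < death_day)
    composite_day = np.minimum(death_day, np.where(hosp_day < death_day, hosp_day, death_day))
    composite_event = death_event | hosp_event

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "region": region,
            "region_pref_logit": region_logit[region],
            "region_pref": expit(region_logit[region]),
            "latent_U": U,
            "age": cov["age"],
            "male": cov["male"],
            "sex": np.where(cov["male"] == 1, "M", "F"),
            "ethnicity": cov["ethnicity"],
            "imd_true": cov["imd_true"],
            "imd": np.where(cov["imd_missing"], np.nan, cov["imd_true"]),
            **{c: cov[c] for c in COMORBIDITIES},
            "treatment": treatment,
            "revasc": revasc,
            "index_date": index_date,
            "index_los": index_los,
            "death_day": death_day,
            "death_event": death_event.astype(np.int64),
            "death_cv": death_cv.astype(np.int64),
            "hosp_day": hosp_day,
            "hosp_event": hosp_event.astype(np.int64),
            "hosp_cause": hosp_cause,
            "composite_day": composite_day,
            "composite_event": composite_event.astype(np.int64),
            "potential_event_time_treated": pot_treated,
            "potential_event_time_control": pot_control,
            "individual_effect": individual_effect,
        }
    )
    return df


def core_analysis_cohort(config: SimConfig) -> pd.DataFrame:
    """Analysis-ready CABG/complex-PCI cohort straight from the fast path.

    Drops simple-PCI patients, adds the ``arm`` label, per-patient composite
    days censored at the horizon, and the regional-rate instrument. Used by
    estimator validation simulations that do not need episode emission.
    """
    core = generate_core(config)
    coh = core[core["revasc"] != "SIMPLE_PCI"].copy()
    coh["arm"] = coh["revasc"]
    coh["composite_days"] = np.minimum(coh["composite_day"], config.horizon_days)
    g = coh.groupby("region")["treatment"].transform
    coh["instrument"] = g("sum") / g("size")
    return coh


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def oracle_true_ate(config: SimConfig, n_mc: int = 100_000) -> OracleATE:
    """Monte-Carlo ground-truth ATE of the 5-year composite indicator.

    Draws ``n_mc`` fresh patients from the configured population, evaluates
    the composite-event indicator under both arms with common exponential
    draws, and returns the mean difference with its Monte-Carlo SE.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    config.validate()
    rng = derive_rng(config.seed, "oracle")
    U = rng.standard_normal(n_mc)
    cov = _sample_population(config, rng, n_mc)
    z = _centred(config, cov)
    m = _frailty_multiplier(config, _outcome_linpred(config, z), U)
    pot = _potential_days(config, rng, m, _treatment_hr(config, z, n_mc))
    horizon = int(config.horizon_days)
    yt = (np.minimum(pot["death_treated"], pot["hosp_treated"]) <= horizon).astype(float)
    yc = (np.minimum(pot["death_control"], pot["hosp_control"]) <= horizon).astype(float)
    diff = yt - yc
    return OracleATE(float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(n_mc)), n_mc)


def calibrate_control_rate(
    config: SimConfig, target: float = 0.70, n_mc: int = 200_000
) -> tuple[float, float]:
    """Scale the baseline hazards so the factual complex-PCI arm's 5-year
    composite rate equals ``target``; returns the scaled (death, CV-hosp)
    intensities. Used once to build the paper-like preset."""
    rng = derive_rng(config.seed, "calibrate")
    U = rng.standard_normal(n_mc)
    cov = _sample_population(config, rng, n_mc)
    z = _centred(config, cov)
    region_logit = config.region_pref_mean_logit + config.region_pref_spread * rng.standard_normal(
        config.n_regions
    )
    region = rng.integers(0, config.n_regions, size=n_mc)
    logit_p = (
        config.instrument_strength * region_logit[region]
        + _treatment_linpred(config, z)
        - config.confounding_strength * U
    )
    control = rng.random(n_mc) >= expit(logit_p)
    om = config.outcome_model
    u_loghr = config.confounding_strength if om.u_loghr is None else om.u_loghr
    m = np.exp(_outcome_linpred(config, z) + u_loghr * U)[control]
    lam = om.death_rate + om.cv_hosp_rate
    t_years = config.horizon_days / DAYS_PER_YEAR

    def rate(scale: float) -> float:
        return float(np.mean(1.0 - np.exp(-scale * lam * m * t_years))) - target

    s = brentq(rate, 1e-3, 1e3, xtol=1e-10)
    return float(s * om.death_rate), float(s * om.cv_hosp_rate)


# ---------------------------------------------------------------------------
# episode emission
# ---------------------------------------------------------------------------

def _assign_violators(config: SimConfig, core: pd.DataFrame, rng: np.random.Generator) -> pd.Series:
    """Disjoint per-type violator assignment among CABG/complex-PCI patients."""
    vtype = pd.Series([""] * len(core), index=core.index, dtype=object)
    eligible_pool = core.index[core["revasc"].isin(["CABG", "COMPLEX_PCI"])].to_numpy()
    n_arm = len(eligible_pool)
    order = rng.permutation(eligible_pool)
    start = 0
    for kind in VIOLATOR_TYPES:
        k = int(round(config.violator_rates.get(kind, 0.0) * n_arm))
        vtype.loc[order[start : start + k]] = kind
        start += k
    return vtype


def generate_hes_like(config: SimConfig) -> SyntheticDataset:
    """Emit episode/death/truth tables for the configured population."""
    config.validate()
    core = generate_core(config)
    rng = derive_rng(config.seed, "episodes")
    horizon = int(config.horizon_days)
    vtype = _assign_violators(config, core, rng)

    episodes: list[dict] = []
    deaths: list[dict] = []
    eid = 0

    def emit(
        pid: int,
        row,
        adm: int,
        dis: int,
        primary: str,
        secondaries: list[str],
        procs: list[tuple[str, int]],
    ) -> None:
        nonlocal eid
        episodes.append(
            {
                "episode_id": eid,
                "patient_id": pid,
                "admission_date": int(adm),
                "discharge_date": int(dis),
                "primary_diagnosis": primary,
                "secondary_diagnoses": "|".join(secondaries[:19]),
                "procedures": "|".join(f"{c}@{int(d)}" for c, d in procs),
                "region": int(row.region),
                "age_at_admission": float(row.age),
                "sex": row.sex,
                "ethnicity": row.ethnicity,
                "deprivation": float(row.imd) if np.isfinite(row.imd) else np.nan,
            }
        )
        eid += 1

    for row in core.itertuples(index=False):
        pid = int(row.patient_id)
        idx = int(row.index_date)
        los = int(row.index_los)
        kind = vtype.iloc[pid]
        comorb_codes = [COMORBIDITY_CODE[c] for c in COMORBIDITIES if getattr(row, c) == 1]

        # qualifying HF admission inside (stale_hf: outside) the 2-year lookback
        if kind == "stale_hf":
            hf_offset = int(rng.integers(731, 1200))
        else:
            hf_offset = int(rng.integers(31, 701))
        hf_adm = idx - hf_offset
        emit(
            pid,
            row,
            hf_adm,
            hf_adm + int(rng.integers(1, 15)),
            str(rng.choice(HF_PRIMARY)),
            comorb_codes,
            [],
        )

        # occasional unrelated lookback admission
        if rng.random() < 0.4:
            off = int(rng.integers(40, 720))
            emit(
                pid,
                row,
                idx - off,
                idx - off + int(rng.integers(1, 8)),
                str(rng.choice(NOISE_PRIMARY)),
                [],
                [],
            )

        # violator edits in the lookback (or the year after, for maternal)
        if kind in ("recent_mi", "cardiogenic_shock", "valve_surgery", "bleeding_risk", "maternal"):
            code = VIOLATOR_CODE[kind]
            if kind == "recent_mi":
                off = int(rng.integers(1, 31))
            elif kind == "cardiogenic_shock":
                off = int(rng.integers(1, 8))
            elif kind == "maternal":  # protocol window is +/- 1 year
                off = int(rng.integers(1, 366))
            else:
                off = int(rng.integers(10, 731))
            adm = idx - off
            if kind == "maternal" and rng.random() < 0.5 and int(row.death_day) > 40:
                adm = idx + int(rng.integers(1, min(365, int(row.death_day) - 2) + 1))
            procs = [(code, adm)] if kind == "valve_surgery" else []
            primary = code if kind != "valve_surgery" else str(rng.choice(NOISE_PRIMARY))
            emit(pid, row, adm, adm + int(rng.integers(1, 8)), primary, [], procs)

        # index revascularization episode(s)
        if row.revasc == "CABG":
            emit(
                pid,
                row,
                idx,
                idx + los,
                INDEX_PRIMARY,
                comorb_codes,
                [(str(rng.choice(CABG_PROCS)), idx)],
            )
        elif row.revasc == "COMPLEX_PCI":
            variant = rng.choice(["multivessel", "stents", "staged"], p=[0.5, 0.25, 0.25])
            if variant == "staged" and int(row.death_day) <= los + 2:
                variant = "multivessel"  # no room for a second stage before death
            if variant == "multivessel":
                procs = [("K492", idx)]
            elif variant == "stents":
                procs = [("K491", idx), (str(rng.choice(["K752", "K754"])), idx)]
            else:
                procs = [("K491", idx)]
            emit(pid, row, idx, idx + los, INDEX_PRIMARY, comorb_codes, procs)
            if variant == "staged":
                gap = int(rng.integers(los + 1, min(90, int(row.death_day) - 1) + 1))
                emit(pid, row, idx + gap, idx + gap + 2, INDEX_PRIMARY, [], [("K491", idx + gap)])
        else:  # SIMPLE_PCI
            emit(pid, row, idx, idx + los, INDEX_PRIMARY, comorb_codes, [("K491", idx)])

        # factual follow-up: first CV hospitalization, then noise admissions
        death_day = int(row.death_day)
        if row.hosp_event == 1:
            day = idx + int(row.hosp_day)
            code = str(rng.choice(HOSP_CAUSE_CODE[row.hosp_cause]))
            emit(pid, row, day, day + int(rng.integers(1, 11)), code, [], [])
        n_noise = rng.poisson(0.6)
        last = min(horizon, death_day - 1)
        for _ in range(n_noise):
            if last < los + 2:
                break
            day = idx + int(rng.integers(los + 1, last + 1))
            sec = [str(rng.choice(NOISE_SECONDARY_CV))] if rng.random() < 0.3 else []
            emit(pid, row, day, day + int(rng.integers(1, 6)), str(rng.choice(NOISE_PRIMARY)), sec, [])

        if death_day <= horizon + 365:
            cause = (
                str(rng.choice(CV_DEATH_CODES))
                if row.death_cv == 1
                else str(rng.choice(NONCV_DEATH_CODES))
            )
            deaths.append({"patient_id": pid, "death_date": idx + death_day, "cause": cause})

    episodes_df = pd.DataFrame(episodes).sort_values(["patient_id", "admission_date"], kind="stable")
    episodes_df = episodes_df.reset_index(drop=True)
    deaths_df = pd.DataFrame(deaths, columns=["patient_id", "death_date", "cause"])
    truth = core[
        [
            "patient_id",
            "latent_U",
            "region_pref",
            "potential_event_time_treated",
            "potential_event_time_control",
            "individual_effect",
        ]
    ].copy()
    truth["violator_type"] = vtype.to_numpy()
    return SyntheticDataset(episodes_df, deaths_df, truth, config, core)


# ---------------------------------------------------------------------------
# trial IPD
# ---------------------------------------------------------------------------

def generate_trial_ipd(config: SimConfig) -> pd.DataFrame:
    """STICH-like baseline covariate table (shifted marginals, same schema).

    Shift parameters come from ``config.ipd_shift``: additive years for age,
    additive prevalence shifts (clipped to [0.01, 0.99]) for binaries.
    """
    config.validate()
    rng = derive_rng(config.seed, "ipd")
    n = int(config.n_ipd)
    cm = config.covariate_model
    shift = config.ipd_shift
    age = cm.age_mean + float(shift.get("age", 0.0)) + cm.age_sd * rng.standard_normal(n)
    male_p = float(np.clip(cm.male_frac + shift.get("male", 0.12), 0.01, 0.99))
    male = (rng.random(n) < male_p).astype(np.int64)
    out = {
        "ipd_id": np.arange(n, dtype=np.int64),
        "age": age,
        "male": male,
        "sex": np.where(male == 1, "M", "F"),
    }
    for c in COMORBIDITIES:
        p = float(np.clip(cm.comorbidity_prev[c] + shift.get(c, 0.0), 0.01, 0.99))
        out[c] = (rng.random(n) < p).astype(np.int64)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write episodes/deaths/truth/patients CSVs plus the config YAML."""
    import pathlib

    from trialemu.config import save_config

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("episodes", "deaths", "truth", "patients"):
        p = out / f"{name}.csv"
        getattr(dataset, name).to_csv(p, index=False)
        paths[name] = str(p)
    cfg = out / "sim_config.yaml"
    save_config(dataset.config_echo, cfg)
    paths["config"] = str(cfg)
    return paths
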