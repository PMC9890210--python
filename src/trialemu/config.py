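"""Simulation configuration for the synthetic HES-like generator.

The generator emulates the statistical structure of an English
hospital-episode extract for heart-failure patients undergoing coronary
revascularization:

* patients live in administrative regions whose surgeons differ in their
  preference for CABG over complex PCI (the instrument);
* a latent frailty ``U`` pushes patients towards PCI and towards worse
  outcomes (confounding by indication favouring CABG);
* outcomes arise from competing exponential death and cardiovascular
  hospitalization processes over a 5-year (1826-day) horizon;
* a configurable fraction of patients carry injected protocol violations
  (recent MI, valve surgery, cardiogenic shock, maternal admission,
  bleeding risk, stale heart-failure history) so the eligibility engine's
  exclusion counts are known exactly.

All dates are integer day indices from an arbitrary epoch; 5 years is
1826 days and the comorbidity lookback is 730 days.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = [
    "ConfigError",
    "CovariateModel",
    "OutcomeModel",
    "SimConfig",
    "paper_like_config",
    "load_config",
    "save_config",
]

FIVE_YEARS_DAYS = 1826
LOOKBACK_DAYS = 730

#: binary comorbidity covariates carried by every patient
COMORBIDITIES = (
    "diabetes",
    "hypertension",
    "lipidaemia",
    "ckd",
    "prior_stroke",
    "prior_mi",
    "pvd",
)

ETHNICITY_LEVELS = ("White", "Asian", "Black", "Mixed", "NA")

VIOLATOR_TYPES = (
    "recent_mi",
    "valve_surgery",
    "cardiogenic_shock",
    "maternal",
    "bleeding_risk",
    "stale_hf",
)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class CovariateModel:
    """Marginal baseline-covariate distributions for the simulated population.

    Defaults approximate an elderly revascularized heart-failure population:
    age ~ N(70, 10) years, three-quarters male, deprivation score lognormal
    with median ~18, and comorbidity prevalences in the 2–79% range.
    """

    age_mean: float = 70.0
    age_sd: float = 10.0
    male_frac: float = 0.756
    ethnicity_probs: dict = field(
        default_factory=lambda: {
            "White": 0.832,
            "Asian": 0.066,
            "Black": 0.008,
            "Mixed": 0.016,
            "NA": 0.078,
        }
    )
    imd_log_mean: float = 2.89
    imd_log_sd: float = 0.62
    missing_imd_frac: float = 0.014
    comorbidity_prev: dict = field(
        default_factory=lambda: {
            "diabetes": 0.375,
            "hypertension": 0.789,
            "lipidaemia": 0.615,
            "ckd": 0.210,
            "prior_stroke": 0.021,
            "prior_mi": 0.313,
            "pvd": 0.115,
        }
    )


@dataclass
class OutcomeModel:
    """Competing death / CV-hospitalization exponential outcome processes.

    ``death_rate`` and ``cv_hosp_rate`` are baseline intensities in events
    per year for a reference (covariate-centred, U = 0) control patient.
    ``treatment_loghr`` is the CABG log hazard ratio applied to both
    processes. Covariate log-HRs act on centred covariates (continuous ones
    standardized), so the baseline intensities stay interpretable as
    population-typical control rates. ``u_loghr=None`` means the latent
    frailty enters the log-hazard with coefficient ``confounding_strength``.
    """

    death_rate: float = 0.0862
    cv_hosp_rate: float = 0.1546
    treatment_loghr: float = math.log(0.65)
    covariate_loghr: dict = field(
        default_factory=lambda: {
            "age": 0.35,
            "male": 0.05,
            "imd": 0.08,
            "diabetes": 0.25,
            "hypertension": 0.10,
            "lipidaemia": 0.05,
            "ckd": 0.45,
            "prior_stroke": 0.25,
            "prior_mi": 0.20,
            "pvd": 0.20,
        }
    )
    u_loghr: float | None = None
    cv_death_frac: float = 0.70
    #: optional effect modification: per-covariate additive shifts of the
    #: treatment log-HR, applied to the centred covariates
    treatment_loghr_modifiers: dict = field(default_factory=dict)


def _default_treatment_coefs() -> dict:
    # logit-scale coefficients of P(CABG); negative entries encode
    # "fitter patients get surgery" confounding on measured covariates
    return {
        "intercept": 0.0,
        "age": -0.35,
        "male": 0.10,
        "imd": 0.0,
        "diabetes": -0.15,
        "hypertension": 0.0,
        "lipidaemia": 0.0,
        "ckd": -0.25,
        "prior_stroke": -0.20,
        "prior_mi": 0.15,
        "pvd": 0.0,
    }


def _default_violator_rates() -> dict:
    return {
        "recent_mi": 0.010,
        "valve_surgery": 0.010,
        "cardiogenic_shock": 0.008,
        "maternal": 0.004,
        "bleeding_risk": 0.010,
        "stale_hf": 0.010,
    }


def _default_ipd_shift() -> dict:
    # STICH-like trial participants vs the administrative population:
    # younger, less hypertension/CKD, more documented prior MI
    return {
        "age": -10.0,
        "diabetes": 0.02,
        "hypertension": -0.19,
        "lipidaemia": -0.01,
        "ckd": -0.13,
        "prior_stroke": 0.05,
        "prior_mi": 0.46,
        "pvd": 0.04,
    }


@dataclass
class SimConfig:
    """Full generator configuration; same seed implies bit-identical output."""

    n_patients: int = 20_000
    n_regions: int = 30
    region_pref_mean_logit: float = 0.0
    region_pref_spread: float = 0.9
    instrument_strength: float = 1.0
    confounding_strength: float = 0.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    treatment_model_coefs: dict = field(default_factory=_default_treatment_coefs)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    horizon_days: int = FIVE_YEARS_DAYS
    violator_rates: dict = field(default_factory=_default_violator_rates)
    simple_pci_frac: float = 0.05
    n_ipd: int = 1200
    ipd_shift: dict = field(default_factory=_default_ipd_shift)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if int(self.n_patients) < 1:
            raise ConfigError("n_patients must be >= 1")
        if int(self.n_regions) < 2:
            raise ConfigError("n_regions must be >= 2")
        if int(self.horizon_days) <= 0:
            raise ConfigError("horizon_days must be > 0")
        if not 0.0 <= self.simple_pci_frac <= 1.0:
            raise ConfigError("simple_pci_frac must be in [0, 1]")
        cm = self.covariate_model
        for name, value in (
            ("covariate_model.male_frac", cm.male_frac),
            ("covariate_model.missing_imd_frac", cm.missing_imd_frac),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for k, p in cm.comorbidity_prev.items():
            if k not in COMORBIDITIES:
                raise ConfigError(f"covariate_model.comorbidity_prev has unknown key {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_model.comorbidity_prev[{k!r}] must be in [0, 1]")
        tot = sum(cm.ethnicity_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-6):
            raise ConfigError("covariate_model.ethnicity_probs must sum to 1")
        for k, p in self.violator_rates.items():
            if k not in VIOLATOR_TYPES:
                raise ConfigError(f"violator_rates has unknown key {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"violator_rates[{k!r}] must be in [0, 1]")
        if sum(self.violator_rates.values()) > 1.0:
            raise ConfigError("violator_rates must sum to <= 1")
        om = self.outcome_model
        if om.death_rate < 0 or om.cv_hosp_rate < 0:
            raise ConfigError("outcome_model rates must be >= 0")
        if not 0.0 <= om.cv_death_frac <= 1.0:
            raise ConfigError("outcome_model.cv_death_frac must be in [0, 1]")

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("covariate_model"), dict):
            d["covariate_model"] = CovariateModel(**d["covariate_model"])
        if isinstance(d.get("outcome_model"), dict):
            d["outcome_model"] = OutcomeModel(**d["outcome_model"])
        return cls(**d)

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def paper_like_config(n_patients: int = 20_000, seed: int = 0, **overrides) -> SimConfig:
    """A preset emulating the study conditions of the source cohort.

    * regional CABG preference on the logit scale centred at 1.35 with SD
      0.9, so regional surgical rates span roughly a third to nearly all
      revascularizations with a high mean preference for surgery;
    * active confounding by indication through the latent frailty
      (``confounding_strength=0.6``, frailer patients towards PCI and worse
      outcomes);
    * baseline hazards calibrated so the control (complex PCI) arm's 5-year
      composite event rate is ~70%;
    * CABG log hazard ratio ln(0.65) on both outcome processes.
    """
    base = SimConfig(
        n_patients=n_patients,
        n_regions=overrides.pop("n_regions", 30),
        region_pref_mean_logit=1.35,
        region_pref_spread=0.9,
        instrument_strength=1.0,
        confounding_strength=0.6,
        # calibrated via synthetic.calibrate_control_rate(target=0.70)
        outcome_model=OutcomeModel(death_rate=0.06939, cv_hosp_rate=0.12445),
        seed=seed,
    )
    return base.with_(**overrides) if overrides else base
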