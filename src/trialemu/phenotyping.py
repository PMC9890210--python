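"""Emulated-protocol phenotyping on episode-level admission data.

Implements the emulated trial protocol for CABG vs complex-PCI
revascularization in heart-failure patients:

* index procedure classification from OPCS-4 codes (CABG K40–K46; complex
  PCI as multivessel K492, three-plus stents K752/K754, or staged K49/K50/K75
  within 90 days);
* eligibility screening with day-exact lookback windows (heart-failure
  admission within 2 years; exclusions for recent MI, cardiogenic shock,
  decompensated HF, valve surgery, bleeding risk, maternal admission);
* covariate extraction from the index episode plus a 2-year comorbidity
  lookback (index episode's own diagnoses included);
* outcome ascertainment over a 5-year (1826-day) horizon under two
  diagnosis-coding dialects: hospitalizations matched on the primary
  diagnosis only, or on any of the 20 diagnosis fields.

Codes are matched by prefix on normalized codes (dots stripped, uppercased),
so a 3-character stem such as ``I50`` matches the 4-character HES code
``I501``. All code lists are configurable; the supplementary lists of the
emulated protocol are not public, so the bundled exclusion lists are
deliberately conservative defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from trialemu.config import COMORBIDITIES, FIVE_YEARS_DAYS, LOOKBACK_DAYS
from trialemu.synthetic import SyntheticDataset

__all__ = [
    "CodeLists",
    "DataIntegrityError",
    "EligibilityResult",
    "IndexClassification",
    "default_code_lists",
    "find_index_revascularization",
    "apply_eligibility",
    "ascertain_outcomes",
    "build_cohort",
]

PRIMARY_ONLY = "PRIMARY_ONLY"
PRIMARY_AND_SECONDARY = "PRIMARY_AND_SECONDARY"

OUTCOMES = ("death", "cv_death", "cv_hosp", "mi", "stroke", "hf_hosp", "vte", "composite")


class DataIntegrityError(ValueError):
    """Raised when the input tables are internally inconsistent."""


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def _matches(code: str, prefixes: tuple[str, ...]) -> bool:
    return any(code.startswith(p) for p in prefixes)


@dataclass
class CodeLists:
    """ICD-10 / OPCS-4 prefix lists driving the phenotyping rules."""

    hf: tuple = ("I50",)
    cabg: tuple = ("K40", "K41", "K42", "K43", "K44", "K45", "K46")
    pci_multivessel: tuple = ("K492",)
    pci_three_stents: tuple = ("K752", "K754")
    pci_any: tuple = ("K49", "K50", "K75")
    cv_hospitalization: tuple = ("I",)
    mi: tuple = ("I21", "I22")
    stroke: tuple = ("I60", "I61", "I62", "I63", "I64")
    hf_hosp: tuple = ("I50",)
    vte: tuple = ("I26", "I80", "I81", "I82")
    cv_death: tuple = ("I",)
    # comorbidity covariates (2-year lookback incl. index episode)
    diabetes: tuple = ("E10", "E11")
    hypertension: tuple = ("I10", "I11", "I12", "I13", "I15")
    lipidaemia: tuple = ("E78",)
    ckd: tuple = ("N18",)
    prior_stroke: tuple = ("I60", "I61", "I62", "I63", "I64", "I69")
    prior_mi: tuple = ("I21", "I22", "I252")
    pvd: tuple = ("I73",)
    # exclusions
    cardiogenic_shock: tuple = ("R570",)
    decompensation_procs: tuple = ("E85", "L91", "X56")
    valve_surgery: tuple = tuple(f"K{i}" for i in range(25, 39))
    bleeding_risk: tuple = ("D65", "D66", "D67", "D68", "I85", "K766", "C", "Q282")
    maternal: tuple = ("O",)

    def __post_init__(self) -> None:
        for f in fields(self):
            value = tuple(normalize_code(c) for c in getattr(self, f.name))
            if not value:
                raise ValueError(f"code list {f.name!r} must be non-empty")
            setattr(self, f.name, value)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in asdict(self).items()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodeLists":
        with open(path) as fh:
            return cls(**{k: tuple(v) for k, v in yaml.safe_load(fh).items()})


def default_code_lists() -> CodeLists:
    return CodeLists()


@dataclass
class IndexClassification:
    patient_id: int
    arm: str  # CABG | COMPLEX_PCI | SIMPLE_PCI | NONE
    index_date: int | None
    component_episodes: list = field(default_factory=list)
    cabg_and_pci_codes: bool = False  # audit flag: both code families on one episode


@dataclass
class EligibilityResult:
    patient_id: int
    eligible: bool
    failed_criteria: list

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.failed_criteria) == 0)


# ---------------------------------------------------------------------------
# episode parsing
# ---------------------------------------------------------------------------

@dataclass
class _Episode:
    episode_id: int
    admission: int
    discharge: int
    primary: str
    secondaries: tuple
    procedures: tuple  # of (code, date)
    region: int
    age: float
    sex: str
    ethnicity: str
    deprivation: float

    def diagnoses(self, dialect: str) -> tuple:
        if dialect == PRIMARY_ONLY:
            return (self.primary,)
        return (self.primary, *self.secondaries)

    def all_diagnoses(self) -> tuple:
        return (self.primary, *self.secondaries)


def _parse_episode_row(row) -> _Episode:
    secs = tuple(normalize_code(c) for c in str(row.secondary_diagnoses).split("|") if c) if isinstance(
        row.secondary_diagnoses, str
    ) and row.secondary_diagnoses else ()
    procs = ()
    if isinstance(row.procedures, str) and row.procedures:
        procs = tuple(
            (normalize_code(p.split("@")[0]), int(p.split("@")[1])) for p in row.procedures.split("|")
        )
    if len(secs) > 19:
        raise DataIntegrityError(f"episode {row.episode_id} has more than 19 secondary diagnoses")
    if row.discharge_date < row.admission_date:
        raise DataIntegrityError(f"episode {row.episode_id} discharged before admission")
    return _Episode(
        int(row.episode_id),
        int(row.admission_date),
        int(row.discharge_date),
        normalize_code(row.primary_diagnosis),
        secs,
        procs,
        int(row.region),
        float(row.age_at_admission),
        str(row.sex),
        str(row.ethnicity),
        float(row.deprivation) if pd.notna(row.deprivation) else np.nan,
    )


def _episodes_by_patient(episodes: pd.DataFrame) -> dict[int, list[_Episode]]:
    out: dict[int, list[_Episode]] = {}
    for row in episodes.itertuples(index=False):
        out.setdefault(int(row.patient_id), []).append(_parse_episode_row(row))
    for eps in out.values():
        eps.sort(key=lambda e: (e.admission, e.episode_id))
    return out


# ---------------------------------------------------------------------------
# index classification
# ---------------------------------------------------------------------------

def find_index_revascularization(
    episodes: list[_Episode] | pd.DataFrame, code_lists: CodeLists, patient_id: int | None = None
) -> IndexClassification:
    """Classify the first revascularization into CABG / complex / simple PCI.

    The first episode carrying any revascularization procedure determines
    candidacy. CABG codes take precedence over PCI codes on the same episode
    (audit-flagged). A PCI is complex if it is multivessel (K492), deploys
    three or more stents (K752/K754), or a second K49/K50/K75 episode occurs
    within 90 days inclusive; the staged index date is the first PCI date.
    """
    if isinstance(episodes, pd.DataFrame):
        by_pat = _episodes_by_patient(episodes)
        if len(by_pat) != 1:
            raise ValueError("expected episodes of exactly one patient")
        ((patient_id, episodes),) = by_pat.items()
    pid = int(patient_id) if patient_id is not None else -1

    def revasc_procs(ep: _Episode) -> list[tuple[str, int]]:
        return [
            (c, d)
            for c, d in ep.procedures
            if _matches(c, code_lists.cabg) or _matches(c, code_lists.pci_any)
        ]

    for i, ep in enumerate(episodes):
        procs = revasc_procs(ep)
        if not procs:
            continue
        cabg = [(c, d) for c, d in procs if _matches(c, code_lists.cabg)]
        pci = [(c, d) for c, d in procs if _matches(c, code_lists.pci_any)]
        if cabg:
            return IndexClassification(
                pid, "CABG", min(d for _, d in cabg), [ep.episode_id], bool(pci)
            )
        index_date = min(d for _, d in pci)
        if any(
            _matches(c, code_lists.pci_multivessel) or _matches(c, code_lists.pci_three_stents)
            for c, _ in pci
        ):
            return IndexClassification(pid, "COMPLEX_PCI", index_date, [ep.episode_id])
        for later in episodes[i + 1 :]:
            later_pci = [
                (c, d) for c, d in later.procedures if _matches(c, code_lists.pci_any)
            ]
            if later_pci:
                gap = min(d for _, d in later_pci) - index_date
                if gap <= 90:  # inclusive of day 90
                    return IndexClassification(
                        pid, "COMPLEX_PCI", index_date, [ep.episode_id, later.episode_id]
                    )
                break
        return IndexClassification(pid, "SIMPLE_PCI", index_date, [ep.episode_id])
    return IndexClassification(pid, "NONE", None, [])


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def _any_dx_in_window(
    episodes: Iterable[_Episode], prefixes: tuple, lo: int, hi: int
) -> bool:
    """True if any admission in [lo, hi] carries a diagnosis in ``prefixes``."""
    return any(
        lo <= ep.admission <= hi and any(_matches(c, prefixes) for c in ep.all_diagnoses())
        for ep in episodes
    )


def apply_eligibility(
    episodes: list[_Episode], index: IndexClassification, code_lists: CodeLists
) -> EligibilityResult:
    """Evaluate every protocol rule (no short-circuiting) against the history.

    Lookbacks run backward from the index date; "within N days" windows are
    inclusive of day N and exclusive of the index day itself.
    """
    if index.arm not in ("CABG", "COMPLEX_PCI"):
        raise ValueError(f"eligibility requires a CABG/COMPLEX_PCI index, got {index.arm}")
    idx = int(index.index_date)
    failed: list[str] = []

    if not _any_dx_in_window(episodes, code_lists.hf, idx - LOOKBACK_DAYS, idx - 1):
        failed.append("no_hf_admission_2y")
    if _any_dx_in_window(episodes, code_lists.mi, idx - 30, idx - 1):
        failed.append("mi_within_30d")
    if _any_dx_in_window(episodes, code_lists.cardiogenic_shock, idx - 7, idx - 1):
        failed.append("shock_within_7d")
    decompensated = any(
        idx - 2 <= ep.admission <= idx - 1
        and any(_matches(c, code_lists.hf) for c in ep.all_diagnoses())
        and any(_matches(c, code_lists.decompensation_procs) for c, _ in ep.procedures)
        for ep in episodes
    )
    if decompensated:
        failed.append("decompensated_hf_2d")
    valve = any(
        any(
            _matches(c, code_lists.valve_surgery) and idx - LOOKBACK_DAYS <= d <= idx - 1
            for c, d in ep.procedures
        )
        for ep in episodes
    )
    if valve:
        failed.append("valve_surgery_2y")
    if _any_dx_in_window(episodes, code_lists.bleeding_risk, idx - LOOKBACK_DAYS, idx - 1):
        failed.append("bleeding_risk_2y")
    if _any_dx_in_window(episodes, code_lists.maternal, idx - 365, idx + 365):
        failed.append("maternal_admission")

    return EligibilityResult(index.patient_id, not failed, failed)


# ---------------------------------------------------------------------------
# outcome ascertainment
# ---------------------------------------------------------------------------

def ascertain_outcomes(
    episodes: list[_Episode],
    death: tuple[int, str] | None,
    index: IndexClassification,
    code_lists: CodeLists,
    dialect: str = PRIMARY_ONLY,
    horizon: int = FIVE_YEARS_DAYS,
) -> dict:
    """Event indicators and days-from-index for the eight trial outcomes.

    Hospitalization outcomes start the day after the index date (day
    ``index+1`` onward); MI follow-up starts from the first admission after
    the index episode's discharge (an MI code can be the indication for the
    revascularization itself); deaths come from the death registry regardless
    of hospitalization. Component episodes of the index classification are
    never counted as outcomes. Non-events are censored at the horizon.
    """
    if dialect not in (PRIMARY_ONLY, PRIMARY_AND_SECONDARY):
        raise ValueError(f"unknown dialect {dialect!r}")
    idx = int(index.index_date)
    component = set(index.component_episodes)
    index_episode = next(e for e in episodes if e.episode_id == index.component_episodes[0])

    followup = [
        e
        for e in episodes
        if e.episode_id not in component and idx + 1 <= e.admission <= idx + horizon
    ]

    def first_hosp(prefixes: tuple, start_after_discharge: bool = False) -> tuple[int, int]:
        for ep in followup:
            if start_after_discharge and ep.admission <= index_episode.discharge:
                continue
            if any(_matches(c, prefixes) for c in ep.diagnoses(dialect)):
                return 1, ep.admission - idx
        return 0, horizon

    out: dict = {}
    death_event, death_days, cv_death = 0, horizon, 0
    if death is not None:
        d_date, cause = death
        delta = int(d_date) - idx
        if delta < 0:
            raise DataIntegrityError(
                f"patient {index.patient_id}: death at {d_date} precedes index {idx}"
            )
        delta = max(delta, 1)  # death on the index day counts from day 1
        if delta <= horizon:
            death_event, death_days = 1, delta
            cv_death = int(_matches(normalize_code(cause), code_lists.cv_death))
    out["death_event"], out["death_days"] = death_event, death_days
    out["cv_death_event"] = cv_death
    out["cv_death_days"] = death_days if cv_death else horizon

    for name, prefixes, after_discharge in (
        ("cv_hosp", code_lists.cv_hospitalization, False),
        ("mi", code_lists.mi, True),
        ("stroke", code_lists.stroke, False),
        ("hf_hosp", code_lists.hf_hosp, False),
        ("vte", code_lists.vte, False),
    ):
        ev, days = first_hosp(prefixes, after_discharge)
        out[f"{name}_event"], out[f"{name}_days"] = ev, days

    comp = int(out["death_event"] or out["cv_hosp_event"])
    times = [t for e, t in ((out["death_event"], out["death_days"]), (out["cv_hosp_event"], out["cv_hosp_days"])) if e]
    out["composite_event"] = comp
    out["composite_days"] = min(times) if times else horizon
    out["dialect"] = dialect
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(
    dataset: SyntheticDataset,
    code_lists: CodeLists | None = None,
    dialect: str = PRIMARY_ONLY,
    horizon: int = FIVE_YEARS_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """One row per eligible patient plus a CONSORT-style attrition log.

    The attrition log counts patients per failed criterion (a patient failing
    several rules appears under each) and totals removed/retained patients.
    """
    code_lists = code_lists or default_code_lists()
    episodes_by_pat = _episodes_by_patient(dataset.episodes)
    pids = dataset.truth["patient_id"]
    if pids.duplicated().any():
        raise DataIntegrityError("duplicate patient ids in truth table")
    deaths = {
        int(r.patient_id): (int(r.death_date), str(r.cause))
        for r in dataset.deaths.itertuples(index=False)
    }

    attrition: dict = {"input_patients": int(len(pids))}

    def bump(key: str) -> None:
        attrition[key] = attrition.get(key, 0) + 1

    rows: list[dict] = []
    for pid in pids.astype(int):
        eps = episodes_by_pat.get(pid, [])
        index = find_index_revascularization(eps, code_lists, patient_id=pid)
        if index.arm == "NONE":
            bump("no_revascularization")
            continue
        if index.arm == "SIMPLE_PCI":
            bump("simple_pci")
            continue
        if index.cabg_and_pci_codes:
            bump("audit_cabg_and_pci_codes")
        elig = apply_eligibility(eps, index, code_lists)
        if not elig.eligible:
            for crit in elig.failed_criteria:
                bump(f"excluded_{crit}")
            bump("excluded_any_criterion")
            continue

        idx = int(index.index_date)
        index_ep = next(e for e in eps if e.episode_id == index.component_episodes[0])
        lookback = [e for e in eps if idx - LOOKBACK_DAYS <= e.admission <= idx]
        row = {
            "patient_id": pid,
            "arm": index.arm,
            "treatment": int(index.arm == "CABG"),
            "index_date": idx,
            "region": index_ep.region,
            "age": index_ep.age,
            "sex": index_ep.sex,
            "male": int(index_ep.sex == "M"),
            "ethnicity": index_ep.ethnicity,
            "imd": index_ep.deprivation,
        }
        for comorb in COMORBIDITIES:
            prefixes = getattr(code_lists, comorb)
            row[comorb] = int(
                any(any(_matches(c, prefixes) for c in ep.all_diagnoses()) for ep in lookback)
            )
        row.update(
            ascertain_outcomes(eps, deaths.get(pid), index, code_lists, dialect, horizon)
        )
        rows.append(row)

    cohort = pd.DataFrame(rows)
    attrition["eligible"] = int(len(cohort))
    attrition["excluded_total"] = attrition["input_patients"] - attrition["eligible"]
    return cohort, attrition
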