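"""Protocol emulation: index classification, day-exact eligibility windows,
outcome ascertainment under both coding dialects, cohort attrition."""

import numpy as np
import pandas as pd
import pytest

from trialemu.config import SimConfig, paper_like_config
from trialemu.phenotyping import (
    PRIMARY_AND_SECONDARY,
    PRIMARY_ONLY,
    DataIntegrityError,
    apply_eligibility,
    ascertain_outcomes,
    build_cohort,
    default_code_lists,
    find_index_revascularization,
    _episodes_by_patient,
)
from trialemu.synthetic import generate_hes_like

CL = default_code_lists()


def make_episodes(specs):
    """Build a one-patient episode table from (adm, dis, primary, secs, procs)."""
    rows = []
    for i, (adm, dis, primary, secs, procs) in enumerate(specs):
        rows.append(
            {
                "episode_id": i,
                "patient_id": 0,
                "admission_date": adm,
                "discharge_date": dis,
                "primary_diagnosis": primary,
                "secondary_diagnoses": "|".join(secs),
                "procedures": "|".join(f"{c}@{d}" for c, d in procs),
                "region": 1,
                "age_at_admission": 70.0,
                "sex": "M",
                "ethnicity": "White",
                "deprivation": 20.0,
            }
        )
    df = pd.DataFrame(rows)
    return _episodes_by_patient(df)[0]


HF_EP = (400, 405, "I509", [], [])  # qualifying HF admission, 600 days before index day 1000


class TestIndexClassification:
    @pytest.mark.parametrize(
        "procs2, gap, expected_arm, expected_index",
        [
            ([("K492", 1000)], None, "COMPLEX_PCI", 1000),  # multivessel
            ([("K491", 1000), ("K752", 1000)], None, "COMPLEX_PCI", 1000),  # 3+ stents
            ([("K491", 1000), ("K754", 1000)], None, "COMPLEX_PCI", 1000),
            ([("K491", 1000)], 80, "COMPLEX_PCI", 1000),  # staged within 90d
            ([("K491", 1000)], 90, "COMPLEX_PCI", 1000),  # boundary: inclusive
            ([("K491", 1000)], 91, "SIMPLE_PCI", 1000),  # just outside
            ([("K491", 1000)], 100, "SIMPLE_PCI", 1000),
            ([("K491", 1000)], None, "SIMPLE_PCI", 1000),
            ([("K401", 1000)], None, "CABG", 1000),
        ],
    )
    def test_pci_complexity_rules(self, procs2, gap, expected_arm, expected_index):
        specs = [HF_EP, (1000, 1003, "I251", [], procs2)]
        if gap is not None:
            specs.append((1000 + gap, 1002 + gap, "I251", [], [("K502", 1000 + gap)]))
        idx = find_index_revascularization(make_episodes(specs), CL, patient_id=0)
        assert idx.arm == expected_arm
        assert idx.index_date == expected_index
        if gap is not None and expected_arm == "COMPLEX_PCI":
            assert len(idx.component_episodes) == 2

    def test_cabg_takes_precedence_on_mixed_episode(self):
        specs = [HF_EP, (1000, 1008, "I251", [], [("K451", 1000), ("K491", 1001)])]
        idx = find_index_revascularization(make_episodes(specs), CL, patient_id=0)
        assert idx.arm == "CABG"
        assert idx.cabg_and_pci_codes

    def test_no_revascularization_is_none_not_error(self):
        idx = find_index_revascularization(make_episodes([HF_EP]), CL, patient_id=0)
        assert idx.arm == "NONE" and idx.index_date is None
        assert find_index_revascularization([], CL, patient_id=0).arm == "NONE"

    def test_first_revascularization_determines_candidacy(self):
        # a simple PCI followed much later by CABG: candidacy set by the PCI
        specs = [
            HF_EP,
            (1000, 1002, "I251", [], [("K491", 1000)]),
            (1400, 1410, "I251", [], [("K401", 1400)]),
        ]
        idx = find_index_revascularization(make_episodes(specs), CL, patient_id=0)
        assert idx.arm == "SIMPLE_PCI"


def _classify(specs):
    eps = make_episodes(specs)
    return eps, find_index_revascularization(eps, CL, patient_id=0)


class TestEligibility:
    INDEX = (1000, 1008, "I251", [], [("K401", 1000)])

    def test_clean_history_is_eligible(self):
        eps, idx = _classify([(900, 905, "I509", [], []), self.INDEX])
        res = apply_eligibility(eps, idx, CL)
        assert res.eligible and res.failed_criteria == []

    def test_stale_hf_history_fails_inclusion(self):
        eps, idx = _classify([(200, 205, "I509", [], []), self.INDEX])  # 800 days prior
        res = apply_eligibility(eps, idx, CL)
        assert "no_hf_admission_2y" in res.failed_criteria

    def test_hf_boundary_exactly_two_years(self):
        eps, idx = _classify([(270, 275, "I509", [], []), self.INDEX])  # exactly 730
        assert apply_eligibility(eps, idx, CL).eligible

    @pytest.mark.parametrize(
        "days_before, should_fail", [(30, True), (31, False), (1, True)]
    )
    def test_mi_window_boundary(self, days_before, should_fail):
        eps, idx = _classify(
            [HF_EP, (1000 - days_before, 1000 - days_before + 2, "I219", [], []), self.INDEX]
        )
        res = apply_eligibility(eps, idx, CL)
        assert ("mi_within_30d" in res.failed_criteria) == should_fail

    @pytest.mark.parametrize("days_before, should_fail", [(7, True), (8, False)])
    def test_shock_window_boundary(self, days_before, should_fail):
        eps, idx = _classify(
            [HF_EP, (1000 - days_before, 1000 - days_before + 1, "R570", [], []), self.INDEX]
        )
        res = apply_eligibility(eps, idx, CL)
        assert ("shock_within_7d" in res.failed_criteria) == should_fail

    def test_valve_surgery_and_bleeding_risk(self):
        eps, idx = _classify(
            [
                HF_EP,
                (500, 505, "J189", [], [("K251", 500)]),
                (600, 602, "D689", [], []),
                self.INDEX,
            ]
        )
        res = apply_eligibility(eps, idx, CL)
        assert "valve_surgery_2y" in res.failed_criteria
        assert "bleeding_risk_2y" in res.failed_criteria

    def test_maternal_admission_window_is_two_sided(self):
        for adm in (700, 1300):  # 300 days before / after
            eps, idx = _classify([HF_EP, (adm, adm + 2, "O800", [], []), self.INDEX])
            assert "maternal_admission" in apply_eligibility(eps, idx, CL).failed_criteria
        eps, idx = _classify([HF_EP, (1400, 1402, "O800", [], []), self.INDEX])  # 400 after
        assert apply_eligibility(eps, idx, CL).eligible

    def test_decompensated_hf_needs_procedure_and_hf_code(self):
        eps, idx = _classify(
            [HF_EP, (998, 999, "I509", [], [("E851", 998)]), self.INDEX]
        )
        assert "decompensated_hf_2d" in apply_eligibility(eps, idx, CL).failed_criteria
        eps, idx = _classify([HF_EP, (998, 999, "I509", [], []), self.INDEX])
        assert apply_eligibility(eps, idx, CL).eligible

    def test_all_rules_evaluated_not_short_circuited(self):
        eps, idx = _classify(
            [(200, 205, "I509", [], []), (980, 982, "I219", [], []), self.INDEX]
        )
        res = apply_eligibility(eps, idx, CL)
        assert set(res.failed_criteria) >= {"no_hf_admission_2y", "mi_within_30d"}

    def test_simple_pci_precondition_error(self):
        eps, idx = _classify([HF_EP, (1000, 1002, "I251", [], [("K491", 1000)])])
        assert idx.arm == "SIMPLE_PCI"
        with pytest.raises(ValueError, match="CABG/COMPLEX_PCI"):
            apply_eligibility(eps, idx, CL)


class TestOutcomes:
    INDEX = (1000, 1008, "I251", [], [("K401", 1000)])

    def test_death_after_horizon_is_censored(self):
        eps, idx = _classify([HF_EP, self.INDEX])
        out = ascertain_outcomes(eps, (1000 + 1900, "I219"), idx, CL)
        assert out["composite_event"] == 0 and out["composite_days"] == 1826
        assert out["death_event"] == 0

    def test_mi_admission_is_both_mi_and_cv_event(self):
        eps, idx = _classify([HF_EP, self.INDEX, (1400, 1404, "I219", [], [])])
        out = ascertain_outcomes(eps, None, idx, CL)
        assert out["mi_event"] == 1 and out["mi_days"] == 400
        assert out["cv_hosp_event"] == 1 and out["cv_hosp_days"] == 400
        assert out["composite_event"] == 1 and out["composite_days"] == 400

    def test_mi_during_index_episode_not_counted(self):
        # admission starting before the index episode's discharge is not
        # "the next admission following the index episode"
        eps, idx = _classify([HF_EP, self.INDEX, (1005, 1012, "I219", [], [])])
        out = ascertain_outcomes(eps, None, idx, CL)
        assert out["mi_event"] == 0
        assert out["cv_hosp_event"] == 1  # CV follow-up starts the day after index

    def test_secondary_position_code_needs_wide_dialect(self):
        eps, idx = _classify([HF_EP, self.INDEX, (1300, 1302, "J189", ["I639"], [])])
        narrow = ascertain_outcomes(eps, None, idx, CL, PRIMARY_ONLY)
        wide = ascertain_outcomes(eps, None, idx, CL, PRIMARY_AND_SECONDARY)
        assert narrow["stroke_event"] == 0
        assert wide["stroke_event"] == 1 and wide["stroke_days"] == 300

    def test_death_before_index_raises(self):
        eps, idx = _classify([HF_EP, self.INDEX])
        with pytest.raises(DataIntegrityError):
            ascertain_outcomes(eps, (900, "I219"), idx, CL)

    def test_cv_death_requires_cv_cause(self):
        eps, idx = _classify([HF_EP, self.INDEX])
        out = ascertain_outcomes(eps, (1500, "C349"), idx, CL)
        assert out["death_event"] == 1 and out["cv_death_event"] == 0

    def test_staged_component_episode_not_an_outcome(self):
        specs = [
            HF_EP,
            (1000, 1002, "I251", [], [("K491", 1000)]),
            (1050, 1052, "I251", [], [("K502", 1050)]),
        ]
        eps, idx = _classify(specs)
        assert idx.arm == "COMPLEX_PCI"
        out = ascertain_outcomes(eps, None, idx, CL)
        assert out["cv_hosp_event"] == 0


def test_dialect_monotonicity_on_generated_data():
    ds = generate_hes_like(paper_like_config(n_patients=400, seed=31))
    narrow, _ = build_cohort(ds, dialect=PRIMARY_ONLY)
    wide, _ = build_cohort(ds, dialect=PRIMARY_AND_SECONDARY)
    merged = narrow.set_index("patient_id").join(
        wide.set_index("patient_id"), rsuffix="_w"
    )
    for outcome in ("cv_hosp", "mi", "stroke", "hf_hosp", "vte", "composite"):
        ev, ev_w = merged[f"{outcome}_event"], merged[f"{outcome}_event_w"]
        assert (ev <= ev_w).all()
        both = (ev == 1) & (ev_w == 1)
        assert (merged.loc[both, f"{outcome}_days_w"] <= merged.loc[both, f"{outcome}_days"]).all()


class TestBuildCohort:
    def test_injected_violators_reappear_exactly(self, paper_ds, paper_cohort):
        _, attrition = paper_cohort
        injected = paper_ds.truth["violator_type"].value_counts().to_dict()
        mapping = {
            "recent_mi": "excluded_mi_within_30d",
            "valve_surgery": "excluded_valve_surgery_2y",
            "cardiogenic_shock": "excluded_shock_within_7d",
            "maternal": "excluded_maternal_admission",
            "bleeding_risk": "excluded_bleeding_risk_2y",
            "stale_hf": "excluded_no_hf_admission_2y",
        }
        for kind, key in mapping.items():
            assert attrition.get(key, 0) == injected.get(kind, 0)

    def test_zero_violators_attrition_only_via_arm(self):
        cfg = SimConfig(
            n_patients=300,
            seed=33,
            violator_rates={k: 0.0 for k in ("recent_mi", "valve_surgery", "stale_hf")},
        )
        ds = generate_hes_like(cfg)
        cohort, attrition = build_cohort(ds)
        assert attrition.get("excluded_any_criterion", 0) == 0
        assert attrition["input_patients"] - len(cohort) == attrition.get("simple_pci", 0)

    def test_cohort_not_larger_than_input(self, paper_ds, paper_cohort):
        cohort, _ = paper_cohort
        assert len(cohort) <= paper_ds.config_echo.n_patients
        assert cohort["patient_id"].is_unique

    def test_arm_partition(self, paper_ds):
        # every patient lands in exactly one classification bucket
        cohort, attrition = build_cohort(paper_ds)
        total = (
            len(cohort)
            + attrition.get("no_revascularization", 0)
            + attrition.get("simple_pci", 0)
            + attrition.get("excluded_any_criterion", 0)
        )
        assert total == attrition["input_patients"]

    def test_duplicate_patient_ids_raise(self, paper_ds):
        import copy

        bad = copy.copy(paper_ds)
        bad.truth = pd.concat([paper_ds.truth, paper_ds.truth.iloc[:1]], ignore_index=True)
        with pytest.raises(DataIntegrityError, match="duplicate"):
            build_cohort(bad)

    def test_roundtrip_matches_core_truth(self, paper_ds, paper_cohort):
        cohort, _ = paper_cohort
        core = paper_ds.patients.set_index("patient_id")
        coh = cohort.set_index("patient_id")
        sub = core.loc[coh.index]
        assert (sub["revasc"] == coh["arm"]).all()
        for c in ("diabetes", "hypertension", "ckd", "prior_mi", "prior_stroke"):
            assert (sub[c] == coh[c]).all()
        assert (sub["composite_event"] == coh["composite_event"]).all()
        ev = coh["composite_event"] == 1
        assert (
            np.minimum(sub.loc[ev, "composite_day"], 1826) == coh.loc[ev, "composite_days"]
        ).all()
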