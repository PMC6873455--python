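"""Index identification, the exclusion cascade, lookback window, small-HRR rule."""

import numpy as np
import pandas as pd
import pytest

from bundlevar.episode_builder import (
    apply_exclusions,
    attach_lookback,
    filter_small_hrrs,
    identify_index_admissions,
)
from tests.conftest import beneficiary, claim


def _bens(*rows):
    return pd.DataFrame([beneficiary(**r) for r in rows])


def _claims(*rows):
    return pd.DataFrame([claim(**r) for r in rows])


class TestIdentify:
    def test_empty_claims_table(self, defs, crosswalk_one_zip):
        cands = identify_index_admissions(
            _claims({}).iloc[:0], _bens({"beneficiary_id": "B1"}), defs, crosswalk_one_zip
        )
        assert cands.empty

    def test_index_codes_only_count_on_inpatient_facility_claims(self, defs, crosswalk_one_zip):
        # six claims; the PHR index code appears on two inpatient facility
        # claims and once on a professional claim -> exactly two candidates
        claims = _claims(
            {"claim_id": "C1", "beneficiary_id": "B1", "procedure_codes": "8151",
             "admission_date": 100, "discharge_date": 104},
            {"claim_id": "C2", "beneficiary_id": "B2", "procedure_codes": "8151",
             "admission_date": 200, "discharge_date": 203},
            {"claim_id": "C3", "beneficiary_id": "B3", "claim_class": "professional",
             "procedure_codes": "8151"},
            {"claim_id": "C4", "beneficiary_id": "B1", "claim_class": "snf"},
            {"claim_id": "C5", "beneficiary_id": "B2", "claim_class": "professional"},
            {"claim_id": "C6", "beneficiary_id": "B3", "admission_date": 50,
             "discharge_date": 52, "procedure_codes": "0000"},
        )
        bens = _bens({"beneficiary_id": "B1"}, {"beneficiary_id": "B2"}, {"beneficiary_id": "B3"})
        cands = identify_index_admissions(claims, bens, defs, crosswalk_one_zip)
        assert len(cands) == 2
        assert set(cands["index_claim_id"]) == {"C1", "C2"}
        assert (cands["procedure"] == "PHR").all()
        assert (cands["hrr_id"] == "HRR000").all()

    def test_claim_matching_two_procedures_yields_flagged_candidates(self, defs, crosswalk_one_zip):
        claims = _claims(
            {"claim_id": "C1", "procedure_codes": "8151|8154",
             "admission_date": 100, "discharge_date": 104},
        )
        cands = identify_index_admissions(claims, _bens({}), defs, crosswalk_one_zip)
        assert sorted(cands["procedure"]) == ["PHR", "PKR"]
        assert (cands["multi_procedure"] == 1).all()

    def test_age_restriction_and_unresolved_zip(self, defs, crosswalk_one_zip):
        claims = _claims(
            {"claim_id": "C1", "beneficiary_id": "B1", "procedure_codes": "8151",
             "admission_date": 100, "discharge_date": 104},
            {"claim_id": "C2", "beneficiary_id": "B2", "procedure_codes": "8151",
             "admission_date": 100, "discharge_date": 104, "provider_zip": "99999"},
        )
        bens = _bens({"beneficiary_id": "B1", "age": 70}, {"beneficiary_id": "B2"})
        cands = identify_index_admissions(claims, bens, defs, crosswalk_one_zip)
        # the 70-year-old never becomes a candidate; the unknown zip is flagged
        assert list(cands["beneficiary_id"]) == ["B2"]
        assert cands["zip_unresolved"].iloc[0] == 1

    def test_missing_race_imputed_from_sponsor(self, defs, crosswalk_one_zip):
        claims = _claims({"claim_id": "C1", "procedure_codes": "8151",
                          "admission_date": 100, "discharge_date": 104})
        cands = identify_index_admissions(
            claims, _bens({"race": "", "sponsor_race": "black"}), defs, crosswalk_one_zip
        )
        assert cands["race"].iloc[0] == "black"


def _candidates(defs, crosswalk, *claim_rows, bens=None):
    claims = _claims(*claim_rows)
    bens = bens if bens is not None else _bens({})
    return identify_index_admissions(claims, bens, defs, crosswalk), bens


class TestExclusions:
    @pytest.mark.parametrize(
        "row, ben_kw, expected",
        [
            ({"procedure_codes": "8151"}, {"dual_coverage": 1}, "dual_coverage"),
            ({"procedure_codes": "8154", "diagnosis_codes": "T100"}, {}, "trauma"),
            ({"procedure_codes": "8106|8107"}, {}, "multilevel_fusion"),
            ({"procedure_codes": "8151", "admission_source": "snf"}, {}, "admitted_from_facility"),
            ({"procedure_codes": "8151", "discharge_status": "died"}, {}, "died_before_discharge"),
            ({"procedure_codes": "8151", "emergent": 1}, {}, "non_elective"),
        ],
    )
    def test_each_rule_fires(self, defs, crosswalk_one_zip, row, ben_kw, expected):
        row = {"claim_id": "C1", "admission_date": 100, "discharge_date": 104, **row}
        cands, bens = _candidates(defs, crosswalk_one_zip, row, bens=_bens(ben_kw))
        episodes, _ = apply_exclusions(cands, bens, defs)
        assert episodes["status"].iloc[0] == "excluded"
        assert episodes["exclusion_reason"].iloc[0] == expected

    def test_trauma_rule_scoped_to_hip_and_knee(self, defs, crosswalk_one_zip):
        # the same trauma diagnosis on a CABG admission does not exclude
        row = {"claim_id": "C1", "procedure_codes": "3610", "diagnosis_codes": "T100",
               "admission_date": 100, "discharge_date": 104}
        cands, bens = _candidates(defs, crosswalk_one_zip, row)
        episodes, _ = apply_exclusions(cands, bens, defs)
        assert episodes["status"].iloc[0] == "included"

    def test_emergent_cabg_enters_case_mix_not_excluded(self, defs, crosswalk_one_zip):
        row = {"claim_id": "C1", "procedure_codes": "3610", "emergent": 1,
               "admission_date": 100, "discharge_date": 104}
        cands, bens = _candidates(defs, crosswalk_one_zip, row)
        episodes, _ = apply_exclusions(cands, bens, defs)
        assert episodes["status"].iloc[0] == "included"
        assert episodes["emergent"].iloc[0] == 1

    def test_first_matching_rule_wins(self, defs, crosswalk_one_zip):
        # dual coverage precedes trauma in the fixed order
        row = {"claim_id": "C1", "procedure_codes": "8154", "diagnosis_codes": "T100",
               "admission_date": 100, "discharge_date": 104}
        cands, bens = _candidates(defs, crosswalk_one_zip, row, bens=_bens({"dual_coverage": 1}))
        episodes, _ = apply_exclusions(cands, bens, defs)
        assert episodes["exclusion_reason"].iloc[0] == "dual_coverage"

    def test_admission_inside_open_window_is_overlapping(self, defs, crosswalk_one_zip):
        cands, bens = _candidates(
            defs, crosswalk_one_zip,
            {"claim_id": "C1", "procedure_codes": "8151", "admission_date": 100,
             "discharge_date": 104},
            {"claim_id": "C2", "procedure_codes": "8154", "admission_date": 150,
             "discharge_date": 153},  # day 46 of C1's window
            {"claim_id": "C3", "procedure_codes": "8154", "admission_date": 300,
             "discharge_date": 303},  # past day 194, opens a new episode
        )
        episodes, _ = apply_exclusions(cands, bens, defs)
        by_claim = episodes.set_index("index_claim_id")
        assert by_claim.loc["C1", "status"] == "included"
        assert by_claim.loc["C2", "exclusion_reason"] == "overlapping_episode"
        assert by_claim.loc["C3", "status"] == "included"

    def test_partition_every_candidate_labeled_once(self, packaged_run):
        episodes = packaged_run["episodes"]
        included = (episodes["status"] == "included").sum()
        excluded = (episodes["status"] == "excluded").sum()
        assert included + excluded == len(episodes)
        assert (episodes.loc[episodes["status"] == "included", "exclusion_reason"] == "").all()
        assert (episodes.loc[episodes["status"] == "excluded", "exclusion_reason"] != "").all()


class TestLookback:
    def _episode_frame(self):
        return pd.DataFrame(
            [{"beneficiary_id": "B1", "index_claim_id": "IDX", "admission_date": 1000}]
        )

    def test_window_boundary_day_183(self):
        claims = _claims(
            {"claim_id": "P1", "claim_class": "professional", "service_date": 1000 - 183,
             "paid_amount": 100.0},
            {"claim_id": "P2", "claim_class": "professional", "service_date": 1000 - 184,
             "paid_amount": 100.0},
        )
        out = attach_lookback(self._episode_frame(), claims)
        assert out["prior_6mo_payments"].iloc[0] == 100.0

    def test_no_prior_claims_gives_zero(self):
        out = attach_lookback(self._episode_frame(), _claims({}).iloc[:0])
        assert out["prior_6mo_payments"].iloc[0] == 0.0

    def test_sums_all_in_window_claims(self):
        claims = _claims(
            {"claim_id": "P1", "claim_class": "professional", "service_date": 950, "paid_amount": 10.0},
            {"claim_id": "P2", "claim_class": "snf", "service_date": 900, "paid_amount": 20.0},
            {"claim_id": "P3", "claim_class": "dme", "service_date": 999, "paid_amount": 30.0},
        )
        out = attach_lookback(self._episode_frame(), claims)
        assert out["prior_6mo_payments"].iloc[0] == 60.0


class TestSmallHRRs:
    def _episodes(self, counts: dict[tuple[str, str], int]) -> pd.DataFrame:
        rows = []
        for (proc, hrr), n in counts.items():
            for i in range(n):
                rows.append({"procedure": proc, "hrr_id": hrr, "status": "included",
                             "exclusion_reason": ""})
        return pd.DataFrame(rows)

    def test_threshold_is_five(self):
        epi = self._episodes({("PHR", "H1"): 5, ("PHR", "H2"): 4})
        out, tally = filter_small_hrrs(epi)
        assert (out.loc[out["hrr_id"] == "H1", "status"] == "included").all()
        assert (out.loc[out["hrr_id"] == "H2", "exclusion_reason"] == "small_hrr").all()
        assert tally.set_index("procedure").loc["PHR", "n_excluded"] == 4

    def test_rule_applies_per_procedure(self):
        epi = self._episodes({("PHR", "H1"): 4, ("PKR", "H1"): 50})
        out, _ = filter_small_hrrs(epi)
        assert (out.loc[out["procedure"] == "PHR", "status"] == "excluded").all()
        assert (out.loc[out["procedure"] == "PKR", "status"] == "included").all()

    def test_no_small_hrrs_leaves_everything(self):
        epi = self._episodes({("PHR", "H1"): 8, ("PKR", "H2"): 6})
        out, tally = filter_small_hrrs(epi)
        assert (out["status"] == "included").all()
        assert (tally["n_excluded"] == 0).all()
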