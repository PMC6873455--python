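"""Identify index admissions and apply eligibility and exclusion rules.

An episode opens at an inpatient facility claim carrying an index procedure
code for a beneficiary aged 18-65, and covers the stay plus 90 days after
discharge.  Candidates are excluded, each with exactly one reason, in a fixed
order so tallies are reproducible:

    dual_coverage, trauma (hip/knee only), multilevel_fusion (spinal fusion
    only), admitted_from_facility (SNF/long-term care/hospice),
    died_before_discharge, non_elective (emergent admission for procedures
    analyzed as elective-only), overlapping_episode

followed by the cohort-level ``small_hrr`` rule: per procedure, episodes in
HRRs with fewer than ``min_count`` included cases are dropped.  A qualifying
admission that starts inside an earlier included episode's 90-day window does
not open a new episode (it is a readmission of the earlier one).

Case-mix fields (age, sex, race with sponsor-race imputation, sponsor rank,
emergency status, DRG weight, Charlson index, cancer management for
colectomy, prior-six-month payments) are attached here for the downstream
cost model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bundlevar.config import (
    EXCLUSION_ORDER,
    FACILITY_ADMISSION_SOURCES,
    ProcedureDefinition,
)

WINDOW_DAYS = 90
LOOKBACK_DAYS = 183


def _codes(cell) -> set[str]:
    if not isinstance(cell, str) or not cell:
        return set()
    return set(cell.split("|"))


def identify_index_admissions(
    claims: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    procedure_defs: dict[str, ProcedureDefinition],
    crosswalk: pd.DataFrame,
) -> pd.DataFrame:
    """Scan inpatient facility claims for index procedure codes.

    Returns one candidate row per (claim, matched procedure definition); a
    claim matching several definitions yields several candidates, each
    flagged ``multi_procedure`` for review.  Candidates are restricted to
    beneficiaries aged 18-65 at admission.  Unresolvable provider zips flag
    the candidate (``zip_unresolved``) rather than dropping it silently.
    """
    ben = beneficiaries.set_index("beneficiary_id").to_dict("index")
    xwalk = crosswalk.set_index("zip").to_dict("index")
    inpatient = claims[claims["claim_class"] == "inpatient_facility"]

    rows = []
    for claim in inpatient.itertuples(index=False):
        proc_codes = _codes(claim.procedure_codes)
        matched = [
            name
            for name, pdef in procedure_defs.items()
            if proc_codes & pdef.index_code_set
        ]
        if not matched:
            continue
        b = ben[claim.beneficiary_id]
        if not 18 <= int(b["age"]) <= 65:
            continue
        xw = xwalk.get(claim.provider_zip)
        race = b["race"] if isinstance(b["race"], str) and b["race"] else ""
        if not race:
            sponsor = b.get("sponsor_race", "")
            race = sponsor if isinstance(sponsor, str) and sponsor else "unknown"
        for name in matched:
            pdef = procedure_defs[name]
            dx = _codes(claim.diagnosis_codes)
            rows.append(
                {
                    "beneficiary_id": claim.beneficiary_id,
                    "procedure": name,
                    "index_claim_id": claim.claim_id,
                    "admission_date": int(claim.admission_date),
                    "discharge_date": int(claim.discharge_date),
                    "provider_zip": claim.provider_zip,
                    "hrr_id": xw["hrr_id"] if xw else "",
                    "wage_index": float(xw["wage_index"]) if xw else np.nan,
                    "zip_unresolved": int(xw is None),
                    "multi_procedure": int(len(matched) > 1),
                    "index_proc_codes": claim.procedure_codes,
                    "index_dx_codes": claim.diagnosis_codes,
                    "admission_source": claim.admission_source,
                    "discharge_status": claim.discharge_status,
                    "emergent": int(claim.emergent),
                    "drg_weight": float(claim.drg_weight) if pd.notna(claim.drg_weight) else np.nan,
                    "age": int(b["age"]),
                    "sex": b["sex"],
                    "race": race,
                    "sponsor_rank_category": b["sponsor_rank_category"],
                    "charlson": int(b["charlson"]),
                    "cancer_management": int(bool(dx & pdef.cancer_flag_codes)),
                }
            )
    candidates = pd.DataFrame(rows)
    if not candidates.empty:
        candidates = candidates.sort_values(
            ["beneficiary_id", "admission_date", "index_claim_id", "procedure"]
        ).reset_index(drop=True)
        candidates.insert(0, "episode_id", [f"E{i:06d}" for i in range(len(candidates))])
    else:
        candidates = pd.DataFrame(columns=["episode_id"])
    return candidates


def apply_exclusions(
    candidates: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    procedure_defs: dict[str, ProcedureDefinition],
    window_days: int = WINDOW_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark every candidate included or excluded with exactly one reason.

    Rules fire in the fixed order of ``EXCLUSION_ORDER``; the first matching
    rule wins.  Returns the labeled episodes and a tally of exclusions by
    procedure and reason (with both episode and patient denominators).
    """
    episodes = candidates.copy()
    if episodes.empty:
        tally = pd.DataFrame(columns=["procedure", "reason", "n_episodes", "n_patients"])
        episodes["status"] = pd.Series(dtype=str)
        episodes["exclusion_reason"] = pd.Series(dtype=str)
        return episodes, tally

    dual = beneficiaries.set_index("beneficiary_id")["dual_coverage"].to_dict()
    reasons = pd.Series("", index=episodes.index, dtype=object)

    for c in episodes.itertuples():
        i = c.Index
        pdef = procedure_defs[c.procedure]
        dx = _codes(c.index_dx_codes)
        pcodes = _codes(c.index_proc_codes)
        if int(dual.get(c.beneficiary_id, 0)):
            reasons[i] = "dual_coverage"
        elif pdef.trauma_exclusion_codes and dx & pdef.trauma_exclusion_codes:
            reasons[i] = "trauma"
        elif pdef.multilevel_fusion_rule and len(pcodes & pdef.index_code_set) >= 2:
            reasons[i] = "multilevel_fusion"
        elif c.admission_source in FACILITY_ADMISSION_SOURCES:
            reasons[i] = "admitted_from_facility"
        elif c.discharge_status == "died":
            reasons[i] = "died_before_discharge"
        elif pdef.elective_only and int(c.emergent):
            reasons[i] = "non_elective"

    # overlapping episodes: first included admission wins, per beneficiary
    for _, grp in episodes.groupby("beneficiary_id", sort=False):
        open_until = None
        for i in grp.sort_values(["admission_date", "index_claim_id", "procedure"]).index:
            if reasons[i]:
                continue
            adm = episodes.at[i, "admission_date"]
            if open_until is not None and adm <= open_until:
                reasons[i] = "overlapping_episode"
            else:
                open_until = episodes.at[i, "discharge_date"] + window_days

    episodes["exclusion_reason"] = reasons
    episodes["status"] = np.where(reasons == "", "included", "excluded")

    tally = _tally(episodes, EXCLUSION_ORDER)
    return episodes, tally


def _tally(episodes: pd.DataFrame, reasons: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for proc, grp in episodes.groupby("procedure"):
        n_epi = len(grp)
        n_pat = grp["beneficiary_id"].nunique()
        for reason in reasons:
            hit = grp[grp["exclusion_reason"] == reason]
            rows.append(
                {
                    "procedure": proc,
                    "reason": reason,
                    "n_episodes": len(hit),
                    "pct_episodes": 100.0 * len(hit) / n_epi if n_epi else 0.0,
                    "n_patients": hit["beneficiary_id"].nunique(),
                    "pct_patients": 100.0 * hit["beneficiary_id"].nunique() / n_pat if n_pat else 0.0,
                }
            )
    return pd.DataFrame(rows)


def attach_lookback(
    episodes: pd.DataFrame,
    claims: pd.DataFrame,
    lookback_days: int = LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Sum each beneficiary's payments in the 183 days before admission.

    The window is ``[admission - lookback_days, admission - 1]``, closed on
    both ends; the index claim itself is never counted.  Amounts are summed as
    supplied, so run this after price standardization to keep the covariate
    free of regional price levels.
    """
    out = episodes.copy()
    by_ben = dict(tuple(claims.groupby("beneficiary_id", sort=False)))
    prior = np.zeros(len(out))
    for k, e in enumerate(out.itertuples(index=False)):
        grp = by_ben.get(e.beneficiary_id)
        if grp is None:
            continue
        lo = e.admission_date - lookback_days
        hi = e.admission_date - 1
        sel = (
            (grp["service_date"] >= lo)
            & (grp["service_date"] <= hi)
            & (grp["claim_id"] != e.index_claim_id)
        )
        prior[k] = grp.loc[sel, "paid_amount"].sum()
    out["prior_6mo_payments"] = prior
    return out


def filter_small_hrrs(
    episodes: pd.DataFrame, min_count: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude episodes in HRRs with fewer than ``min_count`` included cases.

    Applied per procedure: an HRR can keep its knee replacements while losing
    its colectomies.  Returns the updated episodes and a per-procedure tally
    of episodes and HRRs dropped.
    """
    out = episodes.copy()
    rows = []
    for proc, grp in out[out["status"] == "included"].groupby("procedure"):
        counts = grp.groupby("hrr_id").size()
        small = counts[counts < min_count].index
        idx = grp.index[grp["hrr_id"].isin(small)]
        out.loc[idx, "status"] = "excluded"
        out.loc[idx, "exclusion_reason"] = "small_hrr"
        n_proc = len(grp)
        rows.append(
            {
                "procedure": proc,
                "n_excluded": len(idx),
                "pct_excluded": 100.0 * len(idx) / n_proc if n_proc else 0.0,
                "n_hrrs_dropped": len(small),
                "n_hrrs_kept": int((counts >= min_count).sum()),
            }
        )
    return out, pd.DataFrame(rows)


def build_episodes(
    claims: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    crosswalk: pd.DataFrame,
    procedure_defs: dict[str, ProcedureDefinition],
    min_hrr_count: int = 5,
    window_days: int = WINDOW_DAYS,
    lookback_days: int = LOOKBACK_DAYS,
) -> dict:
    """Identification -> exclusions -> lookback -> small-HRR rule, in order.

    ``claims`` should already be price standardized.  Returns a dict with the
    labeled episodes table and both exclusion tallies.
    """
    candidates = identify_index_admissions(claims, beneficiaries, procedure_defs, crosswalk)
    episodes, tally = apply_exclusions(
        candidates, beneficiaries, procedure_defs, window_days=window_days
    )
    episodes = attach_lookback(episodes, claims, lookback_days=lookback_days)
    episodes, small_tally = filter_small_hrrs(episodes, min_count=min_hrr_count)
    return {
        "episodes": episodes,
        "exclusion_tally": tally,
        "small_hrr_tally": small_tally,
        "n_candidates": len(candidates),
    }
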