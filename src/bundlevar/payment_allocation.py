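"""Sort every in-window claim into exactly one of four payment components.

Components: index hospitalization (the index stay plus any facility claim
dated within it), readmissions (inpatient facility stays admitted in days
1-90 after discharge; a stay admitted on day 90 counts in full), post-acute
care (rehab, SNF, outpatient facility, home health, hospice, DME), and
professional fees (clinician claims in any setting — they are never folded
into the facility buckets).  The window rule uses the admission date for
facility claims and the service date otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bundlevar.config import COMPONENTS, KNOWN_CLAIM_CLASSES, POST_ACUTE_CLASSES

WINDOW_DAYS = 90


class UnknownClaimClassError(ValueError):
    """A window claim has a class no bucket accepts."""


@dataclass
class ComponentPayments:
    index_hospitalization: float
    readmissions: float
    post_acute: float
    professional_fees: float

    @property
    def total(self) -> float:
        return (
            self.index_hospitalization
            + self.readmissions
            + self.post_acute
            + self.professional_fees
        )


def _effective_date(claims: pd.DataFrame) -> pd.Series:
    """Facility claims date by admission, everything else by service date."""
    eff = claims["service_date"].astype(float).copy()
    fac = (claims["claim_class"] == "inpatient_facility") & claims["admission_date"].notna()
    eff[fac] = claims.loc[fac, "admission_date"].astype(float)
    return eff


def collect_window_claims(
    episode, claims: pd.DataFrame, window_days: int = WINDOW_DAYS
) -> pd.DataFrame:
    """Return the index claim plus the beneficiary's claims in the 90-day window.

    A claim dated on day 90 after discharge is in; day 91 is out.  Claims
    dated inside the index stay itself (admission..discharge) are part of the
    episode and are collected too (they fold into the index bucket).
    """
    grp = claims[claims["beneficiary_id"] == episode["beneficiary_id"]]
    eff = _effective_date(grp)
    lo, hi = episode["discharge_date"] + 1, episode["discharge_date"] + window_days
    in_window = (eff >= lo) & (eff <= hi)
    in_stay = (eff >= episode["admission_date"]) & (eff <= episode["discharge_date"])
    is_index = grp["claim_id"] == episode["index_claim_id"]
    return grp[is_index | in_window | in_stay].copy()


def bucket_payments(window_claims: pd.DataFrame, index_claim_id: str, discharge_date: int | None = None) -> ComponentPayments:
    """Assign each window claim to exactly one component and total them.

    Raises :class:`UnknownClaimClassError` (listing claim ids) for any claim
    whose class is not recognized — no silent bucket.
    """
    unknown = window_claims[~window_claims["claim_class"].isin(KNOWN_CLAIM_CLASSES)]
    if len(unknown):
        raise UnknownClaimClassError(
            f"claims with unknown class: {unknown['claim_id'].tolist()}"
        )
    paid = window_claims["paid_amount"].to_numpy(dtype=float)
    cls = window_claims["claim_class"]
    is_index = (window_claims["claim_id"] == index_claim_id).to_numpy()
    prof = (cls == "professional").to_numpy()
    post = cls.isin(POST_ACUTE_CLASSES).to_numpy()
    inpatient = (cls == "inpatient_facility").to_numpy()
    # facility claims dated inside the index stay fold into the index bucket
    if discharge_date is not None:
        eff = _effective_date(window_claims).to_numpy()
        in_stay_fac = inpatient & (eff <= discharge_date)
        idx_bucket = is_index | (in_stay_fac & ~is_index)
    else:
        idx_bucket = is_index
    readmit = inpatient & ~idx_bucket
    return ComponentPayments(
        index_hospitalization=float(paid[idx_bucket & ~prof].sum()),
        readmissions=float(paid[readmit & ~prof].sum()),
        post_acute=float(paid[post & ~prof & ~idx_bucket].sum()),
        professional_fees=float(paid[prof].sum()),
    )


def allocate_payments(
    episodes: pd.DataFrame, claims: pd.DataFrame, window_days: int = WINDOW_DAYS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bucket payments for every included episode.

    Returns the episodes table with the four component columns plus ``total``
    added, and an assignment table (claim_id, episode_id, component) that the
    pipeline manifest uses to verify that each claim lands in exactly one
    bucket of exactly one episode.
    """
    out = episodes.copy()
    for comp in COMPONENTS:
        out[comp] = 0.0
    out["total"] = 0.0
    inc = out.loc[
        out["status"] == "included",
        ["episode_id", "beneficiary_id", "index_claim_id", "admission_date", "discharge_date"],
    ]
    if inc.empty:
        return out, pd.DataFrame(columns=["claim_id", "episode_id", "component"])

    m = claims.merge(inc, on="beneficiary_id", how="inner", suffixes=("", "_epi"))
    eff = _effective_date(m).to_numpy()
    disch = m["discharge_date_epi"].to_numpy(float)
    adm = m["admission_date_epi"].to_numpy(float)
    is_index = (m["claim_id"] == m["index_claim_id"]).to_numpy()
    in_window = (eff >= disch + 1) & (eff <= disch + window_days)
    in_stay = (eff >= adm) & (eff <= disch)
    m = m[is_index | in_window | in_stay].copy()
    if m.empty:
        return out, pd.DataFrame(columns=["claim_id", "episode_id", "component"])

    unknown = m[~m["claim_class"].isin(KNOWN_CLAIM_CLASSES)]
    if len(unknown):
        raise UnknownClaimClassError(
            f"claims with unknown class: {sorted(unknown['claim_id'].unique().tolist())}"
        )
    eff = _effective_date(m).to_numpy()
    disch = m["discharge_date_epi"].to_numpy(float)
    is_index = (m["claim_id"] == m["index_claim_id"]).to_numpy()
    prof = (m["claim_class"] == "professional").to_numpy()
    inpatient = (m["claim_class"] == "inpatient_facility").to_numpy()
    comp = np.where(
        prof,
        "professional_fees",
        np.where(
            inpatient,
            np.where(is_index | (eff <= disch), "index_hospitalization", "readmissions"),
            "post_acute",
        ),
    )
    m["component"] = comp
    sums = m.pivot_table(
        index="episode_id", columns="component", values="paid_amount", aggfunc="sum"
    )
    for c in COMPONENTS:
        if c in sums.columns:
            mapped = out["episode_id"].map(sums[c])
            out[c] = mapped.fillna(0.0)
    out["total"] = out[list(COMPONENTS)].sum(axis=1)
    assignments = m[["claim_id", "episode_id", "component"]].reset_index(drop=True)
    return out, assignments


def readmission_rate(episodes: pd.DataFrame) -> pd.Series:
    """Fraction of included episodes with any readmission payment, per procedure."""
    inc = episodes[episodes["status"] == "included"]
    if inc.empty:
        return pd.Series(dtype=float)
    return inc.groupby("procedure").apply(
        lambda g: float(np.mean(g["readmissions"] > 0)), include_groups=False
    )
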