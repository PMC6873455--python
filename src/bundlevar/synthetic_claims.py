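"""Synthetic beneficiary/claims/crosswalk generator with known ground truth.

The generator emulates the structure of purchased-care claims around an index
surgical admission: a facility claim for the index stay, professional claims,
optional inpatient readmissions and post-acute claims inside the 90-day
post-discharge window, and ambulatory claims in the 183-day lookback period.

The cost model is the one the downstream fit assumes.  For episode ``i`` in
region ``j`` the standardized episode total is

    y_ij = exp(x_ij' beta_true) * u_j * eps_ij

with ``u_j ~ Gamma(shape 1/tau, rate 1/tau)`` (mean 1, variance ``tau_true``)
and ``eps_ij`` mean-1 gamma noise with coefficient of variation
``outcome_cv``.  Paid amounts on disk are inflated by the provider zip's wage
index applied to the labor share — exactly what the price standardizer
inverts.  Records that trigger every downstream exclusion rule can be planted
at configurable rates; which episode carries which trigger is recorded in the
ground truth so exclusion recall is checkable.

Dates are integer day offsets from a fixed epoch; only day arithmetic is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bundlevar.config import (
    COMPONENTS,
    POST_ACUTE_CLASSES,
    ProcedureDefinition,
    SimulationConfig,
    default_procedure_defs,
)

GENERIC_INPATIENT_CODE = "9999"  # non-index procedure code for readmission stays

_PLANT_ORDER = (
    "dual_coverage",
    "trauma",
    "multilevel_fusion",
    "admitted_from_facility",
    "died_before_discharge",
    "day91_claim",
)


class ReferentialIntegrityError(ValueError):
    """Population tables and claims generation inputs do not line up."""


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    beta_true: dict[str, float]
    tau_true: float
    u_by_hrr: dict[str, float]
    labor_share: float
    episodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # episodes columns: beneficiary_id, hrr_id, zip, procedure, planted_exclusion,
    # true_expected, realized_total, index_claim_id, day91_claim_id, prior_sum


def _covariate_value(name: str, row: dict) -> float:
    if name == "intercept":
        return 1.0
    if name == "age10":
        return (row["age"] - 45.0) / 10.0
    if name == "female":
        return 1.0 if row["sex"] == "F" else 0.0
    if name == "junior_enlisted":
        return 1.0 if row["sponsor_rank_category"] == "junior_enlisted" else 0.0
    if name == "charlson":
        return float(row["charlson"])
    if name == "drg_weight":
        return float(row["drg_weight"]) - 1.0
    if name == "emergent":
        return float(row["emergent"])
    if name == "cancer":
        return float(row["cancer"])
    raise ValueError(f"configuration error: beta_true has unknown covariate {name!r}")


def generate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw HRRs, wage indices, regional effects, and one beneficiary per episode.

    Each HRR gets one provider zip whose wage index is uniform on
    ``wage_index_range``; regional multiplicative effects ``u_j`` are gamma
    with mean 1 and variance ``tau_true`` (all exactly 1 when ``tau_true=0``).
    When ``confounding_strength > 0`` a latent regional factor shifts the age
    and comorbidity distributions so that case mix is correlated with region.
    Returns the beneficiary table, the zip->HRR/wage-index crosswalk, and the
    ground truth.  Reproducible for a fixed config (including seed).
    """
    rng = np.random.default_rng([config.seed, 0])
    defs = default_procedure_defs()
    unknown = [p for p in config.procedures if p not in defs]
    if unknown:
        raise ValueError(f"configuration error: unknown procedures {unknown}")

    hrr_ids = [f"HRR{j:03d}" for j in range(config.n_hrrs)]
    zips = [f"{10000 + j}" for j in range(config.n_hrrs)]
    wage_index = rng.uniform(*config.wage_index_range, size=config.n_hrrs)
    crosswalk = pd.DataFrame(
        {"zip": zips, "hrr_id": hrr_ids, "wage_index": np.round(wage_index, 4)}
    )

    if config.tau_true > 0:
        shape = 1.0 / config.tau_true
        u = rng.gamma(shape, scale=config.tau_true, size=config.n_hrrs)
    else:
        u = np.ones(config.n_hrrs)
    u_by_hrr = dict(zip(hrr_ids, u))

    # latent regional factor driving case-mix confounding
    z_conf = rng.standard_normal(config.n_hrrs) if config.confounding_strength > 0 else np.zeros(config.n_hrrs)

    n_small = int(round(config.small_hrr_fraction * config.n_hrrs))
    small_hrrs = set(rng.choice(config.n_hrrs, size=n_small, replace=False)) if n_small else set()

    ben_rows: list[dict] = []
    epi_rows: list[dict] = []
    races = np.array(["white", "black", "other"])
    bid = 0
    for j in range(config.n_hrrs):
        if j in small_hrrs:
            n_epi = int(rng.integers(1, 5))
        elif isinstance(config.episodes_per_hrr, tuple):
            n_epi = int(rng.integers(config.episodes_per_hrr[0], config.episodes_per_hrr[1] + 1))
        else:
            n_epi = config.episodes_per_hrr
        c = config.confounding_strength
        age_mean = 45.0 + 10.0 * c * z_conf[j]
        charlson_lam = 0.5 * np.exp(c * z_conf[j])
        for _ in range(n_epi):
            bid += 1
            age = int(np.clip(round(rng.normal(age_mean, 11.0)), 20, 64))
            sex = "F" if rng.random() < 0.45 else "M"
            race = str(rng.choice(races, p=[0.6, 0.2, 0.2]))
            sponsor_race = race
            if rng.random() < 0.05:  # missing race, recoverable from sponsor
                race = ""
            rank = "junior_enlisted" if rng.random() < 0.30 else "other"
            charlson = int(min(rng.poisson(charlson_lam), 6))
            procedure = str(rng.choice(config.procedures))
            pdef = defs[procedure]

            planted = "none"
            if j in small_hrrs:
                planted = "small_hrr"
            else:
                for reason in _PLANT_ORDER:
                    rate = config.exclusion_rates.get(reason, 0.0)
                    if rate <= 0:
                        continue
                    if reason == "trauma" and not pdef.trauma_exclusion_codes:
                        continue
                    if reason == "multilevel_fusion" and not pdef.multilevel_fusion_rule:
                        continue
                    if rng.random() < rate:
                        planted = reason
                        break

            drg_weight = (
                float(np.round(rng.lognormal(0.0, 0.25), 3)) if pdef.uses_drg_weight else 1.0
            )
            emergent = int(not pdef.elective_only and rng.random() < 0.20)
            cancer = int(bool(pdef.cancer_flag_codes) and rng.random() < 0.40)

            ben_rows.append(
                {
                    "beneficiary_id": f"B{bid:06d}",
                    "age": age,
                    "sex": sex,
                    "race": race,
                    "sponsor_race": sponsor_race,
                    "sponsor_rank_category": rank,
                    "charlson": charlson,
                    "dual_coverage": int(planted == "dual_coverage"),
                }
            )
            epi_rows.append(
                {
                    "beneficiary_id": f"B{bid:06d}",
                    "hrr_id": hrr_ids[j],
                    "zip": zips[j],
                    "procedure": procedure,
                    "planted_exclusion": planted,
                    "drg_weight": drg_weight,
                    "emergent": emergent,
                    "cancer": cancer,
                }
            )

    beneficiaries = pd.DataFrame(ben_rows)
    episodes = pd.DataFrame(epi_rows)

    # true expected standardized cost per episode (known at design time)
    ben_lookup = beneficiaries.set_index("beneficiary_id")
    xb = np.zeros(len(episodes))
    for i, erow in enumerate(episodes.itertuples(index=False)):
        row = ben_lookup.loc[erow.beneficiary_id].to_dict()
        row.update({"drg_weight": erow.drg_weight, "emergent": erow.emergent, "cancer": erow.cancer})
        xb[i] = sum(b * _covariate_value(name, row) for name, b in config.beta_true.items())
    episodes["true_expected"] = np.exp(xb) * episodes["hrr_id"].map(u_by_hrr).to_numpy()

    truth = GroundTruth(
        beta_true=dict(config.beta_true),
        tau_true=config.tau_true,
        u_by_hrr=u_by_hrr,
        labor_share=config.labor_share,
        episodes=episodes,
    )
    return beneficiaries, crosswalk, truth


def _split_cents(total_cents: int, weights: list[float]) -> list[int]:
    """Largest-remainder split of an integer cent amount; parts sum exactly."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total_cents
    parts = np.floor(raw).astype(int)
    rem = total_cents - parts.sum()
    order = np.argsort(-(raw - parts))
    parts[order[:rem]] += 1
    return parts.tolist()


def generate_claims(
    config: SimulationConfig,
    population: tuple[pd.DataFrame, pd.DataFrame, GroundTruth],
) -> pd.DataFrame:
    """Generate the claims table for a population; fills realized ground truth.

    Each episode gets an index inpatient facility claim, two professional
    claims, a Bernoulli(``readmission_prob``) inpatient readmission admitted
    uniformly in days 1-90 after discharge, Poisson(``postacute_claim_rate``)
    post-acute claims, and Poisson-many lookback claims in the 183 days before
    admission.  The realized episode total (index + readmission + post-acute +
    professional, standardized scale) is split across components in exact
    cents; amounts on the claims table are wage-inflated.

    Mutates ``population``'s ground truth in place (realized totals, claim
    ids, planted-trigger claim ids, lookback sums) and returns the claims
    table.
    """
    beneficiaries, crosswalk, truth = population
    episodes = truth.episodes
    if episodes.empty or not set(episodes["beneficiary_id"]) <= set(beneficiaries["beneficiary_id"]):
        raise ReferentialIntegrityError("episode plan does not match beneficiary table")
    if not set(episodes["zip"]) <= set(crosswalk["zip"]):
        raise ReferentialIntegrityError("episode zips missing from crosswalk")

    rng = np.random.default_rng([config.seed, 1])
    defs = default_procedure_defs()
    wage = crosswalk.set_index("zip")["wage_index"]
    ls = config.labor_share
    mix = {c: config.component_mix.get(c, 0.0) for c in COMPONENTS}
    pa_classes = sorted(POST_ACUTE_CLASSES)

    claims: list[dict] = []
    cid = 0

    def new_claim(**kw) -> str:
        nonlocal cid
        cid += 1
        claim_id = f"C{cid:07d}"
        base = {
            "claim_id": claim_id,
            "beneficiary_id": "",
            "claim_class": "",
            "service_date": 0,
            "admission_date": np.nan,
            "discharge_date": np.nan,
            "provider_zip": "",
            "paid_amount": 0.0,
            "procedure_codes": "",
            "diagnosis_codes": "",
            "drg_weight": np.nan,
            "admission_source": "",
            "discharge_status": "",
            "emergent": 0,
        }
        base.update(kw)
        claims.append(base)
        return claim_id

    realized_total = np.zeros(len(episodes))
    index_ids: list[str] = []
    day91_ids: list[str] = []
    prior_sums = np.zeros(len(episodes))

    if config.outcome_cv > 0:
        k = 1.0 / config.outcome_cv**2
        noise = rng.gamma(k, scale=1.0 / k, size=len(episodes))
    else:
        noise = np.ones(len(episodes))

    for i, epi in enumerate(episodes.itertuples(index=False)):
        pdef: ProcedureDefinition = defs[epi.procedure]
        zip_code = epi.zip
        factor = ls * float(wage.loc[zip_code]) + (1.0 - ls)
        admission = int(rng.integers(300, 1001))
        discharge = admission + int(rng.integers(3, 9))
        planted = epi.planted_exclusion

        total = epi.true_expected * noise[i]
        total_cents = int(round(total * 100))
        realized_total[i] = total_cents / 100.0

        has_readmit = rng.random() < config.readmission_prob
        n_postacute = int(rng.poisson(config.postacute_claim_rate))

        active = {
            "index_hospitalization": mix["index_hospitalization"],
            "professional_fees": mix["professional_fees"],
            "readmissions": mix["readmissions"] if has_readmit else 0.0,
            "post_acute": mix["post_acute"] if n_postacute > 0 else 0.0,
        }
        parts = dict(
            zip(COMPONENTS, _split_cents(total_cents, [active[c] for c in COMPONENTS]))
        )

        # index facility claim
        codes = [sorted(pdef.index_code_set)[0]]
        dx = []
        if planted == "trauma":
            dx.append(sorted(pdef.trauma_exclusion_codes)[0])
        if planted == "multilevel_fusion":
            codes.append(sorted(pdef.index_code_set)[1])
        if epi.cancer:
            dx.append(sorted(pdef.cancer_flag_codes)[0])
        index_id = new_claim(
            beneficiary_id=epi.beneficiary_id,
            claim_class="inpatient_facility",
            service_date=admission,
            admission_date=admission,
            discharge_date=discharge,
            provider_zip=zip_code,
            paid_amount=parts["index_hospitalization"] / 100.0 * factor,
            procedure_codes="|".join(codes),
            diagnosis_codes="|".join(dx),
            drg_weight=epi.drg_weight if pdef.uses_drg_weight else np.nan,
            admission_source=(
                str(rng.choice(["snf", "ltc", "hospice"]))
                if planted == "admitted_from_facility"
                else "home"
            ),
            discharge_status="died" if planted == "died_before_discharge" else "home",
            emergent=int(epi.emergent),
        )
        index_ids.append(index_id)

        # professional fees: one claim at surgery, one in the follow-up window
        prof_parts = _split_cents(parts["professional_fees"], [0.6, 0.4])
        for amt_cents, day in zip(
            prof_parts, (admission, discharge + int(rng.integers(1, 31)))
        ):
            new_claim(
                beneficiary_id=epi.beneficiary_id,
                claim_class="professional",
                service_date=day,
                provider_zip=zip_code,
                paid_amount=amt_cents / 100.0 * factor,
            )

        if has_readmit:
            re_adm = discharge + int(rng.integers(1, 91))
            new_claim(
                beneficiary_id=epi.beneficiary_id,
                claim_class="inpatient_facility",
                service_date=re_adm,
                admission_date=re_adm,
                discharge_date=re_adm + int(rng.integers(2, 6)),
                provider_zip=zip_code,
                paid_amount=parts["readmissions"] / 100.0 * factor,
                procedure_codes=GENERIC_INPATIENT_CODE,
                admission_source="home",
                discharge_status="home",
            )

        if n_postacute > 0:
            pa_parts = _split_cents(parts["post_acute"], [1.0] * n_postacute)
            for amt_cents in pa_parts:
                new_claim(
                    beneficiary_id=epi.beneficiary_id,
                    claim_class=str(rng.choice(pa_classes)),
                    service_date=discharge + int(rng.integers(1, 91)),
                    provider_zip=zip_code,
                    paid_amount=amt_cents / 100.0 * factor,
                )

        day91_id = ""
        if planted == "day91_claim":
            day91_id = new_claim(
                beneficiary_id=epi.beneficiary_id,
                claim_class="outpatient_facility",
                service_date=discharge + 91,
                provider_zip=zip_code,
                paid_amount=123.45 * factor,
            )
        day91_ids.append(day91_id)

        n_prior = int(rng.poisson(2.0))
        prior = 0.0
        for _ in range(n_prior):
            amt = round(float(rng.lognormal(5.0, 0.5)), 2)
            prior += amt
            new_claim(
                beneficiary_id=epi.beneficiary_id,
                claim_class=str(rng.choice(["outpatient_facility", "professional"])),
                service_date=admission - int(rng.integers(1, 184)),
                provider_zip=zip_code,
                paid_amount=amt * factor,
            )
        prior_sums[i] = round(prior, 2)

    episodes["realized_total"] = realized_total
    episodes["index_claim_id"] = index_ids
    episodes["day91_claim_id"] = day91_ids
    episodes["prior_sum"] = prior_sums

    return pd.DataFrame(claims)


def simulate(config: SimulationConfig) -> dict:
    """Run the full generator; returns dict of tables plus ground truth."""
    population = generate_population(config)
    claims = generate_claims(config, population)
    beneficiaries, crosswalk, truth = population
    return {
        "beneficiaries": beneficiaries,
        "crosswalk": crosswalk,
        "claims": claims,
        "truth": truth,
    }
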