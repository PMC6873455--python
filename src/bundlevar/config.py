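"""Configuration models for the simulation and the analysis pipeline.

All knobs that the analysis stages consume live here as validated pydantic
models so that a malformed configuration fails loudly, naming the field,
before any data are touched.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: payment component labels, in reporting order
COMPONENTS = ("index_hospitalization", "readmissions", "post_acute", "professional_fees")

#: claim classes that count as post-acute care
POST_ACUTE_CLASSES = frozenset(
    {"rehab", "snf", "outpatient_facility", "home_health", "hospice", "dme"}
)

#: all claim classes the pipeline understands
KNOWN_CLAIM_CLASSES = POST_ACUTE_CLASSES | {"inpatient_facility", "professional"}

#: admission sources that trigger the facility-admission exclusion
FACILITY_ADMISSION_SOURCES = frozenset({"snf", "ltc", "hospice"})

#: exclusion reasons in the order they are applied (small_hrr is applied last,
#: at the cohort level, after the per-candidate rules)
EXCLUSION_ORDER = (
    "dual_coverage",
    "trauma",
    "multilevel_fusion",
    "admitted_from_facility",
    "died_before_discharge",
    "non_elective",
    "overlapping_episode",
)

ALL_EXCLUSION_REASONS = EXCLUSION_ORDER + ("small_hrr",)


class ProcedureDefinition(BaseModel):
    """Code sets and rules that define one index procedure.

    ``index_code_set`` holds the procedure codes whose presence on an inpatient
    facility claim opens a candidate episode.  For spinal fusion the index
    codes are level-specific, so two distinct index codes on one claim is the
    operational signature of a multi-level fusion.
    """

    name: str
    index_code_set: set[str]
    trauma_exclusion_codes: set[str] = set()
    multilevel_fusion_rule: bool = False
    cancer_flag_codes: set[str] = set()
    elective_only: bool = True
    uses_drg_weight: bool = False

    @field_validator("index_code_set")
    @classmethod
    def _nonempty(cls, v: set[str]) -> set[str]:
        if not v:
            raise ValueError("index_code_set must be non-empty")
        return v


def default_procedure_defs() -> dict[str, ProcedureDefinition]:
    """Illustrative definitions for the five study procedures.

    The code values are placeholders with the right structure (the real code
    lists are configuration inputs); the rules attached to each procedure are
    the analytic ones: trauma exclusion for hip and knee replacement,
    multi-level detection for spinal fusion, cancer-management flag for
    colectomy, and emergent admissions entering case mix (rather than being
    excluded) for CABG and colectomy only.
    """
    return {
        "PHR": ProcedureDefinition(
            name="PHR",
            index_code_set={"8151"},
            trauma_exclusion_codes={"T100", "T101"},
        ),
        "PKR": ProcedureDefinition(
            name="PKR",
            index_code_set={"8154"},
            trauma_exclusion_codes={"T100", "T101"},
        ),
        "CABG": ProcedureDefinition(
            name="CABG",
            index_code_set={"3610", "3611", "3612"},
            elective_only=False,
            uses_drg_weight=True,
        ),
        "LSF": ProcedureDefinition(
            name="LSF",
            index_code_set={"8106", "8107", "8108"},
            multilevel_fusion_rule=True,
            uses_drg_weight=True,
        ),
        "colectomy": ProcedureDefinition(
            name="colectomy",
            index_code_set={"4573"},
            cancer_flag_codes={"153"},
            elective_only=False,
            uses_drg_weight=True,
        ),
    }


class SimulationConfig(BaseModel):
    """Generative parameters for the synthetic claims study.

    Costs follow a log-linear case-mix model with a multiplicative HRR effect:
    the expected standardized episode total is ``exp(x'beta_true) * u_j`` with
    ``u_j ~ Gamma(shape=1/tau_true, rate=1/tau_true)`` (mean 1, variance
    ``tau_true``).  Paid amounts on disk are inflated by each provider zip's
    wage index applied to the labor share, the exact inverse of the price
    standardization step.
    """

    n_hrrs: int = 40
    episodes_per_hrr: int | tuple[int, int] = 100
    procedures: list[str] = Field(
        default_factory=lambda: ["PHR", "PKR", "CABG", "LSF", "colectomy"]
    )
    beta_true: dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": 9.5,
            "age10": 0.05,
            "female": -0.02,
            "junior_enlisted": 0.04,
            "charlson": 0.10,
        }
    )
    tau_true: float = 0.04
    outcome_cv: float = 0.5
    wage_index_range: tuple[float, float] = (0.8, 1.25)
    labor_share: float = 0.62
    component_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "index_hospitalization": 0.62,
            "readmissions": 0.12,
            "post_acute": 0.06,
            "professional_fees": 0.20,
        }
    )
    readmission_prob: float = 0.08
    postacute_claim_rate: float = 1.2
    exclusion_rates: dict[str, float] = Field(default_factory=dict)
    confounding_strength: float = 0.0
    small_hrr_fraction: float = 0.0
    seed: int = 0

    @field_validator("n_hrrs")
    @classmethod
    def _hrrs_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_hrrs must be >= 1")
        return v

    @field_validator("tau_true", "outcome_cv", "postacute_claim_rate", "confounding_strength")
    @classmethod
    def _nonnegative(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("readmission_prob", "labor_share", "small_hrr_fraction")
    @classmethod
    def _unit_interval(cls, v: float, info) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must lie in [0, 1]")
        return v

    @field_validator("wage_index_range")
    @classmethod
    def _positive_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("wage_index_range must be a positive (lo, hi) interval")
        return v

    @field_validator("component_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"component_mix has unknown components: {sorted(unknown)}")
        if any(f < 0 for f in v.values()):
            raise ValueError("component_mix entries must be >= 0")
        if sum(v.values()) <= 0:
            raise ValueError("component_mix must have positive total")
        return v

    @field_validator("exclusion_rates")
    @classmethod
    def _rates_valid(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = {
            "dual_coverage",
            "trauma",
            "multilevel_fusion",
            "admitted_from_facility",
            "died_before_discharge",
            "day91_claim",
        }
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"exclusion_rates has unknown reasons: {sorted(unknown)}")
        if any(not 0.0 <= p <= 1.0 for p in v.values()):
            raise ValueError("exclusion_rates probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _episode_range_valid(self) -> "SimulationConfig":
        e = self.episodes_per_hrr
        if isinstance(e, tuple):
            lo, hi = e
            if lo < 1 or lo > hi:
                raise ValueError("episodes_per_hrr range must satisfy 1 <= lo <= hi")
        elif e < 1:
            raise ValueError("episodes_per_hrr must be >= 1")
        return self


def packaged_study_config(seed: int = 1) -> SimulationConfig:
    """The packaged synthetic study: five procedures, 40 HRRs, ~4,000 episodes.

    Every exclusion rule has planted triggers at low rates, a tenth of the
    HRRs are generated below the five-case minimum, and regional effects,
    wage inflation, noise and component mix sit at the package defaults.
    """
    return SimulationConfig(
        n_hrrs=40,
        episodes_per_hrr=100,
        seed=seed,
        small_hrr_fraction=0.10,
        exclusion_rates={
            "dual_coverage": 0.02,
            "trauma": 0.01,
            "multilevel_fusion": 0.01,
            "admitted_from_facility": 0.005,
            "died_before_discharge": 0.005,
            "day91_claim": 0.01,
        },
    )


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings.

    Defaults encode the study design: a 90-day post-discharge window, a
    183-day (six-month) lookback, and exclusion of HRRs with fewer than five
    cases per procedure.
    """

    claims_path: Optional[str] = None
    beneficiaries_path: Optional[str] = None
    crosswalk_path: Optional[str] = None
    out_dir: str = "results"
    labor_share: float = 0.62
    min_hrr_count: int = 5
    window_days: int = 90
    lookback_days: int = 183
    n_boot: int = 1000
    seed: int = 0
    permissive: bool = False
    simulation: Optional[SimulationConfig] = None

    @field_validator("min_hrr_count", "window_days", "lookback_days", "n_boot")
    @classmethod
    def _positive(cls, v: int, info) -> int:
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v
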