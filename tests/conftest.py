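"""Shared fixtures: hand-built claim/beneficiary rows and a packaged synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bundlevar.config import (
    PipelineConfig,
    SimulationConfig,
    default_procedure_defs,
    packaged_study_config,
)
from bundlevar.episode_builder import build_episodes
from bundlevar.io_cli import run_pipeline
from bundlevar.payment_allocation import allocate_payments
from bundlevar.price_standardizer import standardize_claims
from bundlevar.synthetic_claims import simulate


def claim(**kw) -> dict:
    """One claims-table row with sensible defaults, overridable per test."""
    base = {
        "claim_id": "C1",
        "beneficiary_id": "B1",
        "claim_class": "inpatient_facility",
        "service_date": 100,
        "admission_date": np.nan,
        "discharge_date": np.nan,
        "provider_zip": "10000",
        "paid_amount": 1000.0,
        "procedure_codes": "",
        "diagnosis_codes": "",
        "drg_weight": np.nan,
        "admission_source": "home",
        "discharge_status": "home",
        "emergent": 0,
    }
    base.update(kw)
    return base


def beneficiary(**kw) -> dict:
    base = {
        "beneficiary_id": "B1",
        "age": 50,
        "sex": "M",
        "race": "white",
        "sponsor_race": "white",
        "sponsor_rank_category": "other",
        "charlson": 0,
        "dual_coverage": 0,
    }
    base.update(kw)
    return base


@pytest.fixture
def defs():
    return default_procedure_defs()


@pytest.fixture
def crosswalk_one_zip():
    return pd.DataFrame({"zip": ["10000"], "hrr_id": ["HRR000"], "wage_index": [1.0]})


def run_sim_to_episodes(config: SimulationConfig):
    """Generator -> standardize -> episodes -> allocation, returning everything."""
    sim = simulate(config)
    std = standardize_claims(sim["claims"], sim["crosswalk"], labor_share=config.labor_share)
    built = build_episodes(std, sim["beneficiaries"], sim["crosswalk"], default_procedure_defs())
    episodes, assignments = allocate_payments(built["episodes"], std)
    return {
        "episodes": episodes,
        "assignments": assignments,
        "claims_std": std,
        "truth": sim["truth"],
        "sim": sim,
        "built": built,
    }


@pytest.fixture(scope="session")
def packaged_run(tmp_path_factory):
    """Full pipeline on the packaged synthetic study (seed 1), run once."""
    out = tmp_path_factory.mktemp("packaged")
    cfg = PipelineConfig(seed=1, n_boot=200, simulation=packaged_study_config(seed=1))
    return run_pipeline(cfg, out)
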