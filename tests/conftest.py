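"""Shared fixtures: small synthetic cohorts built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from connsig import (
    SimConfig,
    simulate_cross_sectional,
    subject_connectome,
)
from connsig.pcr import expand_covariates

TRAIN_COVARIATES = ("sex", "age_years", "age_years^2", "mean_fd_mm", "mean_fd_mm^2")


def cohort_edge_matrix(cohort):
    """Connectomes through the full censor/clean/correlate path."""
    rows, ids = [], []
    for sid in cohort.table["subject_id"]:
        ev = subject_connectome(cohort.runs[sid], labels=cohort.labels)
        if ev is None:
            continue
        rows.append(ev.values)
        ids.append(sid)
    table = cohort.table.set_index("subject_id").loc[ids].reset_index()
    return np.vstack(rows), table


@pytest.fixture(scope="session")
def xsec_cohort():
    """Planted-effect cross-sectional cohort, moderate size."""
    cfg = SimConfig(
        n_subjects=240,
        n_parcels=30,
        n_sites=4,
        families_per_site=20,
        n_runs=2,
        volumes_per_run=130,
        tr_seconds=2.5,
        seed=42,
    )
    return simulate_cross_sectional(cfg)


@pytest.fixture(scope="session")
def xsec_data(xsec_cohort):
    """(X, table) for the planted-effect cohort."""
    X, table = cohort_edge_matrix(xsec_cohort)
    return X, table


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted sleep effect."""
    cfg = SimConfig(
        n_subjects=120,
        n_parcels=24,
        n_sites=3,
        families_per_site=12,
        n_runs=2,
        volumes_per_run=130,
        tr_seconds=2.5,
        effect_size_smn=0.0,
        effect_size_vis=0.0,
        seed=7,
    )
    return simulate_cross_sectional(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
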