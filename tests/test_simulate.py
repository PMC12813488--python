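"""Generator contracts: determinism, nesting, planted-effect structure."""

import numpy as np
import pandas as pd
import pytest

from connsig.connectome import edge_index
from connsig.simulate import (
    SimConfig,
    planted_effect_map,
    simulate_cross_sectional,
    simulate_deprivation,
    simulate_longitudinal,
    validate_nesting,
)

PHENO_ONLY = dict(n_parcels=12, n_runs=1, volumes_per_run=30, tr_seconds=0.8)


def tiny_config(**kw):
    base = dict(
        n_subjects=40,
        n_parcels=18,
        n_sites=2,
        families_per_site=8,
        n_runs=1,
        volumes_per_run=110,
        tr_seconds=2.5,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


def block_means(X, labels, network):
    labels = np.asarray(labels)
    idx = edge_index(len(labels))
    sel = (labels[idx[:, 0]] == network) & (labels[idx[:, 1]] == network)
    return X[:, sel].mean(axis=1)


class TestConfigValidation:
    def test_missing_required_networks_rejected(self):
        with pytest.raises(ValueError, match="somatomotor"):
            SimConfig(n_subjects=10, n_parcels=4, network_labels=["DMN"] * 4)

    def test_label_coverage_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(n_subjects=10, n_parcels=6, network_labels=["SMH", "VIS"])

    @pytest.mark.parametrize("field, value", [
        ("twin_fraction", 1.5),
        ("indicator_loadings", (0.8, 0.6, 1.2)),
        ("n_subjects", 0),
        ("tr_seconds", -1.0),
    ])
    def test_invalid_scalars_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{**dict(n_subjects=10), field: value})


class TestCrossSectional:
    def test_same_seed_identical_outputs(self):
        a = simulate_cross_sectional(tiny_config())
        b = simulate_cross_sectional(tiny_config())
        pd.testing.assert_frame_equal(a.table, b.table)
        sid = a.table["subject_id"].iloc[0]
        assert np.array_equal(a.runs[sid][0].data, b.runs[sid][0].data)
        assert np.array_equal(a.runs[sid][0].fd_mm, b.runs[sid][0].fd_mm)

    def test_nesting_is_strict_tree(self, xsec_cohort):
        validate_nesting(xsec_cohort.table)  # raises on violation
        twins = xsec_cohort.table[xsec_cohort.table["twin_pair_id"] != ""]
        assert len(twins) > 0  # twin structure actually generated

    def test_null_effect_uncorrelated_with_blocks(self, null_cohort):
        from tests_helpers import cohort_edges

        X, table = cohort_edges(null_cohort)
        z = table["latent_sleep_oracle"].to_numpy()
        bound = 2.8 / np.sqrt(len(table))
        for net in ("SMH", "VIS", "DMN"):
            r = np.corrcoef(z, block_means(X, null_cohort.labels, net))[0, 1]
            assert abs(r) < bound

    def test_planted_effect_confined_to_declared_blocks(self, xsec_cohort, xsec_data):
        X, table = xsec_data
        z = table["latent_sleep_oracle"].to_numpy()
        labels = np.asarray(xsec_cohort.labels)
        idx = edge_index(len(labels))
        pattern = planted_effect_map(xsec_cohort.config)
        off = pattern == 0
        # off-block edges: mean correlation with the latent is ~0
        rs = np.array([
            np.corrcoef(z, X[:, e])[0, 1] for e in np.flatnonzero(off)[::7]
        ])
        assert abs(rs.mean()) < 0.05
        # planted blocks: strong, correctly signed association
        smn = np.corrcoef(z, block_means(X, labels, "SMH"))[0, 1]
        vis = np.corrcoef(z, block_means(X, labels, "VIS"))[0, 1]
        assert smn < -0.3  # less sleep -> higher within-SMN connectivity
        assert vis > 0.3

    def test_indicator_correlations_match_loading_products(self):
        cfg = SimConfig(
            n_subjects=2000,
            indicator_loadings=(0.8, 0.6, 0.5),
            seed=11,
            **PHENO_ONLY,
        )
        coh = simulate_cross_sectional(cfg)
        ind = coh.table[["parent_duration", "child_duration", "device_duration"]]
        r = np.corrcoef(ind.to_numpy(), rowvar=False)
        assert r[0, 1] == pytest.approx(0.48, abs=0.05)
        assert r[0, 2] == pytest.approx(0.40, abs=0.05)
        assert r[1, 2] == pytest.approx(0.30, abs=0.05)

    def test_indicator_covariance_converges_to_factor_structure(self):
        lam = np.array([0.8, 0.6, 0.5])
        cfg = SimConfig(n_subjects=5000, indicator_loadings=tuple(lam), seed=13, **PHENO_ONLY)
        coh = simulate_cross_sectional(cfg)
        ind = coh.table[["parent_duration", "child_duration", "device_duration"]]
        r = np.corrcoef(ind.to_numpy(), rowvar=False)
        implied = lam[:, None] @ lam[None, :]
        iu = np.triu_indices(3, 1)
        assert np.max(np.abs(r[iu] - implied[iu])) < 0.03


class TestLongitudinal:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_longitudinal(tiny_config(), delta_sleep_sd=-0.5)

    def test_fixed_seed_identical_pairs(self):
        a = simulate_longitudinal(tiny_config(), 1.0)
        b = simulate_longitudinal(tiny_config(), 1.0)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.edges_t2, b.edges_t2)

    def test_truth_column_stores_planted_coupling(self):
        coh = simulate_longitudinal(tiny_config(n_subjects=100), 1.0, coupling=0.10)
        assert (coh.table["planted_coupling_oracle"] == 0.10).all()

    def test_null_change_carries_no_sleep_signal(self):
        coh = simulate_longitudinal(tiny_config(n_subjects=800), delta_sleep_sd=0.0)
        d_sleep = (coh.table["parent_duration_t2"] - coh.table["parent_duration_t1"]).to_numpy()
        assert d_sleep.std() > 0  # measurement noise still varies
        d_expr = (coh.edges_t2 - coh.edges_t1) @ coh.effect_map
        r = np.corrcoef(d_sleep, d_expr)[0, 1]
        assert abs(r) < 2.8 / np.sqrt(len(d_sleep))

    def test_planted_coupling_has_expected_sign_and_size(self):
        coh = simulate_longitudinal(tiny_config(n_subjects=2000), 1.0, coupling=0.3)
        d_sleep = (coh.table["parent_duration_t2"] - coh.table["parent_duration_t1"]).to_numpy()
        d_expr = (coh.edges_t2 - coh.edges_t1) @ coh.effect_map
        r = np.corrcoef(d_sleep, d_expr)[0, 1]
        assert r == pytest.approx(-0.3, abs=0.06)


class TestDeprivation:
    def test_zero_shift_mean_edge_difference_vanishes(self):
        from tests_helpers import paired_edges

        dep = simulate_deprivation(tiny_config(n_subjects=60, tr_seconds=2.4), 0.0)
        Xt, Xd, _table = paired_edges(dep)
        diff = (Xd - Xt).mean(axis=0)
        assert abs(diff.mean()) < 0.02
        assert np.abs(diff).max() < 0.15  # per-edge session noise only

    def test_positive_shift_moves_blocks_in_planted_directions(self):
        from tests_helpers import paired_edges

        dep = simulate_deprivation(tiny_config(n_subjects=60, tr_seconds=2.4), 1.5)
        Xt, Xd, _table = paired_edges(dep)
        labels = np.asarray(dep.labels)
        idx = edge_index(len(labels))
        smn = (labels[idx[:, 0]] == "SMH") & (labels[idx[:, 1]] == "SMH")
        vis = (labels[idx[:, 0]] == "VIS") & (labels[idx[:, 1]] == "VIS")
        diff = (Xd - Xt).mean(axis=0)
        assert diff[smn].mean() > 0
        assert diff[vis].mean() < 0

    def test_fixed_seed_identical_outputs(self):
        a = simulate_deprivation(tiny_config(), 1.0)
        b = simulate_deprivation(tiny_config(), 1.0)
        sid = a.table["subject_id"].iloc[0]
        assert np.array_equal(a.runs_deprived[sid][0].data, b.runs_deprived[sid][0].data)
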