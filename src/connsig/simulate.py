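"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multisite developmental neuroimaging study plus a
small within-subject sleep-deprivation study:

* community-structured parcel time series (elevated within-network
  correlation over labeled networks, including somatomotor-like ``SM*`` and
  visual-like ``VIS`` blocks),
* a one-factor latent sleep-duration construct observed through three noisy
  indicators (parent-report, child-report, wearable device),
* a planted sleep effect on connectivity: per SD of *reduced* sleep,
  within-somatomotor edges shift up by ``effect_size_smn`` and within-visual
  edges shift by ``effect_size_vis`` (negative),
* site -> family -> twin nesting of subjects,
* motion confounding: a framewise-displacement-linked common signal that
  inflates correlations for high-motion subjects unless nuisance columns
  are regressed out,
* a two-timepoint longitudinal cohort and a paired (typical, deprived)
  deprivation cohort.

Cross-sectional and deprivation cohorts are generated as raw run time
series so the full censoring/cleaning/correlation path is exercised; the
longitudinal *change* is constructed directly at the connectome-edge level
so the planted within-subject coupling between sleep change and
planted-pattern expression change is exact by construction.

Ground-truth latent columns are retained in outputs under ``*_oracle``
names; pipeline stages must never consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import RunTimeSeries, edge_index, vectorize

__all__ = [
    "SimConfig",
    "CrossSectionalCohort",
    "LongitudinalCohort",
    "DeprivationCohort",
    "default_network_labels",
    "planted_effect_map",
    "simulate_cross_sectional",
    "simulate_longitudinal",
    "simulate_deprivation",
    "validate_nesting",
]

#: network label cycle used when none is supplied (field-standard abbreviations)
_DEFAULT_NETWORKS = ("SMH", "VIS", "DMN", "FPN", "DAN", "CO")

#: columns carrying generator ground truth; never inputs to analysis stages
ORACLE_COLUMNS = frozenset(
    {"latent_sleep_oracle", "delta_latent_oracle", "planted_coupling_oracle"}
)


def default_network_labels(n_parcels: int) -> list[str]:
    """Contiguous blocks cycling through six canonical networks."""
    block = int(np.ceil(n_parcels / len(_DEFAULT_NETWORKS)))
    labels = []
    for k, name in enumerate(_DEFAULT_NETWORKS):
        labels.extend([name] * min(block, n_parcels - len(labels)))
    return labels[:n_parcels]


@dataclass
class SimConfig:
    """Generator settings; defaults mirror a large multisite youth study.

    ``effect_size_smn``/``effect_size_vis`` are correlation-scale shifts of
    within-network edges per SD of *reduced* sleep (positive for the
    somatomotor block, negative for the visual block).
    """

    n_subjects: int = 600
    n_parcels: int = 60
    network_labels: list[str] | None = None
    n_sites: int = 6
    families_per_site: int = 40
    twin_fraction: float = 0.15
    n_runs: int = 4
    volumes_per_run: int = 375
    tr_seconds: float = 0.8
    effect_size_smn: float = 0.10
    effect_size_vis: float = -0.08
    indicator_loadings: tuple[float, float, float] = (0.8, 0.6, 0.5)
    motion_confound_strength: float = 0.2
    seed: int = 0
    # background connectivity structure
    within_network_r: float = 0.35
    between_network_r: float = 0.05
    block_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "n_parcels",
            "n_sites",
            "families_per_site",
            "n_runs",
            "volumes_per_run",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not (0.0 <= self.twin_fraction <= 1.0):
            raise ValueError("twin_fraction must lie in [0, 1]")
        if len(self.indicator_loadings) != 3 or not all(
            0.0 < lam < 1.0 for lam in self.indicator_loadings
        ):
            raise ValueError("indicator_loadings must be three values in (0, 1)")
        if self.network_labels is None:
            self.network_labels = default_network_labels(self.n_parcels)
        if len(self.network_labels) != self.n_parcels:
            raise ValueError("network_labels must cover every parcel")
        labels = set(self.network_labels)
        if not any(l.startswith("SM") for l in labels) or "VIS" not in labels:
            raise ValueError(
                "network_labels must include a somatomotor-like ('SM*') and a "
                "visual ('VIS') block"
            )


@dataclass
class CrossSectionalCohort:
    """Phenotype table plus raw run time series for every subject."""

    table: pd.DataFrame
    runs: dict[str, list[RunTimeSeries]]
    labels: list[str]
    config: SimConfig
    effect_map: np.ndarray = field(repr=False)  # oracle: per-SD planted edge shift


@dataclass
class LongitudinalCohort:
    """Two-timepoint phenotypes plus paired connectome edge matrices."""

    table: pd.DataFrame
    edges_t1: np.ndarray
    edges_t2: np.ndarray
    labels: list[str]
    config: SimConfig
    effect_map: np.ndarray = field(repr=False)


@dataclass
class DeprivationCohort:
    """Paired (typical, deprived) sessions of raw run time series."""

    table: pd.DataFrame
    runs_typical: dict[str, list[RunTimeSeries]]
    runs_deprived: dict[str, list[RunTimeSeries]]
    labels: list[str]
    config: SimConfig
    effect_map: np.ndarray = field(repr=False)


def planted_effect_map(config: SimConfig) -> np.ndarray:
    """Edge-vector of correlation shifts per SD of reduced sleep.

    ``effect_size_smn`` on within-somatomotor edges, ``effect_size_vis`` on
    within-visual edges, zero elsewhere.
    """
    labels = np.asarray(config.network_labels)
    idx = edge_index(config.n_parcels)
    li, lj = labels[idx[:, 0]], labels[idx[:, 1]]
    out = np.zeros(idx.shape[0])
    smn = np.char.startswith(li.astype(str), "SM") & (li == lj)
    vis = (li == "VIS") & (li == lj)
    out[smn] = config.effect_size_smn
    out[vis] = config.effect_size_vis
    return out


def _base_correlation(config: SimConfig) -> np.ndarray:
    labels = np.asarray(config.network_labels)
    same = labels[:, None] == labels[None, :]
    mat = np.where(same, config.within_network_r, config.between_network_r)
    np.fill_diagonal(mat, 1.0)
    return mat


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Symmetrize, clip eigenvalues to be positive, renormalize the diagonal."""
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    if w.min() < 1e-4:
        w = np.clip(w, 1e-4, None)
        mat = (v * w) @ v.T
    d = np.sqrt(np.diag(mat))
    return mat / np.outer(d, d)


def _assign_structure(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table with site/family/twin nesting (family strictly within site)."""
    n = config.n_subjects
    site = np.arange(n) % config.n_sites
    order = np.argsort(site, kind="stable")
    site = site[order]
    family = np.empty(n, dtype=int)
    twin_pair = np.full(n, -1, dtype=int)
    n_twin_pairs = int(np.floor(config.twin_fraction * n / 2.0))
    pair_id = 0
    for s in range(config.n_sites):
        members = np.flatnonzero(site == s)
        fam_local = members % config.families_per_site  # cyclic fill within site
        family[members] = s * config.families_per_site + np.sort(fam_local)
    # twins: pairs of consecutive subjects sharing a family
    fam_sorted = np.argsort(family, kind="stable")
    i = 0
    while pair_id < n_twin_pairs and i < n - 1:
        a, b = fam_sorted[i], fam_sorted[i + 1]
        if family[a] == family[b]:
            twin_pair[a] = twin_pair[b] = pair_id
            pair_id += 1
            i += 2
        else:
            i += 1
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{k:04d}" for k in range(n)],
            "site_id": [f"site{si:02d}" for si in site],
            "family_id": [f"fam{f:04d}" for f in family],
            "twin_pair_id": [f"twin{t:04d}" if t >= 0 else "" for t in twin_pair],
        }
    )


def _latent_sleep(
    table: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Latent sleep-duration z with site/family variance components (total ~1)."""
    site_codes = pd.factorize(table["site_id"])[0]
    fam_codes = pd.factorize(table["family_id"])[0]
    site_eff = rng.normal(0.0, np.sqrt(0.05), site_codes.max() + 1)
    fam_eff = rng.normal(0.0, np.sqrt(0.15), fam_codes.max() + 1)
    ind = rng.normal(0.0, np.sqrt(0.80), len(table))
    return site_eff[site_codes] + fam_eff[fam_codes] + ind


def _indicators(
    z: np.ndarray, loadings, rng: np.random.Generator
) -> pd.DataFrame:
    lam = np.asarray(loadings, dtype=float)
    scales = [(8.5, 0.8), (8.0, 1.0), (7.5, 0.9)]  # hours: mean, SD per indicator
    cols = {}
    for k, name in enumerate(("parent_duration", "child_duration", "device_duration")):
        std = lam[k] * z + np.sqrt(1.0 - lam[k] ** 2) * rng.normal(size=z.size)
        mu, sd = scales[k]
        cols[name] = mu + sd * std
    return pd.DataFrame(cols)


def _fd_trace(
    n_volumes: int, subject_scale: float, rng: np.random.Generator
) -> np.ndarray:
    fd = subject_scale * np.abs(rng.normal(1.0, 0.5, n_volumes))
    spikes = rng.random(n_volumes) < 0.04
    fd[spikes] += rng.uniform(0.5, 1.5, spikes.sum())
    return fd


def _simulate_runs(
    config: SimConfig,
    corr: np.ndarray,
    fd_scale: float,
    rng: np.random.Generator,
) -> list[RunTimeSeries]:
    """Sample one subject's runs from a target correlation with confounds added."""
    chol = np.linalg.cholesky(_nearest_correlation(corr))
    runs = []
    for _ in range(config.n_runs):
        nv = config.volumes_per_run
        y = rng.normal(size=(nv, config.n_parcels)) @ chol.T
        fd = _fd_trace(nv, fd_scale, rng)
        # nuisance: 6 motion-like series (first tracks FD) + 4 physiological-ish
        motion = rng.normal(size=(nv, 6)) * 0.5
        motion[:, 0] += (fd - fd.mean()) / (fd.std() + 1e-12)
        phys = np.cumsum(rng.normal(size=(nv, 4)), axis=0)
        phys = (phys - phys.mean(0)) / (phys.std(0) + 1e-12)
        nuisance = np.column_stack([motion, phys])
        # leak nuisance into the parcels; cleaning must remove this
        leak = rng.normal(scale=0.15, size=(nuisance.shape[1], config.n_parcels))
        y = y + nuisance @ leak
        # FD-linked common signal: inflates all correlations for movers
        y = y + config.motion_confound_strength * motion[:, [0]] * np.ones(
            (1, config.n_parcels)
        )
        runs.append(
            RunTimeSeries(data=y, tr_seconds=config.tr_seconds, fd_mm=fd, nuisance=nuisance)
        )
    return runs


def _subject_correlation(
    config: SimConfig,
    base: np.ndarray,
    effect_mat: np.ndarray,
    reduced_sleep_z: float,
    rng: np.random.Generator,
    extra_shift: float = 0.0,
) -> np.ndarray:
    labels = np.asarray(config.network_labels)
    corr = base + effect_mat * (reduced_sleep_z + extra_shift)
    # subject-specific within-network perturbation
    for name in np.unique(labels):
        sel = labels == name
        jitter = rng.normal(0.0, config.block_jitter_sd)
        block = np.outer(sel, sel)
        np.fill_diagonal(block, False)
        corr = corr + jitter * block
    return np.clip(corr, -0.85, 0.85) + np.diag(1.0 - np.diag(np.clip(corr, -0.85, 0.85)))


def simulate_cross_sectional(config: SimConfig) -> CrossSectionalCohort:
    """Multisite cross-sectional cohort: phenotypes + raw run time series.

    Reduced sleep (negative latent z) shifts within-somatomotor edges up by
    ``effect_size_smn`` per SD and within-visual edges by ``effect_size_vis``.
    Byte-identical outputs for identical (config, seed).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_pheno = [np.random.default_rng(s) for s in ss.spawn(2)]

    table = _assign_structure(config, rng_struct)
    z = _latent_sleep(table, rng_pheno)
    table = pd.concat([table, _indicators(z, config.indicator_loadings, rng_pheno)], axis=1)
    table["sex"] = rng_pheno.integers(0, 2, config.n_subjects)
    table["age_years"] = 11.0 + rng_pheno.uniform(0.0, 1.5, config.n_subjects)
    # motion scale mildly anti-correlated with sleep (worse sleep, more motion)
    fd_scale = np.exp(rng_pheno.normal(np.log(0.15), 0.4, config.n_subjects) - 0.08 * z)
    table["latent_sleep_oracle"] = z

    base = _base_correlation(config)
    effect_vec = planted_effect_map(config)
    effect_mat = np.zeros((config.n_parcels, config.n_parcels))
    iu = np.triu_indices(config.n_parcels, k=1)
    effect_mat[iu] = effect_vec
    effect_mat += effect_mat.T

    runs: dict[str, list[RunTimeSeries]] = {}
    mean_fd = np.empty(config.n_subjects)
    subject_seeds = ss.spawn(config.n_subjects)
    for i, sid in enumerate(table["subject_id"]):
        rng_i = np.random.default_rng(subject_seeds[i])
        corr = _subject_correlation(config, base, effect_mat, -z[i], rng_i)
        runs[sid] = _simulate_runs(config, corr, fd_scale[i], rng_i)
        mean_fd[i] = float(np.mean(np.concatenate([r.fd_mm for r in runs[sid]])))
    table["mean_fd_mm"] = mean_fd
    validate_nesting(table)
    return CrossSectionalCohort(
        table=table,
        runs=runs,
        labels=list(config.network_labels),
        config=config,
        effect_map=effect_vec,
    )


def simulate_longitudinal(
    config: SimConfig,
    delta_sleep_sd: float,
    coupling: float = 0.10,
    edge_noise_sd: float = 0.05,
) -> LongitudinalCohort:
    """Two-timepoint cohort with a planted within-subject sleep <-> pattern coupling.

    The baseline connectome is the cohort's Fisher-z background plus edge
    noise and the cross-sectional planted effect. The timepoint-2 connectome
    adds a change vector built in the planted-pattern direction so that the
    population correlation between the *observed* sleep-duration change and
    the change in planted-pattern expression equals ``-coupling`` (decreased
    sleep -> increased expression of the reduced-sleep pattern), with
    orthogonal edge noise that does not load on the pattern.

    ``delta_sleep_sd`` is the SD (latent z units) of the sleep change;
    the ground-truth coupling is stored in ``planted_coupling_oracle``.
    """
    if delta_sleep_sd < 0:
        raise ValueError("delta_sleep_sd must be non-negative")
    if not (0.0 <= coupling < 1.0):
        raise ValueError("coupling must lie in [0, 1)")
    ss = np.random.SeedSequence([config.seed, 7001])
    rng_struct, rng_pheno, rng_edge = [np.random.default_rng(s) for s in ss.spawn(3)]

    table = _assign_structure(config, rng_struct)
    n = config.n_subjects
    z1 = _latent_sleep(table, rng_pheno)
    table["sex"] = rng_pheno.integers(0, 2, n)
    table["age_t1"] = 9.5 + rng_pheno.uniform(0.0, 1.0, n)
    table["age_t2"] = table["age_t1"] + rng_pheno.normal(2.08, 0.1, n)
    table["mean_fd_t1"] = np.exp(rng_pheno.normal(np.log(0.15), 0.35, n))
    table["mean_fd_t2"] = np.exp(rng_pheno.normal(np.log(0.14), 0.35, n))

    # observed sleep change: standardized shape d, reported in hours; when the
    # latent change is degenerate (sd=0) the observed change is measurement
    # noise only and carries no connectivity signal
    d = rng_pheno.normal(size=n)
    hours_scale = 0.8 * (delta_sleep_sd if delta_sleep_sd > 0 else 0.3)
    delta_hours = hours_scale * d
    table["parent_duration_t1"] = 8.5 + 0.8 * (0.8 * z1 + 0.6 * rng_pheno.normal(size=n))
    table["parent_duration_t2"] = table["parent_duration_t1"] + delta_hours
    table["latent_sleep_oracle"] = z1
    table["delta_latent_oracle"] = delta_sleep_sd * d
    table["planted_coupling_oracle"] = coupling

    base_z = np.arctanh(np.clip(vectorize(_base_correlation(config)), -0.85, 0.85))
    pattern = planted_effect_map(config)
    p_hat = pattern / np.linalg.norm(pattern)
    n_edges = pattern.size

    edges_t1 = (
        base_z
        + np.outer(-z1, pattern)
        + rng_edge.normal(scale=0.08, size=(n, n_edges))
    )
    # pattern-direction change with exact standardized coupling
    if delta_sleep_sd > 0:
        signal = coupling * (-d)
    else:
        signal = np.zeros(n)
    eta = rng_edge.normal(size=n)
    along = 0.5 * (signal + np.sqrt(1.0 - coupling**2) * eta)
    noise = rng_edge.normal(scale=edge_noise_sd, size=(n, n_edges))
    noise -= np.outer(noise @ p_hat, p_hat)  # orthogonal to the pattern
    edges_t2 = edges_t1 + np.outer(along, p_hat) + noise

    validate_nesting(table)
    return LongitudinalCohort(
        table=table,
        edges_t1=edges_t1,
        edges_t2=edges_t2,
        labels=list(config.network_labels),
        config=config,
        effect_map=pattern,
    )


def simulate_deprivation(
    config: SimConfig, deprivation_shift: float
) -> DeprivationCohort:
    """Paired typical/deprived sessions of raw run time series.

    The deprived session's target correlation equals the typical session's
    plus ``deprivation_shift`` times the planted somatomotor+/visual- map;
    session noise comes from independent finite-length sampling.
    """
    ss = np.random.SeedSequence([config.seed, 8002])
    rng_pheno = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_subjects
    table = pd.DataFrame(
        {
            "subject_id": [f"dep-{k:03d}" for k in range(n)],
            "sex": rng_pheno.integers(0, 2, n),
            "age_group": rng_pheno.integers(0, 2, n),  # 0=young, 1=old
        }
    )
    fd_scale_t = np.exp(rng_pheno.normal(np.log(0.15), 0.35, n))
    fd_scale_d = fd_scale_t * np.exp(rng_pheno.normal(0.1, 0.15, n))  # sleepier, movier

    base = _base_correlation(config)
    effect_vec = planted_effect_map(config)
    effect_mat = np.zeros((config.n_parcels, config.n_parcels))
    iu = np.triu_indices(config.n_parcels, k=1)
    effect_mat[iu] = effect_vec
    effect_mat += effect_mat.T

    runs_t: dict[str, list[RunTimeSeries]] = {}
    runs_d: dict[str, list[RunTimeSeries]] = {}
    mean_fd_t = np.empty(n)
    mean_fd_d = np.empty(n)
    subject_seeds = ss.spawn(n)
    for i, sid in enumerate(table["subject_id"]):
        rng_i = np.random.default_rng(subject_seeds[i])
        trait = rng_i.normal(0.0, 0.3)  # stable subject offset shared by sessions
        corr_t = _subject_correlation(config, base, effect_mat, trait, rng_i)
        corr_d = np.clip(corr_t + deprivation_shift * effect_mat, -0.85, 0.85)
        np.fill_diagonal(corr_d, 1.0)
        runs_t[sid] = _simulate_runs(config, corr_t, fd_scale_t[i], rng_i)
        runs_d[sid] = _simulate_runs(config, corr_d, fd_scale_d[i], rng_i)
        mean_fd_t[i] = float(np.mean(np.concatenate([r.fd_mm for r in runs_t[sid]])))
        mean_fd_d[i] = float(np.mean(np.concatenate([r.fd_mm for r in runs_d[sid]])))
    table["mean_fd_typical"] = mean_fd_t
    table["mean_fd_deprived"] = mean_fd_d
    return DeprivationCohort(
        table=table,
        runs_typical=runs_t,
        runs_deprived=runs_d,
        labels=list(config.network_labels),
        config=config,
        effect_map=effect_vec,
    )


def validate_nesting(table: pd.DataFrame) -> None:
    """Assert the site -> family -> twin structure is a strict tree."""
    fam_site = table.groupby("family_id")["site_id"].nunique()
    if (fam_site > 1).any():
        bad = fam_site[fam_site > 1].index.tolist()
        raise ValueError(f"families span multiple sites: {bad}")
    if "twin_pair_id" in table.columns:
        twins = table[table["twin_pair_id"].astype(str) != ""]
        if len(twins):
            pair_fam = twins.groupby("twin_pair_id")["family_id"].nunique()
            if (pair_fam > 1).any():
                raise ValueError("twin pairs must share a family")
            sizes = twins.groupby("twin_pair_id").size()
            if (sizes != 2).any():
                raise ValueError("twin pairs must have exactly two members")
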