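"""Stage orchestration binding the modules into the four-result workflow.

Stages (``simulate`` -> ``connectome`` -> ``factor`` -> ``train`` ->
``express`` / ``longitudinal`` / ``deprivation`` -> ``correspond``) read
and write artifacts under the configured output directory; ``all`` runs
them in order. Every artifact is reproducible from (config, seed): files
carry no timestamps and floats use a fixed format, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csio
from .config import PipelineConfig
from .connectome import edge_order_hash, subject_connectome
from .correspondence import contrast_signature, dual_permutation_null, spatial_correlation
from .expression import deprivation_contrast, expression_scores, longitudinal_change_model
from .factor import SleepFactorAnalysis
from .pcr import (
    CovariateResidualizer,
    Neurosignature,
    expand_covariates,
    train_neurosignature,
)
from .permutation import ExchangeabilityBlocks, freedman_lane_null, make_insample_r_statistic
from .simulate import simulate_cross_sectional, simulate_deprivation, simulate_longitudinal

log = logging.getLogger("connsig")

STAGES = (
    "simulate",
    "connectome",
    "factor",
    "train",
    "express",
    "longitudinal",
    "deprivation",
    "correspond",
    "all",
)

#: canonical covariate specification for the cross-sectional model
TRAIN_COVARIATES = ("sex", "age_years", "age_years^2", "mean_fd_mm", "mean_fd_mm^2")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{producing_stage}' stage first"
        )
    return path


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_edge_matrix(path: Path, ids, X: np.ndarray, order_hash: str) -> None:
    header = {"schema": "connsig-edge-matrix-v1", "order_hash": order_hash,
              "n_edges": int(X.shape[1])}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        fh.write("subject_id\t" + "\t".join(f"e{j}" for j in range(X.shape[1])) + "\n")
        for sid, row in zip(ids, X):
            fh.write(sid + "\t" + "\t".join("%.10g" % v for v in row) + "\n")


def _read_edge_matrix(path: Path):
    with open(path) as fh:
        header = json.loads(fh.readline()[2:])
        df = pd.read_csv(fh, sep="\t")
    ids = df["subject_id"].tolist()
    X = df.drop(columns="subject_id").to_numpy(dtype=float)
    return ids, X, header["order_hash"]


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    cohort = simulate_cross_sectional(config.sim_config())
    csio.write_phenotypes(outdir / "phenotypes.tsv", cohort.table)
    csio.write_labels(outdir / "labels.tsv", cohort.labels)
    np.save(outdir / "planted_effect_map.npy", cohort.effect_map)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_parcels": cohort.config.n_parcels,
        "subjects": {},
    }
    for sid, runs in cohort.runs.items():
        path = ts_dir / f"{sid}.npz"
        arrays = {}
        for k, run in enumerate(runs):
            arrays[f"data_{k}"] = run.data
            arrays[f"fd_{k}"] = run.fd_mm
            arrays[f"nuisance_{k}"] = run.nuisance
        np.savez(path, tr_seconds=cohort.config.tr_seconds, n_runs=len(runs), **arrays)
        manifest["subjects"][sid] = {"runs": len(runs), "file": path.name}
    csio.write_manifest(outdir / "manifest.json", manifest)
    log.info("simulate: %d subjects written", len(cohort.runs))


def _load_runs(outdir: Path, sid: str):
    from .connectome import RunTimeSeries

    with np.load(outdir / "timeseries" / f"{sid}.npz") as z:
        tr = float(z["tr_seconds"])
        n_runs = int(z["n_runs"])
        return [
            RunTimeSeries(
                data=z[f"data_{k}"], tr_seconds=tr, fd_mm=z[f"fd_{k}"],
                nuisance=z[f"nuisance_{k}"],
            )
            for k in range(n_runs)
        ]


def stage_connectome(config: PipelineConfig, outdir: Path) -> None:
    manifest = csio.read_manifest(_require(outdir / "manifest.json", "simulate"))
    labels = csio.read_labels(_require(outdir / "labels.tsv", "simulate"))
    ids, rows, dropped = [], [], []
    for sid in manifest["subjects"]:
        runs = _load_runs(outdir, sid)
        ev = subject_connectome(
            runs,
            fd_threshold_mm=config.fd_threshold_mm,
            min_minutes=config.min_run_minutes,
            highpass_hz=config.highpass_hz,
            labels=labels,
        )
        if ev is None:
            dropped.append({"subject_id": sid, "rule": "no eligible runs after censoring"})
            log.warning("connectome: dropped %s (no eligible runs)", sid)
            continue
        ids.append(sid)
        rows.append(ev.values)
    order_hash = edge_order_hash(len(labels), labels)
    _write_edge_matrix(outdir / "connectomes.tsv", ids, np.vstack(rows), order_hash)
    _write_json(outdir / "connectome_log.json", {"dropped": dropped, "kept": len(ids)})


def stage_factor(config: PipelineConfig, outdir: Path) -> None:
    pheno = csio.read_phenotypes(_require(outdir / "phenotypes.tsv", "simulate"))
    indicators = pheno[["parent_duration", "child_duration", "device_duration"]].to_numpy()
    model = SleepFactorAnalysis(orientation="reduced").fit(indicators)
    scores = model.transform(indicators)
    out = pheno[["subject_id"]].copy()
    out["reduced_sleep_score"] = scores
    csio.write_phenotypes(outdir / "sleep_scores.tsv", out)
    _write_json(
        outdir / "factor_model.json",
        {
            "loadings": model.loadings_.tolist(),
            "uniquenesses": model.uniquenesses_.tolist(),
            "scoring_weights": model.scoring_weights_.tolist(),
            "determinacy": model.determinacy_,
            "orientation": "reduced",
            "n_complete": model.n_complete_,
        },
    )


def stage_train(config: PipelineConfig, outdir: Path) -> dict:
    pheno = csio.read_phenotypes(_require(outdir / "phenotypes.tsv", "simulate"))
    ids, X, order_hash = _read_edge_matrix(_require(outdir / "connectomes.tsv", "connectome"))
    scores = csio.read_phenotypes(_require(outdir / "sleep_scores.tsv", "factor"))
    merged = pheno.merge(scores, on="subject_id").set_index("subject_id").loc[ids].reset_index()
    y = merged["reduced_sleep_score"].to_numpy()
    C = expand_covariates(merged, TRAIN_COVARIATES)
    sites = merged["site_id"].to_numpy()

    sig, cv = train_neurosignature(
        X,
        y,
        sites,
        covariates=C,
        grid=config.component_grid,
        inner_folds=config.inner_folds,
        residualize_X=config.residualize_connectomes,
        covariate_spec=TRAIN_COVARIATES,
        order_hash=order_hash,
        random_state=config.seed,
    )
    blocks = ExchangeabilityBlocks.from_table(merged)
    stat = make_insample_r_statistic(X, covariates=C, n_components=cv.n_components_mean)
    fl = freedman_lane_null(
        y,
        C,
        blocks,
        stat,
        B=config.n_permutations,
        rng=np.random.default_rng(config.seed + 1),
    )
    csio.write_signature(outdir / "signature.tsv", sig)
    payload = {
        "r_cv_mean": cv.mean_r,
        "per_site_r": cv.per_site_r,
        "per_site_k": cv.per_site_k,
        "n_components": cv.n_components_mean,
        "permutation_p": fl.p_value,
        "permutation_B": fl.n_permutations,
        "n_subjects": len(ids),
    }
    _write_json(outdir / "cv_results.json", payload)
    return payload


def stage_express(config: PipelineConfig, outdir: Path) -> None:
    sig = csio.read_signature(_require(outdir / "signature.tsv", "train"))
    ids, X, order_hash = _read_edge_matrix(_require(outdir / "connectomes.tsv", "connectome"))
    vals = expression_scores(sig, X, order_hash=order_hash)
    df = pd.DataFrame({"subject_id": ids, "expression": vals})
    csio.write_phenotypes(outdir / "expression.tsv", df)


def stage_longitudinal(config: PipelineConfig, outdir: Path) -> dict:
    sig = csio.read_signature(_require(outdir / "signature.tsv", "train"))
    sim_kwargs = dict(config.sim)
    sim_kwargs.update(n_subjects=config.longitudinal_n, seed=config.seed + 101)
    from .simulate import SimConfig

    cohort = simulate_longitudinal(
        SimConfig(**sim_kwargs),
        delta_sleep_sd=config.delta_sleep_sd,
        coupling=config.longitudinal_coupling,
    )
    e1 = expression_scores(sig, cohort.edges_t1)
    e2 = expression_scores(sig, cohort.edges_t2)
    t = cohort.table
    covs = pd.DataFrame(
        {
            "age_diff": t["age_t2"] - t["age_t1"],
            "age_diff_sq": (t["age_t2"] - t["age_t1"]) ** 2,
            "fd_t1": t["mean_fd_t1"],
            "fd_t1_sq": t["mean_fd_t1"] ** 2,
            "fd_t2": t["mean_fd_t2"],
            "fd_t2_sq": t["mean_fd_t2"] ** 2,
            "sex": t["sex"],
        }
    )
    res = longitudinal_change_model(
        e1, e2, t["parent_duration_t1"], t["parent_duration_t2"], covs, t["site_id"]
    )
    payload = {
        "standardized_beta": res.beta,
        "se": res.se,
        "p_value": res.p_value,
        "method": res.method,
        "n": res.n,
    }
    _write_json(outdir / "longitudinal.json", payload)
    return payload


def _deprivation_config(config: PipelineConfig):
    from .simulate import SimConfig

    kwargs = dict(config.sim)
    kwargs.update(
        n_subjects=config.deprivation_n,
        n_runs=config.deprivation_runs,
        volumes_per_run=config.deprivation_volumes,
        tr_seconds=config.deprivation_tr,
        seed=config.seed + 202,
    )
    return SimConfig(**kwargs)


def _deprivation_connectomes(config: PipelineConfig, outdir: Path):
    labels = csio.read_labels(_require(outdir / "labels.tsv", "simulate"))
    cohort = simulate_deprivation(_deprivation_config(config), config.deprivation_shift)
    Xt, Xd, kept = [], [], []
    for i, sid in enumerate(cohort.table["subject_id"]):
        evt = subject_connectome(
            cohort.runs_typical[sid],
            fd_threshold_mm=config.fd_threshold_mm,
            min_minutes=config.min_run_minutes,
            highpass_hz=config.highpass_hz,
        )
        evd = subject_connectome(
            cohort.runs_deprived[sid],
            fd_threshold_mm=config.fd_threshold_mm,
            min_minutes=config.min_run_minutes,
            highpass_hz=config.highpass_hz,
        )
        if evt is None or evd is None:
            log.warning("deprivation: dropped %s (ineligible session)", sid)
            continue
        Xt.append(evt.values)
        Xd.append(evd.values)
        kept.append(i)
    table = cohort.table.iloc[kept].reset_index(drop=True)
    order_hash = edge_order_hash(len(labels), labels)
    return table, np.vstack(Xt), np.vstack(Xd), order_hash


def stage_deprivation(config: PipelineConfig, outdir: Path) -> dict:
    sig = csio.read_signature(_require(outdir / "signature.tsv", "train"))
    table, Xt, Xd, order_hash = _deprivation_connectomes(config, outdir)
    et = expression_scores(sig, Xt, order_hash=order_hash)
    ed = expression_scores(sig, Xd, order_hash=order_hash)
    res = deprivation_contrast(
        et, ed, table["sex"], table["age_group"],
        table["mean_fd_typical"], table["mean_fd_deprived"],
    )
    _write_edge_matrix(outdir / "deprivation_typical.tsv", table["subject_id"], Xt, order_hash)
    _write_edge_matrix(outdir / "deprivation_deprived.tsv", table["subject_id"], Xd, order_hash)
    csio.write_phenotypes(outdir / "deprivation_table.tsv", table)
    payload = {
        "mean_typical": res.mean_typical,
        "mean_deprived": res.mean_deprived,
        "adjusted_mean_difference": res.mean_difference,
        "t_statistic": res.t_statistic,
        "p_value": res.p_value,
        "n": res.n,
    }
    _write_json(outdir / "deprivation.json", payload)
    return payload


def _deprivation_covariates(table: pd.DataFrame):
    ct = np.column_stack(
        [table["sex"], table["age_group"], table["mean_fd_typical"]]
    ).astype(float)
    cd = np.column_stack(
        [table["sex"], table["age_group"], table["mean_fd_deprived"]]
    ).astype(float)
    return ct, cd


def stage_correspond(config: PipelineConfig, outdir: Path) -> dict:
    pheno = csio.read_phenotypes(_require(outdir / "phenotypes.tsv", "simulate"))
    ids, X, order_hash = _read_edge_matrix(_require(outdir / "connectomes.tsv", "connectome"))
    scores = csio.read_phenotypes(_require(outdir / "sleep_scores.tsv", "factor"))
    _require(outdir / "cv_results.json", "train")
    merged = pheno.merge(scores, on="subject_id").set_index("subject_id").loc[ids].reset_index()
    y = merged["reduced_sleep_score"].to_numpy()
    C = expand_covariates(merged, TRAIN_COVARIATES)

    idt, Xt, _ = _read_edge_matrix(_require(outdir / "deprivation_typical.tsv", "deprivation"))
    idd, Xd, _ = _read_edge_matrix(_require(outdir / "deprivation_deprived.tsv", "deprivation"))
    dep_table = csio.read_phenotypes(_require(outdir / "deprivation_table.tsv", "deprivation"))
    ct, cd = _deprivation_covariates(dep_table)

    # fixed component count for cross-dataset parity, capped by the small
    # sample's stacked-residual rank
    k = max(1, min(config.k_contrast, len(idt) * 2 - ct.shape[1] - 2))
    res = dual_permutation_null(
        X,
        y,
        C,
        Xt,
        Xd,
        cov_typical=ct,
        cov_deprived=cd,
        n_components_large=k,
        n_components_contrast=k,
        B=config.correspondence_permutations,
        rng=np.random.default_rng(config.seed + 3),
    )
    payload = {
        "spatial_r": res.r_observed,
        "permutation_p": res.p_value,
        "B": res.n_permutations,
        "n_components": k,
    }
    _write_json(outdir / "correspondence.json", payload)
    return payload


def run_pipeline(config: PipelineConfig, stage: str) -> dict:
    """Run one stage (or ``all``); returns the summary payload for result stages."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage '{stage}'; choose from {STAGES}")
    outdir = _outdir(config)
    if stage == "all":
        stage_simulate(config, outdir)
        stage_connectome(config, outdir)
        stage_factor(config, outdir)
        train = stage_train(config, outdir)
        stage_express(config, outdir)
        longi = stage_longitudinal(config, outdir)
        dep = stage_deprivation(config, outdir)
        corr = stage_correspond(config, outdir)
        results = {
            "r_cv": train["r_cv_mean"],
            "r_cv_permutation_p": train["permutation_p"],
            "longitudinal_standardized_beta": longi["standardized_beta"],
            "longitudinal_p": longi["p_value"],
            "deprivation_t": dep["t_statistic"],
            "deprivation_mean_difference": dep["adjusted_mean_difference"],
            "correspondence_r": corr["spatial_r"],
            "correspondence_p": corr["permutation_p"],
        }
        _write_json(outdir / "results.json", results)
        return results
    runner = {
        "simulate": stage_simulate,
        "connectome": stage_connectome,
        "factor": stage_factor,
        "train": stage_train,
        "express": stage_express,
        "longitudinal": stage_longitudinal,
        "deprivation": stage_deprivation,
        "correspond": stage_correspond,
    }[stage]
    out = runner(config, outdir)
    return out if isinstance(out, dict) else {}
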