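"""Pipeline configuration: thresholds, model options, cohort sizes, seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Settings for the end-to-end synthetic workflow.

    Thresholds hold the standard censoring/eligibility/filtering constants
    (FD 0.5 mm, 4 minutes of retained data, 0.008 Hz high-pass); model
    options hold the component grid, inner fold count, the fixed contrast
    component count (21), and permutation counts.
    """

    outdir: str = "connsig_out"
    seed: int = 0
    # censoring / eligibility / filtering
    fd_threshold_mm: float = 0.5
    min_run_minutes: float = 4.0
    highpass_hz: float = 0.008
    # model options
    component_grid: list[int] | None = None
    inner_folds: int = 5
    k_contrast: int = 21
    n_permutations: int = 1000
    correspondence_permutations: int = 500
    residualize_connectomes: bool = True
    # cross-sectional cohort
    sim: dict = field(default_factory=dict)
    # longitudinal cohort
    longitudinal_n: int = 1500
    delta_sleep_sd: float = 1.0
    longitudinal_coupling: float = 0.10
    # deprivation cohort
    deprivation_n: int = 76
    deprivation_shift: float = 1.5
    deprivation_runs: int = 2
    deprivation_volumes: int = 200
    deprivation_tr: float = 2.4

    def __post_init__(self):
        for name in ("fd_threshold_mm", "min_run_minutes", "highpass_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_permutations", "correspondence_permutations", "inner_folds",
                     "k_contrast", "longitudinal_n", "deprivation_n"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    def sim_config(self, seed_offset: int = 0) -> SimConfig:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed + seed_offset)
        return SimConfig(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of the scientific settings; paths are excluded so the same
        configuration run in two directories yields identical artifacts."""
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def small_fixture(cls, outdir: str = "connsig_out", seed: int = 0) -> "PipelineConfig":
        """Compact configuration for smoke runs and worked examples."""
        return cls(
            outdir=outdir,
            seed=seed,
            sim=dict(
                n_subjects=300,
                n_parcels=30,
                n_sites=4,
                families_per_site=30,
                n_runs=2,
                volumes_per_run=130,
                tr_seconds=2.5,
            ),
            n_permutations=200,
            correspondence_permutations=200,
            longitudinal_n=300,
            deprivation_n=40,
            deprivation_volumes=120,
        )
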