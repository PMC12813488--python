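"""Neurosignature transport: expression scores and their statistical models.

An expression score is the dot product of a trained signature's edge
weights with a subject's connectome edge vector — how strongly that
connectome expresses the signature. Scores are linear in the connectome and
only comparable across connectomes sharing the signature's edge ordering
(enforced by hash when available, never silently reordered).

Two downstream models:

* longitudinal change: change in expression across two timepoints regressed
  on change in sleep duration in a linear mixed model with a random site
  intercept, controlling for age difference (linear + quadratic), mean
  motion at each timepoint (linear + quadratic), and sex; coefficients are
  standardized (outcome and predictor z-scored on the analysis sample).
* deprivation contrast: within-subject difference in expression (deprived
  minus typical) regressed on an intercept plus mean-centered covariates
  (sex, age group, motion on each scan); the intercept's t-test is the
  adjusted mean difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import EdgeVector
from .pcr import Neurosignature

__all__ = [
    "express",
    "expression_scores",
    "longitudinal_change_model",
    "LongitudinalResult",
    "deprivation_contrast",
    "DeprivationResult",
]


def express(signature: Neurosignature, connectome) -> float:
    """Expression score of one connectome: sum_e weight_e * z_e.

    When the connectome is an :class:`EdgeVector` and both sides carry an
    order hash, a mismatch raises instead of silently reordering.
    """
    if isinstance(connectome, EdgeVector):
        if signature.order_hash and connectome.order_hash and (
            signature.order_hash != connectome.order_hash
        ):
            raise ValueError(
                "edge-ordering hash mismatch between signature and connectome; "
                "refusing to take the dot product"
            )
        values = connectome.values
    else:
        values = np.asarray(connectome, dtype=float)
    if values.shape != signature.weights.shape:
        raise ValueError("connectome and signature must have equal edge counts")
    return float(values @ signature.weights)


def expression_scores(signature: Neurosignature, X, order_hash: str | None = None):
    """Vectorized expression: (n, E) edge matrix -> (n,) scores."""
    X = np.asarray(X, dtype=float)
    if order_hash is not None and signature.order_hash and order_hash != signature.order_hash:
        raise ValueError("edge-ordering hash mismatch; refusing to take dot products")
    if X.shape[1] != signature.weights.size:
        raise ValueError("edge count mismatch between X and signature")
    return X @ signature.weights


@dataclass
class LongitudinalResult:
    """Standardized fixed effect of sleep change on expression change."""

    beta: float
    se: float
    p_value: float
    method: str  # "mixed" or "ols_cluster" (fallback)
    n: int
    covariate_betas: dict = field(default_factory=dict)


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def longitudinal_change_model(
    expr_t1,
    expr_t2,
    sleep_t1,
    sleep_t2,
    covariates: pd.DataFrame,
    site,
) -> LongitudinalResult:
    """Mixed model of expression change on sleep-duration change.

    Fits  Delta expression ~ Delta sleep + covariates + (1 | site); both the
    outcome and the predictor (and covariates) are z-scored on the analysis
    sample first, so the reported coefficient is a standardized beta
    (invariant to affine rescaling of the raw sleep units). If the mixed fit
    is singular or fails to converge, falls back to OLS with cluster-robust
    (by site) standard errors, flagged in ``method``.
    """
    d_expr = np.asarray(expr_t2, dtype=float) - np.asarray(expr_t1, dtype=float)
    d_sleep = np.asarray(sleep_t2, dtype=float) - np.asarray(sleep_t1, dtype=float)
    site = np.asarray(site)
    if len(np.unique(site)) < 3:
        raise ValueError("need at least 3 sites for the site random effect")
    endog = _zscore(d_expr)
    cov_names = list(covariates.columns)
    Xcols = [_zscore(d_sleep)] + [_zscore(covariates[c]) for c in cov_names]
    exog = sm.add_constant(np.column_stack(Xcols))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mixed = sm.MixedLM(endog, exog, groups=site)
            fit = mixed.fit(reml=True, method="lbfgs")
            singular = (not fit.converged) or np.any(~np.isfinite(fit.bse[:2]))
        except (np.linalg.LinAlgError, ValueError):
            fit, singular = None, True
    if fit is not None and not singular:
        beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        method = "mixed"
        cov_betas = {c: float(fit.params[2 + i]) for i, c in enumerate(cov_names)}
    else:
        ols = sm.OLS(endog, exog).fit(cov_type="cluster", cov_kwds={"groups": site})
        beta, se, p = ols.params[1], ols.bse[1], ols.pvalues[1]
        method = "ols_cluster"
        cov_betas = {c: float(ols.params[2 + i]) for i, c in enumerate(cov_names)}
    return LongitudinalResult(
        beta=float(beta),
        se=float(se),
        p_value=float(p),
        method=method,
        n=len(endog),
        covariate_betas=cov_betas,
    )


@dataclass
class DeprivationResult:
    """Adjusted within-subject expression difference after sleep deprivation."""

    mean_typical: float
    se_typical: float
    mean_deprived: float
    se_deprived: float
    mean_difference: float  # covariate-adjusted (intercept of the difference model)
    t_statistic: float
    p_value: float
    n: int


def deprivation_contrast(
    expr_typical,
    expr_deprived,
    sex,
    age_group,
    motion_typical,
    motion_deprived,
) -> DeprivationResult:
    """Within-subject (deprived - typical) expression difference, adjusted.

    The per-subject difference is regressed on an intercept plus
    mean-centered sex, age group, and motion on each scan; because the
    covariates are centered, the intercept is the covariate-adjusted mean
    difference and its t-test is the reported significance.
    """
    et = np.asarray(expr_typical, dtype=float)
    ed = np.asarray(expr_deprived, dtype=float)
    if et.shape != ed.shape:
        raise ValueError("paired sessions required (equal lengths)")
    diff = ed - et
    n = diff.size
    C = np.column_stack(
        [
            np.asarray(sex, dtype=float),
            np.asarray(age_group, dtype=float),
            np.asarray(motion_typical, dtype=float),
            np.asarray(motion_deprived, dtype=float),
        ]
    )
    if n < C.shape[1] + 2:
        raise ValueError("too few subjects for the covariate-adjusted contrast")
    exog = sm.add_constant(C - C.mean(axis=0))
    fit = sm.OLS(diff, exog).fit()
    return DeprivationResult(
        mean_typical=float(et.mean()),
        se_typical=float(et.std(ddof=1) / np.sqrt(n)),
        mean_deprived=float(ed.mean()),
        se_deprived=float(ed.std(ddof=1) / np.sqrt(n)),
        mean_difference=float(fit.params[0]),
        t_statistic=float(fit.tvalues[0]),
        p_value=float(fit.pvalues[0]),
        n=n,
    )
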