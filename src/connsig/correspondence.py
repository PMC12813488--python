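"""Spatial correspondence between independently derived neurosignatures.

The small-sample deprivation study yields its own signature: connectomes
from both sessions are residualized for covariates, stacked, decomposed by
PCA, and each subject's session difference in the leading K component
scores (deprived minus typical) is averaged and multiplied back through the
component loadings to give a single edge map (K = 21 by default, matching
the component count of the large-sample signature for parity).

Correspondence between two signatures is their Pearson correlation across
edges. Its significance comes from a dual permutation: at each iteration
the large-sample signature is rebuilt with shuffled phenotype scores (fixed
component count) and the contrast signature is rebuilt with each subject's
session labels flipped by a fair coin; the correlation of the two permuted
maps forms the null. Both permuted maps are, by construction, unrelated to
sleep, so the null captures the chance level of map correlation under the
two pipelines' spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pcr import CovariateResidualizer, haufe_transform

__all__ = [
    "ContrastSignature",
    "contrast_signature",
    "spatial_correlation",
    "dual_permutation_null",
    "CorrespondenceResult",
]


@dataclass
class ContrastSignature:
    """Edge map of the within-subject session contrast."""

    weights: np.ndarray
    n_components: int
    covariate_spec: tuple[str, ...] = ()
    order_hash: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


def _stacked_residual_pca(X_typical, X_deprived, cov_typical, cov_deprived):
    Xt = np.asarray(X_typical, dtype=float)
    Xd = np.asarray(X_deprived, dtype=float)
    if Xt.shape != Xd.shape:
        raise ValueError("paired sessions must have matching edge matrices")
    n = Xt.shape[0]
    X = np.vstack([Xt, Xd])
    if cov_typical is not None:
        Ct = np.asarray(cov_typical, dtype=float)
        Cd = np.asarray(cov_deprived, dtype=float)
        C = np.vstack([Ct, Cd])
        X = CovariateResidualizer().fit_transform(C, X)
    mu = X.mean(axis=0)
    Xc = X - mu
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-12 * s[0]).sum())
    scores = u * s
    return scores, vt, rank, n


def contrast_signature(
    X_typical,
    X_deprived,
    cov_typical=None,
    cov_deprived=None,
    n_components: int = 21,
    covariate_spec=(),
    order_hash: str = "",
) -> ContrastSignature:
    """Session-contrast signature: loadings times the mean session score change.

    Residualize each session's connectomes against its covariate rows (one
    joint fit over the stacked data), PCA the stacked residuals, take each
    subject's (deprived - typical) difference in the first K component
    scores, average over subjects, and map back to edges through the
    loadings.
    """
    scores, vt, rank, n = _stacked_residual_pca(
        X_typical, X_deprived, cov_typical, cov_deprived
    )
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the stacked residualized "
            f"data has rank {rank}"
        )
    k = n_components
    delta = scores[n:, :k] - scores[:n, :k]  # deprived minus typical
    weights = vt[:k].T @ delta.mean(axis=0)
    return ContrastSignature(
        weights=weights,
        n_components=k,
        covariate_spec=tuple(covariate_spec),
        order_hash=order_hash,
    )


def spatial_correlation(sig_a, sig_b) -> float:
    """Pearson correlation across edges between two edge maps."""
    a = sig_a.weights if hasattr(sig_a, "weights") else np.asarray(sig_a, dtype=float)
    b = sig_b.weights if hasattr(sig_b, "weights") else np.asarray(sig_b, dtype=float)
    ha = getattr(sig_a, "order_hash", "")
    hb = getattr(sig_b, "order_hash", "")
    if ha and hb and ha != hb:
        raise ValueError("edge-ordering hash mismatch between signatures")
    if a.shape != b.shape:
        raise ValueError("signatures must have equal edge counts")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map; spatial correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrespondenceResult:
    r_observed: float
    p_value: float
    null_correlations: np.ndarray = field(repr=False)
    sided: str = "greater"

    @property
    def n_permutations(self) -> int:
        return len(self.null_correlations)


def dual_permutation_null(
    X_large,
    y_large,
    cov_large,
    X_typical,
    X_deprived,
    cov_typical=None,
    cov_deprived=None,
    n_components_large: int = 21,
    n_components_contrast: int = 21,
    B: int = 10000,
    rng=None,
    sided: str = "greater",
    use_haufe: bool = True,
    max_redraws: int = 100,
) -> CorrespondenceResult:
    """Dual-permutation significance of the correspondence of two signatures.

    Observed statistic: spatial correlation between (a) the large-sample
    signature's Haufe pattern (or raw weights when ``use_haufe=False``)
    built with the fixed component count, and (b) the session-contrast
    signature. Null: per iteration, shuffle the large-sample phenotype
    across subjects, rebuild (a); flip each pair's session labels by fair
    coin, rebuild (b); correlate. One-sided p by default (positive
    correspondence); ``sided="two-sided"`` uses |r|. Iterations with a
    degenerate zero-variance map are redrawn and counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(rng)

    # --- large-sample side: precompute residualized PCA once; the basis does
    # not depend on the phenotype, so permutations only refit betas.
    X = np.asarray(X_large, dtype=float)
    y = np.asarray(y_large, dtype=float).ravel()
    n = X.shape[0]
    if cov_large is not None:
        C = np.asarray(cov_large, dtype=float)
        res = CovariateResidualizer()
        y = res.fit_transform(C, y)
        X = CovariateResidualizer().fit_transform(C, X)
    muX = X.mean(axis=0)
    Xc = X - muX
    u, s, vt_a = np.linalg.svd(Xc, full_matrices=False)
    ka = min(n_components_large, int((s > 1e-12 * s[0]).sum()))
    S = u[:, :ka] * s[:ka]
    Va = vt_a[:ka]

    def large_map(y_vec):
        yc = y_vec - y_vec.mean()
        beta, *_ = np.linalg.lstsq(S, yc, rcond=None)
        w = Va.T @ beta
        if use_haufe:
            return haufe_transform(X, w, yhat=S @ beta)
        return w

    # --- contrast side: precompute stacked residual PCA and per-subject
    # score differences; a label flip negates that subject's contribution.
    scores, vt_s, rank, n_pairs = _stacked_residual_pca(
        X_typical, X_deprived, cov_typical, cov_deprived
    )
    kc = min(n_components_contrast, rank)
    D = scores[n_pairs:, :kc] - scores[:n_pairs, :kc]
    Vs = vt_s[:kc]

    def contrast_map(signs):
        return Vs.T @ ((D * signs[:, None]).mean(axis=0))

    map_a = large_map(y)
    map_s = contrast_map(np.ones(n_pairs))
    r_obs = spatial_correlation(map_a, map_s)

    null = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            signs = rng.choice([-1.0, 1.0], size=n_pairs)
            ma = large_map(y[perm])
            ms = contrast_map(signs)
            if ma.std() > 0 and ms.std() > 0:
                null[b] = np.corrcoef(ma, ms)[0, 1]
                break
            redraws += 1
        else:
            raise RuntimeError("degenerate null maps; cannot draw a valid iteration")
    if sided == "greater":
        count = int(np.sum(null >= r_obs))
    elif sided == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(r_obs)))
    else:
        raise ValueError("sided must be 'greater' or 'two-sided'")
    p = (1.0 + count) / (B + 1.0)
    return CorrespondenceResult(
        r_observed=r_obs, p_value=p, null_correlations=null, sided=sided
    )
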