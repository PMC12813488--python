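"""Principal-component-regression neurosignature training.

The predictive model regresses a (residualized) phenotype on connectome
edges via PCA: edges are centered (not per-edge scaled; all edges share the
Fisher-z scale), projected onto the leading K principal components, and a
linear model is fit on the component scores. K is chosen in nested
cross-validation by the 1-SE rule: the smallest K whose mean inner-CV error
is within one standard error of the minimum. Out-of-sample accuracy is
evaluated with leave-one-site-out cross-validation (LOSO-CV) and summarized
as r_cv, the mean correlation between held-out predictions and held-out
(residualized) phenotype across sites.

The final neurosignature is a single edge-weight map obtained by fitting on
the full sample with the rounded mean of the per-fold K and collapsing
component loadings against their betas; its dot product with any connectome
(sharing the edge ordering) yields a predicted score. For interpretation,
the Haufe transform converts the decoding weights into an activation
pattern: the covariance of each edge with the model's prediction, scaled by
the prediction variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CovariateResidualizer",
    "PCRSignature",
    "Neurosignature",
    "CVResult",
    "default_component_grid",
    "one_se_choice",
    "select_components",
    "loso_cv",
    "build_signature",
    "haufe_transform",
    "train_neurosignature",
    "expand_covariates",
]


def expand_covariates(df, columns):
    """Build a covariate matrix from table columns; ``name^2`` squares ``name``.

    The canonical specification is sex, age, age^2, mean FD, mean FD^2.
    """
    cols = []
    for name in columns:
        if name.endswith("^2"):
            base = name[:-2]
            cols.append(np.asarray(df[base], dtype=float) ** 2)
        else:
            cols.append(np.asarray(df[name], dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """OLS residualization with train-only coefficients.

    ``fit`` learns regression coefficients of the targets on the covariates
    (plus intercept) from training rows; ``transform`` applies those
    coefficients to any rows, so held-out data is residualized with training
    parameters and never leaks its own covariate means.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def _design(self, C):
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if self.add_intercept:
            return np.column_stack([np.ones(C.shape[0]), C])
        return C

    def fit(self, C, Y):
        D = self._design(C)
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # name the offending columns via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(D, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            bad = sorted(piv[diag <= 1e-10 * diag[0]].tolist())
            raise ValueError(
                f"covariate design is rank deficient (rank {rank} < {D.shape[1]}); "
                f"collinear columns (0-based, incl. intercept): {bad}"
            )
        Y = np.asarray(Y, dtype=float)
        self.coef_, *_ = np.linalg.lstsq(D, Y, rcond=None)
        return self

    def transform(self, C, Y):
        check_is_fitted(self, "coef_")
        Y = np.asarray(Y, dtype=float)
        return Y - self._design(C) @ self.coef_

    def fit_transform(self, C, Y):
        return self.fit(C, Y).transform(C, Y)


def default_component_grid(n_train: int, cap: int = 250, k_parity: int = 21):
    """Roughly geometric component grid up to min(n/10, cap), always with 21.

    21 is kept in the grid because the small-sample contrast signature is
    built with the same fixed component count for cross-dataset parity.
    """
    upper = max(1, min(n_train // 10, cap))
    grid = {1, 2, 4, 8, 16, 32, 64, 128, 250}
    grid.add(k_parity)
    out = sorted(k for k in grid if k <= upper)
    return out or [1]


def one_se_choice(mean_err, se_err, grid) -> int:
    """Apply the 1-SE rule to an error curve over a component grid.

    Returns the smallest grid value whose mean error does not exceed the
    minimum mean error plus the standard error at the argmin.
    """
    mean_err = np.asarray(mean_err, dtype=float)
    se_err = np.asarray(se_err, dtype=float)
    grid = list(grid)
    if not grid:
        raise ValueError("empty component grid")
    imin = int(np.argmin(mean_err))
    threshold = mean_err[imin] + se_err[imin]
    chosen = next(i for i in range(len(grid)) if mean_err[i] <= threshold)
    return grid[chosen]


def _pca_scores(Xc: np.ndarray, k_max: int):
    """Centered-data SVD: component scores and loadings up to k_max."""
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k_max = min(k_max, (s > 1e-12 * s[0]).sum() if s.size else 0)
    scores = u[:, :k_max] * s[:k_max]
    return scores, vt[:k_max], k_max


def select_components(
    train_X,
    train_y,
    grid=None,
    inner_folds: int = 5,
    groups=None,
    random_state=None,
) -> int:
    """1-SE rule over a component grid with inner cross-validation.

    Inner folds are grouped by site when enough distinct groups exist,
    otherwise plain shuffled K-fold. Error metric is mean squared error of
    held-out predictions; the selected K is the smallest grid value whose
    mean error is within one standard error (at the argmin) of the minimum.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=float)
    n = X.shape[0]
    if grid is None:
        grid = default_component_grid(n)
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty component grid")
    if groups is not None and len(np.unique(groups)) >= inner_folds:
        splitter = GroupKFold(n_splits=inner_folds)
        splits = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=inner_folds, shuffle=True, random_state=random_state)
        splits = splitter.split(X, y)
    errors = np.full((inner_folds, len(grid)), np.nan)
    for f, (tr, te) in enumerate(splits):
        Xtr, Xte = X[tr], X[te]
        mu = Xtr.mean(axis=0)
        k_cap = min(max(grid), len(tr) - 1)
        scores, vt, k_eff = _pca_scores(Xtr - mu, k_cap)
        ytr = y[tr]
        ybar = ytr.mean()
        te_scores = (Xte - mu) @ vt.T
        for gi, k in enumerate(grid):
            kk = min(k, k_eff)
            beta, *_ = np.linalg.lstsq(scores[:, :kk], ytr - ybar, rcond=None)
            pred = te_scores[:, :kk] @ beta + ybar
            errors[f, gi] = np.mean((y[te] - pred) ** 2)
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / np.sqrt(errors.shape[0])
    return one_se_choice(mean_err, se_err, grid)


class PCRSignature(BaseEstimator, RegressorMixin):
    """Principal component regression on connectome edges.

    Parameters
    ----------
    n_components : int or "1se"
        Fixed component count, or nested-CV selection by the 1-SE rule.
    component_grid : sequence of int, optional
        Grid for 1-SE selection (default: geometric grid incl. 21).
    inner_folds : int
        Inner CV folds for selection.
    random_state : int, optional
        Seed for the inner K-fold shuffle.

    Attributes
    ----------
    n_components_ : selected/used component count
    mean_ : (E,) training edge means
    components_ : (K, E) PCA loadings
    betas_ : (K,) regression coefficients on component scores
    weights_ : (E,) edge-space prediction map (components' betas collapsed)
    intercept_ : prediction offset so predict(X) = X @ weights_ + intercept_
    haufe_pattern_ : (E,) activation pattern cov(edge, prediction)/var(prediction)
    """

    def __init__(
        self,
        n_components="1se",
        component_grid=None,
        inner_folds: int = 5,
        random_state=None,
    ):
        self.n_components = n_components
        self.component_grid = component_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_subjects, n_edges) aligned with y")
        n = X.shape[0]
        if self.n_components == "1se":
            k = select_components(
                X,
                y,
                grid=self.component_grid,
                inner_folds=self.inner_folds,
                groups=groups,
                random_state=self.random_state,
            )
        else:
            k = int(self.n_components)
            if k < 1:
                raise ValueError("n_components must be >= 1")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        scores, vt, k_eff = _pca_scores(Xc, min(k, n - 1, X.shape[1]))
        if k_eff < k and self.n_components != "1se":
            raise ValueError(
                f"requested {k} components but the centered data has rank {k_eff}"
            )
        self.n_components_ = k_eff
        self.components_ = vt
        self.y_mean_ = y.mean()
        self.betas_, *_ = np.linalg.lstsq(scores, y - self.y_mean_, rcond=None)
        self.weights_ = vt.T @ self.betas_
        self.intercept_ = self.y_mean_ - self.mean_ @ self.weights_
        yhat = Xc @ self.weights_ + self.y_mean_
        self.haufe_pattern_ = haufe_transform(X, self.weights_, yhat=yhat)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        return X @ self.weights_ + self.intercept_


def haufe_transform(X, weights, yhat=None) -> np.ndarray:
    """Activation pattern from decoding weights: Cov(X) w / Var(w'X).

    Equivalently the per-edge sample covariance with the predicted score,
    divided by the prediction variance.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    if yhat is None:
        yhat = X @ w
    yc = yhat - np.mean(yhat)
    var = yc @ yc / (len(yc) - 1)
    if var <= 0:
        raise ValueError("predicted scores have zero variance; Haufe pattern undefined")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ yc) / (len(yc) - 1) / var


@dataclass
class Neurosignature:
    """Edge-weight prediction map plus training metadata.

    ``weights`` predict (dot product with an edge vector, plus intercept);
    ``haufe_pattern`` is the matching activation/importance map for display
    and spatial comparison.
    """

    weights: np.ndarray
    haufe_pattern: np.ndarray
    n_components: int
    covariate_spec: tuple[str, ...]
    intercept: float = 0.0
    n_subjects: int = 0
    order_hash: str = ""
    train_mean: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.haufe_pattern = np.asarray(self.haufe_pattern, dtype=float)
        if self.weights.shape != self.haufe_pattern.shape:
            raise ValueError("weights and haufe_pattern must be the same length")


@dataclass
class CVResult:
    """Leave-one-site-out evaluation summary."""

    per_site_r: dict
    per_site_k: dict
    mean_r: float
    n_components_mean: int  # rounded mean per-fold K, ties upward

    @property
    def sites(self):
        return list(self.per_site_r)


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def loso_cv(
    X,
    y,
    site_ids,
    covariates=None,
    grid=None,
    inner_folds: int = 5,
    residualize_X: bool = True,
    random_state=None,
) -> CVResult:
    """Leave-one-site-out cross-validation of the PCR pipeline.

    Per held-out site: residualize y (and optionally X) for covariates with
    train-fitted coefficients, select K by nested inner CV (grouped by the
    remaining sites), fit PCR, and correlate held-out predictions with the
    held-out residualized phenotype. Sites with fewer than two subjects are
    excluded from the held-out correlation with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    site_ids = np.asarray(site_ids)
    sites = np.unique(site_ids)
    if len(sites) < 3:
        raise ValueError("LOSO-CV needs at least 3 sites")
    per_r, per_k = {}, {}
    for s in sites:
        te = site_ids == s
        tr = ~te
        if te.sum() < 2:
            warnings.warn(
                f"site {s} has fewer than 2 subjects; excluded from held-out "
                "correlation",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        Xtr, Xte, ytr, yte = X[tr], X[te], y[tr], y[te]
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            res_y = CovariateResidualizer().fit(C[tr], ytr)
            ytr = res_y.transform(C[tr], ytr)
            yte = res_y.transform(C[te], yte)
            if residualize_X:
                res_x = CovariateResidualizer().fit(C[tr], Xtr)
                Xtr = res_x.transform(C[tr], Xtr)
                Xte = res_x.transform(C[te], Xte)
        try:
            k = select_components(
                Xtr,
                ytr,
                grid=grid,
                inner_folds=inner_folds,
                groups=site_ids[tr],
                random_state=random_state,
            )
            model = PCRSignature(n_components=k).fit(Xtr, ytr)
            pred = model.predict(Xte)
            r = _pearson(pred, yte)
        except ValueError:  # degenerate training data (e.g. zero variance)
            k = min(grid) if grid else 1
            r = float("nan")
        if np.isnan(r):
            warnings.warn(
                f"held-out correlation undefined for site {s} (degenerate data)",
                RuntimeWarning,
                stacklevel=2,
            )
        per_r[str(s)] = r
        per_k[str(s)] = k
    ks = np.array(list(per_k.values()), dtype=float)
    k_mean = int(np.floor(ks.mean() + 0.5)) if ks.size else 1
    rs = np.array(list(per_r.values()), dtype=float)
    return CVResult(
        per_site_r=per_r,
        per_site_k=per_k,
        mean_r=float(np.nanmean(rs)) if rs.size else float("nan"),
        n_components_mean=k_mean,
    )


def build_signature(
    X,
    y,
    covariates=None,
    n_components: int = 1,
    covariate_spec=(),
    residualize_X: bool = True,
    order_hash: str = "",
) -> Neurosignature:
    """Full-sample neurosignature with a fixed component count.

    Residualizes for covariates (full-sample coefficients), fits PCR, and
    collapses component loadings against betas into a single edge map.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        y = CovariateResidualizer().fit_transform(C, y)
        if residualize_X:
            X = CovariateResidualizer().fit_transform(C, X)
    model = PCRSignature(n_components=n_components).fit(X, y)
    return Neurosignature(
        weights=model.weights_,
        haufe_pattern=model.haufe_pattern_,
        n_components=model.n_components_,
        covariate_spec=tuple(covariate_spec),
        intercept=float(model.intercept_),
        n_subjects=X.shape[0],
        order_hash=order_hash,
        train_mean=model.mean_,
    )


def train_neurosignature(
    X,
    y,
    site_ids,
    covariates=None,
    grid=None,
    inner_folds: int = 5,
    residualize_X: bool = True,
    covariate_spec=(),
    order_hash: str = "",
    random_state=None,
):
    """LOSO-CV evaluation followed by the full-sample signature build.

    Returns (Neurosignature, CVResult); the full-sample fit uses the rounded
    mean of the per-fold selected component counts.
    """
    cv = loso_cv(
        X,
        y,
        site_ids,
        covariates=covariates,
        grid=grid,
        inner_folds=inner_folds,
        residualize_X=residualize_X,
        random_state=random_state,
    )
    sig = build_signature(
        X,
        y,
        covariates=covariates,
        n_components=cv.n_components_mean,
        covariate_spec=covariate_spec,
        residualize_X=residualize_X,
        order_hash=order_hash,
    )
    return sig, cv
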