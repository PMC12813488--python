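"""Latent sleep-duration factor from three noisy indicators.

Three sleep-duration measures (parent-report, child-report, wearable
device) are modeled as indicators of a single latent sleep-duration factor.
With exactly three indicators the one-factor model is just-identified: it
has zero degrees of freedom, reproduces the observed 3x3 correlation matrix
exactly, and its standardized loadings have the closed-form triad solution

    lambda_1 = sqrt(r12 * r13 / r23)   (and cyclic rotations).

Factor scores use the regression (Thurstone) method, w = R^{-1} lambda on
standardized indicators. The "reduced sleep" orientation simply negates the
duration score, so that higher values mean shorter sleep.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["HeywoodError", "SleepFactorAnalysis", "weighted_average_duration"]

INDICATOR_NAMES = ("parent_duration", "child_duration", "device_duration")


class HeywoodError(ValueError):
    """Raised when the triad solution implies a loading >= 1 (Heywood case)."""


def weighted_average_duration(weekday_hours, weekend_hours):
    """School-week weighted mean of sleep duration: (5*weekday + 2*weekend) / 7."""
    weekday = np.asarray(weekday_hours, dtype=float)
    weekend = np.asarray(weekend_hours, dtype=float)
    if np.any(weekday < 0) or np.any(weekend < 0):
        raise ValueError("hours must be non-negative")
    out = (5.0 * weekday + 2.0 * weekend) / 7.0
    return float(out) if out.ndim == 0 else out


def _triad_loadings(r: np.ndarray) -> np.ndarray:
    r12, r13, r23 = r[0, 1], r[0, 2], r[1, 2]
    if min(r12, r13, r23) <= 0:
        raise ValueError(
            "all three pairwise indicator correlations must be positive for "
            "a one-factor solution with positively oriented loadings"
        )
    lam = np.sqrt(
        np.array([r12 * r13 / r23, r12 * r23 / r13, r13 * r23 / r12])
    )
    if np.any(lam >= 1.0):
        bad = int(np.argmax(lam))
        raise HeywoodError(
            f"Heywood case: implied loading for indicator {bad} is "
            f"{lam[bad]:.4f} >= 1; the correlation triad "
            f"(r12={r12:.3f}, r13={r13:.3f}, r23={r23:.3f}) is inconsistent "
            "with a common-factor model"
        )
    return lam


class SleepFactorAnalysis(BaseEstimator, TransformerMixin):
    """Just-identified one-factor model for the three sleep-duration indicators.

    Parameters
    ----------
    orientation : {"duration", "reduced"}
        "duration": higher score = longer sleep (loadings positive).
        "reduced": negated score, the prediction target of the reduced-sleep
        neurosignature.

    Attributes
    ----------
    loadings_ : (3,) standardized loadings
    uniquenesses_ : (3,) 1 - loadings**2
    scoring_weights_ : (3,) regression-method weights on standardized indicators
    means_, sds_ : training standardization constants
    determinacy_ : sqrt(lambda' R^{-1} lambda), the ceiling on the
        correlation between estimated scores and the true factor
    """

    def __init__(self, orientation: str = "duration"):
        self.orientation = orientation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) indicator matrix")
        complete = ~np.isnan(X).any(axis=1)
        X = X[complete]
        if X.shape[0] < 10:
            raise ValueError("need at least 10 complete-case subjects")
        if self.orientation not in ("duration", "reduced"):
            raise ValueError("orientation must be 'duration' or 'reduced'")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        if np.any(self.sds_ <= 0):
            raise ValueError("constant indicator column")
        r = np.corrcoef(X, rowvar=False)
        self.correlations_ = r
        self.loadings_ = _triad_loadings(r)
        self.uniquenesses_ = 1.0 - self.loadings_**2
        self.scoring_weights_ = np.linalg.solve(r, self.loadings_)
        self.determinacy_ = float(np.sqrt(self.loadings_ @ self.scoring_weights_))
        self.n_complete_ = X.shape[0]
        return self

    def transform(self, X):
        """Per-subject factor scores; rows with any missing indicator are NaN."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) indicator matrix")
        z = (X - self.means_) / self.sds_
        scores = z @ self.scoring_weights_
        if self.orientation == "reduced":
            scores = -scores
        return scores

    def implied_correlations(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Lambda' + Psi (equals observed)."""
        check_is_fitted(self, "loadings_")
        lam = self.loadings_[:, None]
        return lam @ lam.T + np.diag(self.uniquenesses_)


def fit_factor(indicators) -> SleepFactorAnalysis:
    """Functional wrapper: fit the one-factor model on an (n, 3) table."""
    return SleepFactorAnalysis().fit(np.asarray(indicators, dtype=float))


def factor_scores(model: SleepFactorAnalysis, indicators) -> np.ndarray:
    """Functional wrapper over :meth:`SleepFactorAnalysis.transform`."""
    return model.transform(np.asarray(indicators, dtype=float))
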