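"""Freedman-Lane permutation inference with nested exchangeability blocks.

Multisite family studies are not freely exchangeable: twins sit inside
families, families inside sites. Valid permutations therefore (1) never
move a subject across sites, (2) move families as intact units, exchanging
them only with same-size families within their site, and (3) shuffle
members within a family (with twin pairs exchanged as units against other
same-size sub-units and permuted within the pair). This mirrors the
whole-block/within-block convention of standard permutation tooling for
linear models.

Covariates are handled with the Freedman-Lane scheme: fit the reduced
(covariates-only) model, permute its residuals by a block-respecting
ordering, add them back to the reduced fit, and recompute the statistic on
the reconstructed outcome. The p-value uses the (b+1)/(B+1) convention, so
an observed statistic exceeding all B null draws reports p = 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExchangeabilityBlocks",
    "sample_permutation",
    "freedman_lane_null",
    "FreedmanLaneResult",
    "make_insample_r_statistic",
]


class ExchangeabilityBlocks:
    """Nested site -> family -> twin-pair block tree constraining permutations.

    Parameters
    ----------
    site, family : array-like of labels, one per subject
    twin_pair : optional array-like; empty string / NaN marks non-twins
    """

    def __init__(self, site, family, twin_pair=None):
        self.site = np.asarray(site)
        self.family = np.asarray(family)
        n = len(self.site)
        if len(self.family) != n:
            raise ValueError("site and family must have equal length")
        if twin_pair is None:
            twin = np.array([""] * n, dtype=object)
        else:
            twin = np.asarray(
                ["" if (t is None or (isinstance(t, float) and np.isnan(t))) else str(t) for t in twin_pair],
                dtype=object,
            )
        # a twin whose co-twin was excluded upstream is just a singleton
        labels, counts = np.unique(twin[twin != ""], return_counts=True)
        for lab in labels[counts == 1]:
            twin[twin == lab] = ""
        self.twin_pair = twin
        self._validate()
        self._build()

    def _validate(self):
        df = pd.DataFrame({"site": self.site, "family": self.family, "twin": self.twin_pair})
        fam_sites = df.groupby("family")["site"].nunique()
        if (fam_sites > 1).any():
            raise ValueError("malformed nesting: a family spans multiple sites")
        twins = df[df["twin"] != ""]
        if len(twins):
            if (twins.groupby("twin")["family"].nunique() > 1).any():
                raise ValueError("malformed nesting: a twin pair spans families")
            if (twins.groupby("twin").size() != 2).any():
                raise ValueError("malformed nesting: twin pairs must have 2 members")

    def _build(self):
        """Precompute, per site, units grouped by exchange-compatible shape.

        A unit is a twin pair (positions array of length 2) or a singleton;
        units exchange only with same-shape units of the same family-size
        class within the same site, and families exchange as wholes with
        same-size families.
        """
        n = len(self.site)
        self.n_subjects = n
        # family -> member positions, split into twin-pair units and singletons
        self._site_family_groups: list[list[np.ndarray]] = []
        fam_of = pd.Series(range(n)).groupby(
            [pd.Series(self.site), pd.Series(self.family)]
        )
        # organize: site -> {family_size -> [family unit-structures]}
        per_site: dict = {}
        for (site, _fam), idx in fam_of.groups.items():
            positions = np.asarray(sorted(idx))
            per_site.setdefault(site, {}).setdefault(len(positions), []).append(positions)
        self._per_site = per_site
        # twin units within each family: mapping family positions -> list of units
        self._units_of_family: dict = {}
        for (site, fam), idx in fam_of.groups.items():
            positions = np.asarray(sorted(idx))
            twins: dict[str, list[int]] = {}
            singles: list[int] = []
            for p in positions:
                t = self.twin_pair[p]
                if t == "":
                    singles.append(p)
                else:
                    twins.setdefault(t, []).append(p)
            units = [np.asarray(v) for v in twins.values()] + [
                np.asarray([s]) for s in singles
            ]
            self._units_of_family[tuple(positions)] = units

    def _permute_within_family(self, positions: np.ndarray, rng) -> np.ndarray:
        """Member-level source ordering for one family's positions."""
        units = self._units_of_family[tuple(positions)]
        out = np.empty(len(positions), dtype=int)
        # exchange same-size units, permute within units
        by_size: dict[int, list[np.ndarray]] = {}
        for u in units:
            by_size.setdefault(len(u), []).append(u)
        slot = {}
        for size, us in by_size.items():
            order = rng.permutation(len(us))
            for j, u in enumerate(us):
                src = us[order[j]]
                slot[tuple(u)] = src[rng.permutation(size)]
        cursor = 0
        for u in units:
            out[cursor : cursor + len(u)] = slot[tuple(u)]
            cursor += len(u)
        # map back to the family's sorted position slots
        targets = np.concatenate(units)
        ordering = np.argsort(targets)
        return out[ordering], targets[ordering]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one valid permutation as an index array ``perm`` (y_star = y[perm])."""
        perm = np.empty(self.n_subjects, dtype=int)
        for site, size_groups in self._per_site.items():
            for size, families in size_groups.items():
                order = rng.permutation(len(families))
                for j, target_fam in enumerate(families):
                    source_fam = families[order[j]]
                    src_sorted, tgt_sorted = self._permute_within_family(source_fam, rng)
                    # assign: target family slots receive source family members
                    perm[target_fam] = src_sorted
        return perm

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        site_col: str = "site_id",
        family_col: str = "family_id",
        twin_col: str = "twin_pair_id",
    ) -> "ExchangeabilityBlocks":
        twin = table[twin_col] if twin_col in table.columns else None
        return cls(table[site_col].to_numpy(), table[family_col].to_numpy(), twin)


def sample_permutation(blocks: ExchangeabilityBlocks, rng) -> np.ndarray:
    """Functional wrapper over :meth:`ExchangeabilityBlocks.sample`."""
    return blocks.sample(rng)


@dataclass
class FreedmanLaneResult:
    p_value: float
    observed: float
    null_stats: np.ndarray = field(repr=False)
    n_dropped: int = 0

    @property
    def n_permutations(self) -> int:
        return len(self.null_stats)


def freedman_lane_null(
    y,
    covariates,
    blocks: ExchangeabilityBlocks,
    statistic,
    B: int = 1000,
    rng=None,
    alternative: str = "greater",
) -> FreedmanLaneResult:
    """Permutation null for ``statistic(y)`` honoring covariates and blocks.

    The reduced model regresses y on the covariates (intercept-only when
    ``covariates`` is None, in which case the procedure reduces to plain
    permutation of y). ``statistic`` must map a reconstructed outcome vector
    to a scalar; larger = stronger evidence under ``alternative="greater"``
    (use ``"two-sided"`` for |stat|).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if covariates is None:
        D = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        D = np.column_stack([np.ones(n), C])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ coef
    resid = y - fitted

    obs = float(statistic(y))
    null_stats = np.empty(B)
    dropped = 0
    kept = 0
    for _ in range(B):
        perm = blocks.sample(rng)
        y_star = fitted + resid[perm]
        s = float(statistic(y_star))
        if not np.isfinite(s):
            dropped += 1
            continue
        null_stats[kept] = s
        kept += 1
    if dropped > 0.01 * B:
        raise RuntimeError(
            f"{dropped}/{B} permutations produced non-finite statistics"
        )
    null_stats = null_stats[:kept]
    if alternative == "greater":
        count = int(np.sum(null_stats >= obs))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(null_stats) >= abs(obs)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1.0 + count) / (kept + 1.0)
    return FreedmanLaneResult(p_value=p, observed=obs, null_stats=null_stats, n_dropped=dropped)


def make_insample_r_statistic(X, covariates=None, n_components: int = 21):
    """Cheap pipeline statistic for permutation testing.

    Precomputes the covariate hat matrix and the PCA basis of the
    (residualized) edge matrix once; the returned callable maps an outcome
    vector to the in-sample multiple correlation between the outcome
    (residualized for covariates) and its projection on the leading
    components. Refitting the full nested-CV selection per permutation is
    deliberately avoided; the component count is fixed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if covariates is None:
        D = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        D = np.column_stack([np.ones(n), C])
    # residual-maker for covariates, applied to y* each call
    Q_cov, _ = np.linalg.qr(D)
    Xr = X - Q_cov @ (Q_cov.T @ X)
    Xr = Xr - Xr.mean(axis=0)
    u, s, _ = np.linalg.svd(Xr, full_matrices=False)
    k = min(n_components, int((s > 1e-12 * s[0]).sum()))
    Q = u[:, :k]  # orthonormal basis of component-score space

    def stat(y_star: np.ndarray) -> float:
        y_star = np.asarray(y_star, dtype=float).ravel()
        yr = y_star - Q_cov @ (Q_cov.T @ y_star)
        yr = yr - yr.mean()
        denom = np.linalg.norm(yr)
        if denom == 0:
            return float("nan")
        return float(np.linalg.norm(Q.T @ yr) / denom)

    return stat
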