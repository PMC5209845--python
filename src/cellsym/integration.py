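"""Pairwise morphological integration of terminal lobules.

Each of the 26 per-cell analysis units (24 terminal lobules + 2 polar-lobe
apexes) is GPA-aligned as its own dataset, replicate digitisations are
averaged in tangent space, and allometry is removed by multivariate
regression of shape on centroid size.  Covariation between unit pairs is
then measured by two-block partial least squares (singular warps; the PLS
correlation is the Pearson correlation of the paired SW1 scores) and by
the RV coefficient, with permutation tests.  Because quadrant identity is
inherently ambiguous in a biradial cell, quadrant-level runs of mutually
corresponding pairs are averaged into a role-pair integration matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import GeneralizedProcrustesAnalysis
from .synthetic import Population, TemplateSpec

__all__ = [
    "allometry_correct",
    "TwoBlockPLS",
    "two_block_pls",
    "rv_coefficient",
    "pls_permutation_test",
    "unit_shape_blocks",
    "integration_matrix",
    "mantel_test",
    "IntegrationMatrix",
    "ROLES",
]

ROLES = ("a1", "a2", "b1", "b2", "b3", "b4", "polar")


def allometry_correct(shapes: np.ndarray, sizes: np.ndarray, log_size: bool = False) -> np.ndarray:
    """Remove size-predicted shape variation, returning residuals + consensus.

    Every tangent coordinate is regressed on centroid size by least
    squares; the residuals are added back to the consensus (column means),
    so the output has exactly the input mean and zero correlation with
    size.  With zero size variance the input is returned with a warning.
    """
    shapes = np.asarray(shapes, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be strictly positive")
    x = np.log(sizes) if log_size else sizes
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        import warnings

        warnings.warn("zero size variance; allometry correction is the identity", stacklevel=2)
        return shapes.copy()
    consensus = shapes.mean(axis=0)
    centered = shapes - consensus
    slope = (xc @ centered) / denom  # (d,)
    return consensus + centered - np.outer(xc, slope)


class TwoBlockPLS(BaseEstimator):
    """Two-block partial least squares (singular warps) estimator.

    ``fit`` column-centers both blocks and takes the SVD of their
    cross-covariance matrix.  Specimen scores are the data projected on
    the paired singular vectors; the PLS correlation is the Pearson
    correlation of the first score pair.  For reporting, the SW1 pair is
    oriented so the correlation is non-negative (the raw sign is kept in
    ``raw_correlation_``).

    Attributes
    ----------
    singular_values_ : descending non-negative singular values
    x_weights_, y_weights_ : unit-norm singular vectors (columns)
    x_scores_, y_scores_ : specimen scores
    correlation_ : PLS correlation of the first score pair (reported >= 0)
    raw_correlation_ : same, with its original sign
    rv_ : RV coefficient of the two blocks
    """

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("blocks must have the same number of specimens")
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 specimens")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        cov = Xc.T @ Yc / (n - 1)
        u, s, vt = np.linalg.svd(cov, full_matrices=False)
        self.singular_values_ = s
        self.x_weights_ = u
        self.y_weights_ = vt.T
        self.x_scores_ = Xc @ u
        self.y_scores_ = Yc @ vt.T
        r = np.corrcoef(self.x_scores_[:, 0], self.y_scores_[:, 0])[0, 1]
        self.raw_correlation_ = float(r)
        if r < 0:
            self.y_weights_[:, 0] = -self.y_weights_[:, 0]
            self.y_scores_[:, 0] = -self.y_scores_[:, 0]
        self.correlation_ = abs(float(r))
        self.rv_ = rv_coefficient(X, Y)
        return self


def two_block_pls(X, Y) -> TwoBlockPLS:
    return TwoBlockPLS().fit(X, Y)


def rv_coefficient(X, Y) -> float:
    """Escoufier's RV: a multivariate generalization of squared correlation.

    RV = tr(S_XY S_YX) / sqrt(tr(S_XX^2) tr(S_YY^2)), in [0, 1]; equals the
    squared Pearson correlation for univariate blocks and is invariant
    under orthogonal rotation of either block.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc
    syy = Yc.T @ Yc
    sxy = Xc.T @ Yc
    denom = np.sqrt((sxx**2).sum() * (syy**2).sum())
    if denom == 0:
        raise ValueError("RV undefined for a zero-variance block")
    return float((sxy * sxy).sum() / denom)


def pls_permutation_test(X, Y, n_perm: int = 999, seed: int | None = 0) -> float:
    """Permutation p-value for the PLS correlation of SW1.

    Permutes the specimens of one block relative to the other and
    recomputes the PLS correlation each iteration;
    p = (1 + #{r* >= r_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        import warnings

        warnings.warn("n_perm < 99 gives a very coarse p-value resolution", stacklevel=2)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    obs = TwoBlockPLS().fit(X, Y).correlation_
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Y))
        if TwoBlockPLS().fit(X, Y[perm]).correlation_ >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def unit_shape_blocks(
    population: Population, allometry: str = "per-lobule"
) -> dict[str, np.ndarray]:
    """Per-unit specimen-by-coordinate shape blocks, replicate-averaged.

    Each of the 26 units is GPA-aligned as its own dataset across all
    cells and replicates; tangent coordinates are averaged over replicates
    per cell, then allometry-corrected (``"per-lobule"`` uses the unit's
    own centroid size, ``"whole-cell"`` the full-cell size, ``"off"``
    skips the correction).
    """
    if allometry not in ("per-lobule", "whole-cell", "off"):
        raise ValueError("allometry must be 'per-lobule', 'whole-cell' or 'off'")
    tpl = population.template
    n, reps, k, _ = population.coords.shape
    if allometry == "whole-cell":
        whole = population.coords.reshape(n * reps, k, 2)
        cell_size = (
            np.sqrt(((whole - whole.mean(axis=1, keepdims=True)) ** 2).sum(axis=(1, 2)))
            .reshape(n, reps)
            .mean(axis=1)
        )
    blocks = {}
    for name, unit in tpl.units.items():
        configs = population.coords[:, :, unit.indices, :].reshape(n * reps, 7, 2)
        est = GeneralizedProcrustesAnalysis().fit(configs)
        tangent = est.transform().reshape(n, reps, 14).mean(axis=1)
        if allometry == "off":
            blocks[name] = tangent
        else:
            if allometry == "per-lobule":
                sizes = est.centroid_sizes_.reshape(n, reps).mean(axis=1)
            else:
                sizes = cell_size
            blocks[name] = allometry_correct(tangent, sizes)
    return blocks


def _run_pairs(role_a: str, role_b: str, kind: str) -> list[tuple[str, str]]:
    """Quadrant-level unit pairings contributing to one role-pair cell."""
    apex = {"a": "up", "b": "up", "c": "lp", "d": "lp"}
    if kind == "within":
        if role_a == "polar" and role_b == "polar":
            return []
        if role_b == "polar":
            role_a, role_b = role_b, role_a
        if role_a == "polar":
            return [(apex[q], f"{q}{role_b}") for q in "abcd"]
        return [(f"{q}{role_a}", f"{q}{role_b}") for q in "abcd"]
    # cross-semicell pairings
    if role_a == "polar" and role_b == "polar":
        return [("up", "lp")]
    if role_b == "polar":
        role_a, role_b = role_b, role_a
    if role_a == "polar":
        return [("up", f"{q}{role_b}") for q in "cd"] + [("lp", f"{q}{role_b}") for q in "ab"]
    pairs = [(f"{qu}{role_a}", f"{ql}{role_b}") for qu in "ab" for ql in "cd"]
    if role_a != role_b:
        pairs += [(f"{qu}{role_b}", f"{ql}{role_a}") for qu in "ab" for ql in "cd"]
    return pairs


@dataclass
class IntegrationMatrix:
    """Role-pair matrices of averaged PLS correlations, RV and p-values.

    ``within`` matrices pair roles inside a semicell (same-quadrant runs,
    diagonal masked); ``cross`` matrices pair roles across the two
    semicells (diagonal = the same role on opposite semicells).  ``runs``
    lists every contributing quadrant-level PLS run.
    """

    within_pls: pd.DataFrame
    within_rv: pd.DataFrame
    within_p: pd.DataFrame  # median permutation p over the contributing runs
    cross_pls: pd.DataFrame
    cross_rv: pd.DataFrame
    cross_p: pd.DataFrame
    runs: pd.DataFrame


def integration_matrix(
    population: Population,
    n_perm: int = 999,
    seed: int | None = 0,
    allometry: str = "per-lobule",
    blocks: dict[str, np.ndarray] | None = None,
) -> IntegrationMatrix:
    """Average quadrant-level PLS/RV runs into role-pair integration matrices."""
    if blocks is None:
        blocks = unit_shape_blocks(population, allometry=allometry)
    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    roles = list(ROLES)
    mats = {
        key: pd.DataFrame(np.nan, index=roles, columns=roles)
        for key in ("within_pls", "within_rv", "within_p", "cross_pls", "cross_rv", "cross_p")
    }
    run_rows = []
    for i, ra in enumerate(roles):
        for j in range(i, len(roles)):
            rb = roles[j]
            for kind in ("within", "cross"):
                if kind == "within" and ra == rb:
                    continue  # diagonal masked
                pairs = _run_pairs(ra, rb, kind)
                if not pairs:
                    continue
                rs, rvs, ps = [], [], []
                for ua, ub in pairs:
                    run_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                    pls = TwoBlockPLS().fit(blocks[ua], blocks[ub])
                    p = pls_permutation_test(blocks[ua], blocks[ub], n_perm=n_perm, seed=run_seed)
                    rs.append(pls.correlation_)
                    rvs.append(pls.rv_)
                    ps.append(p)
                    run_rows.append(
                        {
                            "role_a": ra, "role_b": rb, "kind": kind,
                            "unit_a": ua, "unit_b": ub,
                            "pls_correlation": pls.correlation_, "rv": pls.rv_, "p": p,
                        }
                    )
                mats[f"{kind}_pls"].loc[ra, rb] = mats[f"{kind}_pls"].loc[rb, ra] = np.mean(rs)
                mats[f"{kind}_rv"].loc[ra, rb] = mats[f"{kind}_rv"].loc[rb, ra] = np.mean(rvs)
                mats[f"{kind}_p"].loc[ra, rb] = mats[f"{kind}_p"].loc[rb, ra] = np.median(ps)
    return IntegrationMatrix(
        within_pls=mats["within_pls"], within_rv=mats["within_rv"], within_p=mats["within_p"],
        cross_pls=mats["cross_pls"], cross_rv=mats["cross_rv"], cross_p=mats["cross_p"],
        runs=pd.DataFrame(run_rows),
    )


def mantel_test(
    matrix_a, matrix_b, n_perm: int = 999, seed: int | None = 0
) -> tuple[float, float]:
    """Mantel correlation between two symmetric value matrices.

    Pearson correlation over the off-diagonal upper-triangle entries
    (cells that are NaN in either matrix are excluded); the null permutes
    rows and columns of one matrix simultaneously.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    m = a.shape[0]
    iu, ju = np.triu_indices(m, k=1)

    def corr(bm):
        x, y = a[iu, ju], bm[iu, ju]
        valid = ~(np.isnan(x) | np.isnan(y))
        return float(np.corrcoef(x[valid], y[valid])[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if corr(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)
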