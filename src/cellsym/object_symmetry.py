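"""Full-cell biradial object-symmetry decomposition.

Each cell is expanded into its four-fold symmetry orbit (identity, the two
labeled axis reflections, and their product), all copies enter one joint
GPA, and the centered tangent coordinates are apportioned among the four
orthogonal character subspaces of the biradial group:

* totally symmetric variation,
* inter-semicell asymmetry (across the isthmus axis),
* left-right asymmetry,
* transversal asymmetry (across both axes).

Per-cell subspace magnitudes are compared by one-way repeated-measures
ANOVA with Tukey HSD pairwise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    GeneralizedProcrustesAnalysis,
    RelabelMap,
    apply_labeled_reflection,
    center,
    optimal_rotation,
)
from .symmetry import SymmetryProjector, enumerate_effects
from .synthetic import BIRADIAL_AXES, Population, TemplateSpec, biradial_projectors

__all__ = [
    "build_symmetry_orbit",
    "decompose_object_symmetry",
    "per_cell_subspace_magnitude",
    "repeated_measures_anova",
    "rm_anova_from_sums_of_squares",
    "cell_mean_configurations",
    "orient_to_symmetry_frame",
    "object_symmetry_analysis",
    "VarianceDecomposition",
    "RMAnovaTable",
]

TRANSFORMS = ("identity", "vertical", "horizontal", "both")


def orient_to_symmetry_frame(coords: np.ndarray, consensus: np.ndarray, template) -> np.ndarray:
    """Rotate a superimposed dataset so its consensus sits in the template frame.

    GPA fixes orientation only up to one global rotation, but the character
    projectors mirror across the *coordinate* axes, so the joint dataset
    must first be rotated to put the symmetry axes of the consensus on the
    coordinate axes.  The rotation (proper, computed by labeled ordinary
    Procrustes of the consensus onto the unit-size template) is applied
    uniformly, which changes no shape relationship.
    """
    ref = center(template.points)
    ref = ref / np.sqrt((ref**2).sum())
    rot = optimal_rotation(consensus, ref)
    return np.asarray(coords) @ rot


def cell_mean_configurations(population: Population) -> np.ndarray:
    """Average the digitisation replicates of each cell.

    Replicates carry independent rigid motions, so each later replicate is
    first rigidly aligned (rotation + translation, no scaling) onto the
    first before coordinate-wise averaging.
    """
    n, reps, k, _ = population.coords.shape
    out = np.empty((n, k, 2))
    for c in range(n):
        ref = center(population.coords[c, 0])
        acc = ref.copy()
        for r in range(1, reps):
            cfg = center(population.coords[c, r])
            acc += cfg @ optimal_rotation(cfg, ref)
        out[c] = acc / reps
    return out


def build_symmetry_orbit(
    cells, vertical_map: RelabelMap, horizontal_map: RelabelMap, cell_ids=None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expand n cells into their 4n-configuration biradial symmetry orbit.

    For every cell emits, in deterministic order, the identity copy, the
    vertical reflection, the horizontal reflection, and the reflection
    across both axes, each relabeled to consistent landmark order.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3:
        raise ValueError("expected an (n, k, 2) array of cells")
    if cells.shape[1] != len(vertical_map.permutation):
        raise ValueError(
            f"landmark count {cells.shape[1]} does not match relabel maps "
            f"({len(vertical_map.permutation)})"
        )
    n = len(cells)
    if cell_ids is None:
        cell_ids = [f"cell{c + 1:03d}" for c in range(n)]
    v = apply_labeled_reflection(cells, vertical_map)
    h = apply_labeled_reflection(cells, horizontal_map)
    vh = apply_labeled_reflection(v, horizontal_map)
    orbit = np.stack([cells, v, h, vh], axis=1).reshape(4 * n, cells.shape[1], 2)
    tags = pd.DataFrame(
        {
            "cell_index": np.repeat(np.arange(n), 4),
            "cell_id": np.repeat(cell_ids, 4),
            "transform": np.tile(TRANSFORMS, n),
        }
    )
    return orbit, tags


@dataclass
class VarianceDecomposition:
    """Apportionment of orbit shape variation among the four character subspaces."""

    effects: list[str]
    ss: dict[str, float]
    proportions: dict[str, float]
    eigenvalues: dict[str, np.ndarray]  # per-subspace PCA (sum = subspace SS)
    axes: dict[str, np.ndarray]  # per-subspace principal axes (rows)
    joint_eigenvalues: np.ndarray
    joint_axes: np.ndarray
    joint_assignment: list[str]  # subspace holding >= 99% of each joint axis
    total_ss: float
    grand_mean: np.ndarray
    tangent: np.ndarray
    tags: pd.DataFrame
    projectors: dict[str, SymmetryProjector]

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effects,
                "ss": [self.ss[e] for e in self.effects],
                "proportion": [self.proportions[e] for e in self.effects],
            }
        )


def _pca_axis_sign(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    out = axes.copy()
    for i, row in enumerate(out):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            out[i] = -row
    return out


def decompose_object_symmetry(
    tangent: np.ndarray,
    tags: pd.DataFrame,
    projectors: dict[str, SymmetryProjector],
    classification_threshold: float = 0.99,
    rank_tol: float = 1e-9,
) -> VarianceDecomposition:
    """Apportion centered orbit tangent coordinates among character subspaces.

    ``tangent`` is the (4n, k, 2) tangent-coordinate output of a joint GPA
    of the symmetry orbit.  Sums of squares are computed inside each
    projected subspace; a joint PCA is also computed and every joint axis
    is classified to the subspace holding at least
    ``classification_threshold`` of its squared norm (a degeneracy warning
    lists unclassifiable axes).
    """
    tangent = np.asarray(tangent, dtype=float)
    n_cfg, k, _ = tangent.shape
    grand_mean = tangent.mean(axis=0)
    centered = tangent - grand_mean
    effects = [e.name for e in enumerate_effects(BIRADIAL_AXES)]

    ss: dict[str, float] = {}
    eigenvalues: dict[str, np.ndarray] = {}
    axes_out: dict[str, np.ndarray] = {}
    for name in effects:
        proj = projectors[name].apply(centered).reshape(n_cfg, -1)
        ss[name] = float((proj**2).sum())
        u, s, vt = np.linalg.svd(proj, full_matrices=False)
        keep = s**2 > rank_tol * max(1.0, s[0] ** 2 if len(s) else 1.0)
        eigenvalues[name] = (s**2)[keep]
        axes_out[name] = _pca_axis_sign(vt[keep])

    total_ss = float((centered.reshape(n_cfg, -1) ** 2).sum())
    proportions = {name: (ss[name] / total_ss if total_ss > 0 else 0.0) for name in effects}

    flat = centered.reshape(n_cfg, -1)
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    keep = s**2 > rank_tol * max(1.0, s[0] ** 2 if len(s) else 1.0)
    joint_eig = (s**2)[keep]
    joint_axes = _pca_axis_sign(vt[keep])
    assignment = []
    unclassified = []
    for i, axis in enumerate(joint_axes):
        shares = {
            name: float((projectors[name].apply(axis.reshape(k, 2)) ** 2).sum())
            for name in effects
        }
        best = max(shares, key=shares.get)
        if shares[best] >= classification_threshold:
            assignment.append(best)
        else:
            assignment.append("mixed")
            unclassified.append(i)
    if unclassified:
        warnings.warn(
            f"joint PCA axes {unclassified} are not confined to a single "
            f"symmetry subspace (threshold {classification_threshold})",
            stacklevel=2,
        )

    return VarianceDecomposition(
        effects=effects, ss=ss, proportions=proportions, eigenvalues=eigenvalues,
        axes=axes_out, joint_eigenvalues=joint_eig, joint_axes=joint_axes,
        joint_assignment=assignment, total_ss=total_ss, grand_mean=grand_mean,
        tangent=tangent, tags=tags, projectors=projectors,
    )


def per_cell_subspace_magnitude(decomposition: VarianceDecomposition) -> pd.DataFrame:
    """Euclidean norm of each cell's centered tangent coordinates per subspace.

    Uses the identity (un-reflected) orbit copy of each cell; by projector
    orthogonality any orbit copy gives the same magnitudes.  The squared
    magnitudes of the four subspaces sum to the squared distance of the
    cell from the grand mean.
    """
    mask = decomposition.tags["transform"] == "identity"
    centered = decomposition.tangent[mask.to_numpy()] - decomposition.grand_mean
    cells = decomposition.tags.loc[mask, "cell_id"].tolist()
    data = {}
    for name in decomposition.effects:
        proj = decomposition.projectors[name].apply(centered)
        data[name] = np.sqrt((proj**2).sum(axis=(1, 2)))
    return pd.DataFrame(data, index=pd.Index(cells, name="cell_id"))


@dataclass
class RMAnovaTable:
    """One-way repeated-measures ANOVA with Tukey HSD pairwise comparisons."""

    table: pd.DataFrame
    f_statistic: float
    p_value: float
    tukey_q: pd.DataFrame
    tukey_p: pd.DataFrame


def rm_anova_from_sums_of_squares(
    ss_between: float,
    df_between: int,
    ss_within: float,
    df_within: int,
    ss_individuals: float,
    df_individuals: int,
) -> tuple[float, float]:
    """Repeated-measures F (and p) from a printed SS/df ledger.

    The residual stratum is the within-condition variation minus the
    between-individuals variation; F = MS_between / MS_residual.
    """
    ss_resid = ss_within - ss_individuals
    df_resid = df_within - df_individuals
    f = (ss_between / df_between) / (ss_resid / df_resid)
    p = float(stats.f.sf(f, df_between, df_resid))
    return float(f), p


def repeated_measures_anova(magnitudes) -> RMAnovaTable:
    """One-way repeated-measures ANOVA over within-cell subspace magnitudes.

    ``magnitudes`` is an (n, m) matrix (cells x conditions, here m = 4
    symmetry components).  The two-way additive decomposition treats cells
    as random subjects; F = MS_between / MS_residual on (m-1, (n-1)(m-1))
    degrees of freedom, and Tukey HSD uses the studentized range on the
    residual mean square.
    """
    if isinstance(magnitudes, pd.DataFrame):
        names = list(magnitudes.columns)
        x = magnitudes.to_numpy(dtype=float)
    else:
        x = np.asarray(magnitudes, dtype=float)
        names = [f"component{j + 1}" for j in range(x.shape[1])]
    n, m = x.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported")

    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_between = n * ((col_means - grand) ** 2).sum()
    ss_subjects = m * ((row_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_resid = ss_total - ss_between - ss_subjects
    df_between, df_subjects = m - 1, n - 1
    df_resid = (n - 1) * (m - 1)
    ms_between = ss_between / df_between
    ms_resid = ss_resid / df_resid
    if ss_between <= 1e-12 * max(ss_total, 1e-300) or ms_resid == 0:
        f = 0.0
        p = 1.0
    else:
        f = ms_between / ms_resid
        p = float(stats.f.sf(f, df_between, df_resid))

    table = pd.DataFrame(
        [
            ("between-components", ss_between, df_between, ms_between),
            ("within-components", ss_subjects + ss_resid, df_subjects + df_resid, np.nan),
            ("between-individuals", ss_subjects, df_subjects, ss_subjects / df_subjects),
            ("residual", ss_resid, df_resid, ms_resid),
            ("total", ss_total, n * m - 1, np.nan),
        ],
        columns=["source", "ss", "df", "ms"],
    )

    q = np.zeros((m, m))
    pq = np.ones((m, m))
    se = np.sqrt(ms_resid / n)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            q[i, j] = abs(col_means[i] - col_means[j]) / se if se > 0 else 0.0
            pq[i, j] = float(stats.studentized_range.sf(q[i, j], m, df_resid)) if se > 0 else 1.0
    tukey_q = pd.DataFrame(q, index=names, columns=names)
    tukey_p = pd.DataFrame(pq, index=names, columns=names)
    return RMAnovaTable(
        table=table, f_statistic=float(f), p_value=float(p), tukey_q=tukey_q, tukey_p=tukey_p
    )


@dataclass
class ObjectSymmetryAnalysis:
    decomposition: VarianceDecomposition
    magnitudes: pd.DataFrame
    anova: RMAnovaTable
    gpa_converged: bool


def object_symmetry_analysis(
    cells: np.ndarray,
    template: TemplateSpec,
    cell_ids=None,
) -> ObjectSymmetryAnalysis:
    """Run the full object-symmetry pipeline on per-cell configurations.

    ``cells`` is an (n, k, 2) array (one configuration per cell, replicate
    averaged upstream if applicable).
    """
    orbit, tags = build_symmetry_orbit(
        cells, template.vertical_map, template.horizontal_map, cell_ids=cell_ids
    )
    est = GeneralizedProcrustesAnalysis().fit(orbit)
    tangent = orient_to_symmetry_frame(est.transform(), est.mean_shape_, template)
    projectors = biradial_projectors(template)
    decomposition = decompose_object_symmetry(tangent, tags, projectors)
    magnitudes = per_cell_subspace_magnitude(decomposition)
    anova = repeated_measures_anova(magnitudes)
    return ObjectSymmetryAnalysis(
        decomposition=decomposition, magnitudes=magnitudes, anova=anova,
        gpa_converged=est.converged_,
    )
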