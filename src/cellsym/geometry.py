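"""Core landmark geometry.

Landmark configurations, centroid size, generalized Procrustes analysis
(GPA), Kendall tangent-space coordinates, Procrustes distances, and labeled
reflections (coordinate mirror plus landmark relabeling).

Conventions
-----------
* A configuration is a ``(k, 2)`` float array of landmark coordinates;
  stacks of configurations are ``(n, k, 2)``.
* The y axis points up.  Reflection across the *vertical* axis negates x
  (a left-right mirror); reflection across the *horizontal* axis negates y
  (swapping the two semicells of a cell).
* GPA uses proper rotations only (determinant +1).  Mirroring is never done
  implicitly by the superimposition; it happens only through an explicit
  :class:`RelabelMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "LandmarkConfiguration",
    "RelabelMap",
    "GPAResult",
    "GeneralizedProcrustesAnalysis",
    "centroid_size",
    "center",
    "gpa",
    "optimal_rotation",
    "opa_align",
    "procrustes_distance",
    "apply_labeled_reflection",
]


@dataclass
class LandmarkConfiguration:
    """One ordered set of 2-D landmarks with cell/replicate identity.

    Parameters
    ----------
    points : (k, 2) array
        Landmark coordinates in arbitrary length units (micrometres in the
        motivating data).  Point order is meaningful and preserved by all
        I/O round trips.
    cell_id : str
        Identifier of the cell the configuration belongs to.
    replicate_id : int
        Digitization index (1 or 2 in a twice-digitised dataset).
    labels : sequence of str, optional
        Per-landmark semantic tags (quadrant / lobule membership).
    """

    points: np.ndarray
    cell_id: str = ""
    replicate_id: int = 1
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinate in configuration {self.cell_id!r}")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels length must equal number of landmarks")

    @property
    def k(self) -> int:
        return self.points.shape[0]


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark deviations from the centroid.

    Translation- and rotation-invariant; scales linearly with the
    configuration.  Returns 0 for fully coincident landmarks (such a
    configuration must be rejected before entering GPA).
    """
    pts = _as_points(config)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


def center(config) -> np.ndarray:
    pts = _as_points(config)
    return pts - pts.mean(axis=0)


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper 2-D rotation R minimizing ||a @ R - b||_F.

    Closed form in 2-D: with M = a.T @ b, the optimum is the rotation by
    atan2(M01 - M10, M00 + M11).  Reflections are never returned.
    """
    m = a.T @ b
    c, s = m[0, 0] + m[1, 1], m[0, 1] - m[1, 0]
    norm = np.hypot(c, s)
    if norm == 0.0:  # degenerate; any rotation is optimal
        return np.eye(2)
    c, s = c / norm, s / norm
    return np.array([[c, s], [-s, c]])


def _rotate_stack_to(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate every (k,2) slice of ``stack`` onto ``target`` (proper rotations)."""
    m = np.einsum("nki,kj->nij", stack, target)
    c = m[:, 0, 0] + m[:, 1, 1]
    s = m[:, 0, 1] - m[:, 1, 0]
    norm = np.hypot(c, s)
    norm[norm == 0.0] = 1.0
    c, s = c / norm, s / norm
    rot = np.empty((len(stack), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = s
    rot[:, 1, 0] = -s
    rot[:, 1, 1] = c
    return np.einsum("nki,nij->nkj", stack, rot)


def opa_align(a, b) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary (two-configuration) Procrustes alignment.

    Centers and scales both configurations to unit centroid size, rotates
    ``a`` onto ``b`` by a proper rotation, and returns
    ``(a_aligned, b_scaled, distance)`` where distance is the full
    Procrustes (root sum of squares) distance between the superimposed
    configurations.
    """
    pa, pb = center(a), center(b)
    sa, sb = np.sqrt((pa**2).sum()), np.sqrt((pb**2).sum())
    if sa == 0 or sb == 0:
        raise ValueError("degenerate (zero-size) configuration")
    pa, pb = pa / sa, pb / sb
    rot = optimal_rotation(pa, pb)
    pa = pa @ rot
    return pa, pb, float(np.sqrt(((pa - pb) ** 2).sum()))


@dataclass
class GPAResult:
    """Outcome of a generalized Procrustes superimposition.

    ``aligned`` holds the unit-size, rotated configurations; ``tangent``
    their orthogonal projections onto the Kendall tangent space at the
    consensus.  ``mean_shape`` equals the coordinate-wise mean of the
    aligned configurations.  ``ss_history`` records the total Procrustes
    sum of squares after every iteration (non-increasing).
    """

    aligned: np.ndarray
    tangent: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool
    ss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


class GeneralizedProcrustesAnalysis(BaseEstimator):
    """Generalized Procrustes superimposition as a scikit-learn transformer.

    ``fit`` iterates: center, scale to unit centroid size, rotate each
    configuration to the current consensus (proper rotations only),
    recompute the consensus as the mean of the rotated configurations,
    until the consensus RMS change falls below ``tol``.  ``transform``
    returns tangent-space coordinates (orthogonal projection onto the
    tangent hyperplane at the consensus).

    Parameters
    ----------
    max_iter : int, default 100
    tol : float, default 1e-10
        Convergence threshold on the RMS change of the consensus.

    Attributes
    ----------
    mean_shape_ : (k, 2) array
        Consensus configuration (mean of the aligned configurations).
    centroid_sizes_ : (n,) array
    n_iterations_ : int
    converged_ : bool
    ss_history_ : array
        Total Procrustes sum of squares per iteration.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = self._validate(X)
        n, k, _ = X.shape
        sizes = np.sqrt(((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=(1, 2)))
        if np.any(sizes == 0):
            raise ValueError("degenerate (zero-size) configuration in input")
        scaled = (X - X.mean(axis=1, keepdims=True)) / sizes[:, None, None]

        consensus = scaled[0].copy()
        aligned = scaled
        ss_history = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            aligned = _rotate_stack_to(scaled, consensus)
            new_consensus = aligned.mean(axis=0)
            ss_history.append(float(((aligned - new_consensus) ** 2).sum()))
            change = np.sqrt(((new_consensus - consensus) ** 2).mean())
            consensus = new_consensus
            if change < self.tol:
                converged = True
                break

        self.aligned_ = aligned
        self.mean_shape_ = consensus
        self.centroid_sizes_ = sizes
        self.n_iterations_ = it
        self.converged_ = converged
        self.ss_history_ = np.asarray(ss_history)
        return self

    def transform(self, X=None):
        """Project aligned configurations onto the tangent space at the consensus.

        With ``X=None`` (the common case) the configurations aligned during
        ``fit`` are projected; otherwise ``X`` is centered, scaled, rotated
        onto the fitted consensus and then projected.
        """
        if X is None:
            aligned = self.aligned_
        else:
            X = self._validate(X)
            sizes = np.sqrt(((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=(1, 2)))
            scaled = (X - X.mean(axis=1, keepdims=True)) / sizes[:, None, None]
            aligned = _rotate_stack_to(scaled, self.mean_shape_)
        m = self.mean_shape_.ravel()
        mhat = m / np.linalg.norm(m)
        flat = aligned.reshape(len(aligned), -1)
        # orthogonal projection onto the affine tangent plane through the consensus
        proj = flat - np.outer((flat - m) @ mhat, mhat)
        return proj.reshape(aligned.shape)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()

    @staticmethod
    def _validate(X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            ks = {np.asarray(_as_points(c)).shape for c in X}
            if len(ks) > 1:
                raise ValueError(f"configurations have non-uniform landmark counts: {ks}")
            X = np.stack([_as_points(c) for c in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) array of configurations")
        if X.shape[0] < 2:
            raise ValueError("GPA needs at least two configurations")
        return X


def gpa(configs, max_iter: int = 100, tol: float = 1e-10) -> GPAResult:
    """Functional wrapper around :class:`GeneralizedProcrustesAnalysis`."""
    est = GeneralizedProcrustesAnalysis(max_iter=max_iter, tol=tol).fit(configs)
    return GPAResult(
        aligned=est.aligned_,
        tangent=est.transform(),
        mean_shape=est.mean_shape_,
        centroid_sizes=est.centroid_sizes_,
        n_iterations=est.n_iterations_,
        converged=est.converged_,
        ss_history=est.ss_history_,
    )


def procrustes_distance(a, b) -> float:
    """Tangent Procrustes distance: Euclidean norm of the coordinate difference.

    Both configurations must live in the same joint superimposition /
    tangent space (e.g. two rows of ``GPAResult.tangent``).
    """
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ValueError(f"landmark count mismatch: {pa.shape} vs {pb.shape}")
    return float(np.sqrt(((pa - pb) ** 2).sum()))


@dataclass
class RelabelMap:
    """A labeled reflection: coordinate mirror plus a landmark relabeling.

    ``axis`` is ``"vertical"`` (negate x) or ``"horizontal"`` (negate y);
    ``permutation[i]`` gives the source landmark whose coordinates land at
    index ``i`` after relabeling.  The permutation must be an involution,
    which makes the whole labeled reflection an involution as well.
    """

    axis: str
    permutation: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError(f"unknown axis {self.axis!r}")
        self.permutation = np.asarray(self.permutation, dtype=int)
        p = self.permutation
        if sorted(p.tolist()) != list(range(len(p))):
            raise ValueError("permutation is not a permutation of 0..k-1")
        if not np.array_equal(p[p], np.arange(len(p))):
            raise ValueError("relabeling permutation must be an involution")


def apply_labeled_reflection(config, rmap: RelabelMap):
    """Reflect coordinates across the map's axis, then relabel the landmarks.

    Applying the same map twice returns the input exactly.  Accepts a
    ``(k, 2)`` / ``(n, k, 2)`` array or a :class:`LandmarkConfiguration`
    (returned as the same type).
    """
    pts = _as_points(config)
    if pts.shape[-2] != len(rmap.permutation):
        raise ValueError("permutation length does not match landmark count")
    out = pts.copy()
    if rmap.axis == "vertical":
        out[..., 0] = -out[..., 0]
    else:
        out[..., 1] = -out[..., 1]
    out = out[..., rmap.permutation, :]
    if isinstance(config, LandmarkConfiguration):
        return LandmarkConfiguration(
            out, cell_id=config.cell_id, replicate_id=config.replicate_id,
            labels=config.labels,
        )
    return out
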