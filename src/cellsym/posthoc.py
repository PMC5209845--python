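"""Post-hoc bootstrap test on semicell Procrustes distances.

For one terminal-lobule role, the two same-semicell copies (left and
right quadrant, replicates averaged first) are averaged on each semicell;
the tangent Procrustes distance between the two semicell averages is the
intra-cell statistic.  Its mean over cells is compared against a bootstrap
distribution of means of inter-cell distances (semicell averages of
*different* cells, both cross-semicell pairings pooled), testing whether
opposite semicells are more similar than unrelated semicells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matching import LobuleDataset

__all__ = ["BootstrapPDResult", "semicell_average_pd", "bootstrap_intercell_test", "semicell_role_means"]


def _role_positions(dataset: LobuleDataset, role: str) -> dict[str, list[str]]:
    by_semicell: dict[str, list[str]] = {"upper": [], "lower": []}
    for pos in dataset.positions:
        if dataset.role_of(pos) == role:
            by_semicell[dataset.semicell_of(pos)].append(pos)
    if not by_semicell["upper"] or not by_semicell["lower"]:
        raise ValueError(f"role {role!r} not present on both semicells")
    return by_semicell


def semicell_role_means(dataset: LobuleDataset, role: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell semicell averages of one lobule role in tangent space.

    Returns (upper, lower), each (n_cells, 14): replicate-averaged,
    then averaged over the two same-semicell quadrant copies.
    """
    if dataset.tangent is None or not dataset.canonicalized:
        raise ValueError("dataset must be canonicalized and GPA-aligned")
    by_semicell = _role_positions(dataset, role)
    n, P, reps = dataset.n_cells, dataset.n_positions, dataset.n_replicates
    y = dataset.tangent.reshape(n, P, reps, 14).mean(axis=2)
    pos_index = {pos: i for i, pos in enumerate(dataset.positions)}
    out = {}
    for semicell, poss in by_semicell.items():
        idx = [pos_index[p] for p in poss]
        out[semicell] = y[:, idx].mean(axis=1)
    return out["upper"], out["lower"]


def semicell_average_pd(dataset: LobuleDataset, role: str) -> np.ndarray:
    """Intra-cell tangent PD between opposite-semicell averages of one role."""
    upper, lower = semicell_role_means(dataset, role)
    return np.sqrt(((upper - lower) ** 2).sum(axis=1))


@dataclass
class BootstrapPDResult:
    """Observed intra-cell mean PD against the inter-cell bootstrap distribution.

    ``rank`` counts bootstrap means below the observed value; a small rank
    means opposite semicells are more similar than semicells of different
    cells.
    """

    role: str
    observed: float
    bootstrap_means: np.ndarray
    rank: int
    n_boot: int
    intercell_pds: np.ndarray


def bootstrap_intercell_test(
    dataset: LobuleDataset,
    role: str,
    n_boot: int = 999,
    seed: int | None = 0,
) -> BootstrapPDResult:
    """Bootstrap test of intra-cell vs inter-cell semicell shape distances.

    The inter-cell set holds the PDs between semicell-averaged role
    configurations of all distinct cell pairs, pooling both cross-semicell
    pairings (2 * C(n, 2) values).  Each bootstrap replicate draws n
    values with replacement and records their mean.
    """
    if n_boot < 99:
        warnings.warn("n_boot < 99 gives a very coarse rank resolution", stacklevel=2)
    upper, lower = semicell_role_means(dataset, role)
    n = len(upper)
    if n < 2:
        raise ValueError("need at least 2 cells")
    observed = float(np.sqrt(((upper - lower) ** 2).sum(axis=1)).mean())

    iu, ju = np.triu_indices(n, k=1)
    pds_ul = np.sqrt(((upper[iu] - lower[ju]) ** 2).sum(axis=1))
    pds_lu = np.sqrt(((lower[iu] - upper[ju]) ** 2).sum(axis=1))
    # sorted so the pooled set (and hence the seeded draws) does not depend
    # on the arbitrary labeling of which semicell is "first"
    intercell = np.sort(np.concatenate([pds_ul, pds_lu]))

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(intercell), size=(n_boot, n))
    boot_means = intercell[draws].mean(axis=1)
    rank = int((boot_means < observed).sum())
    return BootstrapPDResult(
        role=role, observed=observed, bootstrap_means=boot_means, rank=rank,
        n_boot=n_boot, intercell_pds=intercell,
    )
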