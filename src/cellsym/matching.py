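"""Matching-symmetry analysis of terminal lobules.

Each cell contributes 8 (LLS) or 16 (ULS) seven-landmark terminal-lobule
configurations per digitisation replicate.  Lobules are brought to a
common orientation class by sequential labeled reflections (one mirror per
-1 axis bit of the position), all configurations enter one joint GPA, and
the tangent sums of squares are decomposed exactly across

* the individual (cell) effect — totally symmetric variation,
* one nested asymmetric effect per non-trivial character of the sublobe's
  reflection group (7 for LLS, 15 for ULS),
* the measurement-error stratum (replicate deviations).

Pseudo-F ratios test each effect against the pooled remaining nested
asymmetric effects; p-values and Z effect sizes come from permutation
distributions of MS_effect / MS_error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .geometry import GeneralizedProcrustesAnalysis
from .symmetry import CharacterEffect, enumerate_effects, sign_matrix
from .synthetic import LLS_AXES, ULS_AXES, Population, TemplateSpec, _REV

__all__ = [
    "LobuleDataset",
    "AnovaTable",
    "extract_lobules",
    "canonicalize_lobules",
    "align_lobules",
    "procrustes_anova",
    "pooled_pseudo_f",
    "matching_anova",
    "effect_display_name",
]

_DISPLAY = {
    "LLS": {
        "semicell": "Inter-semicell asymmetry",
        "left-right": "Left-right asymmetry",
        "semicell*left-right": "Transversal asymmetry",
        "intra-lobe": "Intra-lobe asymmetry",
        "semicell*intra-lobe": "Intra-lobe and Inter-semicell",
        "left-right*intra-lobe": "Intra-lobe and Left-right",
        "semicell*left-right*intra-lobe": "Intra-lobe and Transversal",
    },
    "ULS": {
        "semicell": "Inter-semicell asymmetry",
        "left-right": "Left-right asymmetry",
        "semicell*left-right": "Transversal asymmetry",
        "main-incision": "Inter-3rd-order-lobules asymmetry",
        "minor-incision": "Intra-3rd-order-lobules asymmetry (type I)",
        "main-incision*minor-incision": "Intra-3rd-order-lobules asymmetry (type II)",
        "semicell*main-incision": "Inter-3rd-order-lobules and Inter-semicell",
        "left-right*main-incision": "Inter-3rd-order-lobules and Left-right",
        "semicell*left-right*main-incision": "Inter-3rd-order-lobules and Transversal",
        "semicell*minor-incision": "Intra-3rd-order-lobules (type I) and Inter-semicell",
        "left-right*minor-incision": "Intra-3rd-order-lobules (type I) and Left-right",
        "semicell*left-right*minor-incision": "Intra-3rd-order-lobules (type I) and Transversal",
        "semicell*main-incision*minor-incision": "Intra-3rd-order-lobules (type II) and Inter-semicell",
        "left-right*main-incision*minor-incision": "Intra-3rd-order-lobules (type II) and Left-right",
        "semicell*left-right*main-incision*minor-incision": "Intra-3rd-order-lobules (type II) and Transversal",
    },
}


def effect_display_name(sublobe: str, effect: CharacterEffect | str) -> str:
    name = effect if isinstance(effect, str) else effect.name
    if name == "symmetric":
        return "Individual"
    return _DISPLAY.get(sublobe, {}).get(name, name)


@dataclass
class LobuleDataset:
    """Seven-landmark lobule configurations indexed by cell x position x replicate.

    Row order is (cell, position, replicate), positions in the fixed order
    of ``positions``; this complete crossing is what the nested ANOVA
    relies on.  ``tangent`` is populated by :func:`align_lobules`.
    """

    coords: np.ndarray  # (N, 7, 2)
    index: pd.DataFrame  # cell_id, cell_index, position, replicate
    sublobe: str  # "LLS" or "ULS"
    axes: tuple[str, ...]
    bits: dict[str, tuple[int, ...]]
    positions: list[str]
    canonicalized: bool = False
    tangent: np.ndarray | None = None
    sizes: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.index["cell_index"].nunique()

    @property
    def n_replicates(self) -> int:
        return self.index["replicate"].nunique()

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def role_of(self, position: str) -> str:
        return position[1:]

    def semicell_of(self, position: str) -> str:
        return "upper" if self.bits[position][0] == 1 else "lower"


def extract_lobules(
    coords: np.ndarray | Population,
    template: TemplateSpec,
    sublobe: str,
    cell_ids=None,
) -> LobuleDataset:
    """Slice full-cell configurations into per-position lobule configurations.

    ``coords`` is (n_cells, n_replicates, k, 2) (or a Population).  Emits
    n_cells * n_positions * n_replicates seven-landmark configurations:
    1088 for LLS and 2176 for ULS at 68 twice-digitised cells.
    """
    if isinstance(coords, Population):
        cell_ids = coords.cell_ids
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        coords = coords[:, None]
    n, reps, k, _ = coords.shape
    if sublobe not in ("LLS", "ULS"):
        raise ValueError("sublobe must be 'LLS' or 'ULS'")
    lobule_map = template.lobule_map(sublobe)
    bits = template.position_bits(sublobe)
    all_idx = np.concatenate(list(lobule_map.values()))
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("lobule index sets overlap")
    if all_idx.max() >= k:
        raise ValueError("lobule map indexes beyond the landmark count")
    for pos, idx in lobule_map.items():
        if len(idx) != 7:
            raise ValueError(f"position {pos} does not map to 7 landmarks")
    positions = sorted(lobule_map)
    if cell_ids is None:
        cell_ids = [f"cell{c + 1:03d}" for c in range(n)]

    rows = []
    out = np.empty((n * len(positions) * reps, 7, 2))
    i = 0
    for c in range(n):
        for pos in positions:
            for r in range(reps):
                out[i] = coords[c, r][lobule_map[pos]]
                rows.append((cell_ids[c], c, pos, r + 1))
                i += 1
    index = pd.DataFrame(rows, columns=["cell_id", "cell_index", "position", "replicate"])
    axes = LLS_AXES if sublobe == "LLS" else ULS_AXES
    return LobuleDataset(
        coords=out, index=index, sublobe=sublobe, axes=axes,
        bits=bits, positions=positions,
    )


def canonicalize_lobules(dataset: LobuleDataset) -> LobuleDataset:
    """Bring all lobule positions into one orientation class.

    Positions whose axis-bit pattern has an odd number of -1 entries are
    mirror images of the reference orientation; they are reflected (x
    negated) with their within-lobule landmark order reversed.  Positions
    with even parity differ from the reference only by a proper rotation,
    which the joint GPA removes.  Idempotent.
    """
    if dataset.canonicalized:
        return dataset
    coords = dataset.coords.copy()
    parity = {
        pos: sum(1 for b in bits if b == -1) % 2 for pos, bits in dataset.bits.items()
    }
    odd_positions = {pos for pos, p in parity.items() if p == 1}
    mask = dataset.index["position"].isin(odd_positions).to_numpy()
    flipped = coords[mask]
    flipped[..., 0] = -flipped[..., 0]
    coords[mask] = flipped[:, _REV, :]
    return dc_replace(dataset, coords=coords, canonicalized=True, tangent=None, sizes=None)


def align_lobules(dataset: LobuleDataset) -> LobuleDataset:
    """Joint GPA of all configurations; stores tangent coordinates and sizes."""
    est = GeneralizedProcrustesAnalysis().fit(dataset.coords)
    return dc_replace(
        dataset, tangent=est.transform(), sizes=est.centroid_sizes_,
    )


@dataclass
class AnovaTable:
    """Procrustes ANOVA ledger with pooled pseudo-F, permutation p and Z."""

    frame: pd.DataFrame
    sublobe: str
    n_perm: int
    seed: int | None
    permutation_scheme: str
    ss_total: float
    df_total: int

    def row(self, source: str) -> pd.Series:
        return self.frame.set_index("effect").loc[source]


def pooled_pseudo_f(ss: dict[str, float], df: dict[str, int]) -> dict[str, float]:
    """Pseudo-F per effect against the pooled remaining nested asymmetric effects.

    ``ss``/``df`` map effect names (including ``"symmetric"`` for the
    individual effect) to their sums of squares and degrees of freedom.
    The individual effect is tested against the pool of all asymmetric
    effects; each asymmetric effect against the pool of the others.
    """
    asym = [name for name in ss if name != "symmetric"]
    if not asym:
        raise ValueError("model has no nested asymmetric effects")
    out = {}
    pooled_ss = sum(ss[a] for a in asym)
    pooled_df = sum(df[a] for a in asym)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["symmetric"] = float(
            (np.float64(ss["symmetric"]) / df["symmetric"]) / (np.float64(pooled_ss) / pooled_df)
        )
        for a in asym:
            rest_ss = pooled_ss - ss[a]
            rest_df = pooled_df - df[a]
            if rest_df <= 0:
                raise ValueError(
                    f"no remaining asymmetric effects to pool against for {a!r}"
                )
            out[a] = float((np.float64(ss[a]) / df[a]) / (np.float64(rest_ss) / rest_df))
    return out


def _component_ss(mean_shapes: np.ndarray, signs: np.ndarray, reps: int) -> np.ndarray:
    """SS per asymmetric character from replicate-mean position shapes.

    ``mean_shapes`` is (n_cells, P, d); ``signs`` is (E, P).  The character
    component of each cell is (1/P) sum_p sign[p] * shape_p, and its SS
    contribution is reps * P * ||component||^2 (one contrast per cell).
    """
    n, P, _ = mean_shapes.shape
    comp = np.einsum("ep,npd->end", signs, mean_shapes) / P
    return reps * P * (comp**2).sum(axis=(1, 2))


def procrustes_anova(
    dataset: LobuleDataset,
    n_perm: int = 999,
    seed: int | None = 0,
    permutation: str = "restricted",
) -> AnovaTable:
    """Nested Procrustes ANOVA of a canonicalized, GPA-aligned lobule dataset.

    The tangent sums of squares are decomposed exactly (Parseval over the
    character basis): individual effect from cell means (df n-1), one
    nested effect per asymmetric character (df n each), measurement error
    from replicate deviations (df n*P*(reps-1)).  Permutation p-values and
    Z scores use MS_effect / MS_error recomputed per permutation; nested
    effects permute position labels within cells (keeping replicate pairs
    together; ``permutation="full"`` uses unrestricted shuffling instead),
    the individual effect shuffles whole lobules across cells.
    """
    if not dataset.canonicalized:
        raise ValueError("dataset must be canonicalized before the ANOVA")
    if dataset.tangent is None:
        raise ValueError("dataset must be GPA-aligned (align_lobules) first")
    if permutation not in ("restricted", "full"):
        raise ValueError("permutation must be 'restricted' or 'full'")
    effects = enumerate_effects(dataset.axes)
    asym_effects = [e for e in effects if not e.is_symmetric]
    n, P, reps = dataset.n_cells, dataset.n_positions, dataset.n_replicates
    N = len(dataset.coords)
    if N != n * P * reps:
        raise ValueError("dataset is not a complete cell x position x replicate crossing")
    d = 14
    y = dataset.tangent.reshape(n, P, reps, d)

    bits_list = [dataset.bits[pos] for pos in dataset.positions]
    signs = sign_matrix(asym_effects, bits_list)

    pair_means = y.mean(axis=2)  # (n, P, d)
    cell_means = pair_means.mean(axis=1)  # (n, d)
    grand = cell_means.mean(axis=0)

    ss = {"symmetric": float(reps * P * ((cell_means - grand) ** 2).sum())}
    char_ss = _component_ss(pair_means, signs, reps)
    for e, s in zip(asym_effects, char_ss):
        ss[e.name] = float(s)
    ss_error = float(((y - pair_means[:, :, None, :]) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())

    df = {"symmetric": n - 1}
    for e in asym_effects:
        df[e.name] = n
    df_error = n * P * (reps - 1)
    df_total = N - 1

    balance = ss["symmetric"] + char_ss.sum() + ss_error
    if not np.isclose(balance, ss_total, rtol=1e-8):
        raise AssertionError(
            f"sum-of-squares decomposition is not exact: {balance} vs {ss_total}"
        )
    # tangent coordinates are unit-centroid-size scaled, so a total SS at
    # float-noise level means a shape-invariant population: report R2 = 0
    if ss_total <= 1e-12 * N:
        ss_total = 0.0

    f_pooled = pooled_pseudo_f(ss, df)
    ms = {k_: ss[k_] / df[k_] for k_ in ss}
    ms_error = ss_error / df_error if df_error > 0 else np.nan

    # permutation distributions on the MS_effect / MS_error scale
    p_vals = {k_: np.nan for k_ in ss}
    z_vals = {k_: np.nan for k_ in ss}
    if n_perm > 0 and df_error > 0:
        if n_perm < 99:
            warnings.warn("n_perm < 99 gives a very coarse p-value resolution", stacklevel=2)
        rng = np.random.default_rng(seed)
        f_obs_err = {k_: ms[k_] / ms_error for k_ in ss}
        n_asym = len(asym_effects)
        f_star_asym = np.empty((n_perm, n_asym))
        f_star_ind = np.empty(n_perm)
        flat_pairs = pair_means.reshape(n * P, d)
        base = np.tile(np.arange(P), (n, 1))
        for b in range(n_perm):
            if permutation == "restricted":
                sigma = rng.permuted(base, axis=1)
                mp = pair_means[np.arange(n)[:, None], sigma]
            else:
                order = rng.permutation(n * P)
                mp = flat_pairs[order].reshape(n, P, d)
            f_star_asym[b] = _component_ss(mp, signs, reps) / n / ms_error
            order = rng.permutation(n * P)
            mg = flat_pairs[order].reshape(n, P, d)
            cm = mg.mean(axis=1)
            f_star_ind[b] = (
                reps * P * ((cm - grand) ** 2).sum() / (n - 1) / ms_error
            )

        def _p_and_z(obs, null):
            sd = null.std(ddof=1)
            if sd == 0:
                warnings.warn("degenerate permutation null distribution", stacklevel=3)
                return 1.0 / (n_perm + 1), np.nan
            p = (1 + int((null >= obs).sum())) / (n_perm + 1)
            z = (obs - null.mean()) / sd
            return p, z

        p_vals["symmetric"], z_vals["symmetric"] = _p_and_z(f_obs_err["symmetric"], f_star_ind)
        for j, e in enumerate(asym_effects):
            p_vals[e.name], z_vals[e.name] = _p_and_z(f_obs_err[e.name], f_star_asym[:, j])

    rows = []
    for e in effects:
        name = e.name
        rows.append(
            {
                "effect": name,
                "source": effect_display_name(dataset.sublobe, e),
                "df": df[name],
                "ss": ss[name],
                "ms": ms[name],
                "r2": ss[name] / ss_total if ss_total > 0 else 0.0,
                "f": f_pooled[name],
                "z": z_vals[name],
                "p": p_vals[name],
            }
        )
    pooled_ss = float(char_ss.sum())
    pooled_df = sum(df[e.name] for e in asym_effects)
    rows.append(
        {
            "effect": "pooled-asymmetry",
            "source": "[Total asymmetry nested within individuals]",
            "df": pooled_df,
            "ss": pooled_ss,
            "ms": pooled_ss / pooled_df,
            "r2": pooled_ss / ss_total if ss_total > 0 else 0.0,
            "f": np.nan, "z": np.nan, "p": np.nan,
        }
    )
    rows.append(
        {
            "effect": "measurement-error",
            "source": "Measurement error",
            "df": df_error,
            "ss": ss_error,
            "ms": ms_error,
            "r2": ss_error / ss_total if ss_total > 0 else 0.0,
            "f": np.nan, "z": np.nan, "p": np.nan,
        }
    )
    rows.append(
        {
            "effect": "total",
            "source": "Total",
            "df": df_total,
            "ss": ss_total,
            "ms": np.nan, "r2": 1.0, "f": np.nan, "z": np.nan, "p": np.nan,
        }
    )
    frame = pd.DataFrame(rows)
    return AnovaTable(
        frame=frame, sublobe=dataset.sublobe, n_perm=n_perm, seed=seed,
        permutation_scheme=permutation, ss_total=ss_total, df_total=df_total,
    )


def matching_anova(
    population: Population,
    sublobe: str,
    n_perm: int = 999,
    seed: int | None = 0,
    permutation: str = "restricted",
) -> tuple[AnovaTable, LobuleDataset]:
    """Extract, canonicalize, align and decompose in one call."""
    dataset = extract_lobules(population, population.template, sublobe)
    dataset = align_lobules(canonicalize_lobules(dataset))
    table = procrustes_anova(dataset, n_perm=n_perm, seed=seed, permutation=permutation)
    return table, dataset
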