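"""Multi-axis reflection symmetry machinery.

A cell (or a set of repeated lobules) carrying ``m`` perpendicular mirror
axes is acted on by the group (Z_2)^m.  Its irreducible characters are the
2^m sign patterns over the axes; each character isolates one orthogonal
(a)symmetry component of shape variation:

* the trivial character is the totally symmetric component;
* a character with sign -1 at one axis captures asymmetry across that axis;
* products of axes capture the combined ("transversal"-like) asymmetries.

Characters double as ANOVA effects: over the 2^m symmetry-equivalent
positions of a repeated unit, each non-trivial character splits the
positions into two equal groups, exactly the "two equal groups within each
cell" construction of nested matching-symmetry models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import RelabelMap, apply_labeled_reflection

__all__ = [
    "CharacterEffect",
    "LobulePositionLabel",
    "enumerate_effects",
    "position_bits",
    "sign_matrix",
    "character_component",
    "SymmetryProjector",
    "effect_table",
]


@dataclass(frozen=True)
class CharacterEffect:
    """One character of the m-axis reflection group.

    ``axes`` is the full ordered axis list; ``minus_axes`` the subset at
    which the character's sign is -1 (empty for the symmetric character).
    """

    axes: tuple[str, ...]
    minus_axes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.axes)) != len(self.axes):
            raise ValueError("duplicate axis names")
        unknown = set(self.minus_axes) - set(self.axes)
        if unknown:
            raise ValueError(f"unknown axes in character: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "*".join(self.minus_axes) if self.minus_axes else "symmetric"

    @property
    def is_symmetric(self) -> bool:
        return not self.minus_axes

    @property
    def signs(self) -> dict[str, int]:
        return {ax: (-1 if ax in self.minus_axes else 1) for ax in self.axes}

    def value(self, bits: Sequence[int]) -> int:
        """Character value at a position encoded by its per-axis bits (+-1)."""
        v = 1
        for ax, b in zip(self.axes, bits):
            if ax in self.minus_axes:
                v *= b
        return v

    def group_value(self, subset: frozenset) -> int:
        """Character value at the group element reflecting the axes in ``subset``."""
        return -1 if len(subset & set(self.minus_axes)) % 2 else 1

    def grouping(self, positions: Mapping[str, Sequence[int]]) -> tuple[list[str], list[str]]:
        """Split position labels into the +1 and -1 groups of this character."""
        plus = [p for p, bits in positions.items() if self.value(bits) == 1]
        minus = [p for p, bits in positions.items() if self.value(bits) == -1]
        return plus, minus


def enumerate_effects(axes: Sequence[str]) -> list[CharacterEffect]:
    """All 2^m characters of the reflection group over ``axes``.

    Ordering is deterministic: graded by the number of -1 axes, then by the
    given axis order.  The first element is always the trivial (symmetric)
    character; the remaining 2^m - 1 are the asymmetric effects.
    """
    axes = tuple(axes)
    if not 1 <= len(axes) <= 6:
        raise ValueError("between 1 and 6 symmetry axes supported")
    if len(set(axes)) != len(axes):
        raise ValueError("duplicate axis names")
    effects = []
    for r in range(len(axes) + 1):
        for combo in itertools.combinations(axes, r):
            effects.append(CharacterEffect(axes=axes, minus_axes=combo))
    return effects


def position_bits(axes: Sequence[str]) -> dict[tuple[int, ...], int]:
    """Deterministic enumeration of the 2^m positions as +-1 bit tuples."""
    m = len(axes)
    combos = list(itertools.product([1, -1], repeat=m))
    return {bits: i for i, bits in enumerate(combos)}


def sign_matrix(effects: Sequence[CharacterEffect], bits_list: Sequence[Sequence[int]]) -> np.ndarray:
    """(n_effects, n_positions) matrix of character values; rows are orthogonal.

    Satisfies S @ S.T = P * I exactly (integer identity) when ``bits_list``
    enumerates all 2^m positions.
    """
    return np.array([[e.value(bits) for bits in bits_list] for e in effects], dtype=float)


def character_component(values: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """(1/P) * sum_p signs[p] * values[p] over the position axis 0.

    For the trivial character (all +1) this is the positional mean; for an
    asymmetric character it is half the difference between its two position
    groups.  ``values`` has shape (P, ...).
    """
    values = np.asarray(values, dtype=float)
    signs = np.asarray(signs, dtype=float)
    if values.shape[0] != signs.shape[0]:
        raise ValueError(
            f"got {values.shape[0]} position values for {signs.shape[0]} positions"
        )
    return np.tensordot(signs, values, axes=(0, 0)) / len(signs)


@dataclass(frozen=True)
class LobulePositionLabel:
    """Semantic label of one terminal-lobule position.

    ``quadrant`` in {a, b, c, d}; ``sublobe`` in {LLS, ULS, polar};
    ``lobule_index`` within the sublobe; ``axis_bits`` the +-1 signs of the
    position with respect to the sublobe's symmetry axes, in axis order.
    The bit encoding is bijective with the position set (8 LLS, 16 ULS
    positions per cell).
    """

    quadrant: str
    sublobe: str
    lobule_index: int
    axis_bits: tuple[int, ...]

    @property
    def name(self) -> str:
        sub = {"LLS": "a", "ULS": "b"}.get(self.sublobe, "p")
        return f"{self.quadrant}{sub}{self.lobule_index}"


class SymmetryProjector:
    """Orthogonal projector onto one character subspace of full-shape space.

    P_chi = (1/2^m) * sum_g chi(g) T_g, where g runs over the group
    generated by the labeled reflections and T_g is the corresponding
    coordinate transform (mirror + relabel).  Idempotent; projectors of
    distinct characters annihilate each other; together they resolve the
    identity.

    The relabel maps must commute pairwise (checked numerically on random
    input at construction).
    """

    def __init__(self, effect: CharacterEffect, relabel_maps: Mapping[str, RelabelMap]):
        missing = set(effect.axes) - set(relabel_maps)
        if missing:
            raise ValueError(f"missing relabel maps for axes: {sorted(missing)}")
        self.effect = effect
        self.maps = {ax: relabel_maps[ax] for ax in effect.axes}
        self._check_commutation()

    def _check_commutation(self) -> None:
        rng = np.random.default_rng(0)
        k = len(next(iter(self.maps.values())).permutation)
        x = rng.normal(size=(k, 2))
        for a, b in itertools.combinations(self.effect.axes, 2):
            ab = apply_labeled_reflection(apply_labeled_reflection(x, self.maps[a]), self.maps[b])
            ba = apply_labeled_reflection(apply_labeled_reflection(x, self.maps[b]), self.maps[a])
            if not np.allclose(ab, ba, atol=1e-9):
                raise ValueError(f"labeled reflections for axes {a!r} and {b!r} do not commute")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Project ``(..., k, 2)`` coordinates onto this character subspace."""
        points = np.asarray(points, dtype=float)
        axes = self.effect.axes
        acc = np.zeros_like(points)
        for r in range(len(axes) + 1):
            for combo in itertools.combinations(axes, r):
                transformed = points
                for ax in combo:
                    transformed = apply_labeled_reflection(transformed, self.maps[ax])
                acc = acc + self.effect.group_value(frozenset(combo)) * transformed
        return acc / 2 ** len(axes)


def effect_table(
    effects: Sequence[CharacterEffect], positions: Mapping[str, Sequence[int]] | None = None
) -> pd.DataFrame:
    """Characters as a DataFrame (name, sign pattern, optional position groups)."""
    rows = []
    for e in effects:
        row = {"effect": e.name, **{f"sign[{ax}]": s for ax, s in e.signs.items()}}
        if positions is not None:
            plus, minus = e.grouping(positions)
            row["group_plus"] = " ".join(plus)
            row["group_minus"] = " ".join(minus)
        rows.append(row)
    return pd.DataFrame(rows)
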