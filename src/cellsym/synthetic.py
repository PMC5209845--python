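"""Synthetic *Micrasterias*-like landmark populations with known ground truth.

The generator emulates the structure of a twice-digitised population of
biradially symmetric cells: a 208-landmark template with four quadrants,
two 7-landmark lower-lateral-sublobe (LLS) terminal lobules and four
upper-lateral-sublobe (ULS) terminal lobules per quadrant, one 7-landmark
polar-lobe apex per semicell, plus non-lobule outline landmarks.

Shape variation is injected additively in the character basis of the
relevant reflection groups, so every simulated component is exactly
orthogonal to the others and the generator can hand the analysis modules a
complete per-cell ground-truth ledger:

* full-cell components: totally symmetric, inter-semicell, left-right and
  transversal deviations (projections of white noise onto the biradial
  character subspaces);
* lobule-level components: one deviation per character of the 3-axis (LLS)
  and 4-axis (ULS) groups, planted in each terminal lobule with the sign
  pattern and local frame of its position;
* allometry: log-normal centroid size with a size-linked shape direction;
* digitisation error: independent landmark-wise noise per replicate;
* a random rigid motion (rotation + translation) per configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, RelabelMap, apply_labeled_reflection
from .symmetry import SymmetryProjector, enumerate_effects

__all__ = [
    "UnitInfo",
    "TemplateSpec",
    "PopulationParams",
    "Population",
    "make_template",
    "simulate_population",
    "biradial_axes",
    "biradial_projectors",
    "LLS_AXES",
    "ULS_AXES",
]

# axis order fixes effect naming and table row order throughout the package
BIRADIAL_AXES = ("semicell", "left-right")
LLS_AXES = ("semicell", "left-right", "intra-lobe")
ULS_AXES = ("semicell", "left-right", "main-incision", "minor-incision")

_MIRROR = np.array([[-1.0, 0.0], [0.0, 1.0]])  # within-unit mirror (canonical frame)
_REV = np.arange(6, -1, -1)  # within-unit index reversal

# canonical 7-landmark lobule: a symmetric cap, invariant under mirror+reversal
_THETA = np.deg2rad([180.0, 150.0, 120.0, 90.0, 60.0, 30.0, 0.0])
_RADII = np.array([2.2, 2.6, 3.0, 3.2, 3.0, 2.6, 2.2])
_L0 = np.column_stack([_RADII * np.cos(_THETA), _RADII * np.sin(_THETA)])
_L0 -= _L0.mean(axis=0)


@dataclass
class UnitInfo:
    """One 7-landmark analysis unit of the template."""

    name: str
    sublobe: str  # "LLS", "ULS" or "polar"
    quadrant: str  # a..d for lobules, "u"/"l" for polar apexes
    role: str  # a1, a2, b1..b4, polar
    indices: np.ndarray
    linear: np.ndarray  # 2x2 placement frame mapping canonical -> template
    construction_parity: int  # number of global reflections used to build it
    center: np.ndarray
    bits: tuple[int, ...] | None = None  # +-1 per symmetry axis (lobules only)

    @property
    def bits_parity(self) -> int:
        if self.bits is None:
            return self.construction_parity
        return sum(1 for b in self.bits if b == -1) % 2

    def injection_frame(self) -> tuple[np.ndarray, bool]:
        """(2x2 frame, reverse_indices) placing a canonical-frame deviation.

        A deviation delta planted as ``delta[rev?][...] @ frame.T`` at this
        unit's landmarks is recovered exactly (up to a proper rotation that
        GPA removes) after canonical re-orientation of the unit.
        """
        s = (self.bits_parity - self.construction_parity) % 2
        frame = self.linear @ _MIRROR if s else self.linear
        return frame, bool(self.bits_parity % 2)


@dataclass
class TemplateSpec:
    """Labeled biradial template: landmarks, relabel maps, and unit index sets."""

    points: np.ndarray
    labels: pd.DataFrame
    vertical_map: RelabelMap
    horizontal_map: RelabelMap
    units: dict[str, UnitInfo]

    @property
    def k(self) -> int:
        return len(self.points)

    def lobule_map(self, sublobe: str) -> dict[str, np.ndarray]:
        """Position label -> landmark index set for one sublobe (LLS or ULS)."""
        return {
            u.name: u.indices for u in self.units.values() if u.sublobe == sublobe
        }

    def position_bits(self, sublobe: str) -> dict[str, tuple[int, ...]]:
        return {
            u.name: u.bits for u in self.units.values() if u.sublobe == sublobe
        }

    def analysis_units(self) -> list[str]:
        """The 26 per-cell units (24 terminal lobules + 2 polar apexes)."""
        return list(self.units)


def _quadrant_bits(quadrant: str) -> tuple[int, int]:
    semicell = 1 if quadrant in "ab" else -1
    left_right = 1 if quadrant in "ad" else -1
    return semicell, left_right


def _rotation(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


# quadrant-a layout: (role, center); the cap of each lobule points outward
_QA_LOBULES = {
    "a1": (-40.0, 10.0),
    "a2": (-44.0, 24.0),
    "b1": (-38.0, 36.0),
    "b2": (-30.0, 45.0),
    "b3": (-20.0, 52.0),
    "b4": (-10.0, 57.0),
}
_QA_OUTLINE = np.array(
    [[-18.0, 4.0], [-34.0, 6.0], [-47.0, 17.0], [-43.0, 30.0], [-26.0, 49.0], [-13.5, 54.0]]
)
_APEX_CENTER = np.array([0.0, 60.0])
_ISTHMUS = np.array([[-6.0, 0.0], [6.0, 0.0]])


def _role_bits(role: str) -> tuple[int, ...]:
    """Intra-quadrant axis bits of a lobule role (excludes quadrant bits)."""
    if role in ("a1", "a2"):
        return (1,) if role == "a1" else (-1,)
    idx = int(role[1])
    main = 1 if idx in (1, 2) else -1
    minor = 1 if idx in (1, 4) else -1
    return (main, minor)


def make_template() -> TemplateSpec:
    """Construct the stylized 208-landmark biradial template.

    Quadrant *a* (upper left) is laid out explicitly; quadrants *b*, *d*
    and *c* are exact mirror images across the vertical and horizontal
    axes (with within-lobule landmark order reversed at each reflection),
    so the template is biradially symmetric by construction.
    """
    points: list[np.ndarray] = []
    rows: list[dict] = []
    units: dict[str, UnitInfo] = {}

    def add_unit(name, sublobe, quadrant, role, pts, linear, parity, center, bits):
        idx = np.arange(len(points), len(points) + 7)
        for i in range(7):
            points.append(pts[i])
            rows.append(
                {"quadrant": quadrant, "unit": name, "role": role, "sublobe": sublobe, "within": i}
            )
        units[name] = UnitInfo(
            name=name, sublobe=sublobe, quadrant=quadrant, role=role, indices=idx,
            linear=np.asarray(linear, float), construction_parity=parity,
            center=np.asarray(center, float), bits=bits,
        )

    def add_outline(quadrant, pts):
        for i in range(len(pts)):
            points.append(pts[i])
            rows.append(
                {"quadrant": quadrant, "unit": f"outline_{quadrant}", "role": "", "sublobe": "outline", "within": i}
            )

    # isthmus margin points sit on the horizontal axis
    for i, p in enumerate(_ISTHMUS):
        points.append(p)
        rows.append({"quadrant": "-", "unit": "isthmus", "role": "", "sublobe": "outline", "within": i})

    # quadrant a built explicitly
    q_sub = {"a1": "LLS", "a2": "LLS", "b1": "ULS", "b2": "ULS", "b3": "ULS", "b4": "ULS"}
    for role, (cx, cy) in _QA_LOBULES.items():
        angle = np.arctan2(cy, cx) - np.pi / 2  # cap points away from the cell center
        rot = _rotation(angle)
        pts = _L0 @ rot.T + np.array([cx, cy])
        bits = _quadrant_bits("a") + _role_bits(role)
        add_unit(f"a{role}", q_sub[role], "a", role, pts, rot, 0, (cx, cy), bits)
    add_outline("a", _QA_OUTLINE)

    fv = np.array([[-1.0, 0.0], [0.0, 1.0]])
    fh = np.array([[1.0, 0.0], [0.0, -1.0]])

    def mirror_quadrant(src_q, dst_q, flip):
        for role in _QA_LOBULES:
            src = units[f"{src_q}{role}"]
            pts = np.array([flip @ points[src.indices[_REV[i]]] for i in range(7)])
            bits = _quadrant_bits(dst_q) + _role_bits(role)
            add_unit(
                f"{dst_q}{role}", q_sub[role], dst_q, role, pts, flip @ src.linear,
                (src.construction_parity + 1) % 2, flip @ src.center, bits,
            )
        src_outline = [
            i for i, r in enumerate(rows) if r["unit"] == f"outline_{src_q}"
        ]
        add_outline(dst_q, np.array([flip @ points[i] for i in src_outline]))

    mirror_quadrant("a", "b", fv)
    mirror_quadrant("a", "d", fh)
    mirror_quadrant("b", "c", fh)

    # polar apexes: one per semicell, centered on the vertical axis
    add_unit("up", "polar", "u", "polar", _L0 + _APEX_CENTER, np.eye(2), 0, _APEX_CENTER, None)
    low = units["up"]
    pts = np.array([fh @ points[low.indices[_REV[i]]] for i in range(7)])
    add_unit("lp", "polar", "l", "polar", pts, fh @ np.eye(2), 1, fh @ _APEX_CENTER, None)

    coords = np.array(points)
    labels = pd.DataFrame(rows)
    if len(coords) != 208:
        raise AssertionError(f"template has {len(coords)} landmarks, expected 208")
    # all landmarks must be distinct for the reflection matching below
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    if dists[:, 1].min() < 1e-6:
        raise AssertionError("template landmarks are not all distinct")

    def match_perm(flip: np.ndarray) -> np.ndarray:
        reflected = coords @ flip.T
        d, nearest = tree.query(reflected, k=1)
        # nearest[j] = template index equal to reflected[j]; the relabeling
        # needed is its inverse (perm[i] = j with reflected[j] == coords[i])
        if d.max() > 1e-9:
            raise AssertionError("template is not symmetric under reflection")
        inv = np.empty(len(coords), dtype=int)
        inv[nearest] = np.arange(len(coords))
        return inv

    vertical_map = RelabelMap("vertical", match_perm(fv))
    horizontal_map = RelabelMap("horizontal", match_perm(fh))

    tpl = TemplateSpec(
        points=coords, labels=labels, vertical_map=vertical_map,
        horizontal_map=horizontal_map, units=units,
    )
    for rmap in (vertical_map, horizontal_map):
        if not np.allclose(apply_labeled_reflection(coords, rmap), coords, atol=1e-9):
            raise AssertionError("template is not invariant under its labeled reflection")
    return tpl


def biradial_axes() -> tuple[str, str]:
    return BIRADIAL_AXES


def biradial_maps(template: TemplateSpec) -> dict[str, RelabelMap]:
    """Axis name -> full-cell labeled reflection for the biradial group."""
    return {"semicell": template.horizontal_map, "left-right": template.vertical_map}


def biradial_projectors(template: TemplateSpec) -> dict[str, SymmetryProjector]:
    """The four character-subspace projectors of the full-cell biradial group."""
    maps = biradial_maps(template)
    return {
        e.name: SymmetryProjector(e, maps) for e in enumerate_effects(BIRADIAL_AXES)
    }


@dataclass
class SharedFactor:
    """A latent factor shared by several lobule roles within each semicell."""

    roles: tuple[str, ...]
    sd: float


@dataclass
class PopulationParams:
    """Variance components of a simulated population (template length units).

    Defaults are the package's standing study conditions: 68 cells
    digitised twice, inter-semicell asymmetry as the dominant asymmetric
    component, marked intra-quadrant lobule asymmetry, mild allometry and
    sub-landmark digitisation error.
    """

    n_cells: int = 68
    n_replicates: int = 2
    sd_symmetric: float = 0.75
    sd_asymmetric: dict = field(
        default_factory=lambda: {
            "semicell": 1.45,
            "left-right": 0.60,
            "semicell*left-right": 0.52,
        }
    )
    lls_char_sd: dict = field(
        default_factory=lambda: {"symmetric": 0.55, "semicell": 0.45, "intra-lobe": 0.45}
    )
    uls_char_sd: dict = field(
        default_factory=lambda: {"symmetric": 0.55, "semicell": 0.42, "minor-incision": 0.42}
    )
    lobule_symmetric_sd_default: float = 0.0
    lobule_char_sd_default: float = 0.15
    log_size_sd: float = 0.08
    allometry_slope: float = 15.0
    sd_measurement_error: float = 0.18
    shared_factors: tuple[SharedFactor, ...] = ()
    translation_range: float = 30.0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        for name, value in self.all_sds().items():
            if value < 0:
                raise ValueError(f"negative sd for {name}")

    def all_sds(self) -> dict[str, float]:
        out = {"symmetric": self.sd_symmetric, "measurement": self.sd_measurement_error}
        out.update({f"cell:{k}": v for k, v in self.sd_asymmetric.items()})
        out.update({f"LLS:{k}": v for k, v in self.lls_char_sd.items()})
        out.update({f"ULS:{k}": v for k, v in self.uls_char_sd.items()})
        return out

    def sublobe_sd(self, sublobe: str, effect_name: str) -> float:
        table = self.lls_char_sd if sublobe == "LLS" else self.uls_char_sd
        if effect_name == "symmetric":
            return table.get(effect_name, self.lobule_symmetric_sd_default)
        return table.get(effect_name, self.lobule_char_sd_default)


@dataclass
class Population:
    """A simulated population plus its ground-truth ledger."""

    coords: np.ndarray  # (n_cells, n_replicates, 208, 2)
    cell_ids: list[str]
    template: TemplateSpec
    params: PopulationParams
    ledger: dict

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_configurations(
        cls, configs: Sequence[LandmarkConfiguration], template: TemplateSpec
    ) -> "Population":
        """Assemble a population from loaded configurations (empty ledger).

        Configurations are grouped by ``cell_id`` (order of first
        appearance) and sorted by ``replicate_id``; every cell must have
        the same number of replicates and ``template.k`` landmarks.
        """
        by_cell: dict[str, list[LandmarkConfiguration]] = {}
        for cfg in configs:
            if cfg.k != template.k:
                raise ValueError(
                    f"configuration {cfg.cell_id!r} has {cfg.k} landmarks, expected {template.k}"
                )
            by_cell.setdefault(cfg.cell_id, []).append(cfg)
        reps = {len(v) for v in by_cell.values()}
        if len(reps) != 1:
            raise ValueError("cells have unequal replicate counts")
        n_reps = reps.pop()
        cell_ids = list(by_cell)
        coords = np.empty((len(cell_ids), n_reps, template.k, 2))
        for c, cid in enumerate(cell_ids):
            for r, cfg in enumerate(sorted(by_cell[cid], key=lambda x: x.replicate_id)):
                coords[c, r] = cfg.points
        params = PopulationParams(n_cells=len(cell_ids), n_replicates=n_reps)
        return cls(coords=coords, cell_ids=cell_ids, template=template, params=params, ledger={})

    def configurations(self) -> list[LandmarkConfiguration]:
        out = []
        for c, cid in enumerate(self.cell_ids):
            for r in range(self.n_replicates):
                out.append(
                    LandmarkConfiguration(self.coords[c, r], cell_id=cid, replicate_id=r + 1)
                )
        return out

    def reconstruct_pre_rigid(self, cell: int, replicate: int) -> np.ndarray:
        """Rebuild one configuration from the ledger (before rigid motion)."""
        led = self.ledger
        shape = (
            self.template.points
            + led["symmetric"][cell]
            + sum(dev[cell] for dev in led["cell_characters"].values())
            + led["lobule_deviation_fields"][cell]
            + led["shared_factor_fields"][cell]
            + led["allometric_shift"][cell]
        )
        return shape * led["sizes"][cell] + led["measurement_noise"][cell, replicate]


def _allometry_direction(template: TemplateSpec) -> np.ndarray:
    """Deterministic unit-norm totally symmetric shape direction."""
    proj = biradial_projectors(template)["symmetric"]
    raw = np.stack(
        [np.sin(np.arange(template.k) * 0.37), np.cos(np.arange(template.k) * 0.11)], axis=1
    )
    d = proj.apply(raw)
    return d / np.linalg.norm(d)


def simulate_population(
    template: TemplateSpec,
    params: PopulationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Simulate a population of twice-digitised cells with a ground-truth ledger.

    Per cell: a totally symmetric deviation, one deviation per asymmetric
    character (full-cell biradial characters, and lobule-level characters
    of the LLS and ULS groups planted with their sign patterns), an
    allometric size effect, then per replicate independent landmark-wise
    digitisation error and a random rigid motion.
    """
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)
    tpl = template
    n, reps, k = params.n_cells, params.n_replicates, tpl.k

    projs = biradial_projectors(tpl)
    cell_effects = [e for e in enumerate_effects(BIRADIAL_AXES) if not e.is_symmetric]

    symmetric = np.empty((n, k, 2))
    cell_characters = {e.name: np.empty((n, k, 2)) for e in cell_effects}
    lobule_fields = np.zeros((n, k, 2))
    shared_fields = np.zeros((n, k, 2))
    lobule_deltas: dict[str, dict[str, np.ndarray]] = {
        "LLS": {}, "ULS": {},
    }

    sublobe_effects = {
        "LLS": enumerate_effects(LLS_AXES),
        "ULS": enumerate_effects(ULS_AXES),
    }
    for sublobe, effects in sublobe_effects.items():
        for e in effects:
            lobule_deltas[sublobe][e.name] = np.empty((n, 7, 2))

    sublobe_units = {
        sublobe: [u for u in tpl.units.values() if u.sublobe == sublobe]
        for sublobe in ("LLS", "ULS")
    }

    # deterministic direction per shared factor (recorded in the ledger)
    factor_dirs = []
    for f in params.shared_factors:
        d = rng.normal(size=(7, 2))
        factor_dirs.append(d / np.linalg.norm(d))
    factor_scores = np.zeros((n, len(params.shared_factors), 2))  # per semicell

    for c in range(n):
        if params.sd_symmetric > 0:
            symmetric[c] = projs["symmetric"].apply(rng.normal(size=(k, 2))) * params.sd_symmetric
        else:
            symmetric[c] = 0.0
        for e in cell_effects:
            sd = params.sd_asymmetric.get(e.name, 0.0)
            if sd > 0:
                cell_characters[e.name][c] = projs[e.name].apply(rng.normal(size=(k, 2))) * sd
            else:
                cell_characters[e.name][c] = 0.0

        for sublobe, effects in sublobe_effects.items():
            for e in effects:
                sd = params.sublobe_sd(sublobe, e.name)
                if sd == 0:
                    lobule_deltas[sublobe][e.name][c] = 0.0
                    continue
                delta = rng.normal(size=(7, 2)) * sd
                lobule_deltas[sublobe][e.name][c] = delta
                for u in sublobe_units[sublobe]:
                    chi = 1 if e.is_symmetric else e.value(u.bits)
                    frame, rev = u.injection_frame()
                    d = delta[_REV] if rev else delta
                    lobule_fields[c, u.indices] += chi * (d @ frame.T)

        for fi, f in enumerate(params.shared_factors):
            for semicell, quadrants in (("upper", "ab"), ("lower", "cd")):
                score = rng.normal() * f.sd
                factor_scores[c, fi, 0 if semicell == "upper" else 1] = score
                for u in tpl.units.values():
                    if u.sublobe in ("LLS", "ULS") and u.quadrant in quadrants and u.role in f.roles:
                        frame, rev = u.injection_frame()
                        d = factor_dirs[fi][_REV] if rev else factor_dirs[fi]
                        shared_fields[c, u.indices] += score * (d @ frame.T)

    log_sizes = rng.normal(0.0, params.log_size_sd, size=n)
    sizes = np.exp(log_sizes)
    direction = _allometry_direction(tpl)
    allometric_shift = (
        params.allometry_slope * log_sizes[:, None, None] * direction[None, :, :]
    )

    noise = rng.normal(0.0, params.sd_measurement_error, size=(n, reps, k, 2))
    angles = rng.uniform(0.0, 2 * np.pi, size=(n, reps))
    translations = rng.uniform(
        -params.translation_range, params.translation_range, size=(n, reps, 2)
    )

    coords = np.empty((n, reps, k, 2))
    for c in range(n):
        shape = (
            tpl.points
            + symmetric[c]
            + sum(cell_characters[e.name][c] for e in cell_effects)
            + lobule_fields[c]
            + shared_fields[c]
            + allometric_shift[c]
        ) * sizes[c]
        for r in range(reps):
            cfg = shape + noise[c, r]
            rot = _rotation(angles[c, r])
            coords[c, r] = cfg @ rot.T + translations[c, r]

    ledger = {
        "symmetric": symmetric,
        "cell_characters": cell_characters,
        "lobule_deltas": lobule_deltas,
        "lobule_deviation_fields": lobule_fields,
        "shared_factor_fields": shared_fields,
        "shared_factor_scores": factor_scores,
        "shared_factor_directions": factor_dirs,
        "allometric_shift": allometric_shift,
        "allometry_direction": direction,
        "log_sizes": log_sizes,
        "sizes": sizes,
        "measurement_noise": noise,
        "rigid_angles": angles,
        "rigid_translations": translations,
    }
    cell_ids = [f"cell{c + 1:03d}" for c in range(n)]
    return Population(
        coords=coords, cell_ids=cell_ids, template=tpl, params=params, ledger=ledger
    )
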