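"""Organ-level geometric growth and 3-D construction of the leaf set.

Individual leaf area follows a normalized logistic over a 12-day
development period, with pre-formed leaves (rank rk < n_p) scaled by
rk/n_p.  Internode length follows the same kind of logistic over 10
days, between IL_min and IL_min + IL_max * c_z where c_z in [0, 1] is
indexed on the branching zone.  Internode diameters come from the pipe
model: cross-sectional area is conserved from distal supports down to
the bearing segment, with every axis tip pinned to the top-shoot
diameter (TSD).  Branch bending is a single small-deflection
Euler-Bernoulli pass per axis: gravity torque from the distal mass,
reduced by a scalar phototropic righting fraction, sets a curvature
increment per internode.

Units are SI (m, m^2, kg, Pa); angles are degrees at interfaces and
radians internally; the z axis points up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .topology import GUType, GrowthUnit, Tree

__all__ = [
    "LeafGrowthParams",
    "InternodeGrowthParams",
    "MechanicsParams",
    "Leaf",
    "normalized_logistic",
    "leaf_area_at",
    "internode_length_at",
    "compute_growth",
    "apply_pipe_model",
    "bend_axes",
    "build_leaf_mesh",
    "build_tree_geometry",
    "total_leaf_area",
]

_G = 9.81  # m s^-2

GOLDEN_ANGLE_DEG = 144.0  # phyllotactic spiral

# phyllochron (days per metamer) by GU type; short/floral GUs are mostly
# preformed and expand their few metamers quickly
DEFAULT_PHYLLOCHRON = {
    GUType.LONG: 2.0,
    GUType.MEDIUM: 2.0,
    GUType.SHORT: 1.0,
    GUType.FLORAL: 1.0,
}

# internode elongation factor by shoot type: short and floral GUs are
# rosettes whose internodes barely extend beyond IL_min
DEFAULT_TYPE_ELONGATION = {
    GUType.LONG: 1.0,
    GUType.MEDIUM: 0.5,
    GUType.SHORT: 0.08,
    GUType.FLORAL: 0.05,
}


def normalized_logistic(d, dev_days: float, steepness: float | None = None):
    """Smooth monotone curve with exactly f(0)=0 and f(d>=dev_days)=1.

    A symmetric logistic with midpoint at dev_days/2 (1%/99% saturation at
    the endpoints by default), affinely rescaled so the endpoints are hit
    exactly and clamped outside [0, dev_days].
    """
    d = np.asarray(d, dtype=float)
    if steepness is None:
        steepness = 2.0 * np.log(99.0) / dev_days
    mid = dev_days / 2.0
    sig = 1.0 / (1.0 + np.exp(-steepness * (d - mid)))
    s0 = 1.0 / (1.0 + np.exp(steepness * mid))
    s1 = 1.0 / (1.0 + np.exp(-steepness * (dev_days - mid)))
    out = np.clip((sig - s0) / (s1 - s0), 0.0, 1.0)
    out = np.where(d <= 0, 0.0, np.where(d >= dev_days, 1.0, out))
    return out if out.ndim else float(out)


@dataclass
class LeafGrowthParams:
    LA_max: float = 4.0e-3  # m^2, maximum individual leaf area
    n_p: int = 8  # pre-formed leaves per shoot
    dev_days: float = 12.0
    steepness: float | None = None

    def __post_init__(self):
        if self.LA_max <= 0:
            raise ValueError("LA_max must be positive")
        if self.n_p < 0:
            raise ValueError("n_p must be >= 0")


@dataclass
class InternodeGrowthParams:
    IL_min: float = 8.0e-3  # m
    IL_max: float = 2.5e-2  # m
    dev_days: float = 10.0
    steepness: float | None = None
    zone_coefficients: dict[int, float] = field(default_factory=lambda: {0: 1.0})

    def __post_init__(self):
        if self.IL_min < 0 or self.IL_max < 0:
            raise ValueError("internode lengths must be non-negative")
        for z, c in self.zone_coefficients.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"zone coefficient c_z[{z}] outside [0, 1]")


@dataclass
class MechanicsParams:
    wood_elasticity: float = 3.0e9  # Pa (young apple wood)
    tissue_density: float = 800.0  # kg m^-3
    leaf_mass_per_area: float = 0.08  # kg m^-2
    phototropism_coeff: float = 0.5  # fraction of gravity torque righted
    branching_angle: float = 45.0  # degrees from bearer axis
    petiole_angle: float = 45.0  # degrees, constant
    max_bend_step: float = 0.2  # rad per internode, numerical clamp
    max_droop: float = 135.0  # degrees from vertical; weeping limit

    def __post_init__(self):
        if self.wood_elasticity <= 0:
            raise ValueError("wood_elasticity must be positive")
        if not 0.0 <= self.branching_angle <= 180.0:
            raise ValueError("branching_angle must be in [0, 180] degrees")


@dataclass
class Leaf:
    area: float  # m^2
    center: np.ndarray  # 3-D point, m
    normal: np.ndarray  # unit vector
    polygon: np.ndarray  # (n_vertices, 3), planar loop


def leaf_area_at(d: float, rk: int, p: LeafGrowthParams) -> float:
    """Individual leaf area after d days of development at leaf rank rk.

    Pre-formed leaves (rk < n_p) reach only the fraction rk/n_p of LA_max.
    """
    if rk < 1:
        raise ValueError("leaf rank starts at 1")
    f = normalized_logistic(d, p.dev_days, p.steepness)
    scale = rk / p.n_p if (p.n_p > 0 and rk < p.n_p) else 1.0
    return float(f * p.LA_max * scale)


def internode_length_at(d: float, zone_id: int, p: InternodeGrowthParams) -> float:
    """Internode length after d days: IL_min + g(d) * IL_max * c_z."""
    if zone_id not in p.zone_coefficients:
        raise KeyError(f"no zone coefficient configured for zone {zone_id}")
    return _internode_length(d, p.zone_coefficients[zone_id], p)


def _internode_length(d: float, c_z: float, p: InternodeGrowthParams) -> float:
    g = normalized_logistic(d, p.dev_days, p.steepness)
    return float(p.IL_min + g * p.IL_max * c_z)


def compute_growth(
    tree: Tree,
    leaf_params: LeafGrowthParams,
    internode_params: InternodeGrowthParams,
    eval_day: float = 90.0,
    phyllochron: dict[GUType, float] | None = None,
) -> None:
    """Set per-metamer birth day, internode length and leaf area.

    Metamers of a current-year GU appear one phyllochron apart; metamers
    not yet emerged at `eval_day` have zero length and no leaf.  GUs of
    earlier years are fully extended and carry no leaves (leaves live on
    the current season's shoots only).  Dead GUs carry no leaves.  A GU
    with a fixed observed length (e.g. a measured trunk) distributes it
    evenly over its metamers.
    """
    phyllochron = phyllochron or DEFAULT_PHYLLOCHRON
    current = tree.age_years
    for gu in tree.gus.values():
        dt = phyllochron[gu.gu_type]
        n = gu.n_metamers
        for m in gu.metamers:
            m.birth_day = (m.rank - 1) * dt
            if gu.year < current:
                age = np.inf
            else:
                age = eval_day - m.birth_day
            if age < 0:
                m.internode_length = 0.0
                m.leaf_area = 0.0
                continue
            cz = m.c_z * DEFAULT_TYPE_ELONGATION[gu.gu_type]
            m.internode_length = _internode_length(age, cz, internode_params)
            if gu.year == current and gu.alive:
                m.leaf_area = leaf_area_at(age, m.rank, leaf_params)
            else:
                m.leaf_area = 0.0
        if gu.fixed_length is not None:
            emerged = [m for m in gu.metamers if m.internode_length > 0 or gu.year < current]
            if emerged:
                each = gu.fixed_length / len(emerged)
                for m in emerged:
                    m.internode_length = each


def _laterals_by_anchor(tree: Tree) -> dict[tuple[int, int], list[GrowthUnit]]:
    out: dict[tuple[int, int], list[GrowthUnit]] = {}
    for gu in tree.gus.values():
        if gu.parent_gu is not None and not gu.is_successor:
            out.setdefault((gu.parent_gu, gu.parent_rank), []).append(gu)
    return out


def apply_pipe_model(tree: Tree, tsd: float, petiole_area: float = 0.0) -> Tree:
    """Assign internode diameters by distal cross-section accumulation.

    The distal-most internode of every axis gets diameter `tsd`; every
    other internode's cross-sectional area is the sum of the areas of its
    distal continuations (same-GU neighbour, successor GU, lateral GU
    bases) plus an optional per-leaf petiole area term.
    """
    if tsd <= 0:
        raise ValueError("tsd must be positive")
    laterals = _laterals_by_anchor(tree)
    area: dict[tuple[int, int], float] = {}  # (gu_id, rank) -> diameter^2
    tip_a = tsd * tsd
    for gu in sorted(tree.gus.values(), key=lambda g: g.gu_id, reverse=True):
        for m in reversed(gu.metamers):
            a = 0.0
            if m.rank < gu.n_metamers:
                a += area[(gu.gu_id, m.rank + 1)]
            elif gu.successor is not None:
                succ = tree.gus[gu.successor]
                a += area[(succ.gu_id, 1)]
            for lat in laterals.get((gu.gu_id, m.rank), []):
                a += area[(lat.gu_id, 1)]
            if m.leaf_area > 0:
                a += petiole_area
            if a == 0.0:
                a = tip_a
            area[(gu.gu_id, m.rank)] = a
            m.internode_diameter = float(np.sqrt(a))
    return tree


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _perp_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(u, z)
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(u, np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _axes_of(tree: Tree) -> list[list[GrowthUnit]]:
    """Axes as chains of GUs linked by terminal-bud succession."""
    axes = []
    for gu in sorted(tree.gus.values(), key=lambda g: g.gu_id):
        if not gu.is_successor:
            chain = [gu]
            while chain[-1].successor is not None:
                chain.append(tree.gus[chain[-1].successor])
            axes.append(chain)
    return axes


def bend_axes(tree: Tree, mech: MechanicsParams) -> Tree:
    """Assign 3-D poses to every metamer, axis by axis, with bending.

    Axes are processed bearers first.  Each lateral axis inserts at
    `branching_angle` from its bearer's local direction, with a
    phyllotactic azimuth.  Along each axis, the curvature increment of
    internode i is (1 - phototropism_coeff) * gravity moment of the
    distal mass / (E I_i), I = pi d^4 / 64, applied cumulatively from the
    base (single small-deflection pass); the axis base never moves.
    """
    warned = False
    ba = np.radians(mech.branching_angle)
    laterals = _laterals_by_anchor(tree)
    axes = _axes_of(tree)

    # subtree mass hanging at each axis (own metamers + attached sub-axes)
    axis_of_gu = {}
    for ax in axes:
        for gu in ax:
            axis_of_gu[gu.gu_id] = ax[0].gu_id
    own_mass: dict[int, float] = {a[0].gu_id: 0.0 for a in axes}
    metamer_mass: dict[tuple[int, int], float] = {}
    for gu in tree.gus.values():
        for m in gu.metamers:
            w = (
                mech.tissue_density
                * np.pi
                * m.internode_diameter**2
                / 4.0
                * m.internode_length
                + mech.leaf_mass_per_area * m.leaf_area
            )
            metamer_mass[(gu.gu_id, m.rank)] = w
            own_mass[axis_of_gu[gu.gu_id]] += w
    subtree_mass: dict[int, float] = {}
    for ax in sorted(axes, key=lambda a: a[0].gu_id, reverse=True):
        tot = own_mass[ax[0].gu_id]
        for gu in ax:
            for m in gu.metamers:
                for lat in laterals.get((gu.gu_id, m.rank), []):
                    tot += subtree_mass[lat.gu_id]
        subtree_mass[ax[0].gu_id] = tot

    E = mech.wood_elasticity
    photo = np.clip(mech.phototropism_coeff, 0.0, 1.0)
    zhat = np.array([0.0, 0.0, 1.0])

    anchor_point: dict[tuple[int, int], np.ndarray] = {}
    anchor_dir: dict[tuple[int, int], np.ndarray] = {}

    for ax in axes:
        first = ax[0]
        if first.parent_gu is None:
            base = np.zeros(3)
            u = zhat.copy()
        else:
            key = (first.parent_gu, first.parent_rank)
            base = anchor_point[key]
            bearer_dir = anchor_dir[key]
            if first.is_successor:
                u = bearer_dir.copy()
            else:
                e1, e2 = _perp_frame(bearer_dir)
                phi = np.radians(GOLDEN_ANGLE_DEG) * (first.parent_rank + first.gu_id)
                perp = np.cos(phi) * e1 + np.sin(phi) * e2
                u = np.cos(ba) * bearer_dir + np.sin(ba) * perp
                u /= np.linalg.norm(u)

        # distal point loads along the axis (own metamers + sub-axis masses)
        chain: list[tuple[GrowthUnit, "Metamer"]] = [
            (gu, m) for gu in ax for m in gu.metamers
        ]
        loads = np.array(
            [
                metamer_mass[(gu.gu_id, m.rank)]
                + sum(
                    subtree_mass[lat.gu_id]
                    for lat in laterals.get((gu.gu_id, m.rank), [])
                )
                for gu, m in chain
            ]
        )
        lengths = np.array([m.internode_length for _, m in chain])
        # unbent arc positions; lever arm of load j on internode i is the
        # horizontal component of the straight-axis offset
        s = np.cumsum(lengths)
        horiz = np.linalg.norm(u - np.dot(u, zhat) * zhat)
        bend_axis = np.cross(zhat, u)
        nb = np.linalg.norm(bend_axis)
        if nb > 1e-12:
            bend_axis = bend_axis / nb
        theta = 0.0
        pos = base.copy()
        for i, (gu, m) in enumerate(chain):
            distal = loads[i:]
            lever = (s[i:] - s[i] + 0.5 * lengths[i]) * horiz
            moment = (1.0 - photo) * _G * float(np.sum(distal * lever))
            d = m.internode_diameter
            I = np.pi * d**4 / 64.0
            if I <= 0.0:
                if moment > 0.0 and not warned:
                    warnings.warn(
                        "zero internode diameter with distal mass; clamping curvature",
                        stacklevel=2,
                    )
                    warned = True
                step = mech.max_bend_step if moment > 0 else 0.0
            else:
                step = min(moment / (E * I) * lengths[i], mech.max_bend_step)
            if nb > 1e-12:
                theta += step
            direction = _rotate(u, bend_axis, theta) if nb > 1e-12 else u
            # weeping limit: no further droop once the axis points well
            # below the horizontal
            droop = np.arccos(np.clip(direction[2], -1.0, 1.0))
            limit = np.radians(mech.max_droop)
            if droop > limit:
                theta -= droop - limit
                direction = _rotate(u, bend_axis, theta) if nb > 1e-12 else u
            m.base = pos.copy()
            pos = pos + direction * m.internode_length
            m.tip = pos.copy()
            anchor_point[(gu.gu_id, m.rank)] = m.tip
            anchor_dir[(gu.gu_id, m.rank)] = direction
    return tree


_N_LEAF_VERTICES = 8
# inscribed polygon of an ellipse at n equally spaced parameter angles has
# area (n/2) a b sin(2 pi / n); scale so the polygon area equals the leaf area
_POLY_AREA_FACTOR = 0.5 * _N_LEAF_VERTICES * np.sin(2 * np.pi / _N_LEAF_VERTICES)


def _leaf_polygon(area: float, center: np.ndarray, longit: np.ndarray,
                  transv: np.ndarray) -> np.ndarray:
    # 2:1 length:width ellipse proxy; a = 2 b
    b = np.sqrt(area / (2.0 * _POLY_AREA_FACTOR))
    a = 2.0 * b
    ang = 2 * np.pi * (np.arange(_N_LEAF_VERTICES) + 0.5) / _N_LEAF_VERTICES
    return (
        center[None, :]
        + np.outer(a * np.cos(ang), longit)
        + np.outer(b * np.sin(ang), transv)
    )


def build_leaf_mesh(tree: Tree, mech: MechanicsParams) -> list[Leaf]:
    """One planar polygon per live leaf of the current season.

    The blade leans away from the axis by the constant petiole angle, at
    the node's phyllotactic azimuth; polygon area equals the metamer's
    leaf area exactly.
    """
    pet = np.radians(mech.petiole_angle)
    leaves: list[Leaf] = []
    for gu in sorted(tree.gus.values(), key=lambda g: g.gu_id):
        if not gu.alive or gu.year != tree.age_years:
            continue
        for m in gu.metamers:
            if m.leaf_area <= 0 or m.tip is None:
                continue
            axis_dir = m.tip - m.base
            nrm = np.linalg.norm(axis_dir)
            axis_dir = axis_dir / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
            e1, e2 = _perp_frame(axis_dir)
            phi = np.radians(GOLDEN_ANGLE_DEG) * m.rank
            radial = np.cos(phi) * e1 + np.sin(phi) * e2
            longit = np.cos(pet) * radial + np.sin(pet) * axis_dir
            longit /= np.linalg.norm(longit)
            transv = np.cross(axis_dir, radial)
            tn = np.linalg.norm(transv)
            transv = transv / tn if tn > 0 else e2
            # re-orthogonalize transverse against the blade direction
            transv = transv - np.dot(transv, longit) * longit
            transv /= np.linalg.norm(transv)
            normal = np.cross(longit, transv)
            b = np.sqrt(m.leaf_area / (2.0 * _POLY_AREA_FACTOR))
            center = m.tip + longit * (2.0 * b)
            poly = _leaf_polygon(m.leaf_area, center, longit, transv)
            leaves.append(Leaf(m.leaf_area, center, normal, poly))
    return leaves


def total_leaf_area(leaves: list[Leaf]) -> float:
    """TLA: sum of individual leaf areas."""
    return float(sum(lf.area for lf in leaves))


def build_tree_geometry(
    tree: Tree,
    leaf_params: LeafGrowthParams,
    internode_params: InternodeGrowthParams,
    mech: MechanicsParams,
    tsd: float,
    eval_day: float = 90.0,
) -> list[Leaf]:
    """Full geometry pass: growth, pipe model, bending, leaf mesh."""
    compute_growth(tree, leaf_params, internode_params, eval_day)
    apply_pipe_model(tree, tsd)
    bend_axes(tree, mech)
    return build_leaf_mesh(tree, mech)
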