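"""Stochastic apple-tree topology over years.

The shoot system is built from growth units (GUs): the portion of an axis
produced in one annual flush.  Four GU states exist (long, medium, short,
floral); the year-to-year fate of each terminal bud follows a first-order
Markov chain over these states.  Along new long and medium GUs, axillary
bud fates are organized in successive branching zones modelled by a
hidden semi-Markov chain (HSMC): zones succeed each other left-to-right
(base to tip), each zone's length is drawn from an occupancy distribution
and each node in a zone draws its lateral fate from the zone's
categorical observation distribution.  Sylleptic laterals grow out the
same year; proleptic laterals wait for the next budbreak; latent buds
bear nothing.  Short GUs die with a constant annual probability; dead
GUs produce nothing and carry no leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "GUType",
    "LateralFate",
    "MarkovParams",
    "ZoneSpec",
    "HsmcClassParams",
    "HsmcParams",
    "Metamer",
    "GrowthUnit",
    "Tree",
    "BranchingSequence",
    "DEFAULT_METAMER_COUNTS",
    "sample_gu_succession",
    "sample_branching_zones",
    "init_trunk_from_sequence",
    "grow_year",
    "count_gus",
]


class GUType(str, Enum):
    LONG = "long"
    MEDIUM = "medium"
    SHORT = "short"
    FLORAL = "floral"


GU_ORDER = [GUType.LONG, GUType.MEDIUM, GUType.SHORT, GUType.FLORAL]


class LateralFate(str, Enum):
    LATENT = "latent"
    SYLLEPTIC_SHORT = "sylleptic_short"
    SYLLEPTIC_MEDIUM = "sylleptic_medium"
    SYLLEPTIC_LONG = "sylleptic_long"
    PROLEPTIC_SHORT = "proleptic_short"
    PROLEPTIC_MEDIUM = "proleptic_medium"
    PROLEPTIC_LONG = "proleptic_long"
    PROLEPTIC_FLORAL = "proleptic_floral"


SYLLEPTIC_FATES = {
    LateralFate.SYLLEPTIC_SHORT,
    LateralFate.SYLLEPTIC_MEDIUM,
    LateralFate.SYLLEPTIC_LONG,
}
PROLEPTIC_FATES = {
    LateralFate.PROLEPTIC_SHORT,
    LateralFate.PROLEPTIC_MEDIUM,
    LateralFate.PROLEPTIC_LONG,
    LateralFate.PROLEPTIC_FLORAL,
}

_FATE_TO_GU = {
    LateralFate.SYLLEPTIC_SHORT: GUType.SHORT,
    LateralFate.SYLLEPTIC_MEDIUM: GUType.MEDIUM,
    LateralFate.SYLLEPTIC_LONG: GUType.LONG,
    LateralFate.PROLEPTIC_SHORT: GUType.SHORT,
    LateralFate.PROLEPTIC_MEDIUM: GUType.MEDIUM,
    LateralFate.PROLEPTIC_LONG: GUType.LONG,
    LateralFate.PROLEPTIC_FLORAL: GUType.FLORAL,
}


def fate_gu_type(fate: LateralFate) -> GUType:
    """GU state produced when a lateral of this fate grows out."""
    return _FATE_TO_GU[fate]


# Metamer count ranges per GU type (inclusive); length classes are disjoint.
DEFAULT_METAMER_COUNTS: dict[GUType, tuple[int, int]] = {
    GUType.LONG: (40, 80),
    GUType.MEDIUM: (15, 39),
    GUType.SHORT: (3, 14),
    GUType.FLORAL: (8, 8),
}


@dataclass
class MarkovParams:
    """First-order Markov chain over GU states for terminal-bud succession.

    Rows/columns are ordered long, medium, short, floral.
    """

    gu_transition: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self):
        self.gu_transition = np.asarray(self.gu_transition, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.validate()

    def validate(self) -> None:
        T = self.gu_transition
        if T.shape != (4, 4):
            raise ValueError("gu_transition must be 4x4 (long, medium, short, floral)")
        if np.any(T < 0) or np.any(self.initial_distribution < 0):
            raise ValueError("probabilities must be non-negative")
        if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("gu_transition rows must sum to 1")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12:
            raise ValueError("initial_distribution must sum to 1")

    def row(self, gu_type: GUType) -> np.ndarray:
        return self.gu_transition[GU_ORDER.index(gu_type)]


@dataclass
class ZoneSpec:
    """One branching zone: occupancy distribution + lateral-fate mixture.

    occupancy: (name, params) with name in {'fixed', 'uniform_int',
    'shifted_negbin', 'shifted_poisson', 'rest'}; support on positive
    integers.  At most one zone per class may use 'rest': it absorbs
    however many nodes remain after the other zones have drawn their
    occupancies, so a short distal zone (e.g. an acrotonic tip) keeps its
    sampled length at the shoot apex whatever the shoot's node count.
    c_z: internode elongation coefficient of the zone (see organ growth).
    """

    name: str
    occupancy: tuple[str, tuple]
    fate_probs: dict[LateralFate, float]
    c_z: float = 1.0

    def __post_init__(self):
        tot = sum(self.fate_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"zone '{self.name}': fate probabilities sum to {tot}")
        if any(p < 0 for p in self.fate_probs.values()):
            raise ValueError("fate probabilities must be non-negative")
        if not 0.0 <= self.c_z <= 1.0:
            raise ValueError("c_z must lie in [0, 1]")

    def sample_occupancy(self, rng: np.random.Generator) -> int:
        kind, par = self.occupancy
        if kind == "rest":
            raise ValueError("'rest' zones do not sample an occupancy")
        if kind == "fixed":
            return int(par[0])
        if kind == "uniform_int":
            lo, hi = par
            return int(rng.integers(lo, hi + 1))
        if kind == "shifted_negbin":
            # support {shift, shift+1, ...}; parameters (r, p, shift)
            r, p, shift = par
            return int(shift + rng.negative_binomial(r, p))
        if kind == "shifted_poisson":
            mu, shift = par
            return int(shift + rng.poisson(mu))
        raise ValueError(f"unknown occupancy distribution '{kind}'")

    def mean_occupancy(self) -> float:
        kind, par = self.occupancy
        if kind == "rest":
            return float("nan")
        if kind == "fixed":
            return float(par[0])
        if kind == "uniform_int":
            return 0.5 * (par[0] + par[1])
        if kind == "shifted_negbin":
            r, p, shift = par
            return shift + r * (1 - p) / p
        if kind == "shifted_poisson":
            mu, shift = par
            return shift + mu
        raise ValueError(kind)

    def sample_fate(self, rng: np.random.Generator) -> LateralFate:
        fates = list(self.fate_probs)
        probs = np.array([self.fate_probs[f] for f in fates])
        return fates[rng.choice(len(fates), p=probs / probs.sum())]


@dataclass
class HsmcClassParams:
    """HSMC parameterization for one parent-shoot length class."""

    zones: list[ZoneSpec]
    transition: np.ndarray | None = None  # zone transition; default sequential

    def __post_init__(self):
        m = len(self.zones)
        if m < 1:
            raise ValueError("need at least one zone")
        if self.transition is None:
            T = np.zeros((m, m))
            for i in range(m - 1):
                T[i, i + 1] = 1.0
            T[m - 1, m - 1] = 1.0
            self.transition = T
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (m, m):
            raise ValueError("zone transition matrix has wrong shape")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("zone transition rows must sum to 1")
        if np.any(np.tril(self.transition, -1) > 0):
            raise ValueError("zones must succeed left-to-right (no backward transitions)")
        if sum(1 for z in self.zones if z.occupancy[0] == "rest") > 1:
            raise ValueError("at most one 'rest' zone per parent class")


@dataclass
class HsmcParams:
    """Branching HSMCs indexed by parent length class ('long' or 'medium')."""

    classes: dict[str, HsmcClassParams]

    def for_parent(self, parent_class: str) -> HsmcClassParams:
        if parent_class not in self.classes:
            raise ValueError(f"no HSMC parameters for parent class '{parent_class}'")
        return self.classes[parent_class]


@dataclass
class Metamer:
    rank: int  # 1 = GU base
    lateral_fate: LateralFate = LateralFate.LATENT
    zone_id: int = 0
    birth_day: float = 0.0  # day within the GU's growing season
    internode_length: float = 0.0  # m
    internode_diameter: float = 0.0  # m
    leaf_area: float = 0.0  # m^2
    c_z: float = 1.0
    # geometry pose, filled by the geometry stage
    base: np.ndarray | None = None
    tip: np.ndarray | None = None


@dataclass
class GrowthUnit:
    gu_id: int
    gu_type: GUType
    year: int
    metamers: list[Metamer] = field(default_factory=list)
    parent_gu: int | None = None  # bearing GU (None for the root trunk)
    parent_rank: int | None = None  # rank of the bearing metamer
    is_successor: bool = False  # continues its parent's axis (terminal bud)
    successor: int | None = None
    alive: bool = True
    fixed_length: float | None = None  # total length override (m), e.g. observed trunk

    @property
    def n_metamers(self) -> int:
        return len(self.metamers)


@dataclass
class Tree:
    age_years: int
    gus: dict[int, GrowthUnit] = field(default_factory=dict)
    root_id: int = 0
    pending_buds: list[tuple[int, int, LateralFate]] = field(default_factory=list)
    rng_seed: int | None = None
    _next_id: int = 0

    def add_gu(self, gu_type: GUType, year: int, n_metamers: int,
               parent_gu: int | None = None, parent_rank: int | None = None,
               is_successor: bool = False) -> GrowthUnit:
        gu = GrowthUnit(self._next_id, gu_type, year,
                        [Metamer(rank=r) for r in range(1, n_metamers + 1)],
                        parent_gu, parent_rank, is_successor)
        self.gus[gu.gu_id] = gu
        if parent_gu is not None and is_successor:
            self.gus[parent_gu].successor = gu.gu_id
        self._next_id += 1
        return gu

    def gus_of_year(self, year: int) -> list[GrowthUnit]:
        return [g for g in self.gus.values() if g.year == year]

    def terminal_gus(self) -> list[GrowthUnit]:
        """Live GUs whose terminal bud has not yet produced a successor."""
        return [
            g
            for g in sorted(self.gus.values(), key=lambda g: g.gu_id)
            if g.alive and g.successor is None
        ]


@dataclass
class BranchingSequence:
    """Observed (or synthetic) first-year trunk: one lateral fate per node."""

    node_fates: list[LateralFate]
    trunk_length: float  # m

    def __post_init__(self):
        if not self.node_fates:
            raise ValueError("branching sequence must be non-empty")
        if self.trunk_length <= 0:
            raise ValueError("trunk_length must be positive")
        self.node_fates = [LateralFate(f) for f in self.node_fates]


def sample_gu_succession(
    current: GUType, params: MarkovParams, rng: np.random.Generator
) -> GUType:
    """Draw next year's GU state for a terminal bud."""
    row = params.row(GUType(current))
    return GU_ORDER[rng.choice(4, p=row)]


def sample_branching_zones(
    parent_class: str,
    n_nodes: int,
    params: HsmcParams,
    rng: np.random.Generator,
) -> list[tuple[int, LateralFate]]:
    """Simulate the HSMC along a parent shoot of `n_nodes` nodes.

    Returns one (zone_id, fate) pair per node, base to tip.  Zone lengths
    follow the occupancy distributions, truncated so the total equals
    n_nodes; zone ids are indices into the class's zone list and are
    non-decreasing along the shoot.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    cls = params.for_parent(parent_class)
    m = len(cls.zones)
    sequential = all(
        cls.transition[i, i + 1] == 1.0 for i in range(m - 1)
    ) if m > 1 else True

    if sequential:
        occ = []
        for z in cls.zones:
            if z.occupancy[0] == "rest":
                occ.append(0)
            else:
                occ.append(max(1, z.sample_occupancy(rng)))
        rest = [i for i, z in enumerate(cls.zones) if z.occupancy[0] == "rest"]
        if rest:
            occ[rest[0]] = max(0, n_nodes - sum(occ))
        out: list[tuple[int, LateralFate]] = []
        for zid, z in enumerate(cls.zones):
            for _ in range(min(occ[zid], n_nodes - len(out))):
                out.append((zid, z.sample_fate(rng)))
        while len(out) < n_nodes:  # shoot longer than all sampled zones
            out.append((m - 1, cls.zones[m - 1].sample_fate(rng)))
        return out

    # general left-to-right walk; the final zone absorbs the remainder
    out = []
    zone = 0
    while len(out) < n_nodes:
        spec = cls.zones[zone]
        occ_n = max(1, spec.sample_occupancy(rng))
        for _ in range(min(occ_n, n_nodes - len(out))):
            out.append((zone, spec.sample_fate(rng)))
        if len(out) >= n_nodes:
            break
        if zone == m - 1:
            while len(out) < n_nodes:
                out.append((zone, spec.sample_fate(rng)))
            break
        zone = int(rng.choice(m, p=cls.transition[zone]))
    return out


def _zone_cz(cls: HsmcClassParams | None, zone_id: int) -> float:
    if cls is None:
        return 1.0
    return cls.zones[zone_id].c_z


def _attach_laterals(
    tree: Tree,
    gu: GrowthUnit,
    year: int,
    rng: np.random.Generator,
    metamer_counts: dict[GUType, tuple[int, int]],
) -> None:
    """Instantiate sylleptic laterals now; store proleptic buds for next year."""
    for m in gu.metamers:
        fate = m.lateral_fate
        if fate == LateralFate.LATENT:
            continue
        if fate in SYLLEPTIC_FATES:
            gtype = fate_gu_type(fate)
            lo, hi = metamer_counts[gtype]
            n = int(rng.integers(lo, hi + 1))
            tree.add_gu(gtype, year, n, parent_gu=gu.gu_id, parent_rank=m.rank)
        else:
            tree.pending_buds.append((gu.gu_id, m.rank, fate))


def init_trunk_from_sequence(
    seq: BranchingSequence,
    rng: np.random.Generator | None = None,
    metamer_counts: dict[GUType, tuple[int, int]] | None = None,
) -> Tree:
    """Build a 1-year-old tree whose trunk carries the observed lateral fates.

    One metamer per node fate (base to top).  Sylleptic fates grow out as
    lateral GUs within year 1; proleptic fates are stored and break at the
    next budbreak; latent nodes bear nothing.  The trunk's total length is
    pinned to the observed `trunk_length`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    metamer_counts = metamer_counts or DEFAULT_METAMER_COUNTS
    tree = Tree(age_years=1)
    trunk = tree.add_gu(GUType.LONG, 1, len(seq.node_fates))
    trunk.fixed_length = seq.trunk_length
    tree.root_id = trunk.gu_id
    for m, fate in zip(trunk.metamers, seq.node_fates):
        m.lateral_fate = LateralFate(fate)
    _attach_laterals(tree, trunk, 1, rng, metamer_counts)
    return tree


def grow_year(
    tree: Tree,
    markov: MarkovParams,
    hsmc: HsmcParams,
    mortality_short: float,
    rng: np.random.Generator,
    metamer_counts: dict[GUType, tuple[int, int]] | None = None,
) -> Tree:
    """Advance the tree by one year of growth (in place; also returned).

    Order of events (deterministic given the rng stream): short-shoot
    mortality; outgrowth of last year's proleptic buds; terminal-bud
    succession base-to-top in GU creation order; HSMC branching of every
    new long/medium GU, whose sylleptic laterals appear the same year.
    """
    if not 0.0 <= mortality_short <= 1.0:
        raise ValueError("mortality_short must be a probability")
    metamer_counts = metamer_counts or DEFAULT_METAMER_COUNTS
    tree.age_years += 1
    year = tree.age_years

    for gu in sorted(tree.gus.values(), key=lambda g: g.gu_id):
        if gu.alive and gu.gu_type == GUType.SHORT:
            if rng.random() < mortality_short:
                gu.alive = False

    new_gus: list[GrowthUnit] = []

    pending, tree.pending_buds = tree.pending_buds, []
    for gu_id, rank, fate in pending:
        bearer = tree.gus[gu_id]
        if not bearer.alive:
            continue
        gtype = fate_gu_type(fate)
        lo, hi = metamer_counts[gtype]
        n = int(rng.integers(lo, hi + 1))
        new_gus.append(
            tree.add_gu(gtype, year, n, parent_gu=gu_id, parent_rank=rank)
        )

    for gu in tree.terminal_gus():
        if gu.year == year:
            continue  # created this year; its terminal grows next year
        nxt = sample_gu_succession(gu.gu_type, markov, rng)
        lo, hi = metamer_counts[nxt]
        n = int(rng.integers(lo, hi + 1))
        new_gus.append(
            tree.add_gu(
                nxt, year, n,
                parent_gu=gu.gu_id, parent_rank=gu.n_metamers, is_successor=True,
            )
        )

    for gu in new_gus:
        if gu.gu_type in (GUType.LONG, GUType.MEDIUM):
            cls_name = "long" if gu.gu_type == GUType.LONG else "medium"
            cls = hsmc.for_parent(cls_name)
            pairs = sample_branching_zones(cls_name, gu.n_metamers, hsmc, rng)
            for m, (zid, fate) in zip(gu.metamers, pairs):
                m.zone_id = zid
                m.lateral_fate = fate
                m.c_z = _zone_cz(cls, zid)
            _attach_laterals(tree, gu, year, rng, metamer_counts)
    return tree


def count_gus(tree: Tree) -> dict[tuple[int, GUType], int]:
    """Exact GU counts keyed by (year, gu_type); includes dead GUs."""
    counts: dict[tuple[int, GUType], int] = {}
    for gu in tree.gus.values():
        key = (gu.year, gu.gu_type)
        counts[key] = counts.get(key, 0) + 1
    return counts
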