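"""Synthetic study inputs.

The field data behind the original study system — the Markov/HSMC
parameterization estimated for the 'Fuji' cultivar and the 108 observed
first-year trunk branching sequences of the bi-parental hybrid
population — are not published.  This module generates structurally
faithful stand-ins: a documented toy Markov/HSMC parameterization
encoding the known qualitative organization (latent basal zone, mixed
median zone, acrotonic distal zone rich in long proleptics just below
the apical bud), synthetic trunk sequences whose branching-density
marginals span the ranges discussed for the real population (roughly
0-25 sylleptic and 0-40 proleptic laterals per metre), analytic leaf
canopies with closed-form STAR expectations, and additive-response
datasets with known truth for validating the sensitivity metamodel.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import qmc

from .geometry import Leaf, _leaf_polygon
from .topology import (
    BranchingSequence,
    HsmcClassParams,
    HsmcParams,
    LateralFate,
    MarkovParams,
    ZoneSpec,
)

__all__ = [
    "SequenceGenSpec",
    "CanopyFixtureSpec",
    "default_markov_params",
    "generate_trunk_sequences",
    "make_canopy_fixture",
    "generate_gam_dataset",
]


def default_markov_params() -> tuple[MarkovParams, HsmcParams]:
    """Documented toy parameterization of GU succession and branching.

    GU succession favours vigour loss with age (long -> medium/short),
    the classical drift of apple shoot demography toward short and floral
    GUs.  The long-parent HSMC has three zones base-to-tip: a latent
    basal zone, a broad mixed median zone, and a short acrotonic distal
    zone where long proleptics concentrate.  Medium parents carry a
    two-zone, mostly latent model.  All values are package defaults, not
    estimates from field data.
    """
    markov = MarkovParams(
        gu_transition=np.array(
            [
                # long   medium  short  floral
                [0.50, 0.25, 0.20, 0.05],  # from long
                [0.15, 0.30, 0.45, 0.10],  # from medium
                [0.02, 0.08, 0.60, 0.30],  # from short
                [0.05, 0.15, 0.70, 0.10],  # from floral (bourse shoot)
            ]
        ),
        initial_distribution=np.array([1.0, 0.0, 0.0, 0.0]),
    )
    L = LateralFate
    long_zones = [
        ZoneSpec(
            "basal_latent",
            ("shifted_negbin", (3, 0.35, 3)),
            {L.LATENT: 1.0},
            c_z=0.3,
        ),
        ZoneSpec(
            "median_mixed",
            ("rest", ()),
            {
                L.LATENT: 0.750,
                L.SYLLEPTIC_SHORT: 0.070,
                L.SYLLEPTIC_MEDIUM: 0.015,
                L.PROLEPTIC_SHORT: 0.080,
                L.PROLEPTIC_MEDIUM: 0.035,
                L.PROLEPTIC_LONG: 0.008,
                L.PROLEPTIC_FLORAL: 0.042,
            },
        ),
        ZoneSpec(
            "distal_acrotonic",
            ("shifted_negbin", (2, 0.60, 1)),
            {
                L.LATENT: 0.35,
                L.PROLEPTIC_LONG: 0.35,
                L.PROLEPTIC_MEDIUM: 0.20,
                L.PROLEPTIC_FLORAL: 0.10,
            },
        ),
    ]
    medium_zones = [
        ZoneSpec(
            "basal_latent",
            ("uniform_int", (4, 8)),
            {L.LATENT: 1.0},
            c_z=0.3,
        ),
        ZoneSpec(
            "distal_mixed",
            ("rest", ()),
            {
                L.LATENT: 0.86,
                L.PROLEPTIC_SHORT: 0.07,
                L.PROLEPTIC_MEDIUM: 0.03,
                L.PROLEPTIC_FLORAL: 0.04,
            },
        ),
    ]
    hsmc = HsmcParams(
        classes={
            "long": HsmcClassParams(long_zones),
            "medium": HsmcClassParams(medium_zones),
        }
    )
    return markov, hsmc


@dataclass
class SequenceGenSpec:
    """Generator settings for synthetic first-year trunk sequences.

    Each sequence draws its own overall sylleptic and proleptic branching
    propensities uniformly from `syl_frac_range` / `pro_frac_range`, so
    the 108-sequence batch spans low to high branching densities, while
    the within-trunk zonation (latent base, mixed middle, acrotonic tip)
    is common to all sequences.
    """

    n_sequences: int = 108
    trunk_length_dist: tuple[float, float] = (1.0, 0.25)  # mean, sd (m)
    nodes_per_m: float = 60.0
    syl_frac_range: tuple[float, float] = (0.0, 0.45)
    pro_frac_range: tuple[float, float] = (0.0, 0.70)
    basal_frac: float = 0.15  # latent basal zone share of nodes
    distal_nodes: int = 6  # acrotonic tip zone
    syl_split: tuple[float, float, float] = (0.5, 0.3, 0.2)  # short, medium, long
    pro_split: tuple[float, float, float, float] = (0.35, 0.30, 0.25, 0.10)
    seed: int = 0

    def __post_init__(self):
        if self.nodes_per_m <= 0:
            raise ValueError("nodes_per_m must be positive")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def generate_trunk_sequences(spec: SequenceGenSpec) -> list[BranchingSequence]:
    """Draw `spec.n_sequences` synthetic trunk branching sequences."""
    rng = np.random.default_rng(spec.seed)
    L = LateralFate
    syl_fates = [L.SYLLEPTIC_SHORT, L.SYLLEPTIC_MEDIUM, L.SYLLEPTIC_LONG]
    pro_fates = [
        L.PROLEPTIC_SHORT,
        L.PROLEPTIC_MEDIUM,
        L.PROLEPTIC_LONG,
        L.PROLEPTIC_FLORAL,
    ]
    syl_split = np.asarray(spec.syl_split) / np.sum(spec.syl_split)
    pro_split = np.asarray(spec.pro_split) / np.sum(spec.pro_split)
    out = []
    for _ in range(spec.n_sequences):
        mean, sd = spec.trunk_length_dist
        length = float(np.clip(rng.normal(mean, sd), 0.4, None))
        n_nodes = max(10, int(round(length * spec.nodes_per_m)))
        p_syl = rng.uniform(*spec.syl_frac_range)
        p_pro = rng.uniform(*spec.pro_frac_range) * (1.0 - p_syl)
        n_basal = int(round(spec.basal_frac * n_nodes))
        n_distal = min(spec.distal_nodes, n_nodes - n_basal)
        fates: list[LateralFate] = [L.LATENT] * n_basal
        for _node in range(n_nodes - n_basal - n_distal):
            u = rng.random()
            if u < p_syl:
                fates.append(syl_fates[rng.choice(3, p=syl_split)])
            elif u < p_syl + p_pro:
                fates.append(pro_fates[rng.choice(4, p=pro_split)])
            else:
                fates.append(L.LATENT)
        for _node in range(n_distal):
            # acrotonic tip: long proleptics just below the apical bud
            u = rng.random()
            if u < 0.45 * (p_pro + 0.2):
                fates.append(L.PROLEPTIC_LONG)
            elif u < 0.65 * (p_pro + 0.2):
                fates.append(L.PROLEPTIC_MEDIUM)
            else:
                fates.append(L.LATENT)
        out.append(BranchingSequence(fates, length))
    return out


@dataclass
class CanopyFixtureSpec:
    """Analytic leaf-canopy fixture with a machine-readable expectation."""

    kind: str  # single_leaf | stacked_k | spherical_cloud | grid_no_overlap
    k: int = 4
    n: int = 100
    leaf_area: float = 3.0e-3  # m^2
    radius: float = 0.5  # m (spherical_cloud)
    seed: int = 0


def _horizontal_leaf(area: float, center: np.ndarray) -> Leaf:
    poly = _leaf_polygon(
        area, center, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    )
    return Leaf(area, center, np.array([0.0, 0.0, 1.0]), poly)


def make_canopy_fixture(spec: CanopyFixtureSpec) -> tuple[list[Leaf], dict]:
    """Build a fixture canopy plus its STAR expectation contract.

    The returned dict holds either an exact `zenith_star` value or an
    `oracle` recipe name telling the caller which independent estimator
    to compare against.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.leaf_area
    if spec.kind == "single_leaf":
        return [_horizontal_leaf(a, np.zeros(3))], {
            "zenith_star": 1.0,
            "tolerance": 0.02,
        }
    if spec.kind == "stacked_k":
        leaves = [
            _horizontal_leaf(a, np.array([0.0, 0.0, 0.01 * i]))
            for i in range(spec.k)
        ]
        return leaves, {"zenith_star": 1.0 / spec.k, "tolerance": 0.02}
    if spec.kind == "grid_no_overlap":
        side = int(np.ceil(np.sqrt(spec.n)))
        pitch = 3.0 * np.sqrt(a)  # comfortably separated
        leaves = []
        for i in range(spec.n):
            r, c = divmod(i, side)
            leaves.append(_horizontal_leaf(a, np.array([c * pitch, r * pitch, 0.0])))
        return leaves, {"zenith_star": 1.0, "tolerance": 0.02}
    if spec.kind == "spherical_cloud":
        leaves = []
        for _ in range(spec.n):
            c = rng.normal(size=3)
            c = c / np.linalg.norm(c) * spec.radius * rng.uniform(0.2, 1.0) ** (1 / 3)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            u = np.cross(v, [0.0, 0.0, 1.0])
            if np.linalg.norm(u) < 1e-9:
                u = np.cross(v, [1.0, 0.0, 0.0])
            u /= np.linalg.norm(u)
            w = np.cross(v, u)
            poly = _leaf_polygon(a, c, u, w)
            leaves.append(Leaf(a, c, v, poly))
        return leaves, {"oracle": "ray_casting", "tolerance": 0.01}
    raise ValueError(f"unknown canopy fixture kind '{spec.kind}'")


def generate_gam_dataset(
    truth_spec: dict[str, Callable[[np.ndarray], np.ndarray]],
    n: int,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Additive-response dataset with known smooth truth on [0, 1]^K.

    Inputs are a Latin hypercube sample; the response is
    intercept + sum_k f_k(x_k) + Gaussian noise.  The returned
    description carries the data-centered truth functions, per-term
    signal variances (effect sizes) and the generative R^2
    (signal variance over total variance; 1 when noise_sd == 0).
    """
    names = list(truth_spec)
    K = len(names)
    sampler = qmc.LatinHypercube(d=K, seed=seed)
    X = sampler.random(n)
    rng = np.random.default_rng(seed + 1)
    signal = np.full(n, float(intercept))
    centered: dict[str, Callable] = {}
    effect_var: dict[str, float] = {}
    for k, name in enumerate(names):
        fk = truth_spec[name]
        vals = np.asarray(fk(X[:, k]), dtype=float)
        mean_k = float(vals.mean())
        signal = signal + vals
        centered[name] = (lambda f, m: (lambda x: np.asarray(f(x)) - m))(fk, mean_k)
        effect_var[name] = float(np.var(vals))
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    y = signal + noise
    var_sig = float(np.var(signal))
    gen_r2 = 1.0 if noise_sd == 0 else var_sig / (var_sig + noise_sd**2)
    desc = {
        "names": names,
        "centered_truth": centered,
        "effect_var": effect_var,
        "generative_r2": gen_r2,
        "noise_sd": noise_sd,
    }
    return X, y, desc
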