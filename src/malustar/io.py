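"""File formats: design/sequence/results CSV, tree JSON, leaf OBJ/PLY.

CSV dialect is fixed: comma separator, period decimal point, UTF-8, a
mandatory header row.  Parsing is strict and locale-independent: "0.005"
is a number, "0,005" is an error naming the offending row and column.

OBJ export writes one polygon face per leaf (no triangulation), so a
round trip preserves the leaf count and total leaf area exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import DesignTable, TraitSet
from .geometry import Leaf
from .topology import BranchingSequence, GrowthUnit, LateralFate, GUType, Metamer, Tree

__all__ = [
    "DESIGN_COLUMNS",
    "read_design",
    "write_design",
    "read_sequences",
    "write_sequences",
    "tree_to_json",
    "tree_from_json",
    "export_leaves",
    "import_leaves_obj",
    "write_results",
    "read_results",
]

DESIGN_COLUMNS = [
    "tree_id",
    "leaf_area",
    "internode_length",
    "top_shoot_diameter",
    "branching_angle",
    "seed",
]

SEQUENCE_COLUMNS = ["sequence_id", "node_rank", "fate_code", "trunk_length"]


class ParseError(ValueError):
    pass


def _strict_float(token: str, row: int, col: str) -> float:
    try:
        return float(token)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}, column '{col}': not a valid number: {token!r}"
        ) from None


def write_design(design: DesignTable, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(
    path: str | Path,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> DesignTable:
    """Strictly parse a design CSV; optional per-trait range validation."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != DESIGN_COLUMNS:
        missing = set(DESIGN_COLUMNS) - set(df.columns)
        extra = set(df.columns) - set(DESIGN_COLUMNS)
        raise ParseError(
            f"bad design header: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        vals = {}
        for col, token in zip(DESIGN_COLUMNS, rec):
            vals[col] = _strict_float(token, i, col)
        if ranges:
            for name, (lo, hi) in ranges.items():
                if not lo <= vals[name] <= hi:
                    raise ParseError(
                        f"row {i}, column '{name}': value {vals[name]} outside "
                        f"[{lo}, {hi}]"
                    )
        traits = TraitSet(
            vals["leaf_area"],
            vals["internode_length"],
            vals["top_shoot_diameter"],
            vals["branching_angle"],
        )
        rows.append((int(vals["tree_id"]), traits, int(vals["seed"])))
    return DesignTable(rows)


def write_sequences(seqs: list[BranchingSequence], path: str | Path) -> None:
    recs = []
    for sid, seq in enumerate(seqs):
        for rank, fate in enumerate(seq.node_fates, start=1):
            recs.append(
                {
                    "sequence_id": sid,
                    "node_rank": rank,
                    "fate_code": fate.value,
                    "trunk_length": seq.trunk_length,
                }
            )
    pd.DataFrame(recs, columns=SEQUENCE_COLUMNS).to_csv(path, index=False)


def read_sequences(path: str | Path) -> list[BranchingSequence]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != SEQUENCE_COLUMNS:
        raise ParseError(f"bad sequence header: {list(df.columns)}")
    out = []
    for sid, grp in df.groupby(df.sequence_id.astype(int), sort=True):
        grp = grp.assign(_rank=grp.node_rank.astype(int)).sort_values("_rank")
        fates = [LateralFate(f) for f in grp.fate_code]
        length = _strict_float(grp.trunk_length.iloc[0], int(grp.index[0]) + 1,
                               "trunk_length")
        out.append(BranchingSequence(fates, length))
    return out


# ---------------------------------------------------------------------------
# Tree JSON

def tree_to_json(tree: Tree, path: str | Path | None = None) -> dict:
    doc = {
        "age_years": tree.age_years,
        "root_id": tree.root_id,
        "rng_seed": tree.rng_seed,
        "pending_buds": [
            [gid, rank, fate.value] for gid, rank, fate in tree.pending_buds
        ],
        "gus": [
            {
                "gu_id": g.gu_id,
                "gu_type": g.gu_type.value,
                "year": g.year,
                "parent_gu": g.parent_gu,
                "parent_rank": g.parent_rank,
                "is_successor": g.is_successor,
                "successor": g.successor,
                "alive": g.alive,
                "fixed_length": g.fixed_length,
                "metamers": [
                    {
                        "rank": m.rank,
                        "fate": m.lateral_fate.value,
                        "zone_id": m.zone_id,
                        "internode_length": m.internode_length,
                        "internode_diameter": m.internode_diameter,
                        "leaf_area": m.leaf_area,
                        "c_z": m.c_z,
                    }
                    for m in g.metamers
                ],
            }
            for g in sorted(tree.gus.values(), key=lambda g: g.gu_id)
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def tree_from_json(src: str | Path | dict) -> Tree:
    if not isinstance(src, dict):
        src = json.loads(Path(src).read_text())
    tree = Tree(age_years=src["age_years"], root_id=src["root_id"],
                rng_seed=src.get("rng_seed"))
    tree.pending_buds = [
        (g, r, LateralFate(f)) for g, r, f in src.get("pending_buds", [])
    ]
    max_id = -1
    for gd in src["gus"]:
        gu = GrowthUnit(
            gu_id=gd["gu_id"],
            gu_type=GUType(gd["gu_type"]),
            year=gd["year"],
            parent_gu=gd["parent_gu"],
            parent_rank=gd["parent_rank"],
            is_successor=gd["is_successor"],
            successor=gd["successor"],
            alive=gd["alive"],
            fixed_length=gd.get("fixed_length"),
        )
        gu.metamers = [
            Metamer(
                rank=md["rank"],
                lateral_fate=LateralFate(md["fate"]),
                zone_id=md["zone_id"],
                internode_length=md["internode_length"],
                internode_diameter=md["internode_diameter"],
                leaf_area=md["leaf_area"],
                c_z=md["c_z"],
            )
            for md in gd["metamers"]
        ]
        tree.gus[gu.gu_id] = gu
        max_id = max(max_id, gu.gu_id)
    tree._next_id = max_id + 1
    return tree


# ---------------------------------------------------------------------------
# Leaf soup OBJ / PLY

def export_leaves(leaves: list[Leaf], path: str | Path, fmt: str = "obj") -> None:
    """Write the leaf set as a polygon soup, one face per leaf."""
    path = Path(path)
    if fmt == "obj":
        lines = ["# malustar leaf soup", f"# leaves {len(leaves)}"]
        for lf in leaves:
            for v in lf.polygon:
                lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        idx = 1
        for lf in leaves:
            k = len(lf.polygon)
            lines.append("f " + " ".join(str(idx + j) for j in range(k)))
            idx += k
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        nv = sum(len(lf.polygon) for lf in leaves)
        header = [
            "ply",
            "format ascii 1.0",
            f"element vertex {nv}",
            "property float x",
            "property float y",
            "property float z",
            f"element face {len(leaves)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        body = []
        for lf in leaves:
            for v in lf.polygon:
                body.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        idx = 0
        for lf in leaves:
            k = len(lf.polygon)
            body.append(f"{k} " + " ".join(str(idx + j) for j in range(k)))
            idx += k
        path.write_text("\n".join(header + body) + "\n")
    else:
        raise ValueError(f"unsupported format '{fmt}' (obj or ply)")


def _polygon_area_normal(poly: np.ndarray) -> tuple[float, np.ndarray]:
    c = poly.mean(axis=0)
    cross = np.zeros(3)
    for i in range(len(poly)):
        a = poly[i] - c
        b = poly[(i + 1) % len(poly)] - c
        cross += np.cross(a, b)
    area = 0.5 * np.linalg.norm(cross)
    n = cross / np.linalg.norm(cross) if np.linalg.norm(cross) > 0 else np.array(
        [0.0, 0.0, 1.0]
    )
    return float(area), n


def import_leaves_obj(path: str | Path) -> list[Leaf]:
    """Read a polygon-soup OBJ back into a list of leaves."""
    verts: list[list[float]] = []
    leaves: list[Leaf] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            ids = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            poly = np.array([verts[i] for i in ids])
            area, normal = _polygon_area_normal(poly)
            leaves.append(Leaf(area, poly.mean(axis=0), normal, poly))
    return leaves


def export_tree_geometry(tree: Tree, path: str | Path, fmt: str = "obj",
                         mech=None) -> None:
    """Export a tree's current leaf mesh (poses and leaf areas must be set,
    e.g. by `geometry.build_tree_geometry`)."""
    from .geometry import MechanicsParams, build_leaf_mesh

    leaves = build_leaf_mesh(tree, mech or MechanicsParams())
    export_leaves(leaves, path, fmt)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
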