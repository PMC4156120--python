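"""Run configuration: a validated YAML schema for end-to-end pipelines.

Unknown keys are rejected so a typo in a config file fails immediately
rather than silently falling back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .topology import HsmcClassParams, HsmcParams, LateralFate, MarkovParams, ZoneSpec

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "markov_to_dict",
    "markov_from_dict",
    "hsmc_to_dict",
    "hsmc_from_dict",
    "load_params_file",
]

SCHEMA_VERSION = 1


class SkyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sectors: int = 46
    flux_term: bool = True


class RunConfig(BaseModel):
    """Umbrella configuration for `malustar run-experiment`."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["geometry", "topology"] = "geometry"
    years: int = Field(5, ge=1)
    seed: int = 0
    n_trees: int = Field(300, ge=1)  # geometry design rows / topology sequences
    trait_ranges: dict[str, tuple[float, float]] | None = None
    sky: SkyConfig = Field(default_factory=SkyConfig)
    resolution: float = Field(2e-3, gt=0)
    mortality_short: float = Field(0.1, ge=0, le=1)
    eval_day: float = Field(90.0, gt=0)
    params_file: str | None = None  # YAML with Markov/HSMC parameters
    out_dir: str = "malustar_run"

    @field_validator("trait_ranges")
    @classmethod
    def _ranges_valid(cls, v):
        if v is None:
            return v
        for name, (lo, hi) in v.items():
            if not lo < hi:
                raise ValueError(f"range for '{name}' must have lo < hi")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Markov / HSMC parameter YAML schema (versioned)

def markov_to_dict(m: MarkovParams) -> dict:
    return {
        "gu_transition": m.gu_transition.tolist(),
        "initial_distribution": m.initial_distribution.tolist(),
    }


def markov_from_dict(d: dict) -> MarkovParams:
    return MarkovParams(
        gu_transition=np.asarray(d["gu_transition"], dtype=float),
        initial_distribution=np.asarray(d["initial_distribution"], dtype=float),
    )


def hsmc_to_dict(h: HsmcParams) -> dict:
    out = {}
    for cls_name, cls in h.classes.items():
        out[cls_name] = {
            "zones": [
                {
                    "name": z.name,
                    "occupancy": [z.occupancy[0], list(z.occupancy[1])],
                    "fates": {f.value: p for f, p in z.fate_probs.items()},
                    "c_z": z.c_z,
                }
                for z in cls.zones
            ],
            "transition": cls.transition.tolist(),
        }
    return out


def hsmc_from_dict(d: dict) -> HsmcParams:
    classes = {}
    for cls_name, spec in d.items():
        zones = [
            ZoneSpec(
                name=z["name"],
                occupancy=(z["occupancy"][0], tuple(z["occupancy"][1])),
                fate_probs={LateralFate(f): p for f, p in z["fates"].items()},
                c_z=z.get("c_z", 1.0),
            )
            for z in spec["zones"]
        ]
        transition = (
            np.asarray(spec["transition"], dtype=float)
            if "transition" in spec
            else None
        )
        classes[cls_name] = HsmcClassParams(zones, transition)
    return HsmcParams(classes)


def load_params_file(path: str | Path) -> tuple[MarkovParams, HsmcParams]:
    """Load Markov + HSMC parameters from the versioned YAML schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported parameter schema version {raw.get('schema_version')!r}"
        )
    return markov_from_dict(raw["markov"]), hsmc_from_dict(raw["hsmc"])


def dump_params_file(
    path: str | Path, markov: MarkovParams, hsmc: HsmcParams
) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "markov": markov_to_dict(markov),
        "hsmc": hsmc_to_dict(hsmc),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
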