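"""Run configuration: YAML-driven model rosters and scenario settings.

A single YAML file drives the whole pipeline (simulate → fit → compare →
select).  The default model roster covers the eight structures studied for
six traits: the unstructured baseline (SMTM), factor-analytic variants
(FA2F, FA3F, FA2G, FA2R), the fully recursive reparameterization (FRM) and
its pruned versions (REC1, REC2, whose masks come from the select step).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cov_structures import CovStructureSpec
from .gibbs import MCMCSettings, ModelSpec
from .trait_data import TraitSet

__all__ = [
    "RunConfig",
    "load_config",
    "default_roster",
    "mask_to_rows",
    "mask_from_rows",
]


def mask_to_rows(mask: np.ndarray) -> list:
    """Strictly-lower boolean mask → list of 0/1 rows (row i has i entries)."""
    p = mask.shape[0]
    return [[int(mask[i, j]) for j in range(i)] for i in range(p)]


def mask_from_rows(rows: list) -> np.ndarray:
    p = len(rows)
    mask = np.zeros((p, p), dtype=bool)
    for i, row in enumerate(rows):
        if len(row) != i:
            raise ValueError(f"mask row {i} must have {i} entries, got {len(row)}")
        for j, v in enumerate(row):
            mask[i, j] = bool(v)
    return mask


def _structure_from_dict(d: dict, p: int) -> CovStructureSpec:
    kind = d.get("kind", "UNS").upper()
    m = d.get("m")
    mask = None
    if "mask" in d and d["mask"] is not None:
        mask = mask_from_rows(d["mask"])
    return CovStructureSpec(kind=kind, m=m, mask=mask)


def default_roster(p: int = 6) -> dict:
    """Structure pairs for the named models (REC1/REC2 start fully recursive
    until select-derived masks are supplied)."""
    uns = {"kind": "UNS"}
    return {
        "SMTM": {"g": dict(uns), "r": dict(uns)},
        "FA2F": {"g": {"kind": "FA", "m": 2}, "r": {"kind": "FA", "m": 2}},
        "FA3F": {"g": {"kind": "FA", "m": 3}, "r": {"kind": "FA", "m": 3}},
        "FA2G": {"g": {"kind": "FA", "m": 2}, "r": dict(uns)},
        "FA2R": {"g": dict(uns), "r": {"kind": "FA", "m": 2}},
        "FRM": {"g": {"kind": "REC"}, "r": {"kind": "REC"}},
        "REC1": {"g": {"kind": "REC"}, "r": {"kind": "REC"}},
        "REC2": {"g": {"kind": "REC"}, "r": {"kind": "REC"}},
    }


@dataclass
class RunConfig:
    """Parsed configuration for one study run."""

    traits: TraitSet = field(default_factory=TraitSet)
    paths: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)  # name -> raw structure dicts
    mcmc: dict = field(default_factory=dict)
    plan: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.models:
            self.models = default_roster(self.traits.p)
        names = list(self.models)
        if len(set(names)) != len(names):
            raise ValueError("model names must be unique")

    def model_spec(self, name: str, **mcmc_overrides) -> ModelSpec:
        if name not in self.models:
            raise KeyError(
                f"unknown model {name!r}; roster: {', '.join(sorted(self.models))}"
            )
        entry = self.models[name]
        p = self.traits.p
        mcmc_kwargs = dict(self.mcmc)
        mcmc_kwargs.update(entry.get("mcmc", {}))
        mcmc_kwargs.update(mcmc_overrides)
        mcmc_kwargs.setdefault("seed", self.seed)
        extra = {
            k: v
            for k, v in entry.items()
            if k not in {"g", "r", "mcmc"}
        }
        return ModelSpec(
            g_structure=_structure_from_dict(entry.get("g", {}), p),
            r_structure=_structure_from_dict(entry.get("r", {}), p),
            mcmc=MCMCSettings(**mcmc_kwargs),
            **extra,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    labels = raw.get("traits") or list(TraitSet().labels)
    traits = TraitSet(tuple(labels))
    return RunConfig(
        traits=traits,
        paths=raw.get("paths", {}),
        models=raw.get("models", {}),
        mcmc=raw.get("mcmc", {}),
        plan=raw.get("plan", {}),
        scenario=raw.get("scenario", {}),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def masks_to_yaml_fragment(
    name: str, mask_g: np.ndarray | None, mask_r: np.ndarray | None
) -> dict:
    """A models-section fragment fixing the given structural zeros."""
    entry: dict = {"g": {"kind": "REC"}, "r": {"kind": "REC"}}
    if mask_g is not None:
        entry["g"]["mask"] = mask_to_rows(mask_g)
    if mask_r is not None:
        entry["r"]["mask"] = mask_to_rows(mask_r)
    return {name: entry}
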