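"""Run configuration: defaults, YAML round-trip, per-stage seed expansion.

One master seed expands deterministically into per-stage seeds (hashed
through numpy's SeedSequence), so any stage can be rerun in isolation and
reproduce its draw stream exactly.
"""

from __future__ import annotations

import copy
from typing import Any, Dict, Optional

import numpy as np
import yaml

__all__ = ["RunConfig", "STAGES"]

STAGES = (
    "grid",
    "traits",
    "truth",
    "observations",
    "rf",
    "bootstrap",
    "attribution",
)

_DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "output_dir": "flnrmap_run",
    "grid": {
        "shape": [40, 80],
        "smoothness": 3.0,
        "mask_fraction": 0.1,
        # rank-3 within-group latent structure: mirrors real covariate
        # stacks where a group's top PCs carry most of its variance
        "within_group_correlation": {"rank": 3, "jitter": 0.05},
    },
    "constants": {},
    "traits": {"rel_sd": 0.10},
    "truth": {
        "coefficients": None,  # None -> global empirical equation slopes
        "intercept": 30.0,
        "pft_offsets": {},
        "noise_sd": 2.0,
        "floor_pct": 1.0,
    },
    "observations": {
        "n": 600,
        "n_clusters": 25,
        "cluster_radius": 1.5,
        "obs_noise_sd": 3.0,
        "tleaf_range": [10.0, 35.0],
        "isolated_fraction": 0.3,
    },
    "rf": {
        "n_trees": 200,
        "candidates": None,  # None -> all 20 candidate predictors
        "holdout_fraction": 0.2,
        "exclusion_radius_km": 150.0,
        "n_reps": 10,
        "min_rows": 30,
    },
    "bootstrap": {"n_boot": 1000},
    "attribution": {
        "enabled": True,
        "n_pcs": 3,
        "spline_df": 10,
        "alpha": 1.0,
        "thresholds": {"leaf_traits": 0.50, "climate": 0.30, "soil": 0.15},
        "min_pft_cells": 20,
        "per_pft_min_cells": 200,
    },
    "zoo": {"enabled": True, "models": ["EM3", "EM4"]},
}


def _deep_update(base: Dict, overrides: Dict) -> Dict:
    for key, value in overrides.items():
        if (
            key in base
            and isinstance(base[key], dict)
            and isinstance(value, dict)
        ):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


class RunConfig:
    """Validated configuration mapping with YAML round-trip."""

    def __init__(self, overrides: Optional[Dict[str, Any]] = None):
        self.data = copy.deepcopy(_DEFAULTS)
        if overrides:
            unknown = set(overrides) - set(_DEFAULTS)
            if unknown:
                raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
            _deep_update(self.data, copy.deepcopy(overrides))

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31 derived from the master."""
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)
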