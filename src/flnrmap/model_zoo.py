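"""Empirical Vcmax25 models (EM1–EM5), their implied fLNR, and map comparison.

Five published empirical model families are represented:

* EM1/EM2 — PFT-specific linear forms Vcmax25 = n1·LNC + n2 (EM2 differs
  from EM1 only in a reduced slope for evergreen broadleaf forest,
  standing in for phosphorus limitation).
* EM3 — power form Vcmax25 = e^3.712 · LNC^0.65.
* EM4 — Vcmax25 = e^3.946 · LNC^(0.921 + 0.282·ln LPC) · LPC^0.121.
* EM5 — PFT-specific linear climate form on temperature, precipitation,
  radiation and a scalar CO2 term.

EM3/EM4 carry their printed constants and accept no overrides.  EM1, EM2
and EM5 coefficients are published elsewhere and must be supplied via a
coefficient file; the package ships a clearly-labelled synthetic example
(``data/em_coefficients_synthetic.yaml``).  Each model's implied nitrogen
allocation follows by inverting Vcmax25 = α25·LNC·fNR·fLNR on the model's
output.  Optimality models (EO, LUNA) enter only as external maps handed
to :func:`compare_maps`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import yaml
from scipy import stats

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .core import invert_flnr
from .grids import CovariateGrid

__all__ = [
    "EmpiricalModelSpec",
    "MapComparison",
    "load_model_specs",
    "load_example_specs",
    "evaluate_model",
    "implied_flnr",
    "compare_maps",
    "FOREST_CLASSES",
]

FOREST_CLASSES = frozenset({"DBF", "EBF", "ENF", "MF"})

_FORMS = ("linear_lnc", "power_lnc", "power_lnc_lpc", "linear_climate")

EM3_LOG_SCALE = 3.712
EM3_EXPONENT = 0.65
EM4_LOG_SCALE = 3.946
EM4_LNC_BASE_EXP = 0.921
EM4_LNC_LPC_EXP = 0.282
EM4_LPC_EXP = 0.121

_CLIMATE_TERMS = ("tair", "pp", "par", "co2")


@dataclass(frozen=True)
class EmpiricalModelSpec:
    """One empirical Vcmax25 model: its functional form and coefficients."""

    model_id: str
    form: str
    coefficients: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.form in ("power_lnc", "power_lnc_lpc"):
            if self.coefficients is not None:
                raise ValueError(
                    f"{self.model_id}: the power-form constants are fixed and "
                    "accept no overrides"
                )
        elif self.coefficients is None:
            raise ValueError(
                f"{self.model_id}: {self.form} requires per-PFT coefficients "
                "(supply a coefficient file)"
            )

    @classmethod
    def em3(cls) -> "EmpiricalModelSpec":
        return cls("EM3", "power_lnc")

    @classmethod
    def em4(cls) -> "EmpiricalModelSpec":
        return cls("EM4", "power_lnc_lpc")


def load_model_specs(path) -> Dict[str, EmpiricalModelSpec]:
    """Read EM1/EM2/EM5-style coefficient blocks from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs: Dict[str, EmpiricalModelSpec] = {}
    for model_id, block in raw.items():
        if not isinstance(block, Mapping) or "form" not in block:
            raise ValueError(f"model block {model_id!r} lacks a 'form' entry")
        specs[model_id] = EmpiricalModelSpec(
            model_id=model_id,
            form=block["form"],
            coefficients=block.get("coefficients"),
        )
    return specs


def load_example_specs() -> Dict[str, EmpiricalModelSpec]:
    """The shipped synthetic example coefficients for EM1/EM2/EM5."""
    ref = importlib.resources.files("flnrmap.data").joinpath(
        "em_coefficients_synthetic.yaml"
    )
    with importlib.resources.as_file(ref) as path:
        return load_model_specs(path)


def evaluate_model(
    spec: EmpiricalModelSpec, grid: CovariateGrid
) -> np.ndarray:
    """Evaluate the model's Vcmax25 (µmol m⁻² s⁻¹) cell-wise on the grid."""
    lnc = grid.layers.get("lnc")
    if lnc is None:
        raise ValueError("grid lacks the 'lnc' layer")
    out = np.full(grid.shape, np.nan)
    if spec.form == "power_lnc":
        with np.errstate(invalid="ignore"):
            out = np.exp(EM3_LOG_SCALE) * lnc ** EM3_EXPONENT
    elif spec.form == "power_lnc_lpc":
        lpc = grid.layers.get("lpc")
        if lpc is None:
            raise ValueError("EM4 requires the 'lpc' layer")
        bad = grid.mask & ~(lpc > 0)
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} cells with non-positive LPC masked (log undefined)"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            expo = EM4_LNC_BASE_EXP + EM4_LNC_LPC_EXP * np.log(lpc)
            out = np.exp(EM4_LOG_SCALE) * lnc ** expo * lpc ** EM4_LPC_EXP
        out[bad] = np.nan
    elif spec.form == "linear_lnc":
        for pft_name in np.unique(grid.pft[grid.mask]):
            cells = grid.mask & (grid.pft == pft_name)
            coef = spec.coefficients.get(pft_name)
            if coef is None:
                warnings.warn(
                    f"{spec.model_id}: no coefficients for PFT {pft_name!r}; "
                    "cells masked"
                )
                continue
            out[cells] = coef["n1"] * lnc[cells] + coef["n2"]
    elif spec.form == "linear_climate":
        for pft_name in np.unique(grid.pft[grid.mask]):
            cells = grid.mask & (grid.pft == pft_name)
            coef = spec.coefficients.get(pft_name)
            if coef is None:
                warnings.warn(
                    f"{spec.model_id}: no coefficients for PFT {pft_name!r}; "
                    "cells masked"
                )
                continue
            val = np.full(int(cells.sum()), float(coef.get("intercept", 0.0)))
            for term in _CLIMATE_TERMS:
                w = float(coef.get(term, 0.0))
                if term == "co2":
                    # CO2 is not a gridded predictor; a scalar mixing ratio
                    # may be supplied alongside its weight.
                    val += w * float(coef.get("co2_ppm", 0.0))
                else:
                    val += w * grid.layers[term][cells]
            out[cells] = val
    out[~grid.mask] = np.nan
    return out


def implied_flnr(
    vcmax25: np.ndarray,
    lnc: np.ndarray,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """The nitrogen-allocation fraction (%) a Vcmax25 field implies."""
    return invert_flnr(vcmax25, lnc, constants)


@dataclass
class MapComparison:
    """Spatial agreement between two co-registered maps."""

    spatial_r: float
    spatial_p: float
    n_cells: int
    per_pft_stats: Dict[str, Dict[str, float]]
    group_test: Dict[str, float]

    def to_dict(self) -> Dict[str, object]:
        return {
            "spatial_r": self.spatial_r,
            "spatial_p": self.spatial_p,
            "n_cells": self.n_cells,
            "per_pft_stats": self.per_pft_stats,
            "group_test": self.group_test,
        }


def _dist_stats(x: np.ndarray) -> Dict[str, float]:
    q = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "p10": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "p90": float(q[4]),
    }


def compare_maps(
    reference: np.ndarray,
    candidate: np.ndarray,
    pft: np.ndarray,
    forest_classes: Set[str] = FOREST_CLASSES,
    min_cells: int = 30,
) -> MapComparison:
    """Pearson correlation, per-PFT distributions and forest/non-forest test.

    Statistics use only cells where both maps are valid.  The group test is
    a Welch two-sample t-test of the candidate's forest vs non-forest
    means (the reference map plays no role there; pass the same field as
    candidate to test the reference itself).
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise ValueError("maps are not co-registered")
    valid = np.isfinite(ref) & np.isfinite(cand)
    n = int(valid.sum())
    if n < min_cells:
        raise ValueError(
            f"only {n} co-valid cells (<{min_cells}); statistics refused"
        )
    r, p = stats.pearsonr(ref[valid], cand[valid])
    pft = np.asarray(pft)
    per_pft = {}
    for name in np.unique(pft[valid]):
        if name == "":
            continue
        per_pft[str(name)] = _dist_stats(cand[valid & (pft == name)])
    is_forest = np.isin(pft, list(forest_classes))
    forest_vals = cand[valid & is_forest]
    nonforest_vals = cand[valid & ~is_forest]
    if forest_vals.size >= 2 and nonforest_vals.size >= 2:
        t, pt = stats.ttest_ind(forest_vals, nonforest_vals, equal_var=False)
        group_test = {
            "t": float(t),
            "p": float(pt),
            "forest_mean": float(forest_vals.mean()),
            "nonforest_mean": float(nonforest_vals.mean()),
            "n_forest": int(forest_vals.size),
            "n_nonforest": int(nonforest_vals.size),
        }
    else:
        group_test = {"t": float("nan"), "p": float("nan")}
    return MapComparison(
        spatial_r=float(r),
        spatial_p=float(p),
        n_cells=n,
        per_pft_stats=per_pft,
        group_test=group_test,
    )
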