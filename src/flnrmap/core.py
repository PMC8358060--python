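"""Derivation of fLNR from Vcmax25 and leaf nitrogen, with uncertainty.

Inverting the identity Vcmax25 = α25·LNC·fNR·fLNR gives

    fLNR (%) = 100 · Vcmax25 / (α25 · fNR · LNC)

Uncertainty in the resulting map has four sources: the gridded Vcmax25
(per-tree sd of the ensemble), the LNC map (propagated from mass-based
nitrogen and specific leaf area), and the two physiological constants α25
and fNR which are only known to within literature ranges.  All four are
propagated by bootstrap (1000 draws by default): Gaussian draws per cell
for the mapped quantities, uniform draws over the printed ranges for the
constants — one draw per iteration shared across all cells, since each
constant is a single physical quantity, not a field.  A per-source mode
holds three sources fixed and varies one, giving the single-source
decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .grids import TraitGrid, UncertainMap

__all__ = ["FLNRProduct", "compute_lnc", "invert_flnr", "bootstrap_flnr"]

logger = logging.getLogger(__name__)

_SOURCES = ("alpha25", "fnr", "lnc", "vcmax25")


@dataclass
class FLNRProduct:
    """fLNR map (%) with total and single-source bootstrap uncertainty."""

    flnr: UncertainMap
    source_contributions: Dict[str, np.ndarray]
    n_boot: int
    seed: int
    n_redrawn: int = 0


def _positive_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, size
) -> Tuple[np.ndarray, int]:
    """Gaussian draws truncated positive by redrawing; returns draw count."""
    draws = rng.normal(mean, sd, size=size)
    n_redrawn = 0
    for _ in range(100):
        bad = draws <= 0
        nbad = int(bad.sum())
        if nbad == 0:
            break
        n_redrawn += nbad
        draws[bad] = rng.normal(np.broadcast_to(mean, size)[bad],
                                np.broadcast_to(sd, size)[bad])
    else:  # pragma: no cover - means/sds implying mostly negative draws
        raise RuntimeError("positive truncation failed to converge")
    return draws, n_redrawn


def compute_lnc(
    traits: TraitGrid, n_boot: int = 1000, seed: int = 0
) -> UncertainMap:
    """Area-based leaf nitrogen LNC = LNCm/SLA (g m⁻²) with bootstrap sd.

    The mean is the exact ratio of means; the sd comes from paired Gaussian
    draws of (LNCm, SLA) truncated positive, per cell.  With zero input
    sds the output sd is exactly zero.
    """
    mask = traits.mask
    mean = np.where(mask, traits.lncm_mean / traits.sla_mean, np.nan)
    sd = np.zeros_like(mean)
    cells = np.nonzero(mask)
    lncm_m = traits.lncm_mean[cells]
    lncm_s = traits.lncm_sd[cells]
    sla_m = traits.sla_mean[cells]
    sla_s = traits.sla_sd[cells]
    if np.any(lncm_s > 0) or np.any(sla_s > 0):
        rng = np.random.default_rng(seed)
        size = (n_boot, lncm_m.size)
        lncm_d, n1 = _positive_normal(rng, lncm_m, lncm_s, size)
        sla_d, n2 = _positive_normal(rng, sla_m, sla_s, size)
        if n1 + n2:
            logger.info("compute_lnc: %d non-positive trait draws redrawn", n1 + n2)
        sd_cells = (lncm_d / sla_d).std(axis=0, ddof=1)
        sd[cells] = sd_cells
    sd[~mask] = np.nan
    return UncertainMap(
        lat=traits.lat, lon=traits.lon, mean=mean, sd=sd,
        quantity="lnc", units="g m-2",
    )


def invert_flnr(
    vcmax25_mean: np.ndarray,
    lnc_mean: np.ndarray,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Invert the nitrogen–carboxylation identity to fLNR in percent.

    Cells with non-positive LNC are masked (NaN) with a warning.
    """
    v = np.asarray(vcmax25_mean, dtype=float)
    l = np.asarray(lnc_mean, dtype=float)
    bad = np.isfinite(l) & (l <= 0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} cells with non-positive LNC masked")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * v / (constants.alpha25 * constants.fnr * l)
    out = np.asarray(out)
    if out.ndim:
        out[bad] = np.nan
        return out
    return float("nan") if bool(bad) else float(out)


def bootstrap_flnr(
    vcmax25: UncertainMap,
    traits: TraitGrid,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    n_boot: int = 1000,
    seed: int = 0,
    mode: str = "per_source",
) -> FLNRProduct:
    """Bootstrap the fLNR map over its four uncertainty sources.

    Per draw: α25 ~ U(alpha25_range) and fNR ~ U(fnr_range) (one value per
    iteration, shared across cells); Vcmax25 ~ N(mean, sd) per cell
    truncated positive; LNC from paired positive-truncated trait draws.
    ``mode='total'`` varies all four; ``mode='per_source'`` additionally
    produces single-source sd fields with the other three held at their
    defaults/means.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if mode not in ("total", "per_source"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = traits.mask & np.isfinite(vcmax25.mean)
    cells = np.nonzero(mask)
    vc_m = vcmax25.mean[cells]
    vc_s = vcmax25.sd[cells]
    lncm_m = traits.lncm_mean[cells]
    lncm_s = traits.lncm_sd[cells]
    sla_m = traits.sla_mean[cells]
    sla_s = traits.sla_sd[cells]
    lnc_m = lncm_m / sla_m
    c = constants
    n_cells = vc_m.size
    size = (n_boot, n_cells)

    state = {"n_redrawn": 0}

    def draw_sd(vary: set, rng: np.random.Generator) -> np.ndarray:
        if "alpha25" in vary:
            alpha = rng.uniform(*c.alpha25_range, size=(n_boot, 1))
        else:
            alpha = np.full((n_boot, 1), c.alpha25)
        if "fnr" in vary:
            fnr = rng.uniform(*c.fnr_range, size=(n_boot, 1))
        else:
            fnr = np.full((n_boot, 1), c.fnr)
        if "vcmax25" in vary and np.any(vc_s > 0):
            vc, nr = _positive_normal(rng, vc_m, vc_s, size)
            state["n_redrawn"] += nr
        else:
            vc = np.broadcast_to(vc_m, size)
        if "lnc" in vary and (np.any(lncm_s > 0) or np.any(sla_s > 0)):
            lncm_d, n1 = _positive_normal(rng, lncm_m, lncm_s, size)
            sla_d, n2 = _positive_normal(rng, sla_m, sla_s, size)
            state["n_redrawn"] += n1 + n2
            lnc = lncm_d / sla_d
        else:
            lnc = np.broadcast_to(lnc_m, size)
        flnr_draws = 100.0 * vc / (alpha * fnr * lnc)
        return flnr_draws.std(axis=0, ddof=1)

    rng = np.random.default_rng(seed)
    total_sd_cells = draw_sd(set(_SOURCES), rng)
    flnr_mean = np.full(vcmax25.mean.shape, np.nan)
    flnr_mean[cells] = 100.0 * vc_m / (c.alpha25 * c.fnr * lnc_m)
    total_sd = np.full(vcmax25.mean.shape, np.nan)
    total_sd[cells] = total_sd_cells

    contributions: Dict[str, np.ndarray] = {}
    if mode == "per_source":
        for src in _SOURCES:
            rng_s = np.random.default_rng(seed + 1 + _SOURCES.index(src))
            fld = np.full(vcmax25.mean.shape, np.nan)
            fld[cells] = draw_sd({src}, rng_s)
            contributions[src] = fld

    flnr_map = UncertainMap(
        lat=vcmax25.lat, lon=vcmax25.lon, mean=flnr_mean, sd=total_sd,
        quantity="flnr", units="%",
    )
    return FLNRProduct(
        flnr=flnr_map,
        source_contributions=contributions,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=state["n_redrawn"],
    )
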