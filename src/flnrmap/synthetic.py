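"""Synthetic globe generator.

Downstream stages (temperature standardization, random-forest upscaling,
fLNR inversion, attribution) are exercised on a fully synthetic world: a
masked half-degree covariate stack, trait maps with uncertainty, a
ground-truth fLNR/Vcmax25 field, and spatially clustered site observations
of Vcmax at leaf temperature.

Continuous covariates are smoothed Gaussian random fields affinely rescaled
into documented realistic ranges; they make no attempt to mimic true Earth
geography or the actual spatial covariance of climate/soil products.  The
ground-truth fLNR field is linear in LMA, LPC, VPD, soil pH, PAR and sand
plus plant-functional-type offsets and Gaussian noise — the generating
analogue of the global empirical fLNR equation — and Vcmax25 follows from
fLNR and LNC through the nitrogen–carboxylation identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .grids import PFT_CLASSES, CovariateGrid, TraitGrid
from .thermal import project_from_25

__all__ = [
    "LAYER_RANGES",
    "GLOBAL_FLNR_COEFFICIENTS",
    "GLOBAL_FLNR_INTERCEPT",
    "TruthBundle",
    "make_covariate_grid",
    "make_traits",
    "make_truth",
    "flnr_linear_surface",
    "make_uniform_covariate_table",
    "sample_observations",
    "write_observations",
    "read_observations",
]

#: Documented realistic ranges used to rescale each continuous layer.
LAYER_RANGES: Dict[str, Tuple[float, float]] = {
    "chl": (5.0, 80.0),       # µg cm-2
    "lnc": (0.5, 3.0),        # g m-2
    "lpc": (0.05, 0.25),      # g m-2
    "lma": (20.0, 250.0),     # g m-2
    "tair": (-5.0, 30.0),     # °C
    "pp": (100.0, 3000.0),    # mm yr-1
    "par": (200.0, 1200.0),   # µmol m-2 s-1
    "vpd": (0.2, 3.0),        # kPa
    "swc": (0.05, 0.45),      # m3 m-3
    "alpha_et": (0.05, 1.0),  # unitless
    "soilC": (1e3, 2e4),      # g m-3
    "soilN": (50.0, 1500.0),  # g m-3
    "cn": (5.0, 40.0),        # unitless
    "ph": (4.0, 8.5),         # unitless
    "sand": (10.0, 90.0),     # %
    "silt": (5.0, 70.0),      # %
    "bulkD": (0.8, 1.8),      # g cm-3
    "cec": (2.0, 40.0),       # cmol kg-1
}

#: Slopes of the global empirical fLNR equation (% fLNR per variable unit)
#: and its intercept (%); the generator's default truth coefficients.
GLOBAL_FLNR_COEFFICIENTS: Dict[str, float] = {
    "lma": -0.19,
    "lpc": 42.2,
    "vpd": 4.76,
    "ph": 0.25,
    "par": 0.0026,
    "sand": 0.032,
}
GLOBAL_FLNR_INTERCEPT = 2.4

_N_KOEPPEN = 5


@dataclass
class TruthBundle:
    """Ground-truth fLNR (%) and Vcmax25 (µmol m⁻² s⁻¹) fields.

    With ``noise_sd = 0`` the Vcmax25 field reproduces
    alpha25·fNR·LNC·fLNR/100 exactly, so inversion recovers fLNR to
    machine precision.
    """

    flnr_true: np.ndarray
    vcmax25_true: np.ndarray
    generating_coefficients: Dict[str, float]
    intercept: float
    pft_offsets: Dict[str, float]
    noise_sd: float
    seed: int
    n_floored: int = 0


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    field = rng.standard_normal(shape)
    if smoothness > 0:
        field = gaussian_filter(field, sigma=smoothness, mode="reflect")
    return field


def _rescale(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field.min(), field.max()
    if fmax == fmin:
        return np.full_like(field, 0.5 * (lo + hi))
    return lo + (hi - lo) * (field - fmin) / (fmax - fmin)


def _banded_categories(
    rng: np.random.Generator, shape, classes: Sequence, flip_fraction: float
):
    """Contiguous latitudinal bands with categorical noise.

    Guarantees every class is present (bands cover all rows; flips are a
    small perturbation), which per-PFT fits downstream require.
    """
    ny, nx = shape
    edges = np.linspace(0, ny, len(classes) + 1).astype(int)
    out = np.empty(shape, dtype=object)
    for k, cls in enumerate(classes):
        out[edges[k] : edges[k + 1], :] = cls
    flip = rng.random(shape) < flip_fraction
    out[flip] = rng.choice(np.asarray(classes, dtype=object), size=int(flip.sum()))
    return out


def make_covariate_grid(
    shape: Tuple[int, int] = (20, 40),
    seed: int = 0,
    smoothness: float = 3.0,
    ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    mask_fraction: float = 0.1,
    pft_flip_fraction: float = 0.1,
    within_group_correlation: Optional[Mapping[str, float]] = None,
) -> CovariateGrid:
    """Generate a masked covariate stack of the 20 candidate predictors.

    Parameters
    ----------
    shape : (nlat, nlon)
        Grid dimensions, at least 10×10.
    seed : int
        Seed; identical calls are bitwise reproducible.
    smoothness : float
        Gaussian-kernel correlation length in cells; 0 gives white noise.
    ranges : mapping, optional
        Per-layer (low, high) overrides of :data:`LAYER_RANGES`.
    mask_fraction : float
        Approximate fraction of cells masked out (non-vegetated blobs).
    within_group_correlation : mapping, optional
        Optional cross-correlation knob: ``{"rank": r, "jitter": j}``
        builds each attribution group's continuous layers from ``r`` shared
        latent fields plus ``j`` (relative sd) of independent jitter, so a
        group's top principal components carry almost all of its variance.
        Default None: all layers independent.
    """
    ny, nx = shape
    if ny < 10 or nx < 10:
        raise ValueError(f"grid shape must be at least 10x10, got {shape}")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    eff_ranges = dict(LAYER_RANGES)
    if ranges:
        eff_ranges.update(ranges)

    # Half-degree cell centers, latitude south -> north, window centered
    # on the equator/prime meridian.
    lat = (np.arange(ny) - ny / 2) * 0.5 + 0.25
    lon = (np.arange(nx) - nx / 2) * 0.5 + 0.25

    continuous = [name for name in LAYER_RANGES]
    raw: Dict[str, np.ndarray] = {}
    if within_group_correlation is None:
        for name in continuous:
            raw[name] = _smooth_field(rng, shape, smoothness)
    else:
        from .attribution import DEFAULT_GROUPS  # avoids a hard import cycle

        rank = int(within_group_correlation.get("rank", 3))
        jitter = float(within_group_correlation.get("jitter", 0.05))
        grouped = {v for vs in DEFAULT_GROUPS.values() for v in vs}
        for gname, gvars in DEFAULT_GROUPS.items():
            latents = [_smooth_field(rng, shape, smoothness) for _ in range(rank)]
            for name in gvars:
                w = rng.standard_normal(rank)
                fld = sum(wi * li for wi, li in zip(w, latents))
                fld = fld / max(np.std(fld), 1e-12)
                fld = fld + jitter * _smooth_field(rng, shape, smoothness)
                raw[name] = fld
        for name in continuous:
            if name not in grouped:
                raw[name] = _smooth_field(rng, shape, smoothness)

    layers = {
        name: _rescale(raw[name], *eff_ranges[name]) for name in continuous
    }

    # Köppen-like climate classes as integer codes, banded like PFTs.
    koeppen = _banded_categories(
        rng, shape, list(range(_N_KOEPPEN)), pft_flip_fraction
    )
    layers["koeppen"] = koeppen.astype(float)

    mask_field = _smooth_field(rng, shape, max(smoothness, 1.0))
    if mask_fraction > 0:
        mask = mask_field > np.quantile(mask_field, mask_fraction)
    else:
        mask = np.ones(shape, dtype=bool)

    pft = _banded_categories(rng, shape, list(PFT_CLASSES), pft_flip_fraction)
    pft = pft.astype("<U3")
    pft[~mask] = ""
    for arr in layers.values():
        arr[~mask] = np.nan

    return CovariateGrid(lat=lat, lon=lon, mask=mask, pft=pft, layers=layers)


def make_traits(
    grid: CovariateGrid,
    seed: int = 0,
    rel_sd: float = 0.10,
    smoothness: float = 3.0,
    sla_range: Tuple[float, float] = (5.0, 25.0),
) -> TraitGrid:
    """Trait maps consistent with the grid's area-based leaf nitrogen.

    SLA (m² kg⁻¹) is an independent smooth field; mass-based leaf nitrogen
    is defined as LNCm = LNC·SLA (mg g⁻¹), so LNCm/SLA reproduces the
    grid's ``lnc`` layer identically.  Per-cell sds are ``rel_sd`` times the
    means, the generator's stand-in for the mapped-product uncertainty
    layers.
    """
    rng = np.random.default_rng(seed)
    sla = _rescale(_smooth_field(rng, grid.shape, smoothness), *sla_range)
    lnc = grid.layers["lnc"]
    lncm = lnc * sla  # (g m-2)·(m2 kg-1) = g kg-1 = mg g-1
    sla = sla.copy()
    sla[~grid.mask] = np.nan
    lncm = np.where(grid.mask, lncm, np.nan)
    # positive floors keep the TraitGrid invariants on vegetated cells
    lncm_safe = np.where(grid.mask, lncm, 1.0)
    sla_safe = np.where(grid.mask, sla, 1.0)
    return TraitGrid(
        lat=grid.lat,
        lon=grid.lon,
        mask=grid.mask,
        lncm_mean=np.where(grid.mask, lncm, np.nan),
        lncm_sd=np.where(grid.mask, rel_sd * lncm_safe, np.nan),
        sla_mean=np.where(grid.mask, sla, np.nan),
        sla_sd=np.where(grid.mask, rel_sd * sla_safe, np.nan),
    )


def flnr_linear_surface(
    table: pd.DataFrame,
    coefficients: Mapping[str, float] = GLOBAL_FLNR_COEFFICIENTS,
    intercept: float = GLOBAL_FLNR_INTERCEPT,
) -> np.ndarray:
    """Evaluate the linear fLNR surface (%) on a covariate table, un-floored.

    This is the raw regression surface used for coefficient-recovery
    experiments; gridded truth generation adds offsets, noise and a
    positivity floor on top of it (see :func:`make_truth`).
    """
    missing = [v for v in coefficients if v not in table.columns]
    if missing:
        raise ValueError(f"coefficient variables missing from table: {missing}")
    out = np.full(len(table), float(intercept))
    for name, coef in coefficients.items():
        out = out + coef * table[name].to_numpy(dtype=float)
    return out


def make_uniform_covariate_table(
    n: int,
    seed: int,
    variables: Sequence[str] = ("lma", "lpc", "vpd", "ph", "par", "sand"),
    ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Independent uniform covariate draws over the documented ranges."""
    eff = dict(LAYER_RANGES)
    if ranges:
        eff.update(ranges)
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {v: rng.uniform(*eff[v], size=n) for v in variables}
    )


def make_truth(
    grid: CovariateGrid,
    traits: TraitGrid,
    coefficients: Optional[Mapping[str, float]] = None,
    intercept: float = GLOBAL_FLNR_INTERCEPT,
    pft_offsets: Optional[Mapping[str, float]] = None,
    noise_sd: float = 2.0,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    seed: int = 0,
    floor_pct: float = 1.0,
) -> TruthBundle:
    """Generate the ground-truth fLNR (%) and Vcmax25 fields.

    fLNR = intercept + Σ coefficient·layer + pft_offset + N(0, noise_sd),
    floored at ``floor_pct`` (with a warning and a count in the bundle) if
    any cell comes out non-positive; Vcmax25 then follows the forward
    nitrogen–carboxylation identity with LNC = LNCm/SLA.
    """
    if coefficients is None:
        coefficients = GLOBAL_FLNR_COEFFICIENTS
    missing = [v for v in coefficients if v not in grid.layers]
    if missing:
        raise ValueError(f"coefficient variables not in grid layers: {missing}")
    rng = np.random.default_rng(seed)
    flnr = np.full(grid.shape, float(intercept))
    for name, coef in coefficients.items():
        flnr = flnr + coef * grid.layers[name]
    offsets = dict(pft_offsets or {})
    for cls, off in offsets.items():
        flnr[grid.pft == cls] += off
    if noise_sd > 0:
        flnr = flnr + rng.normal(0.0, noise_sd, size=grid.shape)
    flnr[~grid.mask] = np.nan

    low = grid.mask & (flnr < floor_pct)
    n_floored = int(low.sum())
    if n_floored:
        warnings.warn(
            f"{n_floored} vegetated cells below {floor_pct}% fLNR floored"
        )
        flnr[low] = floor_pct

    lnc = traits.lnc_mean()
    vcmax25 = constants.alpha25 * constants.fnr * lnc * (flnr / 100.0)
    vcmax25[~grid.mask] = np.nan
    return TruthBundle(
        flnr_true=flnr,
        vcmax25_true=vcmax25,
        generating_coefficients=dict(coefficients),
        intercept=float(intercept),
        pft_offsets=offsets,
        noise_sd=float(noise_sd),
        seed=int(seed),
        n_floored=n_floored,
    )


_SPECIES_GROUP = {
    "DBF": "deciduous tree",
    "EBF": "evergreen tree",
    "ENF": "evergreen tree",
    "MF": "evergreen tree",
    "CRO": "herbaceous",
    "GRA": "herbaceous",
    "SH": "herbaceous",
    "WET": "herbaceous",
}


def sample_observations(
    truth: TruthBundle,
    grid: CovariateGrid,
    n: int = 600,
    n_clusters: int = 25,
    cluster_radius: float = 1.5,
    obs_noise_sd: float = 3.0,
    tleaf_range: Tuple[float, float] = (10.0, 35.0),
    isolated_fraction: float = 0.3,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatially clustered site observations of Vcmax at leaf temperature.

    Most sites scatter around ``n_clusters`` cluster centres (uniform
    within ``cluster_radius`` degrees), mimicking the geographic clumping
    of trait campaigns that spatial cross-validation must contend with;
    ``isolated_fraction`` of sites are placed uniformly over vegetated
    cells, the analogue of sparse single-site records, which is what a
    spatial exclusion radius leaves behind for validation.  Each site
    records Vcmax at a leaf temperature drawn from ``tleaf_range`` —
    obtained by projecting the cell's true Vcmax25 through the peaked
    Arrhenius response plus Gaussian observation noise — together with the
    cell's covariates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_clusters > n:
        raise ValueError("n_clusters may not exceed n")
    if not (0 <= isolated_fraction <= 1):
        raise ValueError("isolated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(grid.mask)
    centre_idx = rng.choice(len(ii), size=n_clusters, replace=len(ii) < n_clusters)
    centres = np.column_stack([grid.lat[ii[centre_idx]], grid.lon[jj[centre_idx]]])

    lat_min, lat_max = grid.lat.min(), grid.lat.max()
    lon_min, lon_max = grid.lon.min(), grid.lon.max()
    rows = []
    n_isolated = int(round(isolated_fraction * n))
    assignments = rng.integers(0, n_clusters, size=n)
    for k in range(n):
        if k < n_isolated:
            c = rng.integers(0, len(ii))
            i, j = int(ii[c]), int(jj[c])
            slat = grid.lat[i] + rng.uniform(-0.25, 0.25)
            slon = grid.lon[j] + rng.uniform(-0.25, 0.25)
            rows.append((k, i, j, slat, slon))
            continue
        clat, clon = centres[assignments[k]]
        for _attempt in range(1000):
            r = cluster_radius * math.sqrt(rng.random())
            theta = rng.random() * 2 * math.pi
            slat = min(max(clat + r * math.sin(theta), lat_min), lat_max)
            slon = min(max(clon + r * math.cos(theta), lon_min), lon_max)
            i = int(np.argmin(np.abs(grid.lat - slat)))
            j = int(np.argmin(np.abs(grid.lon - slon)))
            if grid.mask[i, j]:
                break
        else:  # pragma: no cover - pathological mask
            raise RuntimeError("could not place site on a vegetated cell")
        rows.append((k, i, j, slat, slon))

    tleaf = rng.uniform(*tleaf_range, size=n)
    data: Dict[str, list] = {
        "lat": [],
        "lon": [],
        "tleaf": [],
        "vcmax_obs": [],
        "species_group": [],
        "pft": [],
    }
    layer_names = list(grid.layers)
    for name in layer_names:
        data[name] = []
    for k, i, j, slat, slon in rows:
        v25 = truth.vcmax25_true[i, j]
        v = project_from_25(float(v25), float(tleaf[k]), constants)
        if obs_noise_sd > 0:
            for _ in range(1000):
                vn = v + rng.normal(0.0, obs_noise_sd)
                if vn > 0:
                    break
            v = vn
        data["lat"].append(slat)
        data["lon"].append(slon)
        data["tleaf"].append(float(tleaf[k]))
        data["vcmax_obs"].append(float(v))
        data["species_group"].append(_SPECIES_GROUP[grid.pft[i, j]])
        data["pft"].append(grid.pft[i, j])
        for name in layer_names:
            data[name].append(float(grid.layers[name][i, j]))
    return pd.DataFrame(data)


OBSERVATION_COLUMNS = ["lat", "lon", "tleaf", "vcmax_obs", "species_group", "pft"]


def write_observations(df: pd.DataFrame, path) -> None:
    """Write a site-observation table as CSV (lossless double precision)."""
    df.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation CSV missing required columns: {missing}")
    return df
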