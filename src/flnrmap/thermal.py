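"""Peaked Arrhenius temperature standardization of Vcmax.

Field measurements of the maximum carboxylation rate are taken at leaf
temperature; models and maps work at the 25 °C standard.  The conversion is

    Vcmax(Tl) = Vcmax25 * f(Tl)

    f(Tl) = exp[Ha (Tl − Tref) / (Tref R Tl)]
            * [1 + exp((Tref ΔS − Hd) / (Tref R))]
            / [1 + exp((Tl ΔS − Hd) / (Tl R))]

with Tl in Kelvin.  The function is "peaked": the Arrhenius activation term
rises with temperature while the deactivation term eventually wins, so f has
a single interior optimum (near 33 °C with the default constants).
Temperature acclimation of the parameters is deliberately not modelled.

Interfaces take temperatures in °C and convert internally.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysioConstants

__all__ = ["arrhenius_factor", "standardize_to_25", "project_from_25"]

_KELVIN = 273.15


def arrhenius_factor(
    tleaf_c,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    apply_floor: bool = False,
):
    """Temperature-correction factor f(Tl) of the peaked Arrhenius function.

    Parameters
    ----------
    tleaf_c : float or array-like
        Leaf temperature in °C. Must be finite and above absolute zero.
    constants : PhysioConstants
        Arrhenius parameters (Ha, Hd, ΔS, R, Tref).
    apply_floor : bool
        If True, clip the factor from below at ``constants.floor`` (0.08 by
        default). Opt-in: the floor belongs to the optimality-model context.

    Returns
    -------
    float or ndarray
        Dimensionless factor; exactly 1 at 25 °C.
    """
    t = np.asarray(tleaf_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("leaf temperature must be finite")
    tl = t + _KELVIN
    if np.any(tl <= 0):
        raise ValueError("leaf temperature below absolute zero")
    c = constants
    num = 1.0 + np.exp((c.t_ref * c.delta_s - c.hd) / (c.t_ref * c.r_gas))
    den = 1.0 + np.exp((tl * c.delta_s - c.hd) / (tl * c.r_gas))
    f = np.exp(c.ha * (tl - c.t_ref) / (c.t_ref * c.r_gas * tl)) * num / den
    if apply_floor:
        f = np.maximum(f, c.floor)
    if np.ndim(tleaf_c) == 0:
        return float(f)
    return f


def standardize_to_25(
    vcmax_at_tleaf,
    tleaf_c,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    apply_floor: bool = False,
):
    """Convert Vcmax measured at leaf temperature to its 25 °C equivalent."""
    v = np.asarray(vcmax_at_tleaf, dtype=float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("vcmax must be non-negative")
    f = arrhenius_factor(tleaf_c, constants, apply_floor=apply_floor)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):  # impossible for finite Kelvin inputs, guarded anyway
        raise FloatingPointError("non-positive temperature-correction factor")
    out = v / f
    if np.ndim(vcmax_at_tleaf) == 0 and np.ndim(tleaf_c) == 0:
        return float(out)
    return out


def project_from_25(
    vcmax25,
    tleaf_c,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    apply_floor: bool = False,
):
    """Project 25 °C-standardized Vcmax to a leaf temperature (inverse of
    :func:`standardize_to_25`)."""
    v = np.asarray(vcmax25, dtype=float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("vcmax25 must be non-negative")
    f = arrhenius_factor(tleaf_c, constants, apply_floor=apply_floor)
    out = v * np.asarray(f, dtype=float)
    if np.ndim(vcmax25) == 0 and np.ndim(tleaf_c) == 0:
        return float(out)
    return out
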