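"""Physiological constants linking leaf nitrogen to carboxylation capacity.

The central identity is

    Vcmax25 = alpha25 * LNC * fNR * fLNR

where ``alpha25`` is the specific activity of RuBisCO (µmol CO2 per gram of
RuBisCO per second at 25 °C), ``LNC`` the area-based leaf nitrogen content
(g N m⁻²), ``fNR`` the mass of RuBisCO per gram of nitrogen it contains
(g RuBisCO / g N) and ``fLNR`` the fraction of leaf nitrogen allocated to
RuBisCO (dimensionless here; reported in percent throughout the package).

The temperature response of Vcmax uses a peaked Arrhenius form whose
activation/deactivation energies and entropy term are fixed literature
values, not free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

__all__ = ["PhysioConstants", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class PhysioConstants:
    """Constants of the nitrogen–Vcmax identity and the peaked Arrhenius response.

    Parameters
    ----------
    alpha25 : float
        Specific activity of RuBisCO at 25 °C, µmol CO2 g⁻¹ RuBisCO s⁻¹.
        Literature range [47.34, 60.0]; the default is the lower bound,
        the value used to derive point estimates of fLNR.
    fnr : float
        Mass ratio of the RuBisCO molecule to the nitrogen it contains,
        g RuBisCO g⁻¹ N. Literature range [6.11, 7.16]; default 6.25.
    ha, hd : float
        Activation / deactivation energies for carboxylation, J mol⁻¹.
    delta_s : float
        Entropy term of the peaked Arrhenius function, J mol⁻¹ K⁻¹.
    r_gas : float
        Universal gas constant, J mol⁻¹ K⁻¹.
    t_ref : float
        Reference temperature, K (25 °C).
    floor : float
        Minimum admissible temperature-correction factor. Only applied when
        explicitly requested (the floor is used in the ecological-optimality
        model context to suppress extreme cold-temperature corrections).
    """

    alpha25: float = 47.34
    fnr: float = 6.25
    ha: float = 71513.0
    hd: float = 200000.0
    delta_s: float = 649.12
    r_gas: float = 8.314
    t_ref: float = 298.15
    floor: float = 0.08
    alpha25_range: Tuple[float, float] = (47.34, 60.0)
    fnr_range: Tuple[float, float] = (6.11, 7.16)

    def __post_init__(self) -> None:
        if not (self.hd > self.ha > 0):
            raise ValueError("require hd > ha > 0")
        if self.t_ref <= 0:
            raise ValueError("t_ref must be positive (Kelvin)")
        lo, hi = self.alpha25_range
        if not (lo <= self.alpha25 <= hi):
            raise ValueError(
                f"alpha25={self.alpha25} outside admissible range [{lo}, {hi}]"
            )
        lo, hi = self.fnr_range
        if not (lo <= self.fnr <= hi):
            raise ValueError(f"fnr={self.fnr} outside admissible range [{lo}, {hi}]")

    def with_overrides(self, **kwargs) -> "PhysioConstants":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysioConstants()
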