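"""Concentration-dependent maximal substrate uptake rates.

Uptake of glucose and xylose follows Michaelis-Menten saturation with a
non-competitive ethanol-inhibition factor ``1/(1 + E/K_ie)``; oxygen uptake
is plain Michaelis-Menten in the dissolved-oxygen concentration. These rates
cap the corresponding exchange fluxes of the inner LP (the bound is set to
minus the rate, uptake being negative by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["KineticParams", "UptakeBounds", "uptake_bounds"]


@dataclass(frozen=True)
class KineticParams:
    """Uptake kinetics for one organism.

    Units: ``v_*_max`` mmol/gDW/h; ``K_g``, ``K_z``, ``K_ie`` g/L; ``K_o`` mM.
    A zero ``v_max`` disables the corresponding substrate entirely (the
    half-saturation constant is then ignored).
    """

    v_g_max: float = 0.0
    K_g: float = 0.0
    v_z_max: float = 0.0
    K_z: float = 0.0
    v_o_max: float = 0.0
    K_o: float = 0.0
    K_ie: float = float("inf")

    def __post_init__(self):
        for vmax, k, label in ((self.v_g_max, self.K_g, "glucose"),
                               (self.v_z_max, self.K_z, "xylose"),
                               (self.v_o_max, self.K_o, "oxygen")):
            if vmax < 0:
                raise ValueError(f"negative v_max for {label}")
            if vmax > 0 and k <= 0:
                raise ValueError(f"K for {label} must be > 0 when v_max > 0")
        if self.K_ie <= 0:
            raise ValueError("K_ie must be > 0")


class UptakeBounds(NamedTuple):
    v_g: float  #: maximal glucose uptake, mmol/gDW/h
    v_z: float  #: maximal xylose uptake, mmol/gDW/h
    v_o: float  #: maximal oxygen uptake, mmol/gDW/h


def _mm(vmax: float, s: float, k: float) -> float:
    if vmax == 0.0 or s == 0.0:
        return 0.0
    return vmax * s / (k + s)


def uptake_bounds(G: float, Z: float, E: float, O: float,
                  params: KineticParams) -> UptakeBounds:
    """Maximal uptake rates at concentrations G, Z, E (g/L) and O (mM).

    Raises ``ValueError`` on negative concentrations; callers clamp small
    negatives from the integrator to zero before invoking this.
    """
    if min(G, Z, E, O) < 0:
        raise ValueError(
            f"negative concentration: G={G}, Z={Z}, E={E}, O={O}")
    inhibition = 1.0 / (1.0 + E / params.K_ie)
    return UptakeBounds(
        v_g=_mm(params.v_g_max, G, params.K_g) * inhibition,
        v_z=_mm(params.v_z_max, Z, params.K_z) * inhibition,
        v_o=_mm(params.v_o_max, O, params.K_o),
    )
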