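"""Default kinetic parameters and operating conditions for the batch coculture.

These are the standard operating conditions for the substrate-selective
glucose/xylose coculture: a glucose-selective yeast (glucose uptake
saturating at 22.4 mmol/gDW/h) and a xylose-selective bacterium (xylose
uptake saturating at 12 mmol/gDW/h), 75 g/L total sugar split 50/50, 60/40
or 70/30 glucose/xylose by weight, dissolved oxygen regulated at 0.29 mM
during the aerobic phase, and mixture-dependent batch horizons chosen so
that ~99% of both sugars are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import KineticParams

__all__ = [
    "YEAST_KINETICS", "BACTERIUM_KINETICS", "MOLAR_MASS", "O_AEROBIC_MM",
    "INOCULUM_YEAST", "INOCULUM_BACTERIUM", "Mixture", "MIXTURES",
]

#: Substrate uptake kinetics, glucose-selective yeast.
YEAST_KINETICS = KineticParams(
    v_g_max=22.4, K_g=0.8,       # glucose, mmol/gDW/h and g/L
    v_o_max=2.5, K_o=0.003,      # oxygen, mmol/gDW/h and mM
    K_ie=10.0,                   # ethanol inhibition, g/L
)

#: Substrate uptake kinetics, xylose-selective bacterium.
BACTERIUM_KINETICS = KineticParams(
    v_z_max=12.0, K_z=0.25,
    v_o_max=20.0, K_o=0.024,
    K_ie=20.0,
)

#: Dissolved oxygen setpoint during the aerobic phase (mM; ~98% saturation).
O_AEROBIC_MM = 0.29

#: Initial cellmass concentrations (gDW/L).
INOCULUM_YEAST = 0.044
INOCULUM_BACTERIUM = 0.006

#: Molar masses (g/mol) bridging LP exchange fluxes (mmol/gDW/h) to the
#: mass-based extracellular balances (g/L/h). The toy biomass unit is one
#: carbon-equivalent at 25 g/mol.
MOLAR_MASS = {
    "glucose": 180.16,
    "xylose": 150.13,
    "ethanol": 46.07,
    "glycerol": 92.09,
    "acetate": 60.05,
    "formate": 46.03,
    "lactate": 90.08,
    "succinate": 118.09,
    "co2": 44.01,
    "biomass": 25.0,
}


@dataclass(frozen=True)
class Mixture:
    """One glucose/xylose feed composition with its batch horizon."""

    name: str
    glucose_0: float  # g/L
    xylose_0: float   # g/L
    t_f: float        # h

    @property
    def total_sugar(self) -> float:
        return self.glucose_0 + self.xylose_0


#: The three studied feed compositions (constant 75 g/L total sugar); the
#: batch horizon grows with glucose share so both sugars reach ~99%
#: consumption.
MIXTURES = (
    Mixture("50/50", 37.5, 37.5, 14.0),
    Mixture("60/40", 45.0, 30.0, 16.0),
    Mixture("70/30", 52.5, 22.5, 17.0),
)
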