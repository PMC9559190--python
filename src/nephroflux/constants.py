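"""Physical constants and the internal unit system.

Internal units used throughout the package:

=============  ======================================
quantity       unit
=============  ======================================
length         cm
concentration  mM  (= mmol/L = umol/cm^3)
pressure       mmHg
potential      mV
volume flow    cm^3/s  (per tubule)
volume flux    cm/s    (cm^3 s^-1 per cm^2 membrane)
solute flux    umol s^-1 cm^-2  (= mM * cm/s)
time           s
viscosity      g cm^-1 s^-1  (poise)
=============  ======================================

With these conventions the osmotic pressure of a 1 mM ideal solution at
body temperature is RT_OSM mmHg, and the dimensionless electrodiffusion
exponent is ``zeta = z * F_RT * dV`` with ``dV`` in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

#: dyn/cm^2 per mmHg, used to convert Poiseuille gradients to mmHg/cm.
DYN_PER_MMHG = 1333.22


@dataclass(frozen=True)
class PhysicalConstants:
    """Ideal gas constant, body temperature and Faraday constant.

    ``R`` is in J mol^-1 K^-1, ``T`` in K, ``F`` in C mol^-1.  Derived
    attributes expose the combinations the flux laws actually need in the
    package's internal units.
    """

    R: float = 8.314462618
    T: float = 310.15
    F: float = 96485.33212

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.F <= 0:
            raise ValueError("physical constants must be strictly positive")

    @property
    def RT_osm(self) -> float:
        """Osmotic pressure of 1 mM at temperature T, in mmHg.

        pi = R*T*C;  1 mM = 1 mol/m^3, R*T in Pa m^3/mol, 1 mmHg = 133.322 Pa.
        """
        return self.R * self.T / 133.322

    @property
    def F_RT(self) -> float:
        """F/(R*T) in 1/mV (zeta = z * F_RT * dV with dV in mV)."""
        return self.F / (self.R * self.T) / 1000.0


#: Default constant set at rodent body temperature (37 C).
CONSTANTS = PhysicalConstants()
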