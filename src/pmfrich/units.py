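"""Physical constants and thermodynamic context.

Internal unit system (GROMACS-style reduced MD units):

* length      nm
* energy      kJ/mol
* time        ps
* mass        g/mol (amu)
* temperature K

With these units momenta come out in amu nm/ps and kB = 0.00831446 kJ/mol/K.
Angles are kept in radians internally and degrees at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kJ/(mol K) (CODATA, as used by GROMACS).
KB = 0.008314462618

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 300.0

#: Å → nm conversion factor applied at every file boundary.
ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and derived inverse temperature β = 1/(kB T).

    Parameters
    ----------
    temperature:
        Absolute temperature in K; must be positive.
    """

    temperature: float = DEFAULT_TEMPERATURE
    kB: float = KB
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "beta", 1.0 / (self.kB * self.temperature))

    @property
    def kT(self) -> float:
        """Thermal energy kB·T in kJ/mol."""
        return self.kB * self.temperature
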