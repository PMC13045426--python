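"""Electrolyte groundwork: Bjerrum length, Debye length, nominal ionic strength.

The dispersions modelled here are aqueous fibril solutions whose pH is set
with a strong acid (HCl, below 7) or strong base (NaOH, above 7) and carry
no added salt, so the nominal ionic strength is fixed entirely by pH. The
internal ionic strength inside a dialysed fibril phase can exceed the
nominal one through Donnan retention of counterions; ``SolutionConditions``
keeps both and derives screening quantities from whichever is in force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    DEFAULT_EPS_R,
    DEFAULT_TEMPERATURE_K,
    ELEMENTARY_CHARGE,
    NM_PER_M,
    VACUUM_PERMITTIVITY,
    WATER_ION_PRODUCT,
)

__all__ = [
    "bjerrum_length",
    "debye_length",
    "nominal_ionic_strength",
    "SolutionConditions",
]


def bjerrum_length(T: float = DEFAULT_TEMPERATURE_K, eps_r: float = DEFAULT_EPS_R) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T) in nm.

    Distance at which two elementary charges interact with thermal energy
    kT; about 0.7 nm in water at 23 degC.
    """
    if T <= 0 or eps_r <= 0:
        raise ValueError(f"T and eps_r must be positive, got T={T}, eps_r={eps_r}")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * T
    )
    return lb_m * NM_PER_M


def debye_length(
    I: float, T: float = DEFAULT_TEMPERATURE_K, eps_r: float = DEFAULT_EPS_R
) -> float:
    """Debye screening length kappa^-1 in nm for a 1:1 electrolyte.

    Parameters
    ----------
    I : ionic strength in mol/L.
    """
    if I <= 0:
        raise ValueError(f"ionic strength must be positive, got {I}")
    n = 2.0 * AVOGADRO * I * 1e3  # number density of charges, 1/m^3
    kappa_m = math.sqrt(
        ELEMENTARY_CHARGE**2 * n / (VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * T)
    )
    return NM_PER_M / kappa_m


def nominal_ionic_strength(pH: float) -> float:
    """Ionic strength (mol/L) of pure water adjusted to ``pH`` with HCl/NaOH.

    Half-sum of z^2 c over H+, OH- and the strong-electrolyte counterion
    (Cl- below pH 7, Na+ above) required by electroneutrality. Symmetric
    about pH 7; 1e-7 mol/L at neutrality.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    c_h = 10.0 ** (-pH)
    c_oh = WATER_ION_PRODUCT / c_h
    counter = abs(c_h - c_oh)  # Cl- in acid, Na+ in base
    return 0.5 * (c_h + c_oh + counter)


@dataclass
class SolutionConditions:
    """Solvent state for one sample: pH, temperature, ionic strengths.

    ``I_in`` (the Donnan-adjusted internal ionic strength) starts unset and
    may be filled in by the phase-model solver; screening quantities use it
    when available and fall back to the nominal value otherwise.
    """

    pH: float
    T: float = DEFAULT_TEMPERATURE_K
    eps_r: float = DEFAULT_EPS_R
    I_nom: float = field(default=None)  # type: ignore[assignment]
    I_in: float | None = None

    def __post_init__(self) -> None:
        if self.I_nom is None:
            self.I_nom = nominal_ionic_strength(self.pH)
        if self.I_nom <= 0:
            raise ValueError("I_nom must be positive")
        if self.I_in is not None and self.I_in < self.I_nom:
            raise ValueError(
                f"I_in={self.I_in} below I_nom={self.I_nom}: counterion "
                "retention can only add ions"
            )

    @property
    def ionic_strength(self) -> float:
        """Ionic strength in force: internal if set, else nominal (mol/L)."""
        return self.I_in if self.I_in is not None else self.I_nom

    @property
    def Q(self) -> float:
        """Bjerrum length, nm."""
        return bjerrum_length(self.T, self.eps_r)

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/nm."""
        return 1.0 / debye_length(self.ionic_strength, self.T, self.eps_r)

    def with_internal(self, I_in: float) -> "SolutionConditions":
        """Copy with the internal ionic strength set."""
        return SolutionConditions(
            pH=self.pH, T=self.T, eps_r=self.eps_r, I_nom=self.I_nom, I_in=I_in
        )
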