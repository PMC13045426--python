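"""Rod-rod pair interaction energetics: screened electrostatics + van der Waals.

Two charged cylinders in a 1:1 electrolyte interact through a screened
Coulomb repulsion and a van der Waals attraction. The electrostatic part
uses the line-charge results with a cylinder-corrected effective line
charge

    lambda_eff = lambda * exp(-kappa D/2) / ((kappa D/2) K1(kappa D/2)),

which ties exactly to the interaction amplitude A' of the phase model
through A' = 2 pi lambda_eff^2 Q / kappa (an identity tested to machine
precision). Parallel rods of length L at centre-to-centre distance x repel
with U/kT = 2 L lambda_eff^2 Q K0(kappa x); crossed rods at angle theta
with U/kT = (2 pi lambda_eff^2 Q / kappa) exp(-kappa x) / sin(theta), which
at theta = 90 deg reduces to A' exp(-kappa x).

The van der Waals part uses the nonretarded closed forms for parallel and
crossed cylinders (surface separation s = x - D, radius R = D/2):

    U_par  = -(A_H L / (12 sqrt(2) s^{3/2})) sqrt(R/2)
    U_perp = -A_H R / (6 s)

These are near-contact (Derjaguin) asymptotics, quantitatively valid for
s << R; see docs/methods.md for their behaviour at larger separations.

The relative probability P = exp(-(U_par - U_perp)/kT) of parallel versus
crossed configurations serves as a nematic-ordering benchmark; solving
P(x) = P_target for x estimates the inter-fibril spacing at which parallel
alignment reaches that probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import k0 as _K0, k1 as _K1

from .electrolyte import SolutionConditions
from .geometry import FibrilGeometry

__all__ = [
    "InteractionParams",
    "PairPotentialCurve",
    "DEFAULT_HAMAKER_KT",
    "effective_line_charge",
    "electrostatic_pair",
    "vdw_pair",
    "total_pair_potential",
    "relative_probability",
    "solve_nematic_spacing",
    "potential_curve",
    "NoSpacingSolutionError",
]

#: Hamaker constant assumed for protein fibrils across water, in kT.
DEFAULT_HAMAKER_KT = 3.0


class NoSpacingSolutionError(RuntimeError):
    """P(x) = P_target has no root on the search bracket."""


def effective_line_charge(lam: float, kappa: float, D: float) -> float:
    """Cylinder-corrected effective line charge (e/nm).

    lambda_eff = lambda e^{-kappa D/2} / ((kappa D/2) K1(kappa D/2));
    tends to the bare lambda in the thin-rod limit kappa D -> 0.
    """
    if kappa <= 0 or D <= 0:
        raise ValueError("kappa and D must be positive")
    z = kappa * D / 2.0
    return lam * math.exp(-z) / (z * _K1(z))


@dataclass(frozen=True)
class InteractionParams:
    """Pair-interaction inputs for one solution condition.

    ``lam_eff`` is the cylinder-corrected effective line charge (e/nm) and
    ``A_H`` the Hamaker constant in kT. Build from a bare line charge with
    :meth:`from_bare_charge`.
    """

    lam_eff: float
    A_H: float = DEFAULT_HAMAKER_KT

    def __post_init__(self) -> None:
        if self.A_H < 0:
            raise ValueError("Hamaker constant must be non-negative")

    @classmethod
    def from_bare_charge(
        cls, lam: float, D: float, cond: SolutionConditions, A_H: float = DEFAULT_HAMAKER_KT
    ) -> "InteractionParams":
        return cls(lam_eff=effective_line_charge(lam, cond.kappa, D), A_H=A_H)


@dataclass
class PairPotentialCurve:
    """Tabulated pair potentials versus reduced distance x/D (energies kT)."""

    x_over_D: np.ndarray
    U_el_par: np.ndarray
    U_el_perp: np.ndarray
    U_vdW_par: np.ndarray
    U_vdW_perp: np.ndarray
    U_tot_par: np.ndarray = field(init=False)
    U_tot_perp: np.ndarray = field(init=False)
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.U_tot_par = np.asarray(self.U_el_par) + np.asarray(self.U_vdW_par)
        self.U_tot_perp = np.asarray(self.U_el_perp) + np.asarray(self.U_vdW_perp)
        self.P = np.exp(-(self.U_tot_par - self.U_tot_perp))


def electrostatic_pair(
    x: float, theta: float, L: float, ip: InteractionParams, cond: SolutionConditions
) -> float:
    """Screened electrostatic rod-rod energy (kT) at centre distance x (nm).

    theta = 0 (degrees) selects the parallel branch, which scales with the
    full rod length L; theta in (0, 90] the crossed branch with the
    1/sin(theta) geometric factor. Both branches are positive and strictly
    decreasing in x.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if theta < 0 or theta > 90:
        raise ValueError("theta must lie in [0, 90] degrees")
    kappa, Q = cond.kappa, cond.Q
    if theta == 0.0:
        return 2.0 * L * ip.lam_eff**2 * Q * float(_K0(kappa * x))
    return (
        2.0 * math.pi * ip.lam_eff**2 * Q / kappa
    ) * math.exp(-kappa * x) / math.sin(math.radians(theta))


def vdw_pair(x: float, theta: float, D: float, L: float, A_H: float) -> float:
    """Nonretarded van der Waals rod-rod energy (kT), centre distance x (nm).

    Parallel (theta = 0): -(A_H L / (12 sqrt(2) s^{3/2})) sqrt(R/2);
    crossed (theta > 0): -A_H R / (6 s sin(theta)), with s = x - D the
    surface separation and R = D/2. Negative everywhere, vanishing at
    large s.
    """
    if A_H < 0:
        raise ValueError("Hamaker constant must be non-negative")
    s = x - D
    if s <= 0:
        raise ValueError(f"surface separation s = x - D = {s:.3g} nm <= 0: overlap")
    if A_H == 0.0:
        return 0.0
    R = D / 2.0
    if theta == 0.0:
        return -(A_H * L / (12.0 * math.sqrt(2.0) * s**1.5)) * math.sqrt(R / 2.0)
    return -A_H * R / (6.0 * s * math.sin(math.radians(theta)))


def total_pair_potential(
    x: float,
    theta: float,
    geom: FibrilGeometry,
    ip: InteractionParams,
    cond: SolutionConditions,
) -> float:
    """Sum of electrostatic and van der Waals contributions (kT)."""
    return electrostatic_pair(x, theta, geom.L, ip, cond) + vdw_pair(
        x, theta, geom.D, geom.L, ip.A_H
    )


def relative_probability(U_par: float, U_perp: float) -> float:
    """Boltzmann weight of parallel relative to crossed: exp(-(U_par-U_perp)).

    Equals 1 for equal energies and may exceed 1 when the parallel
    configuration is energetically favoured (U_par < U_perp).
    """
    if not (math.isfinite(U_par) and math.isfinite(U_perp)):
        raise ValueError("energies must be finite")
    return math.exp(-(U_par - U_perp))


def _log_probability_at(x_over_D, geom, ip, cond):
    """ln P(x); working in log space avoids exp underflow near contact."""
    x = x_over_D * geom.D
    return -(
        total_pair_potential(x, 0.0, geom, ip, cond)
        - total_pair_potential(x, 90.0, geom, ip, cond)
    )


def _probability_at(x_over_D, geom, ip, cond):
    return math.exp(_log_probability_at(x_over_D, geom, ip, cond))


def solve_nematic_spacing(
    P_target: float,
    geom: FibrilGeometry,
    ip: InteractionParams,
    cond: SolutionConditions,
    bracket: tuple[float, float] = (1.05, 50.0),
    xtol: float = 1e-4,
) -> float:
    """Reduced spacing x/D at which P(x) reaches ``P_target``.

    Root of P(x) = P_target by bisection on x/D; P is required to be
    strictly monotone over the bracket (asserted on a coarse scan).
    """
    if P_target <= 0:
        raise ValueError("P_target must be positive")
    log_target = math.log(P_target)
    lo, hi = bracket
    grid = np.linspace(lo, hi, 64)
    vals = np.array([_log_probability_at(g, geom, ip, cond) for g in grid])
    diffs = np.diff(vals)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise RuntimeError("P(x) is not monotone on the bracket; cannot bisect")
    f_lo, f_hi = vals[0] - log_target, vals[-1] - log_target
    if f_lo * f_hi > 0:
        raise NoSpacingSolutionError(
            f"P_target={P_target:.4g} outside the P range "
            f"[exp({vals.min():.4g}), exp({vals.max():.4g})] on x/D in [{lo}, {hi}]"
        )
    return brentq(
        lambda u: _log_probability_at(u, geom, ip, cond) - log_target, lo, hi, xtol=xtol
    )


def rising_branch_bracket(
    geom: FibrilGeometry,
    ip: InteractionParams,
    cond: SolutionConditions,
    x_max_over_D: float = 40.0,
    P_cap: float = 0.98,
    n: int = 600,
) -> tuple[float, float]:
    """Bracket of the monotonically rising branch of P(x).

    P(x) is generally non-monotone: the diverging van der Waals attraction
    dominates near contact (P >> 1 possible), screened repulsion suppresses
    parallel alignment at intermediate x (P < 1), and P -> 1 from below as
    all interactions decay. This helper locates the minimum of P and the
    point where P re-approaches unity, the natural bracket for
    :func:`solve_nematic_spacing`.
    """
    grid = np.linspace(1.05, x_max_over_D, n)
    vals = np.array([_log_probability_at(g, geom, ip, cond) for g in grid])
    imin = int(vals.argmin())
    above = np.nonzero(vals[imin:] > math.log(P_cap))[0]
    ihi = imin + int(above[0]) if len(above) else len(grid) - 1
    # step one grid point inside the rising branch so the fine monotonicity
    # scan in the solver does not straddle the minimum
    return float(grid[min(imin + 1, ihi - 1)]), float(grid[ihi])


def potential_curve(
    geom: FibrilGeometry,
    ip: InteractionParams,
    cond: SolutionConditions,
    x_over_D: np.ndarray | None = None,
) -> PairPotentialCurve:
    """Evaluate all branches on a grid of reduced distances."""
    if x_over_D is None:
        x_over_D = np.linspace(1.05, 15.0, 280)
    x_over_D = np.asarray(x_over_D, dtype=float)
    x = x_over_D * geom.D
    return PairPotentialCurve(
        x_over_D=x_over_D,
        U_el_par=np.array([electrostatic_pair(xi, 0.0, geom.L, ip, cond) for xi in x]),
        U_el_perp=np.array([electrostatic_pair(xi, 90.0, geom.L, ip, cond) for xi in x]),
        U_vdW_par=np.array([vdw_pair(xi, 0.0, geom.D, geom.L, ip.A_H) for xi in x]),
        U_vdW_perp=np.array([vdw_pair(xi, 90.0, geom.D, geom.L, ip.A_H) for xi in x]),
    )
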