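"""Fibril electrokinetics: mobility -> surface potential -> linear charge.

The fibrils are long cylinders; their orientation-averaged electrophoretic
mobility is mu = (mu_par + 2 mu_perp)/3, with the parallel component given
by the Smoluchowski form mu_par = eps eps0 psi0 / eta and the transverse
component carrying a generalized Henry factor f(kappa a) that interpolates
between the Hueckel-type (1/2) and Smoluchowski (1) limits of a transverse
cylinder. Surface potential is converted to surface charge density by
solving the full nonlinear Poisson-Boltzmann equation around a cylinder in
a 1:1 electrolyte, which reduces to the Debye-Hueckel Bessel-quotient
closed form for small potentials. Linear charge density is lambda = pi D
sigma (charge per unit length over the cylinder circumference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_bvp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import k0 as _K0, k1 as _K1

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
    WATER_VISCOSITY_23C,
)
from .electrolyte import SolutionConditions

__all__ = [
    "MobilityMeasurement",
    "ChargeState",
    "henry_factor_cylinder",
    "mobility_to_surface_potential",
    "surface_potential_to_mobility",
    "surface_potential_to_linear_charge",
    "linear_charge_to_surface_potential",
    "linear_charge_from_mobility",
    "mobility_from_linear_charge",
    "debye_hueckel_linear_charge",
    "smooth_charge_vs_pH",
    "read_mobility_table",
    "write_charge_table",
]

#: conversion: 1 um*cm/(V*s) = 1e-8 m^2/(V*s)
_MOBILITY_SI = 1e-8


class PBConvergenceError(RuntimeError):
    """Nonlinear Poisson-Boltzmann solve failed to converge."""


@dataclass(frozen=True)
class MobilityMeasurement:
    """One electrophoretic mobility point (mobility in um*cm/(V*s))."""

    pH: float
    I: float  # mol/L
    mobility: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.I <= 0:
            raise ValueError("ionic strength must be positive")
        if not math.isfinite(self.mobility):
            raise ValueError("mobility must be finite")


@dataclass(frozen=True)
class ChargeState:
    """Derived charge descriptors at one pH.

    psi0 in mV, sigma in e/nm^2, lam in e/nm; lam = pi*D*sigma holds by
    construction.
    """

    psi0: float
    sigma: float
    lam: float
    pH: float


def henry_factor_cylinder(kappa_a: float) -> float:
    """Generalized Henry factor for a cylinder transverse to the field.

    Ohshima's closed-form approximation; -> 1/2 as kappa_a -> 0 (Hueckel
    limit of a transverse cylinder) and -> 1 as kappa_a -> inf
    (Smoluchowski limit), monotone in between.
    """
    if kappa_a <= 0:
        raise ValueError("kappa_a must be positive")
    denom = 1.0 + 2.55 / (kappa_a * (1.0 + math.exp(-kappa_a)))
    return 0.5 * (1.0 + 1.0 / denom**2)


def _viscosity(cond: SolutionConditions) -> float:
    # single working temperature; constant overridable via module attribute
    return WATER_VISCOSITY_23C


def mobility_to_surface_potential(
    m: MobilityMeasurement, D: float, cond: SolutionConditions
) -> float:
    """Invert orientation-averaged cylinder mobility for psi0 (mV).

    mu = eps eps0 psi0 (1 + 2 f(kappa D/2)) / (3 eta); linear in psi0, so
    the inversion is algebraic. Zero mobility maps to zero potential.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    f = henry_factor_cylinder(cond.kappa * D / 2.0)
    eps = VACUUM_PERMITTIVITY * cond.eps_r
    eta = _viscosity(cond)
    psi0_V = 3.0 * eta * m.mobility * _MOBILITY_SI / (eps * (1.0 + 2.0 * f))
    return psi0_V * 1e3


def surface_potential_to_mobility(
    psi0_mV: float, D: float, cond: SolutionConditions
) -> float:
    """Forward orientation-averaged mobility (um*cm/(V*s)) from psi0 (mV)."""
    f = henry_factor_cylinder(cond.kappa * D / 2.0)
    eps = VACUUM_PERMITTIVITY * cond.eps_r
    eta = _viscosity(cond)
    mu_SI = eps * (psi0_mV * 1e-3) * (1.0 + 2.0 * f) / (3.0 * eta)
    return mu_SI / _MOBILITY_SI


def _thermal_voltage_mV(cond: SolutionConditions) -> float:
    return BOLTZMANN * cond.T / ELEMENTARY_CHARGE * 1e3


def debye_hueckel_linear_charge(
    psi0_mV: float, D: float, cond: SolutionConditions
) -> float:
    """Debye-Hueckel closed form lambda (e/nm) for a cylinder at psi0.

    lambda_DH = (D y0 / 4Q) * kappa a * K1(kappa a)/K0(kappa a) with
    y0 = e psi0 / kT and a = D/2; small-potential limit of the nonlinear
    solve.
    """
    a = D / 2.0
    ka = cond.kappa * a
    y0 = psi0_mV / _thermal_voltage_mV(cond)
    Q = cond.Q
    return y0 * D * cond.kappa * _K1(ka) / (4.0 * Q * _K0(ka))


def _pb_reduced_slope(y0: float, kappa: float, a: float) -> float:
    """Solve the cylindrical nonlinear PB equation; return dy/dr at r=a.

    y'' + y'/r = kappa^2 sinh(y), y(a)=y0, y(a + 50/kappa)=0. Solved as a
    two-point boundary-value problem with a Debye-Hueckel initial guess and
    continuation in y0 for strongly charged surfaces.
    """
    if y0 == 0.0:
        return 0.0
    b = a + 50.0 / kappa
    r = np.linspace(a, b, 400)

    def rhs(r, y):
        return np.vstack([y[1], kappa**2 * np.sinh(y[0]) - y[1] / r])

    sol = None
    # continuation: ramp the surface potential in steps of <= 2 kT/e
    n_steps = max(1, int(math.ceil(abs(y0) / 2.0)))
    for frac in np.linspace(1.0 / n_steps, 1.0, n_steps):
        y0_step = y0 * frac

        def bc(ya, yb, y0_step=y0_step):
            return np.array([ya[0] - y0_step, yb[0]])

        if sol is None:
            guess_y = y0_step * _K0(kappa * r) / _K0(kappa * a)
            guess_dy = -y0_step * kappa * _K1(kappa * r) / _K0(kappa * a)
            guess = np.vstack([guess_y, guess_dy])
            mesh = r
        else:
            mesh, guess = sol.x, sol.y * (y0_step / (y0 * prev_frac))
        sol = solve_bvp(rhs, bc, mesh, guess, tol=1e-8, max_nodes=50000)
        if not sol.success:
            raise PBConvergenceError(
                f"PB solve failed at y0={y0_step:.3f} (kappa a={kappa * a:.3g}): "
                f"{sol.message}"
            )
        prev_frac = frac
    return float(sol.y[1, 0])


def surface_potential_to_linear_charge(
    psi0_mV: float, D: float, cond: SolutionConditions
) -> float:
    """Linear charge density lambda (e/nm) producing psi0 at the surface.

    Full nonlinear Poisson-Boltzmann solve; sigma follows from Gauss's law
    at r = D/2 (sigma = -y'(a)/(4 pi Q) in e/nm^2) and lambda = pi D sigma.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if psi0_mV == 0.0:
        return 0.0
    y0 = psi0_mV / _thermal_voltage_mV(cond)
    slope = _pb_reduced_slope(y0, cond.kappa, D / 2.0)
    sigma = -slope / (4.0 * math.pi * cond.Q)  # e/nm^2
    return math.pi * D * sigma


def linear_charge_to_surface_potential(
    lam: float, D: float, cond: SolutionConditions
) -> float:
    """Invert the nonlinear PB charge-potential relation: psi0 (mV) from lambda.

    Monotone root-find; used by the forward (synthetic) mobility model.
    """
    if lam == 0.0:
        return 0.0
    # Debye-Hueckel starting bracket, expanded until it encloses the root
    a = D / 2.0
    ka = cond.kappa * a
    kT_mV = _thermal_voltage_mV(cond)
    psi_dh = lam * 4.0 * cond.Q * _K0(ka) / (D * cond.kappa * _K1(ka)) * kT_mV

    def g(psi):
        return surface_potential_to_linear_charge(psi, D, cond) - lam

    lo, hi = 0.0, max(abs(psi_dh), kT_mV)
    sign = 1.0 if lam > 0 else -1.0
    for _ in range(60):
        if g(sign * hi) * sign >= 0:
            break
        hi *= 1.5
    else:
        raise PBConvergenceError("could not bracket surface potential")
    root = brentq(lambda p: g(sign * p), lo, hi, xtol=1e-10, rtol=1e-12)
    return sign * root


def linear_charge_from_mobility(
    m: MobilityMeasurement, D: float, cond: SolutionConditions
) -> ChargeState:
    """Full chain mobility -> psi0 -> sigma, lambda for one measurement."""
    psi0 = mobility_to_surface_potential(m, D, cond)
    lam = surface_potential_to_linear_charge(psi0, D, cond)
    return ChargeState(psi0=psi0, sigma=lam / (math.pi * D), lam=lam, pH=m.pH)


def mobility_from_linear_charge(
    lam: float, pH: float, D: float, cond: SolutionConditions
) -> MobilityMeasurement:
    """Forward model: lambda -> psi0 -> orientation-averaged mobility."""
    psi0 = linear_charge_to_surface_potential(lam, D, cond)
    mu = surface_potential_to_mobility(psi0, D, cond)
    return MobilityMeasurement(pH=pH, I=cond.ionic_strength, mobility=mu)


def smooth_charge_vs_pH(points):
    """Monotone-preserving interpolant lambda(pH) through (pH, lambda) knots.

    Requires >= 3 points with strictly increasing pH; passes through the
    inputs exactly and introduces no spurious extrema between knots (PCHIP).
    """
    pts = sorted(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 (pH, lambda) points")
    ph = np.array([p[0] for p in pts], dtype=float)
    lam = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(ph) <= 0):
        raise ValueError("pH values must be strictly increasing (no duplicates)")
    return PchipInterpolator(ph, lam)


def read_mobility_table(path) -> list[MobilityMeasurement]:
    """Read a mobility CSV (pH, ionic_strength_mM, mobility_umcmVs, sd)."""
    df = pd.read_csv(path)
    required = ["pH", "ionic_strength_mM", "mobility_umcmVs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mobility table missing column(s): {', '.join(missing)}")
    sd = df["sd"] if "sd" in df.columns else np.zeros(len(df))
    return [
        MobilityMeasurement(
            pH=float(r.pH),
            I=float(r.ionic_strength_mM) * 1e-3,
            mobility=float(r.mobility_umcmVs),
            sd=float(s),
        )
        for r, s in zip(df.itertuples(), sd)
    ]


def write_charge_table(states: list[ChargeState], path) -> pd.DataFrame:
    """Write a lambda(pH) CSV (pH, psi0_mV, sigma_e_nm2, lambda_e_nm)."""
    df = pd.DataFrame(
        {
            "pH": [s.pH for s in states],
            "psi0_mV": [s.psi0 for s in states],
            "sigma_e_nm2": [s.sigma for s in states],
            "lambda_e_nm": [s.lam for s in states],
        }
    )
    df.to_csv(path, index=False)
    return df
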