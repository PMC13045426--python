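"""SAXS analysis: cylinder form factor, structure factor, correlation peak.

Dilute fibril dispersions scatter as orientation-averaged rigid cylinders;
the form factor is fitted for diameter D and length L. Above the
isotropic-nematic threshold, inter-fibril correlations appear as a broad
peak in the structure factor S(q) = I(q) / (N P(q)), extracted by dividing
a dense profile by a dilute (form-factor-only) reference scaled by the
fibril-number ratio. The peak position q* converts to a real-space
periodicity d = 2 pi / q*.

Unit convention: q is Angstrom^-1 at every I/O boundary (profiles, peak
positions, windows) and nm^-1 internally; lengths are nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import savgol_filter

__all__ = [
    "SAXSProfile",
    "CylinderFormFactorFit",
    "StructureFactorResult",
    "cylinder_form_factor",
    "fit_form_factor",
    "structure_factor",
    "find_peak",
    "spacing_from_peak",
    "read_profile",
    "NoPeakError",
    "FitFailureError",
]

#: q-unit conversion: 1 Angstrom^-1 = 10 nm^-1.
Q_ANGSTROM_TO_NM = 10.0

_GAUSS_ORDER = 256
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GAUSS_ORDER)


class NoPeakError(RuntimeError):
    """Structure factor has no interior maximum in the requested window."""


class FitFailureError(RuntimeError):
    """Form-factor fit did not converge."""


@dataclass
class SAXSProfile:
    """One background-subtracted 1-D profile: q (A^-1, ascending), I, sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    c: float | None = None  # concentration, wt %
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly ascending")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must match q and be positive")


@dataclass
class CylinderFormFactorFit:
    """Fitted cylinder parameters (D, L in nm) and goodness of fit."""

    D: float
    L: float
    scale: float
    background: float
    redchi: float
    result: object | None = None


@dataclass
class StructureFactorResult:
    """S(q) on the reference grid, with located peak and periodicity."""

    q: np.ndarray
    S: np.ndarray
    q_star: float | None = None
    d_nm: float | None = None


def _cylinder_amplitude_sq(q_nm: np.ndarray, R: float, half_L: float) -> np.ndarray:
    """Orientation average of the squared cylinder amplitude.

    <A^2>(q) = int_0^{pi/2} [2 J1(qR sin a)/(qR sin a) * j0(qL cos a / 2)]^2
    sin a da, evaluated by fixed-order Gauss-Legendre quadrature.
    """
    from scipy.special import j1

    # map nodes to (0, pi/2)
    alpha = 0.25 * math.pi * (_GL_NODES + 1.0)
    w = 0.25 * math.pi * _GL_WEIGHTS
    sin_a = np.sin(alpha)
    cos_a = np.cos(alpha)
    q = np.atleast_1d(q_nm)[:, None]
    zr = q * R * sin_a[None, :]
    zl = q * half_L * cos_a[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = np.where(zr > 1e-12, 2.0 * j1(zr) / zr, 1.0 - zr**2 / 8.0)
        axial = np.where(np.abs(zl) > 1e-12, np.sin(zl) / zl, 1.0 - zl**2 / 6.0)
    integrand = (radial * axial) ** 2 * sin_a[None, :]
    return integrand @ w


def cylinder_form_factor(
    q: np.ndarray, D: float, L: float, scale: float = 1.0, background: float = 0.0
) -> np.ndarray:
    """Orientation-averaged rigid-cylinder intensity on a q grid (A^-1).

    I(q) = scale * V^2 * <A^2>(q) + background, with V = pi R^2 L in nm^3;
    the forward limit (background subtracted) is scale * V^2.
    """
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    q_nm = np.asarray(q, dtype=float) * Q_ANGSTROM_TO_NM
    R = D / 2.0
    V = math.pi * R**2 * L
    return scale * V**2 * _cylinder_amplitude_sq(q_nm, R, L / 2.0) + background


def fit_form_factor(
    p: SAXSProfile, init: dict | None = None
) -> CylinderFormFactorFit:
    """Weighted least-squares cylinder fit of (D, L, scale, background).

    Deterministic given the data and initial values (defaults: typical
    fibril dimensions). D, L and scale are fitted in log space — the
    scale/L valley is severely ill-conditioned in linear parameters — and
    the length is multi-started over a small factor ladder because the
    axial sinc lobes create local minima when the Guinier region is not
    fully covered.
    """
    if len(p.q) < 30:
        raise ValueError("need at least 30 q-points spanning the rod regime")
    defaults = {"D": 4.0, "L": 300.0, "scale": None, "background": 0.0}
    if init:
        defaults.update(init)
    if defaults["scale"] is None:
        V = math.pi * (defaults["D"] / 2.0) ** 2 * defaults["L"]
        defaults["scale"] = max(p.I.max(), 1e-300) / V**2
    weights = 1.0 / p.sigma if p.sigma is not None else 1.0 / np.maximum(p.I, 1e-300)

    def residuals(theta):
        D, L, scale = np.exp(theta[:3])
        bg = theta[3]
        return (cylinder_form_factor(p.q, D, L, scale, bg) - p.I) * weights

    best = None
    for L_factor in (1.0, 0.5, 2.0, 4.0):
        theta0 = np.array(
            [
                math.log(defaults["D"]),
                math.log(defaults["L"] * L_factor),
                math.log(defaults["scale"] / L_factor**2),
                defaults["background"],
            ]
        )
        try:
            res = least_squares(
                residuals, theta0, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200
            )
        except Exception:  # singular Jacobian from an absurd start: skip
            continue
        # status 0 (iteration cap) still carries the best point found;
        # the cost comparison across starts keeps the global candidate
        if np.isfinite(res.cost) and (best is None or res.cost < best.cost):
            best = res
        if best is not None and best.cost < 1e-18:  # already at an exact fit
            break
    if best is None:
        raise FitFailureError("form-factor fit failed from every start")
    D, L, scale = np.exp(best.x[:3])
    n_free = max(len(p.q) - 4, 1)
    return CylinderFormFactorFit(
        D=float(D),
        L=float(L),
        scale=float(scale),
        background=float(best.x[3]),
        redchi=float(2.0 * best.cost / n_free),
        result=best,
    )


def structure_factor(
    dense: SAXSProfile, dilute_reference: SAXSProfile, N_ratio: float
) -> StructureFactorResult:
    """S(q) = I_dense / (N_ratio * I_reference) on the reference grid.

    The dense profile is interpolated onto the reference grid; q-points of
    the reference outside the dense range raise a range error. N_ratio is
    the fibril-number (concentration) ratio dense/reference, so a dense
    profile that is a pure rescale of the reference gives S identically 1.
    """
    if N_ratio <= 0:
        raise ValueError("N_ratio must be positive")
    q_ref = dilute_reference.q
    if q_ref[0] < dense.q[0] or q_ref[-1] > dense.q[-1]:
        raise ValueError(
            "reference q grid extends beyond the dense profile; cannot "
            "interpolate outside the measured range"
        )
    I_dense = np.interp(q_ref, dense.q, dense.I)
    S = I_dense / (N_ratio * dilute_reference.I)
    return StructureFactorResult(q=q_ref.copy(), S=S)


def find_peak(
    sf: StructureFactorResult, q_window: tuple[float, float] = (0.01, 0.04)
) -> float:
    """Locate the S(q) maximum inside ``q_window`` (A^-1) by interpolation.

    A smoothing spline is fitted to S(q) in the window and its maximum
    taken; a monotone S (maximum at a window edge) raises
    :class:`NoPeakError`.
    """
    lo, hi = q_window
    if lo >= hi:
        raise ValueError("q_window must be (lo, hi) with lo < hi")
    if lo < sf.q[0] or hi > sf.q[-1]:
        raise ValueError("q_window must lie inside the S(q) grid")
    mask = (sf.q >= lo) & (sf.q <= hi)
    qw, Sw = sf.q[mask], sf.S[mask]
    if len(qw) < 5:
        raise ValueError("too few grid points inside the peak window")
    # light local smoothing, then an interpolating spline whose maximum is
    # located analytically; deterministic for a given grid
    if len(Sw) >= 9:
        Sw = savgol_filter(Sw, window_length=9, polyorder=3)
    spline = CubicSpline(qw, Sw)
    res = minimize_scalar(
        lambda q: -float(spline(q)), bounds=(qw[0], qw[-1]), method="bounded",
        options={"xatol": 1e-7},
    )
    q_star = float(res.x)
    span = qw[-1] - qw[0]
    if q_star - qw[0] < 1e-3 * span or qw[-1] - q_star < 1e-3 * span:
        raise NoPeakError(
            "S(q) has no interior maximum in the window (monotone or edge peak)"
        )
    # prominence: the interior maximum must rise measurably above both edges
    S_star = float(spline(q_star))
    edge = max(float(spline(qw[0])), float(spline(qw[-1])))
    if S_star - edge <= 1e-6 * max(abs(S_star), 1.0):
        raise NoPeakError("S(q) is flat in the window: no significant peak")
    sf.q_star = q_star
    sf.d_nm = spacing_from_peak(q_star)
    return q_star


def spacing_from_peak(q_star: float) -> float:
    """Real-space periodicity d = 2 pi / q* in nm for q* in A^-1."""
    if q_star <= 0:
        raise ValueError("q_star must be positive")
    return 2.0 * math.pi / (q_star * Q_ANGSTROM_TO_NM)


def read_profile(path, c: float | None = None, label: str = "") -> SAXSProfile:
    """Read a 3-column text profile (q_Angstrom_inv, I, optional sigma).

    Accepts whitespace- or comma-delimited text with optional comment
    lines starting with '#'.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("profile must have at least two columns (q, I)")
    # tolerate a header row of column names
    if not np.issubdtype(df.dtypes[0], np.number):
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = range(df.shape[1])
    sigma = df[2].to_numpy(float) if df.shape[1] > 2 else None
    return SAXSProfile(
        q=df[0].to_numpy(float), I=df[1].to_numpy(float), sigma=sigma, c=c, label=label
    )
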