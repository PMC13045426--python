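"""FRAP analysis: trace normalization, exponential recovery fit, metrics.

A circular region of interest (ROI) inside a condensate is photobleached
and its fluorescence recovery monitored, together with a reference ROI in
a nearby unbleached condensate and a background ROI. Double normalization

    I_t = [(T1_t - B_t) / (T1_0 - B_0)] / [(T2_t - B_t) / (T2_0 - B_0)]

cancels acquisition photobleaching common to both ROIs (time 0 is the last
pre-bleach frame, so I_0 = 1 exactly). The post-bleach recovery is fitted
with I(t) = A (1 - exp(-t/tau)) + C; half-time and apparent diffusion
coefficient follow as tau_1/2 = tau ln 2 and D_app = 0.88 w^2 / (4 tau_1/2)
with w the ROI radius, and the mobile fraction as
(I_inf - I_bl) / (I_0 - I_bl) with I_inf = A + C from the fit plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "normalize_trace",
    "fit_recovery",
    "recovery_metrics",
    "mobile_fraction",
    "analyze_trace",
    "read_trace",
    "DegenerateTraceError",
    "FitFailureError",
]


class DegenerateTraceError(ValueError):
    """Trace cannot be normalized (zero denominator or no dynamic range)."""


class FitFailureError(RuntimeError):
    """Recovery fit did not converge."""


@dataclass
class FRAPTrace:
    """Raw three-ROI trace; ``bleach_index`` is the first post-bleach frame."""

    t: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    B: np.ndarray
    bleach_index: int
    omega: float = 1.5  # ROI radius, um (3 um diameter ROIs)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("T1", "T2", "B"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, k)) != n for k in ("T1", "T2", "B")):
            raise ValueError("t, T1, T2, B must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly ascending")
        if not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index must leave >=1 pre- and post-bleach frame")
        if self.omega <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class FRAPFit:
    """Exponential recovery fit I(t) = A (1 - e^{-t/tau}) + C."""

    A: float
    C: float
    tau: float
    tau_half: float
    D_app: float
    mobile_fraction: float


def normalize_trace(tr: FRAPTrace) -> np.ndarray:
    """Double-normalized intensity I_t.

    The time-0 reference values are averaged over all pre-bleach frames
    (noise robustness; for a noise-free trace I = 1 exactly at the last
    pre-bleach frame because bleached and reference ROI coincide before
    the bleach).
    """
    pre = slice(0, tr.bleach_index)
    num0 = np.mean(tr.T1[pre] - tr.B[pre])
    den0 = np.mean(tr.T2[pre] - tr.B[pre])
    num = tr.T1 - tr.B
    den = tr.T2 - tr.B
    if num0 == 0 or den0 == 0 or np.any(den == 0):
        raise DegenerateTraceError("zero denominator in normalization")
    return (num / num0) / (den / den0)


def fit_recovery(I: np.ndarray, t: np.ndarray, bleach_index: int) -> tuple[float, float, float]:
    """Fit A, C, tau on the post-bleach frames (time re-zeroed at bleach).

    Initial values come from the curve endpoints; a trace with no dynamic
    range (constant series) is rejected.
    """
    I = np.asarray(I, float)
    t = np.asarray(t, float)
    Ip = I[bleach_index:]
    tp = t[bleach_index:] - t[bleach_index]
    if len(Ip) < 10:
        raise ValueError("need >= 10 post-bleach frames")
    if np.ptp(Ip) < 1e-12:
        raise DegenerateTraceError("constant post-bleach series: tau unbounded")

    def model(t, A, C, tau):
        return A * (1.0 - np.exp(-t / tau)) + C

    C0 = Ip[0]
    A0 = max(Ip[-1] - Ip[0], 1e-6)
    tau0 = max(tp[-1] / 3.0, np.finfo(float).tiny)
    try:
        popt, _ = curve_fit(
            model,
            tp,
            Ip,
            p0=[A0, C0, tau0],
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"recovery fit failed: {exc}") from exc
    A, C, tau = map(float, popt)
    return A, C, tau


def recovery_metrics(tau: float, omega: float) -> tuple[float, float]:
    """Half-time tau_1/2 = tau ln 2 (s) and D_app = 0.88 w^2/(4 tau_1/2) (um^2/s)."""
    if tau <= 0 or omega <= 0:
        raise ValueError("tau and omega must be positive")
    tau_half = tau * math.log(2.0)
    D_app = 0.88 * omega**2 / (4.0 * tau_half)
    return tau_half, D_app


def mobile_fraction(I_inf: float, I_bl: float, I_0: float = 1.0) -> float:
    """Mobile fraction (I_inf - I_bl) / (I_0 - I_bl)."""
    if I_0 == I_bl:
        raise DegenerateTraceError("I_0 equals I_bl: bleach depth zero")
    return (I_inf - I_bl) / (I_0 - I_bl)


def analyze_trace(tr: FRAPTrace) -> FRAPFit:
    """Normalize, fit the recovery, and derive all metrics for one trace."""
    I = normalize_trace(tr)
    A, C, tau = fit_recovery(I, tr.t, tr.bleach_index)
    tau_half, D_app = recovery_metrics(tau, tr.omega)
    mf = mobile_fraction(I_inf=A + C, I_bl=C, I_0=I[tr.bleach_index - 1])
    return FRAPFit(A=A, C=C, tau=tau, tau_half=tau_half, D_app=D_app, mobile_fraction=mf)


def read_trace(path, bleach_index: int | None = None, omega: float | None = None) -> FRAPTrace:
    """Read a trace CSV (t_s, T1, T2, B).

    ``bleach_index`` and ``roi_radius_um`` may be given as '# key: value'
    header comments in the file or as arguments (arguments win).
    """
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                meta[k.strip()] = float(v)
    df = pd.read_csv(path, comment="#")
    for col in ("t_s", "T1", "T2", "B"):
        if col not in df.columns:
            raise ValueError(f"trace file missing column: {col}")
    bi = bleach_index if bleach_index is not None else int(meta.get("bleach_index", 0))
    om = omega if omega is not None else meta.get("roi_radius_um", 1.5)
    return FRAPTrace(
        t=df["t_s"].to_numpy(),
        T1=df["T1"].to_numpy(),
        T2=df["T2"].to_numpy(),
        B=df["B"].to_numpy(),
        bleach_index=bi,
        omega=om,
    )
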