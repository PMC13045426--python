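"""Seeded generators emulating every measurement channel of the analysis.

Each generator forward-models one input the pipeline consumes — traced
worm-like-chain contours, cylinder-form-factor SAXS profiles with an
optional correlation peak, three-ROI FRAP traces, electrophoretic mobility
titrations, and binary phase observations around known thresholds — with
the statistical structure the corresponding fitting stage assumes. A fixed
seed yields byte-identical outputs; a scenario's root seed fans out to
per-channel substreams via ``numpy.random.SeedSequence``.

Noise models: multiplicative log-normal for SAXS (detector intensities are
positive with roughly constant relative error), additive Gaussian for FRAP
and mobility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .electrolyte import SolutionConditions
from .electrokinetics import MobilityMeasurement, mobility_from_linear_charge
from .frap import FRAPTrace
from .geometry import FibrilGeometry
from .morphometry import ContourTrace
from .phase_model import (
    PhaseObservation,
    classify_regime,
    predict_threshold_concentration,
)
from .saxs import SAXSProfile, cylinder_form_factor

__all__ = [
    "ScenarioSpec",
    "gen_wlc_contours",
    "gen_saxs_profile",
    "gen_frap_trace",
    "gen_mobility_titration",
    "gen_phase_observations",
]


@dataclass
class ScenarioSpec:
    """A reproducible bundle of generator settings sharing one root seed."""

    seed: int
    geometry: FibrilGeometry
    lam_of_pH: dict[float, float]
    I_in_of_pH: dict[float, float] = field(default_factory=dict)
    saxs_noise: float = 0.02
    frap_noise: float = 0.01
    mobility_noise: float = 0.05
    n_contours: int = 500

    def substreams(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def gen_wlc_contours(
    Lp: float,
    Lc_range: tuple[float, float],
    n: int,
    seed: int,
    step: float = 2.0,
) -> list[ContourTrace]:
    """Sample 2-D worm-like chains with persistence length ``Lp`` (nm).

    Chains are built from fixed-length segments whose turning angles are
    Gaussian with variance step/Lp, the discretisation of a 2-D WLC whose
    tangent correlation decays as exp(-s / (2 Lp)). Contour lengths are
    drawn uniformly from ``Lc_range``. ``Lp=inf`` gives straight lines.
    """
    if n < 1 or Lp <= 0 or step <= 0:
        raise ValueError("need n >= 1, Lp > 0, step > 0")
    lo, hi = Lc_range
    if not 0 < lo <= hi:
        raise ValueError("Lc_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    traces = []
    sigma = 0.0 if math.isinf(Lp) else math.sqrt(step / Lp)
    for i in range(n):
        Lc = rng.uniform(lo, hi)
        n_seg = max(1, int(round(Lc / step)))
        ds = Lc / n_seg
        sig = sigma * math.sqrt(ds / step) if sigma else 0.0
        turns = rng.normal(0.0, sig, n_seg) if sig else np.zeros(n_seg)
        theta0 = rng.uniform(0.0, 2.0 * math.pi)
        angles = theta0 + np.concatenate([[0.0], np.cumsum(turns[1:])])
        steps = ds * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        traces.append(ContourTrace(points=pts, fibril_id=i))
    return traces


def gen_saxs_profile(
    D: float,
    L: float,
    c_list: list[float],
    peak: tuple[float, float, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
    q: np.ndarray | None = None,
    scale: float = 1.0,
    peak_min_c: float | None = None,
) -> list[SAXSProfile]:
    """Cylinder-form-factor profiles at concentrations ``c_list`` (wt %).

    Intensity: I_c(q) = c * scale * V^2 <A^2>(q) * S_c(q) with an optional
    Gaussian correlation peak S(q) = 1 + amp * exp(-(q-q0)^2 / (2 w^2))
    (``peak = (q0, amp, w)`` in A^-1) applied to profiles with
    c >= ``peak_min_c`` (all, when None). Multiplicative log-normal noise
    of relative magnitude ``noise``. The most dilute member is always
    peak-free so it can serve as the form-factor reference.
    """
    if q is None:
        q = np.geomspace(1e-3, 0.3, 250)
    q = np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    c_min = min(c_list)
    P = cylinder_form_factor(q, D, L, scale=scale, background=0.0)
    profiles = []
    for c in c_list:
        S = np.ones_like(q)
        use_peak = peak is not None and c > c_min
        if use_peak and peak_min_c is not None:
            use_peak = c >= peak_min_c
        if use_peak:
            q0, amp, width = peak
            S = S + amp * np.exp(-((q - q0) ** 2) / (2.0 * width**2))
        I = c * P * S
        if noise > 0:
            I = I * rng.lognormal(mean=0.0, sigma=noise, size=q.shape)
        sigma_arr = noise * I if noise > 0 else None
        profiles.append(SAXSProfile(q=q.copy(), I=I, sigma=sigma_arr, c=c, label=f"{c} wt%"))
    return profiles


def gen_frap_trace(
    A: float,
    C: float,
    tau: float,
    acq_decay: float = 0.0,
    noise: float = 0.0,
    n_frames: int = 80,
    n_pre: int = 10,
    dt: float = 0.5,
    seed: int = 0,
    omega: float = 1.5,
    F0: float = 1000.0,
    B0: float = 50.0,
) -> FRAPTrace:
    """Three-ROI trace whose double-normalized recovery is A(1-e^{-t/tau})+C.

    ``C`` is the bleach depth (normalized intensity of the first
    post-bleach frame) and ``A`` the recovering amplitude, so the plateau
    is A + C and the mobile fraction A / (1 - C). Both ROIs share the same
    exponential acquisition photobleaching rate ``acq_decay`` (1/s), which
    the normalization cancels exactly. Acquisition noise is additive
    Gaussian on the bleached-ROI signal with standard deviation
    ``noise`` * F0 * decay(t), so ``noise`` is exactly the standard
    deviation of the double-normalized intensity (1/noise is the SNR of
    the recovery curve); the reference and background ROIs are treated as
    smooth, as they are in practice far better averaged.
    """
    if not 0 < n_pre < n_frames:
        raise ValueError("need 0 < n_pre < n_frames")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    decay = np.exp(-acq_decay * t)
    T2 = F0 * decay + B0
    T1 = np.empty(n_frames)
    T1[:n_pre] = F0 * decay[:n_pre]
    tp = t[n_pre:] - t[n_pre]
    recovery = A * (1.0 - np.exp(-tp / tau)) + C
    T1[n_pre:] = recovery * F0 * decay[n_pre:]
    T1 = T1 + B0
    B = np.full(n_frames, B0)
    if noise > 0:
        T1 = T1 + rng.normal(0.0, noise, n_frames) * F0 * decay
    return FRAPTrace(t=t, T1=T1, T2=T2, B=B, bleach_index=n_pre, omega=omega)


def gen_mobility_titration(
    lam_of_pH,
    D: float,
    pH_grid: np.ndarray,
    noise: float = 0.0,
    seed: int = 0,
    T: float | None = None,
) -> list[MobilityMeasurement]:
    """Forward-modelled electrophoretic mobilities along a pH titration.

    For each pH the nominal solution conditions are built, lambda(pH) is
    converted to a surface potential through the nonlinear
    Poisson-Boltzmann relation, and the orientation-averaged mobility is
    evaluated; the sign of the mobility follows the sign of lambda, so an
    isoelectric point in lambda(pH) appears as a mobility sign change.
    Additive Gaussian noise in mobility units (um cm / V s).
    """
    rng = np.random.default_rng(seed)
    out = []
    for pH in np.asarray(pH_grid, dtype=float):
        kwargs = {} if T is None else {"T": T}
        cond = SolutionConditions(pH=float(pH), **kwargs)
        lam = float(lam_of_pH(pH))
        m = mobility_from_linear_charge(lam, float(pH), D, cond)
        mob = m.mobility + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        out.append(
            MobilityMeasurement(pH=float(pH), I=cond.I_nom, mobility=mob, sd=noise)
        )
    return out


def gen_phase_observations(
    geometry: FibrilGeometry,
    lam_of_pH,
    I_in_of_pH,
    pH_grid,
    c_grid,
    seed: int = 0,
    jitter: float = 0.0,
    lam_LLPS: float = 1.0,
) -> tuple[list[PhaseObservation], list[dict]]:
    """Label a (pH, c) grid and extract per-pH LLCPS start concentrations.

    For each pH the threshold concentration is forward-predicted from
    lambda(pH) and the supplied internal ionic strength; each grid
    concentration is labelled isotropic/LLCPS/LLPS, with an optional
    multiplicative observation jitter (log-normal of width ``jitter``)
    on the threshold before labelling. Returns the per-pH observations
    (mean = first labelled concentration at or above threshold, min =
    jittered threshold) together with the full label table.
    """
    rng = np.random.default_rng(seed)
    observations, labels = [], []
    for pH in pH_grid:
        lam = float(lam_of_pH(pH))
        cond = SolutionConditions(pH=float(pH)).with_internal(float(I_in_of_pH(pH)))
        c_IN = predict_threshold_concentration(geometry, lam, cond).c_IN
        c_eff = c_IN * (rng.lognormal(0.0, jitter) if jitter > 0 else 1.0)
        regimes = [classify_regime(lam, c, c_eff, lam_LLPS) for c in c_grid]
        for c, r in zip(c_grid, regimes):
            labels.append({"pH": float(pH), "c_wt": float(c), "regime": r})
        above = [c for c, r in zip(c_grid, regimes) if r != "isotropic"]
        if above:
            regime = "LLPS" if lam <= lam_LLPS else "LLCPS"
            observations.append(
                PhaseObservation(
                    pH=float(pH),
                    c_mean=float(min(above)),
                    c_min=float(min(min(above), c_eff)),
                    regime_label=regime,
                )
            )
    return observations, labels
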