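"""Fibril morphometry from traced contours: contour length and persistence length.

Fibrils deposited on mica and imaged by AFM are traced as ordered 2-D
polylines. The persistence length is estimated by fitting the mean squared
end-to-end distance versus contour length to the worm-like-chain (WLC)
prediction for chains equilibrated in two dimensions,

    <R^2>(Lc) = 4 Lp Lc [1 - (2 Lp / Lc)(1 - e^{-Lc/(2 Lp)})],

whose limits are <R^2> -> Lc^2 for rigid filaments (Lp >> Lc) and
<R^2> -> 4 Lp Lc in the flexible limit. A projected-3-D convention
(<R^2> = 2 Lp Lc [1 - (Lp/Lc)(1 - e^{-Lc/Lp})]) is available behind a flag
for chains equilibrated in 3-D before adsorption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ContourTrace",
    "contour_length",
    "wlc_mean_square_r",
    "wlc_persistence_length",
    "read_contours",
]


@dataclass
class ContourTrace:
    """One traced fibril: ordered (x, y) vertices in nm, optional height."""

    points: np.ndarray
    H: float | None = None
    fibril_id: int | str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError("a contour needs at least 2 points")

    @property
    def L_c(self) -> float:
        return contour_length(self)

    @property
    def R2(self) -> float:
        """Squared end-to-end distance, nm^2."""
        return float(np.sum((self.points[-1] - self.points[0]) ** 2))


def contour_length(tr: ContourTrace) -> float:
    """Polyline arc length (nm); always >= end-to-end distance."""
    seg = np.diff(tr.points, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def wlc_mean_square_r(Lc, Lp: float, convention: str = "2d") -> np.ndarray:
    """WLC mean squared end-to-end distance (nm^2) at contour length Lc.

    ``convention='2d'`` (default) is for chains equilibrated on the
    surface; ``'3d-projected'`` for chains equilibrated in solution and
    projected on deposition.
    """
    Lc = np.asarray(Lc, dtype=float)
    if Lp <= 0:
        raise ValueError("Lp must be positive")
    if convention == "2d":
        s = Lc / (2.0 * Lp)
        with np.errstate(over="ignore"):
            return 4.0 * Lp * Lc * (1.0 - (1.0 / np.maximum(s, 1e-300)) * (1.0 - np.exp(-s)))
    if convention == "3d-projected":
        s = Lc / Lp
        return 2.0 * Lp * Lc * (1.0 - (1.0 / np.maximum(s, 1e-300)) * (1.0 - np.exp(-s)))
    raise ValueError(f"unknown convention {convention!r}")


def wlc_persistence_length(
    traces: list[ContourTrace],
    n_bins: int = 10,
    convention: str = "2d",
    n_bootstrap: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Persistence length (nm) with a bootstrap confidence interval.

    Traces are binned by contour length; the bin-mean R^2 values are fitted
    to the WLC closed form by least squares weighted with the bin counts.
    With fewer than 20 traces, or all traces at one contour length, the fit
    is ill-conditioned: a warning is emitted and the point estimate still
    returned (CI may be degenerate).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    Lc = np.array([t.L_c for t in traces])
    R2 = np.array([t.R2 for t in traces])
    if len(traces) < 20:
        warnings.warn("fewer than 20 traces: persistence-length fit is noisy", stacklevel=2)
    if np.ptp(Lc) < 1e-9 * Lc.mean():
        warnings.warn(
            "all traces share one contour length: ill-conditioned WLC fit",
            stacklevel=2,
        )

    def fit_once(Lc_s, R2_s):
        edges = np.quantile(Lc_s, np.linspace(0, 1, min(n_bins, max(2, len(Lc_s) // 5)) + 1))
        edges[-1] += 1e-9
        idx = np.clip(np.searchsorted(edges, Lc_s, side="right") - 1, 0, len(edges) - 2)
        centers, means, counts = [], [], []
        for b in range(len(edges) - 1):
            m = idx == b
            if m.sum() == 0:
                continue
            centers.append(Lc_s[m].mean())
            means.append(R2_s[m].mean())
            counts.append(m.sum())
        centers = np.array(centers)
        means = np.array(means)
        counts = np.array(counts, dtype=float)
        lp0 = max(np.mean(R2_s) / (4.0 * np.mean(Lc_s)), 1e-3)
        popt, _ = curve_fit(
            lambda L, Lp: wlc_mean_square_r(L, Lp, convention),
            centers,
            means,
            p0=[lp0],
            sigma=1.0 / np.sqrt(counts),
            bounds=(1e-6, np.inf),
            maxfev=10000,
        )
        return float(popt[0])

    lp_hat = fit_once(Lc, R2)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(traces)
    for _ in range(n_bootstrap):
        take = rng.integers(0, n, n)
        try:
            boots.append(fit_once(Lc[take], R2[take]))
        except RuntimeError:
            continue
    if boots:
        alpha = 0.5 * (1.0 - ci_level)
        ci = (
            float(np.quantile(boots, alpha)),
            float(np.quantile(boots, 1.0 - alpha)),
        )
    else:
        ci = (lp_hat, lp_hat)
    return lp_hat, ci


def read_contours(path, heights_path=None) -> list[ContourTrace]:
    """Read contour vertices CSV (fibril_id, x_nm, y_nm) into traces.

    ``heights_path`` may point to a per-fibril table (fibril_id, height_nm).
    """
    df = pd.read_csv(path)
    for col in ("fibril_id", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"contour file missing column: {col}")
    heights = {}
    if heights_path is not None:
        hdf = pd.read_csv(heights_path)
        heights = dict(zip(hdf["fibril_id"], hdf["height_nm"]))
    traces = []
    for fid, g in df.groupby("fibril_id", sort=True):
        traces.append(
            ContourTrace(
                points=g[["x_nm", "y_nm"]].to_numpy(),
                H=heights.get(fid),
                fibril_id=fid,
            )
        )
    return traces
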