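"""Orchestration of the end-to-end analysis chain.

Thin, file-oriented wrappers over the library modules: each ``run_*``
function validates its inputs, logs the physical parameters in force,
executes one stage of the analysis (charge inference, phase-diagram
assembly, pair potentials, SAXS, FRAP, morphometry) and writes
deterministic CSV/JSON outputs. The numbered scripts under ``analysis/``
drive these functions; they are equally usable from a notebook.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frap as frap_mod
from . import morphometry, pair_potential, phase_model, saxs
from .electrokinetics import (
    linear_charge_from_mobility,
    read_mobility_table,
    smooth_charge_vs_pH,
    write_charge_table,
)
from .electrolyte import SolutionConditions
from .geometry import FibrilGeometry

__all__ = [
    "RunConfig",
    "run_charge",
    "run_phase_diagram",
    "run_pair_potential",
    "run_saxs",
    "run_frap",
    "run_morphometry",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Physical parameters and defaults shared across pipeline stages."""

    temperature_K: float = 296.15
    eps_r: float = 78.4
    rho_AF: float = 1.3  # g/mL
    rho_w: float = 1.0  # g/mL
    b0: float = phase_model.ONSAGER_B0
    hamaker_kT: float = pair_potential.DEFAULT_HAMAKER_KT
    lam_LLPS: float = 1.0  # e/nm
    diameter_nm: float = 20.9 / 5.4
    aspect_ratio: float = 95.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "temperature_K", "eps_r", "rho_AF", "rho_w", "b0", "hamaker_kT",
            "lam_LLPS", "diameter_nm", "aspect_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from YAML, rejecting unknown keys."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @property
    def geometry(self) -> FibrilGeometry:
        return FibrilGeometry.from_aspect_ratio(self.diameter_nm, self.aspect_ratio)

    def conditions(self, pH: float) -> SolutionConditions:
        return SolutionConditions(pH=pH, T=self.temperature_K, eps_r=self.eps_r)

    def echo(self) -> None:
        logger.info("run configuration: %s", asdict(self))


def run_charge(input_csv, out_csv, config: RunConfig) -> pd.DataFrame:
    """Mobility table -> per-pH charge state table (lambda(pH))."""
    config.echo()
    measurements = read_mobility_table(input_csv)
    states = []
    for m in measurements:
        cond = SolutionConditions(
            pH=m.pH, T=config.temperature_K, eps_r=config.eps_r, I_nom=m.I
        )
        states.append(linear_charge_from_mobility(m, config.diameter_nm, cond))
    return write_charge_table(states, out_csv)


def run_phase_diagram(
    observations_csv, lambda_csv, out_csv, config: RunConfig
) -> pd.DataFrame:
    """Observed LLCPS starts + lambda(pH) knots -> full phase-diagram table."""
    config.echo()
    obs_df = pd.read_csv(observations_csv)
    for col in ("pH", "c_wt_percent"):
        if col not in obs_df.columns:
            raise ValueError(f"observations file missing column: {col}")
    lam_df = pd.read_csv(lambda_csv)
    for col in ("pH", "lambda_e_nm"):
        if col not in lam_df.columns:
            raise ValueError(f"lambda file missing column: {col}")
    lam_of_pH = smooth_charge_vs_pH(list(zip(lam_df["pH"], lam_df["lambda_e_nm"])))
    observations = [
        phase_model.PhaseObservation(
            pH=float(r.pH),
            c_mean=float(r.c_wt_percent),
            c_min=float(getattr(r, "c_min_wt_percent", r.c_wt_percent)),
            regime_label=str(getattr(r, "regime_label", "LLCPS")),
        )
        for r in obs_df.itertuples()
    ]
    table = phase_model.build_phase_diagram(
        observations,
        lam_of_pH,
        config.geometry,
        b0=config.b0,
        rho_AF=config.rho_AF,
        rho_w=config.rho_w,
        lam_LLPS=config.lam_LLPS,
    )
    table.to_csv(out_csv, index=False)
    return table


def run_pair_potential(
    pH: float,
    lam: float,
    I_in: float,
    out_csv,
    config: RunConfig,
    P_target: float | None = None,
) -> dict:
    """Potential curves at one pH; optionally solve the nematic spacing."""
    config.echo()
    geom = config.geometry
    cond = config.conditions(pH).with_internal(I_in)
    ip = pair_potential.InteractionParams.from_bare_charge(
        lam, geom.D, cond, A_H=config.hamaker_kT
    )
    curve = pair_potential.potential_curve(geom, ip, cond)
    pd.DataFrame(
        {
            "x_over_D": curve.x_over_D,
            "U_el_par_kT": curve.U_el_par,
            "U_el_perp_kT": curve.U_el_perp,
            "U_vdW_par_kT": curve.U_vdW_par,
            "U_vdW_perp_kT": curve.U_vdW_perp,
            "U_tot_par_kT": curve.U_tot_par,
            "U_tot_perp_kT": curve.U_tot_perp,
            "P": curve.P,
        }
    ).to_csv(out_csv, index=False)
    result = {"pH": pH, "lambda_e_nm": lam, "I_in_M": I_in, "lam_eff_e_nm": ip.lam_eff}
    if P_target is not None:
        try:
            result["x_nematic_over_D"] = pair_potential.solve_nematic_spacing(
                P_target, geom, ip, cond
            )
        except (pair_potential.NoSpacingSolutionError, RuntimeError) as exc:
            result["x_nematic_over_D"] = None
            result["spacing_status"] = str(exc)
    return result


def run_saxs(
    profile_paths: list,
    reference_path,
    out_prefix,
    config: RunConfig,
    concentrations: list[float] | None = None,
    reference_c: float = 1.0,
    q_window: tuple[float, float] = (0.01, 0.04),
) -> dict:
    """Fit the dilute reference, extract S(q) for each dense profile."""
    config.echo()
    out_prefix = Path(out_prefix)
    ref = saxs.read_profile(reference_path, c=reference_c, label="reference")
    fit = saxs.fit_form_factor(ref)
    results = {
        "form_factor_fit": {
            "D_nm": fit.D,
            "L_nm": fit.L,
            "scale": fit.scale,
            "background": fit.background,
            "redchi": fit.redchi,
        },
        "structure_factors": [],
    }
    cs = concentrations or [None] * len(profile_paths)
    for path, c in zip(profile_paths, cs):
        dense = saxs.read_profile(path, c=c, label=str(path))
        n_ratio = (c / reference_c) if c else 1.0
        sf = saxs.structure_factor(dense, ref, N_ratio=n_ratio)
        entry = {"profile": str(path), "c_wt": c}
        try:
            q_star = saxs.find_peak(sf, q_window)
            entry["q_star_A_inv"] = q_star
            entry["d_nm"] = saxs.spacing_from_peak(q_star)
        except (saxs.NoPeakError, ValueError) as exc:
            entry["q_star_A_inv"] = None
            entry["peak_status"] = str(exc)
        pd.DataFrame({"q_A_inv": sf.q, "S": sf.S}).to_csv(
            out_prefix.with_name(out_prefix.name + f"_S_{Path(path).stem}.csv"),
            index=False,
        )
        results["structure_factors"].append(entry)
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(results, fh, indent=2)
    return results


def run_frap(trace_csv, out_json, config: RunConfig) -> dict:
    """Fit one FRAP trace and write the recovery metrics as JSON."""
    config.echo()
    tr = frap_mod.read_trace(trace_csv)
    fit = frap_mod.analyze_trace(tr)
    result = {
        "A": fit.A,
        "C": fit.C,
        "tau_s": fit.tau,
        "tau_half_s": fit.tau_half,
        "D_app_um2_s": fit.D_app,
        "mobile_fraction": fit.mobile_fraction,
    }
    with open(out_json, "w") as fh:
        json.dump(result, fh, indent=2)
    return result


def run_morphometry(contours_csv, out_json, config: RunConfig, heights_csv=None) -> dict:
    """Contour statistics and WLC persistence length from traced fibrils."""
    config.echo()
    traces = morphometry.read_contours(contours_csv, heights_csv)
    Lc = np.array([t.L_c for t in traces])
    lp, ci = morphometry.wlc_persistence_length(traces, seed=config.seed)
    heights = [t.H for t in traces if t.H is not None]
    result = {
        "n_fibrils": len(traces),
        "Lc_mean_nm": float(Lc.mean()),
        "Lc_sd_nm": float(Lc.std(ddof=1)) if len(Lc) > 1 else 0.0,
        "Lp_nm": lp,
        "Lp_ci_nm": list(ci),
        "H_mean_nm": float(np.mean(heights)) if heights else None,
    }
    with open(out_json, "w") as fh:
        json.dump(result, fh, indent=2)
    return result
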