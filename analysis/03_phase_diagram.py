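#!/usr/bin/env python
"""Assemble the lysozyme phase diagram from observed LLCPS start points.

Inputs are the observed mean start concentrations of liquid-liquid
crystalline phase separation at pH 2-7 (1.49, 0.97, 0.90, 0.83, 0.68,
0.58 wt %) and the charge-density anchors (3.0 e/nm at pH 2, 1.17 at
pH 7, ~1 at the LLPS onset pH 8). For each pH the internal (Donnan)
ionic strength is bisected until the charged-rod threshold theory matches
the observation; the table reports I_in, the effective diameter, twisting
factor, composite prefactor and regime.
"""

from pathlib import Path

import pandas as pd

from fibrilphase.pipeline import RunConfig, run_phase_diagram

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(parents=True, exist_ok=True)

# observed LLCPS start concentrations (mean, minimum) per pH
obs_path = OUT / "lysozyme_observations.csv"
pd.DataFrame(
    {
        "pH": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
        "c_wt_percent": [1.49, 0.97, 0.90, 0.83, 0.68, 0.58],
        "c_min_wt_percent": [1.25, 0.90, 0.70, 0.70, 0.45, 0.45],
        "regime_label": ["LLCPS"] * 6,
    }
).to_csv(obs_path, index=False)

lam_path = OUT / "lysozyme_lambda_knots.csv"
pd.DataFrame(
    {"pH": [2.0, 7.0, 8.0], "lambda_e_nm": [3.0, 1.17, 1.0]}
).to_csv(lam_path, index=False)

config = RunConfig()
table = run_phase_diagram(obs_path, lam_path, OUT / "phase_diagram.csv", config)

cols = ["pH", "lambda_e_nm", "c_obs_wt", "I_in_M", "kappa_inv_nm",
        "D_eff_nm", "h", "prefactor", "regime_predicted"]
print("lysozyme phase-diagram table (Donnan-solved per pH):")
print(table[cols].round(4).to_string(index=False))
print(
    f"\nsolved internal ionic strength falls from "
    f"{table.I_in_M.iloc[0] * 1e3:.1f} mM at pH 2 to "
    f"{table.I_in_M.iloc[-1] * 1e3:.2f} mM at pH 7, while the effective "
    f"diameter grows from {table.D_eff_nm.iloc[0]:.1f} to "
    f"{table.D_eff_nm.iloc[-1]:.1f} nm - weaker screening swells the "
    "excluded volume and lowers the ordering threshold."
)
print(f"wrote {OUT / 'phase_diagram.csv'}")
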