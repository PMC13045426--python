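#!/usr/bin/env python
"""Infer fibril linear charge density from the mobility titration.

Runs the electrokinetic inversion (orientation-averaged generalized-Henry
mobility -> surface potential -> nonlinear Poisson-Boltzmann surface
charge -> lambda = pi D sigma) on the synthetic titration from stage 01,
then fits the monotone lambda(pH) interpolant used by later stages.
"""

from pathlib import Path


from fibrilphase.pipeline import RunConfig, run_charge

ROOT = Path(__file__).resolve().parents[1]
SRC = ROOT / "results" / "synthetic" / "mobility_titration.csv"
OUT = ROOT / "results" / "charge"
OUT.mkdir(parents=True, exist_ok=True)

config = RunConfig()
table = run_charge(SRC, OUT / "charge_vs_pH.csv", config)

below_iep = table[table.lambda_e_nm > 0.2]
print("inferred linear charge density lambda(pH):")
print(table.round(3).to_string(index=False))
iep_window = table[(table.lambda_e_nm.shift(1) > 0) & (table.lambda_e_nm <= 0)]
if len(iep_window):
    print(f"isoelectric point bracketed near pH {iep_window.pH.iloc[0] - 0.5:.1f}")
print(f"wrote {OUT / 'charge_vs_pH.csv'}")
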