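#!/usr/bin/env python
"""Generate the synthetic input bundle for the downstream analysis stages.

Emulates the five measurement channels at their study conditions: an
electrophoretic-mobility titration across pH 2-12 (isoelectric point near
pH 10), dilute + dense SAXS profiles with a correlation peak at
q = 0.03 1/A, six FRAP bleach-recovery traces at SNR 10, 500 traced
worm-like-chain contours (Lp = 2000 nm, the rigid fibril regime
Lp/Lc ~ 10), and phase observations on a (pH, concentration) grid.
Everything is seeded; outputs land under results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fibrilphase import synthetic as syn
from fibrilphase.electrokinetics import smooth_charge_vs_pH
from fibrilphase.geometry import LYSOZYME

SEED = 20260930
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

# titration-shaped charge density: 3.0 e/nm at pH 2 declining through
# 1.17 e/nm at pH 7 toward zero at the isoelectric point near pH 10
lam_of_pH = smooth_charge_vs_pH([(2.0, 3.0), (7.0, 1.17), (8.0, 1.0), (10.0, 0.0), (12.0, -0.8)])

rngs = np.random.SeedSequence(SEED).spawn(5)
seeds = [int(r.generate_state(1)[0] % 2**31) for r in rngs]

# 1. mobility titration
ms = syn.gen_mobility_titration(
    lam_of_pH, LYSOZYME.D, pH_grid=np.arange(2.0, 12.5, 1.0), noise=0.15, seed=seeds[0]
)
pd.DataFrame(
    {
        "pH": [m.pH for m in ms],
        "ionic_strength_mM": [m.I * 1e3 for m in ms],
        "mobility_umcmVs": [m.mobility for m in ms],
        "sd": [m.sd for m in ms],
    }
).to_csv(OUT / "mobility_titration.csv", index=False)

# 2. SAXS: dilute reference + dense profiles, peak at 0.03 1/A above 2.5 wt %
profiles = syn.gen_saxs_profile(
    D=LYSOZYME.D,
    L=LYSOZYME.L,
    c_list=[1.0, 1.5, 2.0, 3.0, 4.0, 5.0],
    peak=(0.03, 0.6, 0.005),
    peak_min_c=2.5,
    noise=0.02,
    seed=seeds[1],
    q=np.geomspace(8e-4, 0.3, 250),
)
for prof in profiles:
    np.savetxt(
        OUT / f"saxs_{prof.c:.1f}wt.dat",
        np.c_[prof.q, prof.I, prof.sigma],
        header="q_Angstrom_inv I sigma",
    )

# 3. FRAP: six independent tactoid traces at SNR 10
for j in range(6):
    tr = syn.gen_frap_trace(
        A=0.42, C=0.30, tau=5.0, acq_decay=0.005, noise=0.10,
        n_frames=160, dt=0.25, n_pre=20, seed=seeds[2] + j,
    )
    path = OUT / f"frap_trace_{j}.csv"
    with open(path, "w") as fh:
        fh.write(f"# bleach_index: {tr.bleach_index}\n# roi_radius_um: {tr.omega}\n")
        pd.DataFrame({"t_s": tr.t, "T1": tr.T1, "T2": tr.T2, "B": tr.B}).to_csv(
            fh, index=False
        )

# 4. WLC contours (rigid regime, Lp/Lc ~ 10)
traces = syn.gen_wlc_contours(Lp=2000.0, Lc_range=(100.0, 600.0), n=500, seed=seeds[3])
rows = [
    {"fibril_id": tr.fibril_id, "x_nm": x, "y_nm": y}
    for tr in traces
    for x, y in tr.points
]
pd.DataFrame(rows).to_csv(OUT / "wlc_contours.csv", index=False)

# 5. phase observations around forward-modelled thresholds
I_in_of_pH = lambda pH: 0.02 * 10 ** (-0.18 * (pH - 2.0))
obs, labels = syn.gen_phase_observations(
    LYSOZYME,
    lam_of_pH,
    I_in_of_pH,
    pH_grid=np.arange(2.0, 8.5, 1.0),
    c_grid=np.arange(0.1, 4.01, 0.05),
    seed=seeds[4],
    jitter=0.03,
)
pd.DataFrame(
    [
        {
            "pH": o.pH,
            "c_wt_percent": o.c_mean,
            "c_min_wt_percent": o.c_min,
            "regime_label": o.regime_label,
        }
        for o in obs
    ]
).to_csv(OUT / "phase_observations.csv", index=False)
pd.DataFrame(labels).to_csv(OUT / "phase_labels.csv", index=False)

with open(OUT / "scenario.json", "w") as fh:
    json.dump(
        {
            "seed": SEED,
            "substream_seeds": seeds,
            "geometry": {"D_nm": LYSOZYME.D, "L_nm": LYSOZYME.L},
            "I_in_model": "0.02 * 10**(-0.18 (pH-2)) mol/L",
        },
        fh,
        indent=2,
    )

print(f"synthetic inputs written to {OUT}")
print(f"  mobility points: {len(ms)}; SAXS profiles: {len(profiles)}; "
      f"FRAP traces: 6; contours: {len(traces)}; phase rows: {len(labels)}")
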