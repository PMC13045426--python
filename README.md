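# fibrilphase

Phase behaviour of charged, rod-like amyloid fibril dispersions: a library
and analysis pipeline that maps solution conditions (pH, ionic strength,
concentration) onto the three regimes seen in lysozyme and
β-lactoglobulin fibril solutions — isotropic dispersion, liquid–liquid
crystalline phase separation (LLCPS, nematic tactoids) and liquid–liquid
phase separation (LLPS, disordered condensates).

It is written for soft-matter and protein-assembly researchers who want to
go from routine measurements (electrophoretic mobility, SAXS profiles,
FRAP traces, AFM contour traces, cross-polarized phase observations) to a
quantitative charged-rod phase diagram without re-deriving the theory each
time.

## The model

A dispersion of thin rigid charged rods (diameter *D*, length *L*) orders
into a nematic phase above the threshold volume fraction

```
φ_I-N = b₀ (1 − 0.75 h)⁻¹ · D² / (L · D_eff),      b₀ = 3.290
```

where the electrostatic double layer swells the excluded volume through an
effective diameter

```
D_eff = D + κ⁻¹ (ln A′ + C_E + ln 2 − ½),
A′    = 8π λ² Q e^(−κD) / (κ³ D² K₁²(κD/2)),
```

with λ the linear charge density (e/nm), Q the Bjerrum length (0.7 nm in
water at 23 °C), κ⁻¹ the Debye length, C_E Euler's constant, and the
twisting factor *h* = (κ D_eff)⁻¹ penalising parallel alignment of
screened charged rods. φ converts to weight percent via
c = 100·φρ_AF/[φρ_AF + (1−φ)ρ_w] with ρ_AF = 1.3 g/mL.

Fibril solutions dialysed against pH-adjusted water retain counterions
(Donnan partitioning), so the ionic strength inside the fibril phase
exceeds the nominal, pH-set value. `solve_internal_ionic_strength`
inverts the theory: it bisects I_in on [I_nom, 1 M] until the predicted
threshold matches an observed LLCPS start concentration.

Around this core the package provides:

- `electrolyte` — Bjerrum/Debye lengths, pH-set nominal ionic strength;
- `electrokinetics` — mobility → surface potential (orientation-averaged
  generalized Henry) → λ via the cylindrical nonlinear Poisson–Boltzmann
  equation;
- `pair_potential` — screened line-charge repulsion + nonretarded
  cylinder van der Waals attraction (Hamaker constant 3 kT), the parallel
  vs crossed Boltzmann weight P = e^(−(U∥−U⊥)/kT), and a spacing solver;
- `saxs` — orientation-averaged cylinder form-factor fitting, structure
  factors S(q) = I/(N·P), peak location, d = 2π/q*;
- `frap` — double normalization, I(t) = A(1 − e^(−t/τ)) + C fitting,
  τ½ = τ ln 2, D_app = 0.88 ω²/(4 τ½), mobile fraction;
- `morphometry` — contour statistics and 2-D worm-like-chain persistence
  length from ⟨R²⟩(L_c);
- `synthetic` — seeded generators for all five input channels;
- `pipeline` — file-level stages driven by the numbered scripts in
  `analysis/`.

## Worked example

The central solve: at pH 2.0 lysozyme fibrils (D = 20.9/5.4 ≈ 3.87 nm,
L = 95 D, λ = 3.0 e/nm) begin LLCPS at 1.49 wt %. What internal ionic
strength is consistent with that?

```python
from fibrilphase import phase_model as pm
from fibrilphase.electrolyte import SolutionConditions
from fibrilphase.geometry import LYSOZYME

cond = SolutionConditions(pH=2.0)
I_in = pm.solve_internal_ionic_strength(1.49, LYSOZYME, 3.0, cond)
pred = pm.predict_threshold_concentration(LYSOZYME, 3.0, cond.with_internal(I_in))
print(f"I_in = {I_in*1e3:.1f} mM, D_eff = {pred.params.D_eff:.1f} nm, "
      f"h = {pred.params.h:.3f}, prefactor = {pred.params.prefactor:.3f}")
```

prints

```
I_in = 19.5 mM, D_eff = 13.3 nm, h = 0.163, prefactor = 3.750
```

i.e. the fibril phase holds ≈ 19.5 mM of ions against a 10 mM nominal
bath, the double layer swells the effective diameter to 3.4 × the bare
one, and the composite threshold prefactor b₀/(1 − 0.75 h) evaluates to
3.750. Running the full observation set (`analysis/03_phase_diagram.py`)
shows I_in falling from 19.5 mM at pH 2 to 1.6 mM at pH 7 while D_eff
grows from 13 to 36 nm — weaker screening lowers the ordering threshold,
which is why the LLCPS start concentration drops with pH until, near the
isoelectric point (λ ≲ 1 e/nm), attraction takes over and LLPS appears.

The numbered scripts under `analysis/` run the whole chain on seeded
synthetic inputs (`01_simulate_inputs.py` → `07_morphometry.py`), writing
tables under `results/`.

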