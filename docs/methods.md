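# Methods

This note records the models implemented in `fibrilphase`, the choices
made where the formulation was genuinely open, the numerical machinery,
and what the synthetic-data tests do and do not demonstrate.

## Electrolyte groundwork

Water adjusted to a target pH with HCl (below 7) or NaOH (above 7) and no
added salt has nominal ionic strength I_nom = ½Σz²c over H⁺, OH⁻ and the
strong-electrolyte counterion fixed by electroneutrality; the ion product
is held at 10⁻¹⁴ (single working temperature, 23 °C) so I_nom is exactly
symmetric about pH 7. Defaults: T = 296.15 K, ε_r = 78.4, η = 0.933 mPa·s,
all overridable through `RunConfig`. With CODATA constants the Bjerrum
length at these defaults is 0.7197 nm, which rounds to the conventional
0.7 nm. Activity coefficients are ignored throughout (dilute regime,
consistent with the Debye–Hückel level of the rest of the theory).

## Electrokinetics

Measured mobilities are orientation averages over freely rotating rods,
µ = (µ∥ + 2µ⊥)/3, with µ∥ the Smoluchowski result and µ⊥ carrying
Ohshima's closed-form generalized Henry factor
f(κa) = ½[1 + (1 + 2.55/(κa(1+e^(−κa))))⁻²], which interpolates between
the transverse-cylinder Hückel limit (½) and the Smoluchowski limit (1).
Relaxation (Dukhin) corrections are omitted — the framework is
Henry-level by construction. The mobility–potential relation is linear,
so its inversion is algebraic.

Surface potential converts to surface charge by solving the full
cylindrical nonlinear Poisson–Boltzmann equation for a 1:1 electrolyte,
y'' + y'/r = κ² sinh y, as a two-point boundary-value problem between the
surface r = D/2 and r = D/2 + 50 κ⁻¹ (relative tolerance 10⁻⁸, collocation
with a Debye–Hückel initial guess and continuation in steps of ≤ 2 kT/e
for strongly charged surfaces). Gauss's law at the surface gives
σ = −y'(a)/(4πQ) in e/nm² and λ = πDσ. For ψ₀ ≤ 5 mV the solve agrees
with the Debye–Hückel closed form λ_DH ∝ ψ₀ κ K₁(κa)/K₀(κa) to well
under 1%; at 100 mV the nonlinear solution carries visibly more charge
(charge saturation), as it must.

## The charged-rod ordering threshold

The isotropic–nematic (LLCPS) threshold is

φ_I-N = b₀ (1 − 0.75 h)⁻¹ D²/(L D_eff),

with b₀ = 3.290 the isotropic-branch coexistence constant of the hard-rod
theory (the alternative 3.340 is selectable in `RunConfig`), so the
neutral hard-rod limit φ = b₀ D/L is recovered exactly when the clamp
D_eff = D engages and h → 0. D_eff and A′ are as printed in the README;
the effective diameter is clamped below at the bare D because a smaller
excluded volume than the hard core is unphysical. The twisting correction
diverges at h = 4/3; states beyond it raise an out-of-regime error rather
than returning a number.

The weak-charge condition λQ < 1 behind the Debye–Hückel amplitude is
violated at pH 2 (λQ ≈ 2.1). The bare λ is nevertheless used in A′, in
fidelity to the model as stated; a charge-renormalization hook is the
natural extension but is deliberately not implemented.

### Donnan inversion

c_theory(I_in) is strictly increasing over the physically relevant range
(more screening → smaller D_eff → higher threshold), so matching an
observed LLCPS start concentration is a bracketed root-find on
[I_nom, 1 M] (relative tolerance 10⁻⁶ on concentration). At very high I
the D_eff clamp makes c_theory saturate; the solver detects the end of
the rising branch on a coarse scan and restricts the bracket to it. The
solved I_in for the lysozyme observation set decreases monotonically from
≈ 19.5 mM (pH 2) to ≈ 1.6 mM (pH 7), the expected signature of
counterion washout as the fibril charge falls.

### The composite prefactor

The threshold prefactor is reported as b₀/(1 − 0.75 h). A noteworthy
structural property of the formula chain: under the constraint that
c_theory matches a fixed observation, κD_eff — and hence h — is almost
independent of the matched I_in (h ≈ 0.163 across two decades of ionic
strength at the pH 2 lysozyme conditions), so the composite prefactor is
pinned near 3.75 and the twist correction alone, (1 − 0.75 h)⁻¹, near
1.14. Both numbers are surfaced in the phase-diagram table and by
`scripts/acceptance.py`.

## Pair potentials

Electrostatics: screened line-charge results with the cylinder-corrected
effective line charge λ_eff = λ e^(−κD/2)/((κD/2)K₁(κD/2)), which ties to
the phase model exactly through A′ = 2π λ_eff² Q/κ (machine-precision
identity, tested). Parallel rods: U∥/kT = 2 L λ_eff² Q K₀(κx) over the
full length L (end effects ignored; L ≫ κ⁻¹). Crossed rods at angle θ:
U(θ)/kT = (2π λ_eff² Q/κ) e^(−κx)/sin θ, which at θ = 90° is A′ e^(−κx).
x is centre-to-centre everywhere.

Van der Waals: nonretarded near-contact (Derjaguin) closed forms with
surface separation s = x − D and R = D/2 — parallel
−(A_H L/(12√2 s^{3/2}))√(R/2), crossed −A_H R/(6 s sin θ) — with
A_H = 3 kT by default. These are asymptotic forms valid for s ≪ R. A
brute-force pairwise Hamaker integration oracle (the 6-D r⁻⁶ volume
integral reduced analytically to 2-D/3-D quadratures, itself validated
against the exact thin-rod far field −3πA R⁴/(8x⁵) per unit length)
confirms both forms to within 5% at s/R ≤ 0.01, and equally shows that at
s ≳ R they overestimate the attraction by one to two orders of magnitude.
They are used at all separations regardless, as the conventional
benchmark forms in this field; quantitative statements at s ≳ R should be
read accordingly.

The orientation statistic is P = e^(−(U∥−U⊥)/kT), evaluated in log space
(near contact ΔU can exceed 700 kT and e^(−ΔU) underflows). P(x) is
non-monotone in general — van der Waals attraction dominates near
contact, screened repulsion at intermediate x, and P → 1 from below far
out — so the spacing solver bisects only on a monotone bracket, asserted
at runtime; `rising_branch_bracket` locates the natural one.

At the pH 2.0 self-consistent state (I_in ≈ 19.5 mM, κ⁻¹ ≈ 2.2 nm) the
screened electrostatics at x = 5.4 D ≈ 20.9 nm are essentially fully
decayed (κx ≈ 9.6), so the parallel/perpendicular asymmetry there is set
by the van der Waals difference and P(5.4 D) ≈ 2.2; appreciably
charge-dominated asymmetry at that distance requires κ⁻¹ ≳ 4 nm, i.e.
internal ionic strengths below the pH 2 nominal value, which the Donnan
constraint I_in ≥ I_nom excludes. At pH 3–6, where the solved I_in is in
the single-mM range, the P = 0.012 spacing solution exists and moves
outward with pH (x/D ≈ 4.6 → 6.7), reproducing the qualitative trend of
increasing inter-fibril spacing with decreasing screening.

## SAXS

The form factor is the orientation-averaged rigid cylinder,
⟨[2J₁(qR sin α)/(qR sin α) · sinc(qL cos α/2)]²⟩ evaluated by fixed
256-node Gauss–Legendre quadrature (10⁻⁴ relative agreement with adaptive
quadrature, tested), scaled by V² so the forward limit is scale·V².
Fitting is weighted least squares with D, L and scale in log space — the
linear parameterization has a pathologically ill-conditioned scale/L
valley — and a deterministic multi-start ladder on L (×0.5, 1, 2, 4)
because the axial sinc lobes create local minima when the q range does
not reach the Guinier region. With q_min L/2 ≲ 2 recovery from noise-free
data is exact; on a grid with q_min L/2 ≫ 1, L is weakly constrained and
only D should be trusted (the fit reports both regardless).

S(q) = I_dense/(N_ratio · I_ref) on the reference grid, with the dense
profile interpolated and out-of-range reference points refused. Peak
location applies light Savitzky–Golay smoothing (window 9, order 3) and
takes the analytic maximum of a cubic-spline interpolant inside the
window (default 0.01–0.04 Å⁻¹); edge maxima and peaks of prominence
below 10⁻⁶ raise a no-peak error. q is Å⁻¹ at every I/O boundary and
nm⁻¹ internally; d = 2π/q* with the Å → nm conversion asserted by test.

## FRAP

Double normalization I_t = [(T1−B)/(T1₀−B₀)]/[(T2−B)/(T2₀−B₀)] cancels
any acquisition decay common to both ROIs exactly. The time-0 reference
values are averaged over all pre-bleach frames rather than taken from a
single frame: a single noisy reference frame injects a common
multiplicative error of order the acquisition noise into the entire
curve, which at SNR 10 dominates every parameter error; with noise-free
data the two conventions coincide (I = 1 exactly at the last pre-bleach
frame). The recovery fit I(t) = A(1 − e^(−t/τ)) + C runs on post-bleach
frames only with time re-zeroed at the bleach (the model has no bleach
transient), endpoint-based initial values, and A ≥ 0. The plateau is
taken from the fit (I_∞ = A + C), not the last frame. τ½ = τ ln 2 and
D_app = 0.88 ω²/(4τ½) with ω the ROI radius (default 1.5 µm, a 3 µm
bleach spot). Documented recovery tolerances on synthetic traces: exact
at zero noise; τ within ~10% (median over traces) at SNR 30 with 60
frames; at SNR 10 single-trace τ is information-limited (spread ~20–30%),
so the pipeline reports ensemble medians over several independent traces,
as multi-tactoid experiments do, which brings all four parameters within
10%.

## Morphometry

Persistence length comes from the 2-D equilibrated worm-like-chain
relation ⟨R²⟩ = 4LpLc[1 − (2Lp/Lc)(1 − e^(−Lc/2Lp))], the appropriate
convention for fibrils equilibrated on mica before AFM imaging; the
projected-3-D variant is available behind a flag. Traces are binned by
contour length (quantile bins), bin-mean R² fitted by least squares
weighted with bin counts, and the confidence interval obtained by seeded
bootstrap over traces (default 200 resamples). Rigid ensembles drive
Lp far beyond the longest contour (flagged by magnitude rather than by a
special value); a single-contour-length ensemble is ill-conditioned and
warns but still returns the point estimate.

## Synthetic data

The generators are first-class code and define the conditions every
recovery test runs under; all take explicit seeds and are byte-identical
under a fixed seed, with scenario bundles fanning one root seed into
per-channel substreams.

- WLC contours: fixed-step chains with Gaussian turning angles of
  variance δs/Lp (tangent correlation e^(−s/2Lp)); ensemble ⟨R²⟩ agrees
  with the closed form within Monte-Carlo error (tested at 3 s.e.).
- SAXS: cylinder form factor times an optional Gaussian correlation peak
  (defaults q₀ = 0.03 Å⁻¹) on dense members only, multiplicative
  log-normal noise (detector intensities are positive with roughly
  constant relative error); default grid q ∈ [10⁻³, 0.3] Å⁻¹ so the
  reference member constrains L.
- FRAP: three-ROI traces sharing an exponential acquisition decay; the
  `noise` parameter is exactly the standard deviation of the normalized
  intensity (SNR = 1/noise).
- Mobility: full forward electrokinetic model (PB inversion included)
  plus additive Gaussian noise; a sign change in λ(pH) produces the
  isoelectric sign change in mobility.
- Phase observations: forward-predicted thresholds with log-normal
  observation jitter and a concentration-grid observation window; the
  extracted start concentrations bracket the generating thresholds, and
  rows with λ ≤ 1 e/nm are labelled LLPS.

What these tests show: the estimators invert their own forward models at
realistic noise levels, the theory chain is internally consistent, and
every identity and limit holds. What they do not show: that real fibril
data obey the models — real SAXS has polydispersity and instrument
smearing (not modelled; the form factor is monodisperse by design), real
FRAP has bleach-profile and diffusion-during-bleach corrections beyond
the 0.88 factor, real contours carry tracing noise, and real mobility
data include end and relaxation effects outside Henry-level theory.

## Known limitations

- The threshold theory is second-virial level with the (1 − 0.75 h)⁻¹
  twist approximation; no nematic-branch concentration, coexistence gap,
  or cholesteric pitch.
- Bare λ in A′ beyond its weak-charge domain at low pH (see above).
- Derjaguin van der Waals forms used outside their s ≪ R regime, as is
  conventional; absolute attraction magnitudes at large spacing are
  overestimates.
- Monodisperse rods: one (D, L) per dispersion; length and diameter
  polydispersity shift thresholds in reality.
- The LLPS boundary is a heuristic classifier (λ ≤ 1 e/nm and above
  onset), not a free-energy calculation.
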