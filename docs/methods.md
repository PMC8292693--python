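# Methods

This note documents the models implemented in `carbonpbs`, the choices made
where the design was open, what the synthetic-data generator emulates, and
the numerical conventions. Units throughout: lengths mm, doses Gy (physical)
or GyE (biological/clinical), LET keV/µm, angles rad. Depth `z` is
water-equivalent depth from the phantom surface; lateral coordinates are at
the isocenter plane with the beam along +z.

## Physical dose model

Dose is a superposition of pencil beams, each the sum of three laterally
Gaussian components: the primary ¹²C core and two fragment-halo terms. Each
component contributes `IDD_n(z) · G_n(x, y; σ_n(z))`, where the IDD
(integral depth dose, Gy·mm²/MU) is the plane-integrated dose at depth z for
one beam and `G_n` integrates to one over the plane, so absolute dose is
carried entirely by the IDDs.

**Primary depth dose.** `IDD_12C(z) = Φ₀ 2^(−z/λ) ∫ N(z′−z; σ_strag)
S(R₀−z′) dz′`. The attenuation half-length λ encodes the total nuclear
cross section (λ ∝ 1/σ_tot). When a scored curve used the wrong cross
section, the primary curve is corrected pointwise by
`2^(−z/λ′)/2^(−z/λ)` and the fragment curve by the constant `λ/λ′`
(fragment production scales linearly with the cross section). The
convolution uses trapezoid quadrature on a ±5σ window with step
min(0.25 mm, σ/5); the end-of-range singularity of S(r) ∝ r^(1/p−1) is
capped at r = 0.05 mm inside the quadrature (the straggling kernel smooths
it; the cap moves the peak by far less than the straggling width).

**Absolute scale.** A uniform-grid irradiation measures the dose-area
product DAP = D·Δ²/Q at 2 cm depth; all curves are scaled so the
chamber-side total IDD equals the DAP there. Because this renormalizes
everything, the fluence normalization convention before scaling is
immaterial.

**Chamber convention.** The large-area chamber (radius R = 60 mm) misses
part of the 25-mm third component: ε = 1 − exp(−R²/2σ₃²) ≈ 0.944. Stored
curves keep both conventions: `idd_frag` is the chamber-side fragment curve
(= IDD₂ + ε·IDD₃ once absolute), while `idd2`/`idd3` are the engine-side
curves used for dose.

**Lateral model.** The primary width follows Fermi–Eyges transport of the
second moments (σ₁₁, σ₁₂, σ₂₂) per axis, with the angular increment per
water step Δθ² = C·Z^(−0.16)·A^(−0.92)·ln(R/R′), C = 0.0015. In-water
transport uses 1-mm steps with the local residual ranges (a 10-mm step
agrees within 1%). The halo widths are σ₂(z) = C₁ below z_p − C₂ and
√(C₁² + C₃(z−z_p+C₂)²) beyond (C₁ = 5 mm, C₂ = 30 mm, C₃ = 0.006), and
σ₃ = 25 mm fixed. IDD₃(z) builds up as C₄(1−e^(−z/C₅)) and decays beyond
the peak with length C₆·z_p (C₄ = 21 Gy·mm²/MU, C₅ = 500 mm, C₆ = 1.5).
The two typographically ambiguous groupings (C₃ multiplying the squared
offset; C₆·z_p as the decay length) are each isolated in a single function
(`lateral.sigma2`, `lateral.idd3`) so the alternative reading is a one-line
change. The adopted σ₂ grouping yields halo growth of ~15–25 mm over 30 cm,
the plotted scale of the source data; C₃²-scaling would give <1 mm.
Range shifters of water-equivalent thickness L shift the fragment depth
curves (`IDD₃(z; L) = IDD₃(z+L)`) and widen σ₂ by the same squared-size
increment as the first component: σ₂(z;L)² = σ₂(z+L)² + σ₁(z;L)² − σ₁(z+L)².
A negative radicand (possible with noisy σ₁ inputs) clamps to σ₂(z+L) with
a warning. z_p denotes the *dose-peak* depth (the Bragg peak), which sits
about one peak-offset (~2 mm here) upstream of the mean range because the
stopping power rises toward the end of range.

**Engine numerics.** Voxel-center sampling; Gaussians truncated at 5σ
(components 1–2) and 4σ (component 3), configurable via
`engine.CUTOFF_SIGMA`. In homogeneous media the per-layer spot sum
factorizes into separable x/y Gaussian matrices, evaluated as one matrix
product per component per slice. Phase-space splitting of the first
component uses a fixed 19 sub-beams (center + rings of 6 and 12 at 0.599σ
and 1.449σ, width 0.75σ); the ring radii and non-negative weights were fit
once to the unit 2-D Gaussian and reproduce it within 0.7% wherever the
profile exceeds 5% of its peak, at every depth (offsets and widths scale
with the local σ). Heterogeneity handling is limited to water-equivalent
depth scaling along the central axis (`wepl_along_axis`, midpoint sampling
at a tenth of the voxel spacing); full 3-D heterogeneity splitting is out
of scope.

## Beam modeling (library construction)

Per beam: (1) fit λ′ by least squares between the corrected scored total
and the chamber curve (bounded scalar minimization on [60, 400] mm);
(2) normalize to the DAP; (3) recover the isocenter phase space from in-air
sizes at z = −200/0/+200 mm — in air σ²(z) is an exact quadratic, so the
moments follow from finite differences, and non-physical solutions
(negative angular variance or determinant) raise a fit failure.

Fragment parameters come from frame-pattern irradiations: hollow square
frames (patterns A–G, 3-mm spacing, counts 81…360) with the center dose
measured at seven depths per beam — five proximal of the peak and two
beyond it (fractions 0.2…1.5 of the peak depth; the distal points are what
constrain the IDD₃ decay constant). Per depth, the known first-component
contribution is subtracted and (IDD₂, IDD₃, σ₂, σ₃) fitted by bounded
nonlinear least squares on relative residuals with three seeded starts;
a second pass fixes σ₃ = 25 mm (its fitted values are depth-independent).
The per-depth values are then condensed into the analytic σ₂ and IDD₃
models by global least squares across beams, using each beam's estimated
peak depth (quadratic refinement of the corrected primary curve's maximum).
Fit weights are relative throughout because agreement is judged in percent.

IDNF (per-beam integral-dose normalization factors) solves a bounded linear
least-squares problem on the relative residuals between calculated and
measured mid-SOBP doses across volume-irradiation cases, one factor per
(energy, shifter) beam, bounds [0.9, 1.1]; a beam in no case keeps factor 1
with a warning. The estimator choice (least squares across cases rather
than per-beam averaging) is ours; the two coincide for single-beam cases.

LQ survival fitting is non-negative-β linear least squares on
−ln SF = αd + βd², no intercept (SF(0) = 1 by construction).

## Biological model

Mixed fields dose-average α and β over beam contributions. The second
Gaussian component carries both carbon isotopes (¹¹C etc.) and Z ≤ 5
fragments; the scored ratio R(z) splits it: d^(C) = d^(1) + (1−R)d^(2),
d^(frag) = R·d^(2) + d^(3). This partition conserves the triple-Gaussian
total by construction (the typeset source formula would not; we treat that
as a typesetting loss and use the conserving form). Carbon α comes from a
directly scored dose-averaged α(z) (the LET spectrum near the peak is too
broad for a point lookup); carbon β and both helium coefficients are looked
up at the beam's dose-averaged LET (linear interpolation, endpoint-clamped).
β is dose-averaged directly; a √β-averaging convention is available via
`mix_lq(..., beta_mode="sqrt")` since some mixed-field formulations use it.

Event-based scoring: dose-averaged LET is the deposit-weighted mean
stopping power over filtered events (Z = 6 for carbon, Z ≠ 6 for
fragments); dose-averaged α applies the α(LET) map per event first.
Non-carbon species use (Z/6)²-scaled carbon stopping power at the same
energy per nucleon — a stand-in adequate for the synthetic event mixtures.
Empty filtered sets return NaN (flagged missing), as does R(z) with no
secondary deposit and RBE at zero physical dose.

Photon-equivalent dose inverts the photon LQ in closed form,
d_bio = (√(α_X²+4β_X e) − α_X)/(2β_X) with α_X = 0.33 Gy⁻¹,
β_X = 0.06 Gy⁻², exact to 10⁻¹⁰ over 0–20 Gy; d_clin = 1.46·d_bio. At the
fixed 10%-survival effect E = −ln 0.1 these are 4.03 and 5.88 GyE.

The shipped LQ(LET) tables are synthetic stand-ins (piecewise linear,
carbon α rising to a plateau near 150–200 keV/µm, helium lower and flatter,
β slowly declining); the published curves are not tabulated anywhere we can
read them from. Consequently absolute RBE values from the default tables
are not facility values — tests that need absolute numbers use the printed
mid-SOBP LQ constants (α = 0.77 Gy⁻¹, β = 0.074 Gy⁻²) instead, and
RBE-related checks on the synthetic library are trend-based (RBE falls
monotonically as SOBP width grows).

## Planning

Layers sit on the 3-mm range ladder spanning [range − width, range]; the
lateral lattice is 3-mm with a 6-mm margin around the square field. Spots
within a layer share one weight (the lattice is uniform, so lateral
flatness is by construction) and goal points lie on a 2-mm central-axis
grid. The goal grid stops 4 mm short of the nominal range: the flat region
physically ends at the deepest constituent Bragg peak (~2 mm upstream of
the range) plus a ripple-filter width of transition. The objective
F = Σ(e_i − E)² plus a one-sided OAR penalty Σ max(0, e_i − E_OAR)² — the
OAR penalty form is our choice; only the OAR goal effect itself is
prescribed. Because α_i d_i and β_i d_i are linear in the weights, e is a
quadratic form and the gradient is analytic; L-BFGS-B with w ≥ 0 runs to a
relative-F tolerance of 1e-8 or 500 iterations, returning the best iterate
with a flag on non-convergence. Minimum-MU deliverability constraints are
out of scope.

Prescription scaling multiplies every weight by F_scale = D_pres/5.88 GyE.
Reported doses follow the planning convention: physical, biological and
clinical dose scale linearly with F_scale and the RBE stays at its
10%-survival value (the LQ-exact effect at the scaled dose would differ;
the linear convention is the one the planning chain defines). Depth
profiles therefore evaluate the effect at the 10% level
(weights / F_scale) and scale doses linearly.

## Synthetic data generator

The generator replaces Monte Carlo scoring and facility dosimetry with a
closed-form truth model so the full modeling chain is exercised end to end:

* Range–energy: R = kE^p with p = 1.795 and k fixed by R(430 MeV/n) =
  300 mm (this also gives R(140) ≈ 40 mm). Stopping power follows
  analytically; 1 MeV/mm in water equals 1 keV/µm, giving entrance LET
  ≈ 9.6 keV/µm at 430 MeV/n. Air mass stopping power is approximated by the
  water value (they agree to a few percent), which puts K(430 MeV/n) at
  ≈ 4.7×10⁷ particles/MU against the 5×10⁷ design figure.
* Attenuation: truth λ = 150 mm; the raw scored curves deliberately use
  λ = 170 mm and fragment curves scaled by 150/170, so the correction step
  of the modeling chain must actually recover λ′.
* Straggling: σ = max(0.012·R^0.935, 1.8) mm. The floor emulates the ripple
  filter that broadens pristine peaks: the facility stacks layers at 3-mm
  range steps, which is only ripple-free if the effective peak width is
  ≳1.6 mm (with sub-mm straggling the stacked effect ripples by ±8%).
  1.8 mm is a plausible Gaussian-equivalent width for a 3-mm ripple filter
  and keeps stacked-SOBP effect ripple below 1% on a fine depth grid.
* Fragment curves: IDD₃ from the analytic model with the printed constants;
  IDD₂ is an independent saturating build-up (amplitude 50 Gy·mm²/MU,
  half-length 150 mm, 25-mm distal tail) so that fragments carry ~10–15% of
  the dose near the peak. The chamber curve is IDD₁ + IDD₂ + ε·IDD₃.
* Optics: isocenter spot size 2.5 + 250/R mm (≈3.3 mm at 300 mm range,
  ≈9 mm for the shallowest beams), angular variance 2.25×10⁻⁶ rad², the y
  waist 100 mm upstream; shifters act as thin scatterers 400 mm upstream.
* Default ladder: 12 energies with ranges 300 down to 36 mm in 24-mm steps,
  shifters 0–21 mm in 3-mm steps — a contiguous 3-mm range ladder.
* Events: species mixture (primary ¹²C, ¹¹C, Z = 1..5) with depth-dependent
  proportions tied to the attenuated fluence; energies uniform ±20% around
  species means; deposits S(E)·(Z/6)²·1 mm. All generators are
  deterministic under a fixed seed.

What passing tests do and do not show: the roundtrip tests demonstrate that
the modeling chain recovers the generating model exactly in form and within
2% in dose under realistic noise-free measurements, and within stated
tolerances under 1% noise. They do not validate the analytic forms against
real beams — the truth model satisfies the fitted forms by construction
(except the ¹²C peak-anchor offset, which the chain must estimate), which
is precisely what makes parameter recovery a well-posed check of the
procedures rather than of the physics.

## Known limitations

* Single-Gaussian primary (no Molière tails); fixed sub-beam count.
* Heterogeneity only via central-axis WEPL; no CT/DICOM integration.
* LQ(LET) tables are stand-ins; absolute RBE from the defaults is not a
  facility value.
* Single-field optimization only; multifield plans are summed, not jointly
  optimized.
* No monitor recombination or temperature/pressure corrections; no
  minimum-MU spot constraints.

## Problem sizes used in the shipped tests

The test suite runs the full chain on a three-energy ladder (24 beams,
ranges 129–201 mm), frame fits on the three shifter-free beams
(7 depths × 7 patterns each), and SOBP optimizations with up to ~40 layers
on the full 96-beam default library; the whole suite completes in well
under a minute on one CPU.
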