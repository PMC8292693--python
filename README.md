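# carbonpbs

Physical and biological beam modeling for carbon-ion pencil-beam scanning:
a triple-Gaussian dose engine, the beam-modeling procedures that build its
beam library from measurements, a mixed-field linear-quadratic (LQ)
biological model, and single-field SOBP spot-weight optimization.

## Who this is for

Medical physicists and researchers who need a transparent, tested
implementation of the carbon-scanning dose-calculation chain: from monitor
units and integral depth doses through fragment-halo modeling to
photon-equivalent ("clinical") dose and RBE. A synthetic-data module stands
in for Monte Carlo scoring and facility dosimetry, so every procedure runs
and is verifiable end to end without external data.

## The model

Physical dose at point *i* from spots *j* with weights *w_j* (in monitor
units, MU):

    d_i = Σ_j w_j Σ_{n=1..3} IDD_n(z) · G_n(x_i − x_j, y_i − y_j; σ_n(z))

* **IDD_n(z)** — integral depth dose of component *n* (Gy·mm²/MU).
  The primary ¹²C component is an attenuated fluence, Φ₀·2^(−z/λ), times the
  range-straggled stopping power S(R₀ − z); the two fragment-halo components
  follow analytic depth models (saturating-exponential IDD₃ with constants
  C₄, C₅, C₆; IDD₂ obtained by decomposing the chamber fragment curve with
  the chamber detection efficiency ε = 1 − exp(−R²/2σ₃²)).
* **G_n** — normalized lateral Gaussians: anisotropic σ₁ₓ, σ₁ᵧ from
  Fermi–Eyges transport of the measured phase space (σ₁₁, σ₁₂, σ₂₂) with the
  Kanematsu scattering power Δθ² = C·Z^(−0.16)·A^(−0.92)·ln(R/R′); hyperbolic
  σ₂(z) with constants C₁, C₂, C₃; fixed σ₃ = 25 mm.
* **Monitor units** — 1 MU = 25 nC of collected monitor charge; particles
  per MU K = Q/(G·e) with gain G = (S/ρ)·d·g/W.
* **Biology** — survival S = exp(−αd − βd²) with dose-averaged mixing over
  beams; the second component's dose is split between carbon isotopes and
  lighter fragments by the scored ratio R(z); carbon α comes from a directly
  scored depth curve, other LQ coefficients from LET tables. The biological
  dose d_bio inverts the photon LQ (α_X = 0.33 Gy⁻¹, β_X = 0.06 Gy⁻²),
  d_clin = 1.46·d_bio, RBE = d_clin/d_phys at fixed 10% survival
  (E = −ln 0.1).
* **Planning** — spot weights minimize F(w) = Σ_i (e_i − E)² over target
  points (L-BFGS-B, analytic gradient); the plan is then scaled to the
  prescription by F_scale = D_pres / 5.88 GyE. The spot file always carries
  F_scale in its header — without it the clinical dose cannot be reproduced.

## Worked example

```
$ carbonpbs synth make-beamlib --seed 0 --small --out lib
wrote 24 beams to lib (seed=0)

$ carbonpbs plan optimize --beamlib lib --range 150 --sobp 45 --field 40 \
      --prescription 3.6 --out-spots spots.txt --out-profile profile.tsv
F_scale = 0.61218
effect flatness: max |e/E - 1| = 0.0052 over 21 goal points
wrote depth profile -> profile.tsv
```

The optimizer flattened the biological effect to within 0.5% of
−ln(0.1) ≈ 2.303 across the SOBP (depths 105–146 mm). The 10%-survival
clinical dose is always 1.46 × 4.03 = 5.88 GyE, so prescribing 3.6 GyE gives
F_scale = 3.6/5.88 = 0.612, which scales every spot weight and is recorded
in the spot-file header. Evaluating the scaled plan at mid-SOBP
(z = 127.5 mm):

```python
from carbonpbs import io, planning
lib = io.read_beam_library("lib")
plan = io.read_spot_list("spots.txt")
prof = planning.depth_profile(plan, lib, [127.5])
# dose=2.352 Gy, d_clin=3.601 GyE, RBE=1.531
```

The clinical dose matches the prescription; the RBE is the fixed
10%-survival value (its absolute size depends on the LQ(LET) tables, which
ship as clearly labeled synthetic stand-ins — load facility tables for real
use).

Other commands: `carbonpbs beamlib model` (full modeling chain on synthetic
measurements), `dose calc`, `frame fit`, `idnf calibrate`, `bio profile`,
`report`.

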