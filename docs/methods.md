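# Methods

## Model

The package simulates a coarse-grained cell-density model of cortex–medulla
self-organization in the (inner) mouse thymus.  Four fields live on a fixed
periodic domain (2D or 3D):

* `rho_T` — self-reactive single-positive (CD4) thymocytes, μm⁻³
* `rho_Tstar` — activated (antigen-recognized) thymocytes, μm⁻³
* `rho_M` — medullary thymic epithelial cells (mTECs), μm⁻³
* `rho_C` — one effective medullary chemokine, nM

with the dynamics

```
∂t ρT  = D_T ∇²ρT  − ∇·(ρT v_C)  − k_r ρT ρM + p φ(ρM)   [− k_ex ρT]
∂t ρT* = D_T ∇²ρT* − ∇·(ρT* v_C) + k_r ρT ρM − d ρT*
∂t ρM  = D_M ∇²ρM  + k_b ρT* ρM (1 − ρM/K) − k_m ρM
∂t ρC  = D_C ∇²ρC  + k_e ρM − k_c ρC
∂t ρT0 = D_T ∇²ρT0 − ∇·(ρT0 v_C) + p_T0 φ(ρM) − k_ex ρT0
```

where `φ(ρM) = 1/(1 + (ρM/μ)²)` is a smooth cortex indicator (production of
SP thymocytes is restricted to regions of low mTEC density), and the
chemotactic drift is the Keller–Segel form with receptor-kinetics
sensitivity, `v_C = T χ(ρC) ∇ρC`, `χ(ρC) = K_offon/(K_offon + ρC)²`.

The optional fifth species `rho_T0` (self-tolerant thymocytes) shares the
motility and chemotaxis of the self-reactive cells but is never activated;
it leaves the organ at the slow exit rate `k_ex = 1/(120 h)` (a five-day
dwell time).  When the tolerant species is enabled, the same exit term is
also added to the self-reactive equation (`exit_term_on`), as the two
species are then compared within one consistent "localization" model.

Assumptions worth keeping in mind: cells are described by smooth densities
(no cell-scale granularity, hence smoother cortico-medullary junctions than
micrographs show); the domain is fixed and periodic (no capsule, no tissue
mechanics, no subcapsular zone); all mTEC subtypes are pooled into one
population; all medullary chemokines are pooled into one effective species;
dendritic-cell–driven deletion is implicit in the activated-thymocyte decay.

## Parameters

Wild-type defaults (package `ModelParams()`), units μm, h, μm⁻³, nM:

| symbol | value | meaning |
|---|---|---|
| D_C | 2.34e4 μm²/h | chemokine diffusivity |
| D_T | 2.4e4 μm²/h | thymocyte motility |
| D_M | 3 μm²/h | mTEC motility |
| T | 1e5 μm²/h | taxis strength |
| K_offon | 5 nM | receptor binding constant |
| p | 2.5e-6 μm⁻³h⁻¹ | SP thymocyte production |
| μ | 1e-4 μm⁻³ | cortex-indicator density scale |
| d | 1 h⁻¹ | activated-thymocyte deletion |
| k_r | 1.5e3 μm³h⁻¹ | activation (recognition) coefficient |
| k_b | 3e3 μm³h⁻¹ | mTEC birth coefficient |
| K | 7.5e-4 μm⁻³ | mTEC carrying capacity |
| k_m | 5e-3 h⁻¹ | mTEC decay |
| k_e | 6.67e4 nM·μm³h⁻¹ | chemokine emission (calibrated, below) |
| k_c | 10 h⁻¹ | chemokine decay |
| k_ex | 1/120 h⁻¹ | thymus exit (extended model) |
| L | 3000 μm | reference box side |
| t_max | 2000 h | reference simulated time (~12 weeks) |

**Chemokine-scale calibration.**  Because a single effective chemokine
stands in for many real ones, the emission coefficient `k_e` and taxis
strength `T` are effective parameters; only the combinations
`(k_e·K/k_c)/K_offon` (how saturated the receptor is inside mature medulla)
and `T/D_T` (drift vs. diffusion) matter for the dynamics.  The package
fixes the first combination to 1: a medulla at carrying capacity sustains a
local chemokine concentration equal to the receptor binding constant,
`k_e = K_offon·k_c/K = 6.67e4 nM·μm³/h`, placing the receptor at half
saturation inside the medulla — the operating point of maximal chemotactic
dynamic range.  `T` is kept at 1e5 μm²/h.  With this calibration the
wild-type point is linearly unstable both with and without chemotaxis, and
the chemotaxis knockouts reproduce the expected localization reversal.
`audit_units()` dimension-checks every term of the five equations under
this unit convention.

## Uniform states and linear stability

Nontrivial uniform steady states solve
`p φ(ρM) k_b (1 − ρM/K) = d k_m` (with a production-sharing correction when
the exit term is on); roots are bracketed by a dense scan over ρM ∈ (0, K)
and polished with Brent's method.  The mTEC-free branch has no finite
thymocyte density unless the exit term is on (constant production, no
sink), and is reported as such.  Note that ρM = 0 is locally absorbing —
the mTEC birth term is quadratic in ρM at low density (ρT* itself is
enslaved to ρM) — so pattern formation requires either a linear instability
of a nontrivial uniform state or finite-amplitude nucleation by seeds.

Linear stability of a uniform state against Fourier modes e^{iq·x} reduces
to a 4×4 eigenvalue problem per wavenumber: the reaction Jacobian, minus
q²·diag(D), plus the chemotaxis coupling `+ρ̄ T χ(ρ̄C) q²` from the
chemokine column into the two motile rows (a converging drift flux toward
chemokine maxima — aggregation).  Two reduced variants separate the
mechanisms: `no_chemotaxis` (T = 0) isolates the growth-induced
(Turing-type) instability carried by the mTEC–activated-thymocyte positive
feedback; `no_bistability` linearizes the mTEC proliferation in ρM about
the steady state (`k_b ρT* M̄ (1 − ρM/K)`), which preserves the fixed point
but removes the quadratic self-catalysis, isolating the chemotaxis-driven
(Keller–Segel) instability.  The `no_bistability` construction is this
package's own choice of a bistability-free reduction; other reductions are
possible.  At wild-type parameters the uniform state is unstable in the
full model and at T = 0, with fastest-growing wavelengths near 1.4 mm; the
(k_b, T) scan shows the chemotaxis-independent band at low k_b,
stabilization at large k_b when T = 0, and a chemotaxis-driven extension of
the unstable region at large T.

## Numerics

Spatial discretization is pseudospectral on a uniform periodic grid (real
FFTs); gradients, Laplacians and flux divergences are spectrally exact, and
the quadratic chemotaxis flux is dealiased with the 2/3 rule.  Time
stepping is first-order exponential IMEX (ETD1): diffusion plus every
constant-coefficient decay (d, k_m, k_c, k_ex) is integrated exactly via
the spectral propagator, while the remaining reactions and the chemotaxis
flux divergence are explicit.  Global convergence is first order in dt
(verified against fine-dt references), and measured exponential growth
rates of seeded Fourier modes match the linear stability analysis to
within 2%.

The step size adapts to `min(dt_max, 0.5·dx/max|v_C|, 0.25/max-reaction-
rate)` with dt_max = 0.1 h; in patterned states the advective CFL bound
dominates (dt ≈ 0.01–0.02 h at dx = 23.4 μm).

The grid must resolve the chemokine decay length `sqrt(D_C/k_c) ≈ 48 μm`;
grids with dx > 24 μm trigger a warning.  The mTEC front width
`sqrt(D_M/k_m) ≈ 24 μm` is of the order of one grid cell at the default
resolutions, so the spectral representation of ρM undershoots slightly at
fronts.  The dynamical state is kept in spectral space; real-space copies
(used for the nonlinear terms and all outputs) are clipped to non-negative
values and the clipped mass is logged per step (bounded in the test suite
below 1e-5 of the mTEC mass per step at dx = 23.4 μm in developed
patterns).  All recorded fields are non-negative.

## Initial conditions

**Seeds (default).**  The medulla grows from 300 small scattered regions of
mature medullary tissue in the reference (3 mm)^d box: smooth-edged solid
balls of diameter 60 μm at carrying-capacity density, positions drawn
uniformly in continuum coordinates (reproducible from the seed of the run,
independent of grid resolution); all other fields start at zero.  The seed
count scales with the domain volume for smaller boxes.  Two rasterization
rules keep this well defined numerically: (i) seeds narrower than 3·dx are
deposited at width 3·dx with amplitude rescaled to conserve each seed's
mass, and the rasterized field is rescaled so the deposited total equals
the analytic total exactly; (ii) the profile is a solid ball rather than a
tapered bump — a tapered bump of the same width carries ~5× less mTEC mass
and fails to nucleate in 3D: its activated-thymocyte level peaks well
below the k_m/k_b growth threshold and the seed dies (the 3D nucleation
race is marginal; in 2D both profiles nucleate).  Seed-amplitude
sensitivity is therefore substantial in 3D — seeds must carry roughly a
full ball of carrying-capacity tissue at 60 μm to take — and weak in 2D.

Two parameter regimes cannot nucleate from seeds in 3D at all in this
implementation (verified at fine resolution): the insular production rate
(p = 1e-6; thymocytes accumulate too slowly relative to seed decay) and
the extended localization model started with the exit term on (ρT is
capped at p/k_ex).  Insular morphologies are reproduced in 2D; the
localization statistics use the staged protocol below.

**Uniform + noise.**  Alternatively a run may start from the nontrivial
uniform steady state with 1% multiplicative noise, probing the linear
instability directly.  This requires the nontrivial branch to exist; at
the insular production rate (p = 1e-6) it does not (p·k_b < d·k_m), and
insular medullae exist only as nucleated, finite-amplitude structures.

**Fixed morphologies.**  For recognition-rate comparisons the mTEC field
can be frozen (`medulla_frozen`) in prescribed shapes — a centered sphere,
lamellae of given period, or a uniform field — with the interior density
set to the intra-medullary mean of a reference self-organized run and the
geometry solved so the total mTEC content matches that run exactly (the
rasterized field is rescaled so the match is exact on the grid).

## Morphometrics

* **Medulla mask / volume fraction φM** — `ρM > μ` (strict), mean of the mask.
* **Pattern length ℓ** — 2π/q̄ with q̄ the first moment of the *squared*
  radially averaged power spectrum of (mask − mean), q = 0 excluded.
  Squaring the shell spectrum suppresses the odd harmonics of thresholded
  (square-wave-like) patterns, which otherwise bias a plain first moment
  15–25% toward short lengths; the estimator recovers stripe periods within
  10% and checkerboard diagonal wavelengths within 15%.  A mean-chord-length
  alternative is available (`method="chord"`).
* **Connected components** — face adjacency with full periodic wrap.
* **Normalized covariance** — `C_AB = ⟨ρA ρB⟩/(⟨ρA⟩⟨ρB⟩) − 1` over the whole
  domain; 0 for uncorrelated fields, −1 for disjoint supports.
* **Medulla-to-cortex ratio** — mean density on the mask over mean density
  off the mask.
* **Effective recognition rate** — `k_rec = k_r ⟨ρT ρM⟩/⟨ρT⟩`, the
  volume-averaged recognition rate of self-reactive thymocytes; the
  model's proxy for negative-selection efficiency.
* **Predicted volume fraction** — equating total thymocyte production in
  the cortex, `p(1−φM)V`, with total deletion in the medulla,
  `d ρ̄T* φM V`, and pinning the medullary activated-thymocyte level by the
  mTEC balance `ρ̄T* = k_m/(k_b(1−ρ̂/K))` with the interior-density
  convention ρ̂ = K/2, gives `φM = κ/(1+κ)`, `κ = (p/d)·k_b(1−ρ̂/K)/k_m` —
  linear in p/d at low φM.  This is an order-of-magnitude balance; it is
  used for rank ordering across (p, d), not as a quantitative predictor.

## Experiments and problem sizes

Named experiments: `wt`, `wt_hi_turnover` (p, d ×10), `insular` (p = 1e-6),
`swiss_cheese` (p = 7e-6), `no_chemotaxis` (T = 0), `localization` /
`localization_no_chemotaxis` (exit term + tolerant species from t = 0),
`localization_staged` / `localization_staged_no_chemotaxis` (pattern grown
from seeds with the base model, then the exit term and tolerant species
switched on and equilibrated for 800 h ≈ 7 exit times — the protocol used
for localization statistics, since with the exit term on from the start
the capped thymocyte density cannot nucleate the medulla in 3D), `pd_scan`,
`sphere_krec`, `lamellae_krec`, `sphere_then_dynamics` (medulla frozen as a
sphere until t_switch = 3000 h, then cross-talk dynamics on until 6000 h).
Every experiment is reproducible from (name, overrides, rng seed) and emits
a manifest.

The package's reference study conditions are the 3 mm box at n = 256 (2D)
or n = 128 (3D).  The test suite and the acceptance script run desk-scale
versions chosen to keep dx ≤ 24 μm while fitting a laptop/CI budget:
2D n = 128, L = 3000 μm (printed-number reproduction and the
function-follows-form run, t_max = 2000 h); 2D n = 32, L = 750 μm (the 5×5
(p, d) scan, rates scanned upward from wild type so the pattern length
stays below the box size) with the joint-rate length-scale comparison in a
2D n = 64, L = 1500 μm box; 3D n = 24, L = 562.5 μm (scaled-down
morphology-class, localization-ratio and covariance checks).  Scalar
morphology metrics (φM, ratios, k_rec) are intensive and tolerate the
reduced boxes, although the covariance magnitudes are box-geometry
sensitive (the desk 3D box holds about one pattern wavelength); absolute
length-scale measurements near the box size saturate at the box scale and
are only compared across runs sharing a box.

## What the synthetic runs do and do not show

All inputs are synthetic: the model generates its own data from parameters
and seeded random initial conditions.  Passing tests therefore demonstrate
internal consistency — instability structure, morphology classes and their
parameter control, localization reversal under chemotaxis knockout, and
the morphology dependence of the effective recognition rate — under the
stated parameter reconstruction and calibration.  They do not validate the
parameter values against tissue, do not capture cell-scale interface
roughness, capsule/boundary effects, mTEC subtype structure, or repertoire
effects, and desk-scale boxes under-sample large-scale coarsening.

## Known limitations

* First-order time accuracy; stiff chemotaxis fronts cap dt via the CFL
  bound, dominating runtime in patterned states.
* ρM fronts are ~1 cell wide at dx = 23.4 μm; clipped undershoot mass is
  logged and small but nonzero.
* In 3D the seed-nucleation race is marginal: outcomes near the nucleation
  boundary (e.g., insular parameters in small boxes) are sensitive to seed
  mass and resolution.
* The printed 2:1 medulla-to-cortex ratio for self-reactive thymocytes is
  geometry-sensitive: it depends on the ratio of the thymocyte penetration
  depth to the medullary branch width, and coarse 2D boxes with large
  pattern scales underestimate it.
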