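# thymosim

Simulation and analysis of cortex–medulla self-organization in the mouse
thymus by thymic cross-talk.

## The problem

The thymus deletes self-reactive T cells (negative selection) in its
medulla, a convoluted structure intertwined with the cortex.  The medulla
is not a prefabricated scaffold: medullary epithelial cells (mTECs) need
proliferation signals from the very thymocytes they activate — a two-way
feedback called thymic cross-talk.  `thymosim` implements a spatially
explicit density model of this feedback for people studying tissue
self-organization and negative selection: four coupled
reaction–advection–diffusion fields on a periodic 2D/3D domain —
self-reactive thymocytes ρT, activated thymocytes ρT*, mTECs ρM and one
effective chemokine ρC:

```
∂t ρT  = D_T ∇²ρT  − ∇·(ρT v_C)  − k_r ρT ρM + p φ(ρM)
∂t ρT* = D_T ∇²ρT* − ∇·(ρT* v_C) + k_r ρT ρM − d ρT*
∂t ρM  = D_M ∇²ρM  + k_b ρT* ρM (1 − ρM/K) − k_m ρM
∂t ρC  = D_C ∇²ρC  + k_e ρM − k_c ρC
```

with cortex indicator φ(ρM) = 1/(1+(ρM/μ)²) and Keller–Segel drift
v_C = T·χ(ρC)·∇ρC, χ(ρC) = K/(K+ρC)².  The package provides:

* a pseudospectral exponential-IMEX solver (`thymosim.solver`),
* linear stability analysis with reduced model variants separating the
  chemotaxis-driven (Keller–Segel) and growth-driven (Turing-type)
  instabilities (`thymosim.stability`),
* morphometrics: medullary volume fraction φM, pattern length, normalized
  covariances, medulla-to-cortex ratios, and the effective recognition
  rate k_rec = k_r⟨ρT ρM⟩/⟨ρT⟩ (`thymosim.morphometrics`),
* named experiments — wild type, production/degradation variants,
  chemotaxis knockouts, thymocyte-localization runs, (p, d) scans and
  frozen-morphology (sphere/lamellae/uniform) recognition-rate
  comparisons (`thymosim.scenarios`),
* a `thymosim` CLI (`simulate`, `scan`, `lsa`, `analyze`, `fixtures`)
  writing HDF5 snapshots, CSV metrics and JSON manifests.

See `docs/methods.md` for the model assumptions, parameter table, the
chemokine-scale calibration and all numerical choices.

## Worked example

A two-dimensional wild-type run in a 1.5 mm box, from 75 scattered
medullary seeds to quasi-steady state:

```python
import thymosim as ts

grid = ts.Grid.make(2, 64, 1500.0)          # periodic, dx = 23.4 μm
res = ts.run_experiment("wt", grid, rng_seed=1, t_max=2000.0)
m = res.final_metrics
print(f"phi_M = {m.phi_M:.3f}   k_rec = {m.k_rec:.3f} /h   "
      f"components = {m.n_components:.0f}")

ok, drift = ts.quasi_steady_check(res.trajectory)
print("quasi-steady:", ok)
```

which prints (about one minute on a laptop core):

```
phi_M = 0.340   k_rec = 0.220 /h   components = 2
quasi-steady: True
```

Read: the medulla occupies ~34% of the tissue, organized into a patterned
structure rather than one compact blob, and self-reactive thymocytes are
recognized at an effective rate of ~0.22 per hour.  Switching chemotaxis
off (`"no_chemotaxis"`) still yields a patterned medulla (the growth-driven
instability survives) but inverts the thymocyte localization and lowers
k_rec below the well-mixed value k_r·⟨ρM⟩; in the full 3 mm reference box
the chemotactic colocalization lifts k_rec above it.

The linear stability structure behind this:

```python
disp = ts.dispersion_relation(ts.ModelParams())
print(disp.unstable, disp.fastest_wavelength)   # True, ~1.4 mm
```

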