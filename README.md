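# scatterpet

2-D PET scatter-imaging toolkit: simulation of single-scattered and
nonscattered (true) coincidence data from digital phantoms, reconstruction
of the attenuation/electron-density map from scattered data
(scatter-to-attenuation, S2A), and joint estimation of activity and
attenuation from both data types.

It is aimed at image-reconstruction researchers studying whether
low-energy, object-scattered coincidences can supply the attenuation
information that PET emission data alone famously cannot (the MLAA
crosstalk problem), and at anyone who needs a small, fully inspectable
sandbox for the nonlinear scatter measurement equation.

## The model

A single-scattered coincidence is indexed by a *surface of response* (SOR)
`i = (d_s, d_n, E)`: the detector of the scattered photon, the detector of
the nonscattered photon, and the scattered photon's energy bin.  The
Compton relation `cos θ = 2 − 511/E` ties the energy to the scattering
angle, and in 2-D the possible scattering positions form a pair of circular
arcs through both detectors (radius `R = b / 2 sin θ` for baseline `b`);
an energy bin sweeps those arcs into an annular band.

The expected scatter counts are

    ȳ_i = Σ_s ( Σ_e b_i[s,e] λ_e ) · exp( − Σ_t k_i[s,t] ρ_t ) · ρ_s
        = Σ_s a_i[s] · exp( − Σ_t k_i[s,t] ρ_t ) · ρ_s ,

where `λ` is the activity image, `ρ` the electron density (stored in units
of the 511 keV attenuation coefficient, 1/cm), `B = (b_i[s,e])` the
attenuation-free sensitivity tensor, and `K = (k_i[s,t])` the effective
intersection lengths of the broken line of response `d_n → x_s → d_s`.
The density appears **twice** — as scatterer and as attenuator — so the
model is nonlinear in `ρ`.  Nonscattered data follow the usual attenuated
line-integral model `z̄ = (Uλ) ⊙ exp(−Uρ)`.

Algorithms provided (all maximum-likelihood, Poisson data model):

| update | estimates | data | character |
|---|---|---|---|
| MLEM-OSL | ρ | scatter | MLEM on the linearized model, Ã one step late |
| MLGA | ρ | scatter | gradient ascent on the full nonlinear likelihood |
| scatter-MLEM | λ | scatter | exact MLEM (model is linear in λ) |
| trues-MLEM/OSEM | λ | trues | standard attenuated MLEM |
| trues-MLTR | ρ | trues | relaxed transmission update |

plus the joint schedules built from them: the **2-algorithm**
(trues-OSEM¹⁰₄ + scatter-MLGA¹⁰₄) for low attenuation, the **4-algorithm**
(scatter-MLEM + trues-MLEM + scatter-MLGA + trues-MLTR) for any
attenuation, and the **MLAA** baseline (trues-MLEM + trues-MLTR).

The key structural fact the toolkit demonstrates: the linearization behind
MLEM-OSL misrepresents the sign of `∂ȳ/∂ρ` wherever the radiological
products `ρᵀK` exceed 1, so MLEM-OSL diverges on human-scale objects while
converging on rat-scale ones; MLGA converges at every scale, and the
criterion `max_j Σ_s ρ_s k_i[s,j] ≤ 1` isolates the SORs on which the
linearization is still trustworthy.

## Worked example

```python
import numpy as np
from scatterpet import (EnergyBinning, build_scatter_system,
                        build_trues_system, chest_phantom, initial_guesses,
                        run_s2a, simulate_measurements)

ph = chest_phantom(resolution=9, scale=0.2)      # rat-scale chest slice
scatter = build_scatter_system(ph.scanner, ph.grid, EnergyBinning(10))
trues = build_trues_system(ph.scanner, ph.grid)
meas = simulate_measurements(ph, scatter, trues)  # noise-free ȳ and z̄
_, rho0 = initial_guesses(ph)                     # 0.07/cm bounding box
rho, trace = run_s2a(scatter, ph.lam, meas.y, rho0,
                     algorithm="mlga", n_iterations=200, rho_true=ph.rho)
print(f"NMSE(rho) after 200 iterations: {trace[-1]['nmse_rho']:.2e}")
```

prints

```
NMSE(rho) after 200 iterations: 1.16e-03
```

i.e. the reconstructed attenuation map differs from the truth by about
0.1 % of the image energy.  Swapping `algorithm="mlem_osl"` converges here
too, but at `scale=1.0` (human size) it diverges within three iterations
while MLGA still converges — the spatial-scale problem in one line.  The
scripts in `examples/` walk through each capability (forward model,
system building, scale dependence, data reduction, joint estimation,
MLAA crosstalk escape, density sweeps, single-voxel likelihood surfaces)
and print the numbers they compute.

A thin CLI wraps the experiment driver:

```sh
scatterpet preset --list
scatterpet preset fig6-rat-9x9-mlga --out out-rat
scatterpet run --config my_experiment.yaml --out out
```

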