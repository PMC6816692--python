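"""Rescuing MLEM-OSL with the low-attenuation data-reduction criterion.

An SOR i is kept iff max_j sum_s rho[s] * k_i[s, j] <= 1 — the
multidimensional analog of k*rho <= 1, evaluated with the current density
estimate every iteration.  Removing the high-attenuation SORs (rows of the
system and entries of the data) restores the validity of the linearization
and speeds up MLEM-OSL at intermediate (rabbit) scale.
"""

from scatterpet import EnergyBinning, build_scatter_system, \
    build_trues_system, chest_phantom, initial_guesses, \
    low_attenuation_sor_mask, run_s2a, simulate_measurements

ph = chest_phantom(resolution=9, scale=0.35, n_detectors=32)
scatter = build_scatter_system(ph.scanner, ph.grid, EnergyBinning(10))
trues = build_trues_system(ph.scanner, ph.grid)
meas = simulate_measurements(ph, scatter, trues)
_, rho0 = initial_guesses(ph)

mask = low_attenuation_sor_mask(scatter, ph.rho)
print(f"SORs satisfying the criterion at the true density: "
      f"{mask.n_retained}/{scatter.n_sors} "
      f"({100 * mask.fraction_retained:.1f}%)")

for reduce_data, label in ((False, "full data"), (True, "reduced data")):
    _, trace = run_s2a(scatter, ph.lam, meas.y, rho0, algorithm="mlem_osl",
                       n_iterations=120, reduce_data=reduce_data,
                       rho_true=ph.rho)
    for threshold in (0.05, 0.01):
        it = next((r["iteration"] for r in trace
                   if r.get("nmse_rho", 1) < threshold), None)
        print(f"  {label:12s}: NMSE(rho) < {threshold} after "
              f"{it} iterations")
# The reduced run reaches each error level in fewer iterations: discarding
# data that violates the linearization is a net win for MLEM-OSL.
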