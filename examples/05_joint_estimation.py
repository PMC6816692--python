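"""Joint estimation of activity and attenuation from scattered plus
nonscattered data.

Neither image is known: the 2-algorithm alternates blocks of trues-OSEM
(updating the activity with the current attenuation) and scatter-MLGA
(updating the attenuation with the current activity); the 4-algorithm adds
scatter-MLEM and trues-MLTR so that both data types inform both images —
needed at high attenuation.
"""

from scatterpet import EnergyBinning, build_scatter_system, \
    build_trues_system, chest_phantom, initial_guesses, nmse, \
    run_2algorithm, run_4algorithm, simulate_measurements

base = chest_phantom(resolution=9, scale=1.0, n_detectors=32)
scatter1 = build_scatter_system(base.scanner, base.grid, EnergyBinning(10))
trues1 = build_trues_system(base.scanner, base.grid)

# low attenuation: 2-algorithm at rat scale
ph = chest_phantom(resolution=9, scale=0.2, n_detectors=32)
scatter, trues = scatter1.scaled(0.2), trues1.scaled(0.2)
meas = simulate_measurements(ph, scatter, trues)
lam0, rho0 = initial_guesses(ph)
state, trace = run_2algorithm(scatter, trues, meas.y, meas.z, lam0, rho0,
                              n_iterations=25, lam_true=ph.lam,
                              rho_true=ph.rho, track_likelihoods_every=100)
print(f"2-algorithm, rat scale, {len(trace)} sub-iterations:")
print(f"  NMSE(lambda) = {nmse(state.lam, ph.lam):.2e}, "
      f"NMSE(rho) = {nmse(state.rho, ph.rho):.2e}")

# high attenuation: 4-algorithm at human scale
meas1 = simulate_measurements(base, scatter1, trues1)
lam0, rho0 = initial_guesses(base)
state4, trace4 = run_4algorithm(scatter1, trues1, meas1.y, meas1.z,
                                lam0, rho0, n_iterations=250,
                                lam_true=base.lam, rho_true=base.rho,
                                track_likelihoods_every=100)
print(f"4-algorithm, human scale, {len(trace4)} sub-iterations:")
print(f"  NMSE(lambda) = {nmse(state4.lam, base.lam):.2e}, "
      f"NMSE(rho) = {nmse(state4.rho, base.rho):.2e}")
# Both runs recover the true images from flat/bounding-box initial guesses;
# NMSE well below 0.05 means the remaining error is a small fraction of
# the image energy.
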