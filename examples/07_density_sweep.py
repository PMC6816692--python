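"""Geometrical density of the system quantities K and A_lambda.

With a flat activity source covering the whole field of view (the maximal
case), the fraction of structurally nonzero entries of the rank-3 tensor K
and the matrix A_lambda measures how much sparsity the SOR geometry
affords.  All distinct detector pairs are enumerated here; the density
falls as the detector count grows because narrowly separated pairs, whose
loci barely clip the grid, make up a growing share.
"""

from scatterpet import density_sweep

table = density_sweep(detector_counts=(4, 8, 16, 32),
                      voxel_counts=(4, 8, 16),
                      n_energy_bins=4)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\ndensity_K / density_A are percentages of the logical dimensions")
print("(candidate SORs x voxels x voxels, and candidate SORs x voxels).")
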