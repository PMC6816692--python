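"""Why combining trues and scatter data resolves joint nonuniqueness.

On a single-voxel, single-detector-pair problem (b = k = u = 1), the trues
likelihood has an extended ridge (activity scaling vs attenuation offset)
and the scatter likelihood admits two attenuation solutions at any fixed
activity.  Their joint likelihood has a unique maximum — at the truth.
"""

import numpy as np

from scatterpet import single_voxel_joint_surface

lam_grid = np.round(np.arange(0.1, 3.01, 0.01), 10)
rho_grid = np.round(np.arange(0.02, 4.01, 0.02), 10)

for rho_true in (0.2, 2.0):
    res = single_voxel_joint_surface(rho_true, lam_grid=lam_grid,
                                     rho_grid=rho_grid)
    lam_hat, rho_hat = res["joint_argmax"]
    print(f"rho_true = {rho_true}:")
    print(f"  expected counts  ybar = {res['ybar_true']:.4f}, "
          f"zbar = {res['zbar_true']:.4f}")
    print(f"  joint-likelihood argmax on the grid: "
          f"lambda = {lam_hat}, rho = {rho_hat}")
# Both regimes: the argmax lands exactly on (1.0, rho_true), even though
# each individual likelihood is maximized along whole curves of (lambda,
# rho) pairs.
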