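# Methods

## Measurement models

The scatter model treats each single-scattered coincidence as a broken
line of response `d_n → x_s → d_s`: annihilation photons are emitted
somewhere on the segment `x_s → d_n`; one photon reaches `d_n` directly,
the other scatters at `x_s` by the Compton angle θ fixed by its measured
energy (`cos θ = 2 − 511/E`, valid for E in [511/3, 511] keV) and reaches
`d_s`.  Discretized on an image grid, the expected counts on SOR
`i = (d_s, d_n, E-bin)` are

    ȳ_i = Σ_s a_i[s] · exp(−Σ_t k_i[s,t] ρ_t) · ρ_s,
    a_i[s] = Σ_e b_i[s,e] λ_e,

with `B` the attenuation-free sensitivity (per unit density in the
scattering voxel s, per unit activity in the emitting voxel e) and `K` the
effective intersection lengths of the broken LOR with each attenuating
voxel t.  Two standing assumptions are baked in: the effective lengths do
not depend on the emission point along the broken LOR, and the attenuation
coefficient is proportional to the electron density.  The trues model is
`z̄ = (Uλ) ⊙ exp(−Uρ)` with `U` the exact chord–voxel intersection-length
matrix.  Both models serve simulation *and* reconstruction (inverse-crime
setting, deliberate: the study isolates algorithmic behavior from model
mismatch).

Units: `ρ` is stored numerically equal to the 511 keV attenuation
coefficient μ (1/cm), so `k` is a length in cm and `Kρ` is dimensionless.
The ratio of attenuation coefficients on the low-energy leg is a hook
(`mu_ratio`) and defaults to 1 (energy-independent attenuation).

## System construction

Detector rings are point detectors, equally spaced.  SOR candidates are
ordered detector pairs with angular separation ≥ 45° (configurable; the
cut avoids near-tangent chords) crossed with the energy bins reachable by
single scatter (7 of the default 10 equal-width bins descending from
511 keV).

In 2-D the constant-angle locus is the pair of circular arcs on which the
detector baseline subtends 180° − θ (inscribed-angle construction,
`R = b / 2 sin θ`).  An energy *bin* collects scatter over a whole angular
interval, so its SOR is the annular band between the bin-edge arcs.  The
band is sampled at the arcs of the midpoint energies of n equal energy
sub-intervals, n chosen adaptively so adjacent arcs are at most one voxel
apart at the chord midpoint (2 ≤ n ≤ 12), and each arc is sampled at 8
midpoint-rule points per voxel width (both knobs configurable).  Samples
inside the grid are binned into scattering voxels; per broken LOR, `K`
rows are the band-weighted *average* of the two-leg path lengths over the
samples in that voxel, and `B` accumulates band weight × emission-segment
length.  `k_i[s,s] > 0` is guaranteed on the full support (a scattering
voxel always attenuates its own broken LOR), and `k_i[s,·] = 0` for
geometrically incompatible s, so the (i, s) supports of `B` and `K`
coincide.  SORs whose band misses the grid are dropped from the
enumeration but remain in the logical dimensions used for density
bookkeeping.

Ray tracing is exact axis-aligned slab clipping (Liang–Barsky style),
vectorized over segments; segments lying exactly on a voxel edge are
assigned to one neighbor (half-open slabs).  The whole build runs in voxel
units and multiplies lengths back at the end, which makes building at
scale factor c *exactly* the unit-scale build with every length times c —
the scale sweeps therefore reuse one build via `ScatterSystem.scaled`.

In the default `geometric` weight mode all physical constants are unity
and `B` carries one length factor (so `B` and `K` both scale linearly with
the spatial scale); `physics` mode additionally applies the Klein–Nishina
cross-section, the angle-to-energy Jacobian, and the sub-bin energy width.

## Algorithms and numerical choices

* Poisson log-likelihood without the log(y!) term.  In update ratios only,
  0/0 bins contribute 0 and expected counts are floored at 1e-15; reported
  likelihood values are never floored.
* MLEM-OSL: multiplicative MLEM update with the attenuated matrix
  `Ã = A_λ ⊙ exp(−Kρ)` rebuilt from the current ρ at every update (true
  one-step-late semantics), followed by a clamp at zero.  The
  sparsity-preserving `a·expm1(−Kρ) + a` evaluation pattern is inherent to
  the pair-row storage: exponentials are taken only on stored support.
* MLGA: `ρ ← max(0, ρ + s ⊙ ∇LL)` with the full nonlinear gradient
  `∂LL/∂ρ_j = Σ_i (ã_i[j] − Σ_s ρ_s k_i[s,j] ã_i[s]) (y_i/ȳ_i − 1)`.
  Step-size rules: MLEM-like `s = γ ρ ⊘ Ãᵀ1` (default), constant α,
  scaled β·ρ.
* Step-size constants are calibrated once for fastest-yet-stable
  convergence on the chest phantom across all spatial scales.  With the
  MLEM-like rule, γ = 1 overshoots high-attenuation voxels onto the zero
  clamp — which is absorbing for ρ-proportional steps — and stalls;
  **γ = 0.5** is stable and fast at every scale and is the standalone
  default.  Inside joint schedules the default is halved again
  (**γ = 0.25**) because the activity the scatter gradient sees is itself
  still converging.
* Data reduction: SOR i is retained iff `max_j Σ_s ρ_s k_i[s,j] ≤ 1`
  (boundary inclusive), re-evaluated with the current ρ every iteration
  (cadence configurable); retained rows keep their order.
* Subsets: rows are partitioned by angular key (d_s for SORs, first
  detector for LORs) modulo the subset count, and OSEM/MLGA sensitivities
  are recomputed on each subset.
* Divergence guard: runs halt and record the iteration when estimates or
  NMSE become non-finite (or NMSE exceeds 1e6) — MLEM-OSL divergence at
  human scale is an expected, reportable outcome, not an exception.
* MLAA plateau detector: relative change of the apparent trues
  log-likelihood below 1e-8 over 20 consecutive iterations (configurable).
  Under this package's conditions MLAA creeps rather than hard-plateaus,
  so the crosstalk experiment uses a fixed MLAA iteration budget as the
  hand-over point; the scatter-driven escape behavior is unaffected.
* Joint fixed point: every schedule started at the truth with its own
  noise-free data is stationary to numerical precision.

## Synthetic data

The chest phantom is parametric and normative for this package: an
elliptical soft-tissue body (μ = 0.096/cm, water-like), two lung ellipses
(μ = 0.03/cm), a spine disc (μ = 0.13/cm), activity 1 inside the body with
a lesion of 4× contrast inside the left lung.  The 18×18 version has
2.5 cm voxels inside a 40 cm-radius, 64-detector ring; the 9×9 version is
its exact 2×2 block average (same physical extent).  Spatial scales 1,
0.35, and 0.2 (human, rabbit, rat) shrink every length uniformly, so the
dimensionless attenuation `Kρ` shrinks with them — the same phantom sweeps
from high to low attenuation.  Initial guesses: ρ = 0.07/cm inside the
object support dilated by one voxel (a generous bound with roughly correct
attenuation factors), activity homogeneous over the FOV normalized to the
true total (configurable).  Flat phantoms (λ = 1, μ = 0.1/cm, initial
μ = 0.05/cm) cover the FOV for the complexity/density harness.

Measurements are noise-free expected counts; the default pipeline contains
no randomness whatsoever and is bit-reproducible.  A seeded Poisson
sampler exists behind an explicit flag for experimentation and is excluded
from all reproduction studies.

What passing tests show — and don't: the simulations share the forward
model with the reconstruction and assume perfect energy resolution, no
detector scatter, no multiple scatter, no noise, and point detectors.
Convergence and crosstalk-escape results therefore characterize the
*algorithms* on their own model; they do not by themselves predict
performance on measured data, where energy blur and model mismatch will
slow or degrade all of the schedules.

## Problem sizes used in the reproductions

The bundled studies run the 9×9 phantom with the full 64-detector,
10-energy-bin geometry (≈18,000 SORs, ≈360,000 broken LORs, K with
≈5.8 million nonzeros): S2A runs use 500 iterations, joint runs 1000
sub-iterations, and the crosstalk study 400 MLAA + 300 escape iterations.
The 18×18 phantom is fully supported and used in the examples
documentation, with the same qualitative behavior.  Density sweeps use
N_E = 4 bins with detector counts up to 64 and grids up to 16×16.

## Density harness and its limits

Geometrical density is the percentage of stored nonzeros relative to the
logical dimensions (candidate SORs × voxels × voxels for K), measured
with a flat activity source — an upper bound for any less extended source.
The harness enumerates *all* distinct detector pairs (no separation cut):
the decline of density with growing detector count is driven by the
increasing share of narrowly separated pairs whose loci barely clip the
grid, and a separation cut removes exactly that effect.  With exact area
discretization (every voxel the band crosses is marked), coarse grids
over-mark, so at fixed physical extent the densities of both K and A_λ
decrease monotonically as the grid is refined; a rasterization that
samples voxels more sparsely than it marks them would instead under-mark
coarse grids and show density rising with voxel count.  Reported density
values are therefore tied to this package's discretization; trends across
detector counts are robust, absolute percentages are not.

## Known limitations

2-D only; point detectors; no time-of-flight; no detector scatter,
multiple scatter, or energy blur; no regularization or priors; step-size
constants are calibrated on the bundled phantom family and may need
retuning for very different objects.
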