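# Methods

## Elastic model and traction reconstruction

The substrate is a homogeneous, isotropic, semi-infinite linear elastic
half-space; defaults are E = 12 000 Pa (soft silicone in the stiffness
range of muscle tissue), ν = 0.5 (incompressible), pixel size
0.16 µm/px (40× objective). Only in-plane surface tractions and
displacements are modelled; out-of-plane components, finite gel
thickness and substrate heterogeneity are neglected. Under these
assumptions the forward map is diagonal in Fourier space with the 2×2
Boussinesq tensor G̃(k) (see README); ν = 0.5 introduces no singularity
in the tensor, so no special-casing is required.

The inverse solver (`substrate.reconstruct_traction`) applies per-
wavevector Tikhonov regularization, T̃ = (G̃ᵀG̃ + λI)⁻¹G̃ᵀũ.

**Units of λ.** The regularization constant is quoted in the source
analysis as 2.47 × 10⁻⁵ in "per-pixel-squared" units without a defined
normalization. The package applies λ to the normal equations formed with
displacements in pixels and the Green's tensor nondimensionalized by E
(internally the solver works in E·pixel units and converts to Pa on
output). This keeps the constant transferable across magnifications and
stiffnesses. The interpretation is isolated in `reconstruct_traction` so
it can be swapped; note that under it G̃ᵀG̃ is of order 10²–10⁴ at the
resolved wavevectors, so the default λ is an extremely mild ridge — the
practical noise control in this pipeline comes from tracking-window
smoothing and from analysing at the bead-spacing resolution (below),
not from λ. The alternative reading (tensor in px/Pa without
E-normalization) was evaluated and rejected: it suppresses all features
below a ~125 px wavelength and attenuates recovered tractions by ~70 %
on ground-truth scenes.

**Zero mode.** G̃ diverges at k = 0: a rigid displacement offset is
unobservable and the net force is not recoverable. The forward solver
sets ũ(0) = 0; the inverse subtracts the mean displacement and sets
T̃(0) = 0, i.e. enforces global force balance. Consequently the exact
λ = 0 forward→inverse round trip holds for zero-net-force traction
fields (the physically expected case for a cell in mechanical
equilibrium); validation fixtures therefore use dipole/ring patterns.

**Periodicity control.** The FFT solution is implicitly periodic. The
forward solver zero-pads the traction grid 2× per axis (exact for
compactly supported traction; images pushed to twice the field of view),
which brings it within 0.8 % relative RMS of a direct real-space
Boussinesq convolution over the central quarter of a 64×64 test grid.
The inverse cosine-tapers the displacement border (default
min(8, n/8) nodes) and zero-pads 2× before inversion, then crops.
`pad_factor=1` disables both for exact periodic round trips.

## Bead detection

Images are band-passed with a difference of Gaussians (σ = 1.5 / 2.0 px,
matched to the spot size of ~100 nm beads), then scored with the
Shi–Tomasi minimum-eigenvalue corner response; peaks above
`quality_level` × max response survive non-maximum suppression
(radius 5 px). Each peak is re-centered on the local DoG maximum (the
squared-gradient response can sit one pixel off the spot apex) and
refined by 1D quadratic interpolation per axis on the DoG profile,
giving ~0.1 px localization at SNR 20 on rendered fixtures.

## Displacement tracking

A translation-only iterative Lucas–Kanade tracker with image pyramids
(3 levels) tracks each bead from the relaxed (reference) image into the
loaded image; displacement is gel deformation at material points of the
relaxed state, the reference-configuration convention of FTTC. The
window support is 61 px. Inside the window the normal equations are
Gaussian-weighted with σ = window/10 ≈ 6 px: at typical bead densities a
uniform 61-px window contains ~25 beads and returns their average
motion, which smears traction features — measured 0.25 px RMS against
forward-model warps, versus 0.06–0.08 px with the weighting. The wide
support is retained for robustness at coarse pyramid levels. Tracks are
validated by a forward-backward consistency check (1 px tolerance) and a
maximum-displacement bound; a residual threshold is available but off by
default. Failed beads are flagged lost and excluded.

Drift correction subtracts the median vector of tracked beads outside
the cell mask (all beads if no mask); with fewer than 5 reference beads
it warns and leaves the field unchanged.

## Gridding and analysis resolution

Scattered bead vectors are linearly interpolated onto a regular grid
(Delaunay/barycentric, exact for affine fields), with nearest-neighbour
fill outside the convex hull. The default node spacing is 13 px — the
mean bead spacing at the default seeding density (60 beads per
100×100 px, √(10⁴/60) ≈ 12.9 px). This choice is load-bearing: a grid
finer than the bead spacing manufactures sub-data-resolution structure
from the triangulation, and because the default λ is effectively inert
the inversion amplifies it (on ground-truth scenes, gridding at 8 px
gave +23 % median / up to +59 % per-cell max-traction error; at 13 px,
2.5 % median / 10 % worst). If the bead density differs substantially
from the default, `grid_spacing` should be set to the actual mean bead
spacing.

## Per-cell readouts

Strain energy U = ½ Σ (t·u) ΔA is summed over the full field of view
(it is an acquisition-level quantity; the mask only selects nodes for
the traction statistics), with ΔA the physical area per node; stored in
joules. Max and mean |T| are taken over grid nodes mapped to mask pixels
by nearest pixel. Published per-cell strain energies in this assay
family are quoted in µJ, several orders of magnitude above what
½∫T·u dA yields for single cells (~10⁻¹⁴ J here); the formula is
implemented as stated and the unit discrepancy is noted rather than
resolved. Both per-cell max and per-cell mean traction are emitted, so a
group "average traction" can be aggregated either way.

## Statistics

Two-tailed Mann–Whitney U: midrank ties; exact two-tailed p by
subset-sum enumeration of the null distribution when n₁+n₂ ≤ 16 with no
ties (2·min(P(U≤u), P(U≥u)), capped at 1), otherwise the normal
approximation with tie and continuity correction; the method used is
recorded. The summary-statistics t-test uses
t = Δmean/√(SEM₁²+SEM₂²) with Student df = n₁+n₂−2 by default and a
Welch–Satterthwaite option. SEM uses the n−1 sample standard deviation.
Cells are treated as the sampling unit in group comparisons, matching
per-cell dot plots. Significance labels: *** p<0.001, ** p<0.01,
* p<0.05, n.s. otherwise.

## Synthetic scenes: what they emulate, and what they do not

Each scene: an adhesion-like ground-truth traction pattern (default: six
disks of radius 24 px with a 12 px cosine rim, plateau 1000 Pa, pulling
toward the cell center from a 48 px ring — zero net force by symmetry);
displacement from the elastic forward model; ~60 beads per 100×100 px
rendered as Gaussian spots (σ = 1.3 px, the diffraction limit for
100 nm beads at 40×) at subpixel positions; Poisson shot noise plus
Gaussian read noise (2 % of bead peak); a disk cell mask. Loaded bead
positions equal relaxed positions plus the bilinearly interpolated truth
field, exactly — all stochasticity lives in bead placement and camera
noise. The cosine rim keeps the truth within what bead-sampled data can
represent; adhesion-scale tractions are not step functions. Cohorts draw
per-cell plateau magnitudes from truncated normals (defaults 1000 vs
600 Pa, CV 20 %), giving bead displacements of ~0.5–2.5 px at 12 kPa.

Not emulated: realistic cell geometry, bead polydispersity and
aggregation, uneven illumination, focus drift, photobleaching, gel
inhomogeneity, out-of-plane motion. Passing ground-truth recovery on
these scenes validates the algorithmic chain (detection → tracking →
gridding → inversion → metrics) under idealized imaging; it does not
certify accuracy on real images with those artifacts.

## Numerical choices and problem sizes

Scene fixtures use 256×256 px images (192×192 in orchestration tests)
with 10–12 cells per arm, and the truth grid is rasterized at 8 px —
sizes chosen so the full validation suite completes in a few minutes
while leaving recovery conclusions unchanged from larger runs. End-to-end
recovery on noiseless scenes achieves ~5 % median max-traction error and
~28 % median strain-energy error (energy is biased low: both T and u are
attenuated by window smoothing and linear-interpolation flattening, and
the product compounds it); recovered metrics scale as α and α² under a
truth rescale to within 0.3 %. LK iterations stop at a 5×10⁻³ px step or
25 iterations; interpolation is bilinear throughout. CSV outputs use
fixed float formatting and stable row ordering, so identical configs and
inputs reproduce outputs byte for byte.

## Known limitations

* The λ interpretation is a convention; with a differently normalized
  constant the reconstruction bandwidth would change and the analysis
  grid spacing guidance above would need re-deriving.
* Semi-infinite substrate: thin gels (< a few bead-displacement decay
  lengths) bias tractions upward; no finite-thickness correction.
* The tracker estimates translation only; local rotation/shear within a
  window biases estimates for very large deformation gradients.
* Strain energy over the field of view includes contributions from
  neighbouring cells if several cells share an acquisition.
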