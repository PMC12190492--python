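# tfmkit

Traction force microscopy (TFM) analysis for adherent cells on soft
elastic substrates — built around the workflow used to compare the
contractility of dystrophin-deficient (DMD) and wild-type muscle stem
cells: paired fluorescent-bead images → bead detection and optical-flow
tracking → regularized Fourier-transform traction cytometry (FTTC) →
per-cell strain energy and maximum traction → two-group nonparametric
statistics.

Because raw microscopy data of this kind is rarely public, the package
ships a forward-model synthetic-scene generator (beads as diffraction-
limited Gaussian spots, displacements from the elastic half-space
solution, camera shot/read noise) so every stage — and the end-to-end
recovery of known ground truth — is testable without any download.

## Who it is for

Mechanobiology groups running bead-based 2D TFM on soft silicone or
polyacrylamide gels (≈ 1–50 kPa) who want a scriptable, tested pipeline
from TIFF image pairs and cell masks to per-cell readouts and group
comparisons, and method developers who need a ground-truth benchmark for
tracking/inversion choices.

## The model

A cell exerts an in-plane traction field **T**(x) on the surface of a
linear elastic half-space (Young's modulus *E*, Poisson ratio ν = 0.5
for incompressible gels). The surface displacement **u**(x), measured by
tracking fiducial beads, is related to **T** per wavevector **k** through
the Fourier-space Boussinesq Green's tensor

```
G̃(k) = 2(1+ν)/(E|k|³) · [ (1−ν)|k|² + ν k_y²   −ν k_x k_y
                           −ν k_x k_y            (1−ν)|k|² + ν k_x² ]
```

so that ũ(k) = G̃(k)·T̃(k). The inverse problem is solved per wavevector
with Tikhonov (ridge) regularization,

```
T̃(k) = (G̃ᵀG̃ + λI)⁻¹ G̃ᵀ ũ(k),   T̃(0) = 0  (global force balance),
```

with λ = 2.47 × 10⁻⁵ applied in pixel-normalized units (displacements in
px, Green's tensor nondimensionalized by *E*; see `docs/methods.md`).
Per cell, the pipeline reports

* **strain energy** U = ½ Σ (T·u) ΔA over the field of view (J), and
* **max / mean traction magnitude** |T| over grid nodes inside the cell
  mask (Pa),

and compares groups with two-tailed Mann–Whitney U tests (exact by
enumeration for small tie-free samples), mean ± SEM summaries, fold
ratios of group means, and unpaired t-tests computed from printed
summary statistics.

## Worked example

```sh
python analysis/01_simulate_cohort.py    # 12 + 12 synthetic cells
python analysis/02_run_tfm_pipeline.py   # full imaging pipeline per cell
python analysis/03_group_statistics.py   # group comparison + worked example
```

prints (abridged):

```
simulated 24 cells (12 per group, 256x256 px, seed 2026)
  DMD: truth max traction 969 ± 161 Pa (mean ± SD)
  WT: truth max traction 622 ± 101 Pa (mean ± SD)
analysed 24 cells
  median |max traction error|: 9.0 %
  median |strain energy error|: 28.8 %
max_traction_pa: DMD 1023 ± 39.2 (n=12) vs WT 670.5 ± 35.2 (n=12); U = 140, p = 9.735e-05 ***
strain_energy_j: DMD 1.792e-14 ± 1.67e-15 (n=12) vs WT 7.429e-15 ± 6.98e-16 (n=12); U = 138, p = 0.0001558 ***
stem-cell counts (from printed summaries): fold ratio 3.7, t = 6.58 (df = 10), p = 6.2e-05 ***
```

The disease-like group is simulated with 1000 Pa mean adhesion traction
vs 600 Pa for the control-like group (20 % cell-to-cell CV); the pipeline
recovers per-cell maximum traction to a ~9 % median error, the group
separation is detected at p < 10⁻⁴, and the last line reproduces the
published 3.7-fold stem-cell-count difference from its printed group
means and SEMs. Intermediate tables land under `results/`, images under
`scratch/`.

The same stages are available as a CLI
(`tfmkit simulate | detect | track | reconstruct | measure | compare | run`)
for use on real TIFF image pairs and masks via a YAML config.

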