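# bundletrac

Semi-automatic tracing of filament bundles in noisy, anisotropic 3D density
maps — the situation of cryo-electron tomograms of actin bundles such as the
one filling an inner-ear hair-cell stereocilium. A stereocilium shaft packs
hundreds of roughly parallel actin filaments ~12 nm apart in a hexagonal
lattice; low electron dose makes the tomogram extremely noisy, and the
missing wedge of the tilt series elongates every density along Z, merging
neighbouring filaments in cross-section. Generic single-filament tracers
fail here because the fit is ambiguous between a filament and its neighbours.

`bundletrac` exploits the one thing the bundle guarantees: filaments change
direction *collectively and gradually*. Who is it for: structural biologists
and image-analysis developers who need ball-and-stick centerline models of a
bundle from a tomogram plus one seed point per filament.

## Method

1. **Bundle-axis detection.** X–Z cross-sections (thickness-averaged slabs)
   are sampled every 55 slices along Y; the sub-pixel peak shift `(dx, dz)`
   of the 2D cross-correlation of consecutive sections gives the local
   bundle direction `normalize(dx, Δy, dz)`. A series of these vectors forms
   an axis field `v(y)`.
2. **Longitudinal averaging.** Each voxel `p` is replaced by the mean of
   trilinear samples `Φ(p + k·v(p_y))`, `k = −15 … 15`. Filament signal is
   coherent along the axis, noise is not, so single-slice cross-sections of
   the averaged map show the hexagonal lattice clearly.
3. **Tracing.** From a seed on a starting slab, the next marker is found by
   scoring a zero-mean, unit-norm kernel of seven 2D Gaussians (one central
   peak plus six at hexagon vertices, the filament's neighbourhood) against
   downstream slabs at distances 10, 25, 45 and 70 voxels:

   `score(c) = ⟨K, patch(c)⟩`,  `K = Σ_{k=0..6} G_σ(x − v_k) − mean`, `‖K‖ = 1`.

   Hexagon spacing (11–15 voxels) and orientation are re-optimized at every
   placement; the best-scoring candidate step wins, ties going to the
   shortest step. A one-peak variant is available for comparison.
4. **Cross-distance metric.** Agreement between two filament models:
   `D_f = (1/n) Σ_i ‖P_i − Q_i‖`, where `P_i` are the reference markers in
   the common y-range and `Q_i` the nearest points on the finely
   interpolated test filament.
5. **Polynomial kernel-regression denoiser.** At every voxel a quadratic
   `f(x,y,z)` is fitted by weighted least squares, minimizing
   `Σ_q (f(q) − Φ(q))² W(q − p)` with the anisotropic Gaussian weight
   `W = S ∗ R` (`H = H_S + H_R`): `S` elongated along the filament
   direction, `R` a missing-wedge-aware PSF model with Z width twice the XY
   width. The denoised value is `f(p)`.

A synthetic phantom generator (`bundletrac phantom`) produces hexagonal
bundles with known ground-truth centerlines, collective bend/tilt,
Z-elongated PSF and controllable noise, so the whole pipeline is testable
without tomogram downloads.

## Worked example

```sh
bundletrac phantom --set n_shells=3 --set noise_sigma=1.0 \
    --out-volume vol.mrc --out-truth truth.csv --out-seeds seeds.csv
bundletrac axis vol.mrc --step 55 --thickness 30 --out axis.csv
bundletrac average vol.mrc --axis axis.csv --half-window 15 --pre-gauss 1.0 --out avg.mrc
bundletrac trace avg.mrc --seeds seeds.csv --axis axis.csv --peaks 7 --out model.csv
bundletrac evaluate --ref truth.csv --test model.csv --threshold 3 --out report.json
```

The final command logs (37 filaments, 12-voxel spacing, noise equal to the
pre-PSF peak filament amplitude, seed 42):

```
INFO bundletrac: evaluate: mean D_f = 0.356 voxels, 37/37 within 3
```

i.e. the traced centerlines deviate from the ground truth by 0.36 voxels on
average — far below the ~12-voxel filament spacing — and every filament is
within the 3-voxel agreement threshold. The five-variant ablation
(`bundletrac ablation vol.mrc --seeds seeds.csv --truth truth.csv --out abl.json`)
prints on the same fixture:

```
Trace_L_G_7: 0.356   Trace_L_7: 0.355   Trace_G_7: 0.409
Trace_L_1: 0.561     Trace_L_G_1: 0.555
```

showing the seven-peak kernel beating the one-peak kernel and longitudinal
averaging beating its absence, the two design claims of the method.

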