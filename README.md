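# octbga

Automatic analysis of optic-nerve-head (ONH) OCT volumes for glaucoma
assessment: retinal layer segmentation, cup/disk morphometry, the
peripapillary RNFL thickness profile, and the **BGA** (biomorphological
glaucoma advancement) score with its linear conversion to an expected
perimetric mean defect (MD). It is written for ophthalmic image-analysis
researchers who need a tested, scriptable reimplementation of this
pipeline that runs on open file formats and on synthetic phantoms with
analytic ground truth — no proprietary tomograph container required.

## The method

Given an 8-bit OCT stack `L(m, n, i)` (axial row `m`, A-scan column `n`,
B-scan `i`), the pipeline computes:

1. **Denoising** — 3×3×3 median filter.
2. **RPE** — per A-scan brightness maximum,
   `L_RPE(n,i) = argmax_m L(m,n,i)` (the RPE is the brightest band);
   ties are broken by continuity with neighbouring columns.
3. **Disk mask** — columns whose RPE depth departs from the mean by more
   than the threshold fraction `p_m = 2/3` (the RPE terminates and the
   bright floor lies deeper inside the neural canal), followed by
   largest-component/fill-holes cleanup.
4. **ILM** — Otsu binarization of the supra-RPE region; the ILM is the
   first foreground row of each column.
5. **RNFL lower boundary** — first Prewitt gradient edge strictly
   between ILM and RPE, then an *active-edge correction*: each contour
   point is moved to the row maximizing the mean-brightness contrast
   between a window above and below, which bridges vessel-shadow gaps.
6. **Cup mask** — disk columns whose ILM lies deeper than the per-B-scan
   RPE chord raised 150 μm anteriorly.
7. **Geometry** — centroids, equivalent radius `r = sqrt(area/π)`, and
   the minimum cup-to-disk boundary distance `r_min`.
8. **Polar profile** — RNFL thickness resampled over the annulus
   `ρ ∈ [2r_disk, 3r_disk]` in 1° bins with TSNIT quadrant labels.
9. **BGA** — with disk centroid `(n_d0, i_d0)`, cup centroid
   `(n_c0, i_c0)` and a normative profile `L^WZ(θ)`:

   ```
   w_g(1) = |(n_d0, i_d0) − (n_c0, i_c0)| / r_disk        (cup eccentricity)
   w_g(2) = 1 − r_min / r_disk                            (boundary proximity)
   w_g(3) = mean_θ |L^ROI(θ) − L^WZ(θ)| / L^WZ(θ)         (RNFL deviation)
   w_BGA  = (w_g(1) + w_g(2) + w_g(3)) / 3
   MD     = 24 · w_BGA − 9.34  [dB]
   ```

A synthetic phantom generator renders ONH volumes (bright RNFL slab, RPE
band, disk excavation, cup depression, vessel shadows, Gaussian noise)
whose circular geometry gives every score a closed form, and an
exploratory factor-analysis module (correlation matrix, Kaiser/Cattell
class counts, varimax-rotated loadings, class–MD correlations) covers
the feature-selection side of the method.

## Worked example

```bash
octbga phantom --out out/ph
octbga segment out/ph/volume.tiff out/ph/calibration.ini \
       --reference out/ph/reference.csv --out out/seg
```

prints

```
w_BGA=0.1804 predicted_MD=-5.01 dB
```

and writes `out/seg/features.csv`, e.g.

```
n_d0,i_d0,r_disk,n_c0,i_c0,r_cup,r_min,w_g(1),w_g(2),w_g(3),w_BGA,predicted_MD_dB
128.0,32.0,27.920259870998752,128.0,32.0,13.831277655967225,12.806248474865697,0.0,0.5413277478778855,0.0,0.18044258262596183,-5.009378016976916
```

The default phantom has a concentric cup of half the disk radius and an
RNFL that matches the reference profile, so the analytic scores are
`w_g = (0, 0.5, 0)` and `w_BGA = 1/6 ≈ 0.167`: the measured 0.180 and
the predicted MD of −5.01 dB (vs −5.34 analytic) reflect ~1 px mask
rasterization error in `r_min`. Surfaces (CSV) and masks (PNG) land in
the same directory. `octbga factor table.csv --out out/fa` writes the
factor-analysis report for a feature table.

From Python:

```python
from octbga import PhantomSpec, generate_phantom, run_segment

spec = PhantomSpec(noise_sd=0.0)
volume, truth = generate_phantom(spec)
result = run_segment(volume, spec.reference_profile())
print(result.bga)               # wg1/wg2/wg3, w_BGA, predicted MD
print(truth.true_features)      # analytic ground truth for comparison
```

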