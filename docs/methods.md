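# Methods

## Scope and model

The package analyses ONH-centred OCT stacks `L(m, n, i)` — axial row
`m` (0 = vitreous side), A-scan column `n`, B-scan `i`, 8 bits/voxel —
and condenses them into three normalized morphometric scores and their
mean, the BGA score, which converts linearly to an expected perimetric
mean defect. The analysis assumes:

* the RPE is the brightest band of every A-scan, so its depth is the
  per-column brightness argmax;
* the optic disk is the en-face region where that depth departs
  markedly from its mean (the RPE terminates at the neural canal and
  the brightest deep structure there is the excavated floor);
* the RNFL presents as a bright slab starting at the ILM whose lower
  boundary is the first light-to-dark transition below the ILM;
* disk and cup are compact, roughly convex en-face regions (centroid,
  equivalent radius and boundary distance are meaningful).

Tilted anatomies, peripapillary atrophy, and non-compact cups violate
these assumptions and are out of scope.

## Parameters

All tunables live in `PipelineConfig`, serialized to INI:

| parameter | default | units | role |
|---|---|---|---|
| `median_mask` | (3, 3, 3) | voxels | denoising mask; odd per axis |
| `border` | replicate | — | border handling for median and Prewitt passes |
| `p_m` | 2/3 | — | disk threshold fraction (see below) |
| `disk_threshold_mode` | reciprocal | — | `reciprocal`: flag RPE rows > mean/p_m; `literal`: > p_m·mean |
| `otsu_scope` | bscan | — | Otsu sample per B-scan or per volume |
| `gradient_floor` | 2 | gray levels | minimum Prewitt magnitude counted as an edge; 0 = literal first-positive-edge rule |
| `refine_window` | (5, 5) | rows | heights of the above/below contrast windows of the active-edge correction |
| `cup_offset_um` | 150 | μm | anterior offset of the cup reference chord above the RPE |
| `polar_bins` | 360 | — | angular resolution of the peripapillary profile |
| `eye` | right | — | TSNIT quadrant orientation; `left` mirrors θ |
| `md_slope`, `md_intercept` | 24, −9.34 | dB/unit, dB | BGA→MD conversion line |

Numerical conventions: all indices are 0-based (the published formulas
are 1-based; every equation is translated once, at the module surface).
Surfaces are (N, I) float arrays with NaN as the undefined sentinel.

## Design choices where the procedure was open

* **Disk threshold direction.** Read literally, "RPE row > p_m·mean"
  with p_m = 2/3 flags nearly every column, because almost all RPE rows
  exceed two-thirds of their own mean. The stated intent is a *maximum
  acceptable shift* of the RPE inside the disk, so the default flags
  rows deeper than mean/p_m = 1.5·mean (a 50 % depth excursion); the
  verbatim rule remains available via `disk_threshold_mode="literal"`.
* **RPE tie-breaking.** Columns with several tied brightness maxima
  take the candidate nearest the median RPE of the 5×5 en-face
  neighbourhood of uniquely solved columns, falling back to the
  smallest row. Median filtering flattens a band peak into a short
  plateau, so ties are common on noise-free data; the continuity prior
  keeps the surface coherent.
* **Gradient floor.** A literal "gradient > 0" rule fires on the first
  noise voxel below the ILM; the default floor of 2 gray levels makes
  the first-edge rule meaningful on denoised data while remaining
  switchable to the literal behaviour.
* **Active-edge correction target.** The correction is defined
  generically on any contour; the pipeline applies it to the RNFL lower
  boundary (the published illustration shows exactly that), with
  candidates constrained to (ILM, RPE] so the layer ordering survives,
  gaps bridged by linear interpolation along `n` before the scan, and
  the per-B-scan search half-range set to the median |ILM − RPE|.
  Among equal-contrast rows the candidate nearest the input contour
  wins (a 10⁻⁶·|Δ| tie penalty).
* **Otsu tie rule.** When an empty histogram span separates the two
  classes, every cut through it maximizes the between-class variance
  exactly; the middle of the tied run is returned (mid-plateau rule,
  as in common reference implementations).
* **Cup reference surface** is a per-B-scan chord between the RPE
  sampled just outside the two disk-edge crossings, not a global plane:
  this tolerates tilt and matches the per-B-scan processing style.
* **Polar geometry.** θ = atan2(n − n_d0, i − i_d0), so displacement
  along +n maps to θ = 90°. With anisotropic en-face sampling, ρ is
  measured in μm (the annulus is elliptical in pixel space) and the
  pixel-count disk radius converts through the geometric mean of the
  two lateral scales. Bins with under 50 % usable samples are flagged
  invalid, and the RNFL deviation score normalizes by the valid-bin
  count so partial coverage still yields a mean. The score is not
  clamped: thickness beyond twice the reference exceeds 1.
* **Cup-offset monotonicity.** Raising the reference chord farther
  above the RPE enlarges the set of columns whose ILM lies below it;
  cup area is therefore non-decreasing in `cup_offset_um`. (The tests
  assert this direction.)
* **Factor analysis** uses conventional defaults where the published
  description is generic: principal-component extraction
  (λ_j^{1/2}·v_j), varimax rotation, regression-method scores,
  pairwise-complete Pearson correlations, mean imputation for scoring,
  LV excluded. The Cattell elbow is the 1-based position of the
  eigenvalue maximizing the second difference of the descending
  spectrum.

## The phantom generator

`PhantomSpec` describes a synthetic ONH volume with closed-form
geometry: flat ILM at `ilm_base_row` dipping by `cup_depth_um` inside a
circular cup (cosine-ramp walls of ±1 px), an RNFL slab of angular
thickness `rnfl_thickness_um(θ)`, the RPE as a Gaussian band (σ = 2 px)
at `rpe_depth_row` outside a circular disk, a deeper bright floor band
inside it, optional vessel shadows (multiplicative attenuation of whole
columns from the ILM down), and additive Gaussian noise clipped to
[0, 255]. Defaults: 256×256×64 voxels, 4 μm axial and 12 μm isotropic
en-face sampling, disk radius 28 px centred at (128, 32), concentric
cup of 14 px, 160 μm cup depth, 100 μm RNFL against a constant 100 μm
reference, noise s.d. 5 gray levels.

Rendering choices that matter:

* The RNFL slab has **sharp axial edges** while only the RPE/floor are
  Gaussian bands: a soft slab edge leaks gradient energy a few rows
  below the detected ILM and the first-edge rule would fire there even
  without noise. Surfaces are rounded to integer rows before rendering
  and the ground truth stores the rounded surfaces, so recovery errors
  measure segmentation, not rasterization. The RNFL truth row is the
  first dark row below the slab, matching the contrast-window
  convention of the active-edge correction.
* The **disk floor** band (default 5/3 of the RPE depth) is what makes
  the depth-excursion disk rule well-posed; with the RPE merely absent
  the brightness argmax would land on the shallower inner retina.
* **Vessel shadows dim the whole column from the ILM down.** Leaving a
  bright unshadowed cap above the vessel creates an artificial strong
  edge that both the RPE argmax and the contrast correction lock onto —
  the opposite of the low-contrast gap the correction exists to fix.
  At attenuation ≥ 0.5 the shadowed RNFL falls below the per-B-scan
  Otsu threshold and the ILM itself becomes undefined; robustness
  studies use 0.4.
* The polar annulus [2r, 3r] partially exits the 64-B-scan stack for
  the default 28 px disk; those θ bins are flagged invalid and the
  deviation score averages the remainder. Keeping the annulus fully
  inside an isotropic 256×256×64 grid would cap the disk radius at
  ~10 px, where mask rasterization alone exceeds the score tolerances.

What the phantom does **not** emulate: speckle statistics, eye motion,
curvature/tilt of the retina, peripapillary atrophy, non-circular disks
or cups, intensity inhomogeneity. Passing the phantom studies therefore
shows the pipeline implements the stated geometry faithfully and is
robust to moderate additive noise and shadows — not that it meets any
accuracy level on clinical scans.

## Synthetic cohorts

The clinical cohort behind the published structure–function
correlations is not public, so the statistical modules are validated by
parameter recovery: (i) (BGA, MD) pairs with BGA ~ U(0, 1) and
MD = 24·BGA − 9.34 + N(0, 4.1 dB) — the noise level that makes the
population correlation ≈ 0.86 for a uniform BGA; OLS must recover the
slope within ±3 over replicates; (ii) feature tables that are signed
noisy copies of three latent factors with the block/sign pattern of
clinical ONH features (cup shape with rim features negative, RNFL
thickness, disk size); the factor model must find three classes with
each feature loading > 0.7 on its own class. Problem sizes (n = 110
and n = 200, 20-phantom geometry grids at 256×256×64) were chosen so
the full suite completes in about half a minute on one core while
keeping Monte-Carlo bounds comfortably away from their thresholds.

## Known limitations

* The disk threshold couples to absolute RPE depth, so a strongly
  tilted volume shifts the mask; no tilt normalization is applied.
* `w_g(2)` inherits ~1 px mask-rasterization error in `r_min`
  (≈ 0.03 at the default 28 px disk radius).
* The active-edge correction assumes exactly one dominant
  light-to-dark transition inside the search band; pathologies with
  additional strong edges (e.g. schisis) can capture it.
* The factor-analysis variants (rotation, extraction, scoring) are
  conventional choices, not a reconstruction of the original software.
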