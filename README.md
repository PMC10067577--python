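# flimcyte

Single-cell **optical metabolic imaging (OMI)** from multiphoton
fluorescence-lifetime microscopy (FLIM), for labs quantifying immune- and
tumour-cell metabolism in intact tissue: per-pixel bi-exponential decay
fitting of NAD(P)H and FAD autofluorescence, lifetime-gated ensemble
segmentation of mCherry-labelled immune cells, per-cell extraction of the
twelve OMI parameters, and the population statistics (Glass's Δ,
Mann–Whitney, ±4 SD z-score heatmaps, Ward clustering) used to compare cell
groups. A seeded synthetic-scene generator with known ground truth makes the
whole chain testable without any microscope.

## The model

Each pixel's photon-arrival histogram is fitted to

$$I(t) = \alpha_1 e^{-t/\tau_1} + \alpha_2 e^{-t/\tau_2} + C,\qquad \alpha_1+\alpha_2=1,$$

convolved with the instrument response function. τ₁ is the short component:
*free* NAD(P)H or *protein-bound* FAD. The weighted mean lifetime is
τₘ = α₁τ₁ + α₂τ₂ and the optical redox ratio is
N/(N+F) from the two channels' intensities. The twelve per-cell parameters
are τ₁, τ₂, α₁, α₂, τₘ per channel, the redox ratio, and cell size.

Segmentation gates the mCherry lifetime map to 800–1500 ps (rejecting
non-specific red autofluorescence), intersects it with an intensity
foreground from an ensemble of 25 threshold specs (otsu, yen, minimum,
triangle, local and their pairwise unions/intersections), labels and
morphologically refines the regions (label-aware dilate/close, border
clearing, small-object filter), and lets every (threshold, expansion)
variant compete by Dice coefficient against ground truth.

## Worked example

```python
from flimcyte import (SceneSpec, generate_scene, segment_image, dice_coefficient,
                      DatasetSpec, generate_dataset, compare_groups)
from flimcyte.stats import comparisons_frame

# one synthetic field of view; segment it against its own ground truth
scene = generate_scene(SceneSpec(seed=7), channels=("mcherry",))
mask, report = segment_image(scene.intensity["mcherry"], scene.lifetime,
                             truth=scene.truth.mask)
print(f"cells found: {mask.max()}   "
      f"Dice vs truth: {dice_coefficient(mask, scene.truth.mask):.3f}")

# two synthetic immune-cell populations with built-in tissue contrasts
table, _ = generate_dataset(DatasetSpec(n_cells_per_tissue=100, seed=7))
df = comparisons_frame(compare_groups(table, "tissue", "spleen"))
print(df[["parameter", "mean_experimental", "mean_control",
          "glass_delta_abs", "mw_p", "significant_effect"]].round(3).to_string(index=False))
```

prints

```
cells found: 11   Dice vs truth: 0.867
   parameter  mean_experimental  mean_control  glass_delta_abs  mw_p  significant_effect
  nadph_tau1            377.806       373.404            0.160 0.334               False
  nadph_tau2           2209.252      2117.100            0.168 0.334               False
nadph_alpha1              0.839         0.798            4.136 0.000                True
nadph_alpha2              0.161         0.202            4.136 0.000                True
 nadph_tau_m            671.245       723.403            0.511 0.005               False
    fad_tau1            199.839       228.026            1.954 0.000                True
    fad_tau2           1961.003      2284.758            0.406 0.007               False
  fad_alpha1              0.901         0.850            4.175 0.000                True
  fad_alpha2              0.099         0.150            4.175 0.000                True
   fad_tau_m            372.337       534.945            1.453 0.000                True
 redox_ratio              0.524         0.599            3.645 0.000                True
   cell_size            141.312        94.901            4.184 0.000                True
```

The segmentation found the ten true cells plus one distractor fragment and
overlaps the ground-truth whole-cell masks with Dice 0.87. The comparison
table recovers the contrasts built into the generator — tumour immune cells
show lower FAD τₘ (≈ 372 vs 535 ps, Glass's Δ ≈ 1.5), a higher bound-FAD
fraction α₁, a lower redox ratio and ~1.5× larger size — while parameters
with no built-in shift (NAD(P)H τ₁/τ₂) stay below the Δ > 0.8 significance
gate even when the Mann–Whitney p-value is small, which is precisely why the
effect-size gate exists at single-cell sample sizes.

A decay fit by itself follows the statsmodels pattern:

```python
from flimcyte import BiexpDecayModel, biexp_forward, InstrumentResponse

irf = InstrumentResponse(center=488, fwhm=250)          # Gaussian IRF, ps
decay = biexp_forward(400, 2200, 0.6, irf=irf, total_photons=1e6)
result = BiexpDecayModel(decay, irf=irf).fit()
print(result.summary())                                  # estimates ± std err
```

There is also a CLI (`flimcyte simulate / fit / segment / features / stats /
pipeline`) that chains the stages on directories of TIFF + JSON-sidecar
files and writes a provenance JSON with every run.

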