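# reefspec

Pipeline for mapping coral bleaching from UAV-borne VNIR hyperspectral
imagery of shallow reefs: from georeferenced radiance datacubes and
in-water survey tables, through white-reference reflectance conversion,
log-ratio bathymetry and water-column correction, spectral-signature
extraction and normalized-difference bleaching indices, to RBF-SVM
pixel classification and a thematic-map accuracy report.

Because real campaign imagery of this kind is rarely shareable, the
package ships a first-class scene simulator that renders shallow-reef
scenes with known ground truth — per-(genus, bleaching level) endmember
spectra, Lambert–Beer water-column attenuation, sensor noise, survey
points and optional spume (sea-foam) contamination — so every stage of
the pipeline is testable end to end.

## Who it is for

Remote-sensing and reef-ecology researchers prototyping shallow-water
benthic classification workflows: the library gives each stage as a
plain function over NumPy arrays and pandas tables, plus a `reefspec`
CLI that runs stages individually or the whole workflow from a config
file.

## The method

**Bleaching scale.** Corals are scored on the six-point visual scale:
level 1 = severely bleached (whitest), level 6 = healthy. Classes are
(genus × level) pairs, e.g. `Porites massive L4`.

**Reflectance.** A radiance cube L(λ) is converted to reflectance with
the white-reference panel spectrum W(λ): R(λ) = L(λ)/W(λ), clipped to
[0, 1]. An optional gamma brightening v ↦ v^(1/(1+g)), g ≤ 0.75, is
available as a pre-classification step.

**Bathymetry.** Relative depth uses the standard band-ratio transform
for shallow water,

    index = ln(n·R_blue) / ln(n·R_green),    n = 1000 (default),

at the grid bands nearest 480 and 540 nm. Green light attenuates faster
than blue, so the index increases monotonically with depth and is
approximately independent of bottom brightness. A least-squares line
against surveyed depths calibrates it to metres.

**Water-column correction.** The fraction of spectral variance due to
the water column is modelled by an empirical quadratic in the
log-transformed green/blue ratio x = ln(R_green/R_blue):

    y(x) = −18.353·x² + 10.805·x + 0.238   (percent, floored at 0)

and each spectrum is rescaled by 1/(1 − y/100).

**Indices.** The registry holds 34 normalized-difference bleaching
indices (R_λ1 − R_λ2)/(R_λ1 + R_λ2) spanning 395–768 nm for *Acropora*,
*Porites* massive, *Goniopora*, *Turbinaria* and soft corals, the
four-band genus index (R_540 − R_575)/(R_450 + R_586), and green/yellow
NDVI variants against 750 nm.

**Classification.** A one-vs-one support vector machine with the
Gaussian radial basis kernel

    K(x_i, x_j) = exp(−γ‖x_i − x_j‖²),  γ > 0,

trained on labeled spectra from windows around survey points, classifies
every pixel. A k-means partition flags pixels whose supervised label
disagrees with their cluster's majority (it never overwrites them), and
Savitzky–Golay spectral smoothing plus per-band spatial median filtering
denoise the cube. Spume polygons can be rasterized into an exclusion
mask applied to training, mapping and assessment.

**Accuracy report.** Per surveyed class: a signature match score, the
fraction of survey points whose class appears within a 3×3 window of
their pixel, mapped pixel count and scene-area percent, an
excessive-area (EA) flag when the mapped area exceeds 5× the class's
reference prevalence, and an overall accuracy that is 0 for EA rows and
otherwise min(signature %, points %).

## Worked example

```python
from reefspec.experiments import recall_experiment, bathymetry_experiment

for cls, recall in recall_experiment(seed=1).items():
    print(f"{cls:22s} recall {recall:.3f}")
rho, albedo_spread, depth_spread = bathymetry_experiment(seed=1)
print(f"spearman {rho:.4f} albedo_spread {albedo_spread:.4f} "
      f"depth_spread {depth_spread:.4f}")
```

prints

```
Acropora L1            recall 1.000
Acropora L3            recall 1.000
Acropora L5            recall 1.000
Porites massive L2     recall 1.000
Porites massive L4     recall 1.000
Porites massive L6     recall 1.000
spearman 1.0000 albedo_spread 0.0101 depth_spread 0.0289
```

The first block is per-class recall of the depth-corrected SVM map on a
128×128 synthetic scene (six coral classes, 0–3 m depth, 1% reflectance
noise, 64 survey points): every class is recovered. The second line
shows the relative-depth index rank-correlates perfectly with true depth
on a zero-noise scene, and that switching the bottom from bright sand to
dark benthos moves the index by about a third of what a 1 m depth change
does — the albedo robustness that makes the log-ratio usable without
knowing the bottom type.

The same workflow runs from the shell:

```sh
reefspec simulate --out-dir scene --rows 64 --cols 64 --seed 1
reefspec run-all config.txt       # paths + parameters in a key=value file
```

producing a class map, depth map, signature table, index rasters and the
accuracy-report CSV under the configured output directory.

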