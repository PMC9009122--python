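# lysoquant

Quantification of lysosomal health from multichannel fluorescence
microscopy, for labs studying lysosomal dysfunction in neurons — e.g.
lysosomal membrane permeabilization (LMP) and impaired autophagy in
Parkinson's-disease models.

Given confocal images of a cell-body marker (such as tyrosine hydroxylase),
a nucleus stain, a lysosome membrane marker (LAMP2) and a lysosomal enzyme
(cathepsin D), `lysoquant` computes per cell:

- **puncta counts and areas** — difference-of-Gaussians denoising, automatic
  (isodata/Otsu) thresholding inside the cell mask, binarization,
  8-connected component labelling, and an area filter discarding puncta
  smaller than 10 px;
- **colocalization** — pixel-wise Pearson *r* within the cell, thresholded
  Manders coefficients M1 = Σᵢ Aᵢ·[i ∈ mask_A ∩ mask_B] / Σᵢ Aᵢ·[i ∈ mask_A]
  (and M2 symmetrically), and the binary-AND overlap area;
- **the LMP score** — the fraction of enzyme signal *outside* lysosomes,
  cytosolic fraction = 1 − lysosomal/total, either area-based on binary
  masks or intensity-weighted with local cytosolic background subtraction;
- **lysosome positioning** — the nucleus reduced to its moment-equivalent
  ellipse; each lysosome's distance to the nuclear border defined as
  |centroid − ellipse centre| − (a+b)/2, in cells passing a 2:1
  cytoplasm:nucleus area gate;
- **autophagy flux** — yellow (GFP ∧ mCherry, autophagosome) versus red
  (mCherry only, autolysosome) dot classification of the tandem
  mCherry-GFP-LC3 reporter;
- **ratiometric pH** — a linear 440/535-nm emission-ratio standard curve
  over pH 3.5–7.0, fitted ratio-on-pH and inverted;
- **statistics for nested data** — two-way fixed-effects ANOVA with Tukey
  HSD, unpaired *t*, and a nested *t*-test that averages cells within each
  animal and compares animal means (the animal is the independent unit).

Because raw microscopy of this kind is rarely shareable, the package ships
a first-class synthetic-data generator (`lysoquant.synthgen`): confocal-like
fields at 80-nm pixel size with elliptical nuclei, superelliptical cell
bodies, Gaussian-spot puncta with a controllable colocalized fraction, a
diffuse cytosolic component, PSF blur, and Poisson + Gaussian read noise —
with every hidden parameter recorded as ground truth, so the whole pipeline
is testable end to end.

## Worked example

```python
import lysoquant as lq

params = lq.ImageSimParams(seed=42, coloc_fraction=0.75, diffuse_fraction=0.3)
image, rois, truth = lq.simulate_cell_image(params)

counts, _ = lq.quantify_puncta(image, rois)
print(counts[["cell_id", "channel", "count", "total_area_um2"]].to_string(index=False))

coloc = lq.quantify_coloc(image, rois, lmp_variant="intensity")
print(coloc[["pearson_r", "m1", "m2", "cytosolic_fraction"]].round(3).to_string(index=False))

distances, _ = lq.quantify_position(image, rois)
print(f"median distance to nucleus border: {distances['distance_to_border_um'].median():.2f} um")
```

prints

```
cell_id  channel  count  total_area_um2
 cell00 puncta_a     11          2.0864
 cell00 puncta_b     15          2.9184
 pearson_r    m1    m2  cytosolic_fraction
     0.828 0.984 0.716               0.561
median distance to nucleus border: 0.80 um
```

The field was simulated with 11 lysosome-channel and 15 enzyme-channel
puncta — both recovered exactly. M2 ≈ 0.72 reflects that 11 of the 15
enzyme puncta sit on lysosomes (11/15 ≈ 0.73). The measured cytosolic
fraction 0.56 combines the designed 30 % diffuse (leaked) signal with the
four enzyme puncta placed outside lysosomes: of the remaining 70 % punctate
signal, 4/15 is non-lysosomal, so ≈ 0.30 + 0.70 · 0.27 ≈ 0.49 plus PSF
tails — the score measures *non-lysosomal* enzyme, not only the diffuse
part. Lysosomes sit on average 0.8 µm outside the nuclear border at the
simulated 80-nm pixel size.

The same operations are available from the shell:

```sh
lysoquant simulate image --seed 42 --out-dir sim/
lysoquant quantify coloc --image sim/field.ome.tif \
    --cytoplasm sim/cytoplasm_labels.tif --nuclei sim/nucleus_labels.tif \
    --min-area 10 --threshold isodata --out coloc.csv
lysoquant stats --records measurements.csv --test nested-t --out stats.csv
```

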