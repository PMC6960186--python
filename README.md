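# fwrnet

Fuzzy weighted recurrence networks (FWRN) of multi-channel images, with a
paired biopsy/tumor cohort analysis for immunohistochemistry (IHC) data.

## The problem

Pathologist scoring of IHC-stained tissue (brown DAB-positive signal on a
blue hematoxylin counter-stain) is subjective and coarse: a whole slide is
reduced to an intensity grade of 0–3. `fwrnet` instead quantifies the
*spatial texture* of stain expression by turning each image tile into a
weighted complex network and summarising it with two graph statistics.
Because the construction works on any multi-channel raster, it applies to
RGB histology tiles, grayscale images, or other channel stacks.

It is intended for computational-pathology and image-analysis researchers
who want a texture-sensitive, fully automated alternative to manual IHC
grading — in particular for paired specimen designs (a biopsy taken before
therapy and a resected tumor after it) where the *ratio* of a texture
statistic between the two specimens is the candidate biomarker.

## The method

For an image **I** of size M × N × K, every pixel whose
(2m+1) × (2m+1) window fits in the image is summarised per channel by the
window's Frobenius norm, giving feature vectors

> y_ij = ( ‖W_ij1‖_F, …, ‖W_ijK‖_F ),  ‖W‖_F = √(Σ f²)

Fuzzy c-means (weighting exponent α, c clusters) assigns each vector x_n a
membership μ_ni ∈ [0,1] to every cluster. Pairs of vectors are then scored
by the max–min fuzzy similarity routed through the clusters,

> R_ab = max_i min(μ_ai, μ_bi),  W = R − I,

yielding a dense symmetric edge-weight matrix in [0,1] — the fuzzy weighted
recurrence network. Two statistics summarise it:

* **CC** — average weighted clustering coefficient (Fagiolo form),
  C_i = Σ_{j,k} (w_ij w_ik w_jk)^{1/3} / (k_i (k_i − 1));
* **CP** — characteristic path length, the mean of all-pairs Dijkstra
  shortest path lengths after mapping similarity weights to lengths
  (default length = 1/w).

The cohort pipeline tiles each slide into 150 × 150 subimages, drops
mostly-background tiles, averages CC and CP over kept tiles per specimen,
forms per-patient tumor/biopsy ratios, and correlates those ratios with
survival within shorter- and longer-survival subgroups (Pearson R with a
two-sided sign-test p = 2·(1/2)^n). Predictive probabilities are estimated
as the fraction of patients inside a ratio window whose survival falls in a
target range. A 25-patient rectal-cancer cohort table ships as a packaged
fixture.

## Worked example

```python
import fwrnet as f

# a synthetic two-stain IHC-like tile: brown blobs on blue background
img = f.generate_ihc_image(
    f.StainTextureParams(image_size=(64, 64), blob_scale=4.0, seed=7))

feats = f.extract_features(img, f.WindowConfig(m=3, node_stride=4))
net = f.build_network(feats, f.FCMConfig(c=8, seed=0))
m = f.compute_metrics(net)
print(f"CC = {m.CC:.4f}, CP = {m.CP:.4f}, nodes = {m.n_nodes}")
```

prints

```
CC = 0.1085, CP = 8.0177, nodes = 225
```

A 64 × 64 tile at m = 3 has 58 × 58 valid window centers; stride 4 keeps
225 of them as network nodes. Regenerating the same image with a finer
stain texture (`blob_scale=2.0`, same seed) gives `CC = 0.0651` — the
clustering coefficient rises with spatial stain coherence, which is what
makes the tumor/biopsy CC ratio informative about texture change between
specimens.

The same computation from the shell:

```bash
fwrnet make-fixtures --out-dir fixtures --n-patients 8 --image-size 64
fwrnet metrics fixtures/S001_biopsy.png --tile-size 64 --clusters 8 --out m.csv
printf 'tile_size: 64\nc: 8\n' > small.yaml   # fixture tiles are 64 px
fwrnet cohort fixtures/manifest.csv fixtures/cohort.csv --config small.yaml --out-dir report
```

`report/` then contains per-specimen means, per-patient ratios, subgroup
associations and ratio-window probabilities, each stamped with the config
hash and seed.

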