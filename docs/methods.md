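# Methods

This note documents the models, numerical choices and limitations behind
`fwrnet`, in the package's own terms.

## Window features

Each pixel with a full (2m+1) × (2m+1) neighbourhood inside the image is
summarised per channel by the Frobenius norm of its local window — the
square root of the sum of squared intensities. The norm depends only on
the multiset of window values, so it is exactly invariant under
right-angle rotations and flips of the window (invariance under arbitrary
rotations holds only approximately on a pixel grid, and the test suite
asserts only the exact discrete cases). A `squared_norm` switch drops the
radical for users who want raw window energy; all defaults use the true
norm. Centers whose window would cross the image boundary are skipped, so
stride-1 extraction of an M × N image yields (M − 2m)(N − 2m) vectors.

`node_stride` (default 4) subsamples valid centers every s-th row and
column. This is a tractability control: a 150 × 150 tile at m = 3 has
144² = 20 736 valid centers, and the recurrence network is dense, so the
pairwise relation at stride 1 would need ~3.4 GB and all-pairs Dijkstra
over 20 736 nodes is far beyond routine budgets. Stride 4 gives 1 296
nodes per 150-tile (225 per 64-tile), which preserves the texture
statistics the metrics respond to. Stride is configurable down to 1 for
small tiles.

Intensities are normalised to [0, 1] on load whatever the source bit
depth; coordinates are 0-based (row, col).

## Tiling and background exclusion

Slides are cut into non-overlapping square tiles (default 150 px) in
row-major order; trailing partial tiles are dropped rather than padded.
A tile is excluded as background when more than `max_background_frac`
(default 0.5) of its pixels have mean channel intensity above
`white_luminance_frac` (default 0.9) of full scale. Both thresholds are
configurable and logged per tile; near-white is the right background
criterion for brightfield IHC scans, but not for fluorescence data.

## Fuzzy c-means and the recurrence network

FCM alternates the closed-form center update
v_j = Σ μ_nj^α x_n / Σ μ_nj^α and the membership update
μ_nj = 1 / Σ_i (d_nj/d_ni)^{2/(α−1)} from a seeded uniform-random
row-stochastic U, stopping when the Frobenius norm of the membership
change falls below ε (default 1e-5) or after T = 100 iterations. Each
alternation weakly decreases the objective J = Σ μ^α d², which the fit
records per iteration. Degenerate zero distances (a point coinciding with
a center) get a crisp membership, split equally over coincident centers.
Defaults α = 2, T = 100, ε = 1e-5, and c = 20 for full-size 150-px tiles
(near the partition-entropy optimum for such data); the smaller test
tiles use c = 8. Partition entropy is Bezdek's
H = −(1/L) Σ μ ln μ — natural log, so 0 ≤ H ≤ ln c, 0 for crisp
partitions; the log base only rescales H and cannot change the argmin
used for cluster-count selection (ties break toward smaller c).

The network relation is computed between data-point pairs routed through
the clusters, R_ab = max_i min(μ_ai, μ_bi): two windows are similar when
some cluster claims both strongly. Reflexivity fixes R_aa = 1, and the
adjacency is W = R − I. Consequences worth knowing: W is symmetric with
entries bounded by each endpoint's maximum membership; crisp partitions
make W binary and block-structured (connecting recurrence classes); and W
is dense whenever memberships are spread. One FCM (and hence one network)
is fit per tile — fitting one global partition per slide would change the
meaning of cross-tile comparisons and is deliberately not done; the
per-tile choice is recorded in each network's provenance.

## Network statistics

The weighted clustering coefficient follows Fagiolo:
C_i = Σ_{j,k} (w_ij w_ik w_jk)^{1/3} / (k_i(k_i − 1)) with k_i the count
of neighbours with w > τ (default τ = 0, so a dense positive W gives
k_i = L − 1). Weights are used raw since they already lie in [0, 1]; a
`normalize_by_max` flag reproduces Fagiolo's original max-scaling (and
the networkx convention, which the tests cross-check). Nodes of degree
0 or 1 contribute C_i = 0 and are included in the average by default;
`exclude_low_degree` averages over degree-≥2 nodes instead. With 0/1
weights the statistic reduces exactly to the unweighted
triangle-density coefficient.

Shortest paths are Dijkstra over transformed edge lengths. Weights are
similarities, not costs, so a transform is required and is stamped into
every result: default length = 1/w (CP ≥ 1 whenever weights ≤ 1);
length = 1 − w is available but rejects unit-weight edges (zero length).
CP averages over ordered pairs, 1/(N(N−1)) Σ d_ij — identical to the
unordered mean for symmetric networks. A disconnected network raises an
error naming the component count rather than returning an infinite or
silently truncated mean.

Useful invariances, all property-tested: CC scales linearly and CP
inversely under uniform weight scaling (fixed topology, reciprocal
transform); both are invariant under node relabeling.

## Cohort analysis

Per specimen, CC and CP are arithmetic means over kept tiles; tiles from
several slides of the same (patient, specimen) pool into one mean. The
biomarker is the per-patient tumor/biopsy ratio of each metric. Patients
split into a shorter-survival group (≤ 75 months) and a longer-survival
group (≥ 101 months); survivals strictly between the boundaries (none in
the packaged cohort) are left unlabelled with a warning.

Within each group the ratio–survival association is reported as the
Pearson correlation R together with a two-sided sign-test probability
2·(1/2)^n, which depends only on the group size (9.7656e-04 at n = 11,
1.2207e-04 at n = 14). The sign-test form is the package's reporting
convention for these very small subgroups; it is not the sampling p-value
of the Pearson statistic, and the two should not be conflated — R carries
the effect size, p the binary concordance benchmark. Predictive
probabilities are k/n counts: among the n patients whose ratio lies in a
closed window (defaults: CC ratio ∈ [0.97, 1.05], CP ratio ∈
[0.99, 1.10]), the fraction k/n whose survival lies in a closed target
range (101–288 months for CC, 126–288 for CP). All windows are
configurable.

The packaged 25-patient table is carried as raw columns. Its source
prints internally inconsistent demographic summaries (a gender split
reversed between two summary tables, and a follow-up range matching no
per-patient column); the fixture exposes only the per-patient columns and
leaves those summaries unreconciled.

## Synthetic data

`generate_ihc_image` emulates a brightfield two-stain field: a seeded
white-noise image blurred with a Gaussian kernel of width `blob_scale`
(the spatial correlation length, in pixels) is thresholded at the
(1 − dab_fraction) quantile; above-threshold pixels take a brown DAB hue,
the rest a blue hematoxylin hue, plus clipped per-channel Gaussian noise
(sd 0.03). Quantile thresholding pins the realized stain fraction to the
target within a few pixels. The generator captures two-class color
structure and tunable texture scale — it does *not* model optical-density
stain mixing, nuclear morphology, tissue folds or scanner artifacts, so
tests passing on it demonstrate sensitivity to spatial stain texture, not
robustness to real histology confounds.

The network CC rises monotonically with `blob_scale` over roughly 2–8 at
the 64-px/stride-4/c = 8 operating point (mapped empirically; the
response flattens and gets noisier above ~8). The synthetic cohort
exploits this: each patient's biopsy uses blob scale 3, the tumor uses
3·r with a heterogeneity ratio r spread evenly over [0.7, 2.4] (small
seeded jitter, random assignment), so tumor blob scales stay inside the
monotone region.

Cohort survivals: responders get survival = 180 + 60·(r − 1) months plus
Gaussian noise (sd 10), clipped to the longer-survival band 101–288;
non-responders get survivals uniform in the shorter band 15–75. Two
deliberate variance-control choices make small-cohort tests meaningful:

* the responder noise is residualized against r, so the realized slope
  is exactly the designed effect and a zero effect size yields exactly
  uncorrelated survivals;
* the non-responder survivals are residualized against {r, r²}, making
  that arm an *exact* empirical null rather than a sampled one (a sampled
  null at n = 14 fluctuates with sd ≈ 0.28 in R, which would swamp any
  null assertion).

Even so, the measured ratio carries per-tile metric noise, and the chance
correlation between that noise and survival is amplitude-invariant; the
remedy is the method's own: specimens are 256 × 256 (sixteen 64-px tiles
averaged), mirroring whole-slide multi-tile averaging and keeping the
noise share of the measured-ratio variance small. At this operating point
the end-to-end pipeline recovers responder-arm R ≈ 0.87–0.92 and null-arm
|R| ≤ 0.13 across the first few seeds.

## Problem sizes and determinism

Default test and acceptance computations use 64-px tiles (225-node
networks), c = 8, 28-patient synthetic cohorts (896 networks end to end);
full-size 150-px tiles at c = 20 produce 1 296-node networks and take
~15 s each, dominated by dense all-pairs Dijkstra. Every stochastic step
(FCM initialisation, texture fields, cohort draws, fixture graphs) is
driven by an explicit integer seed, and identical inputs reproduce
bit-identical outputs, including CSV bytes; output files carry the config
hash and seed.

## Known limitations

* No stain deconvolution or color normalisation: channels are raw R/G/B,
  so staining-protocol shifts change features directly.
* Dense networks only; no sparse/approximate relation construction, so
  node counts beyond a few thousand are impractical.
* The sign-test p is a size-only benchmark, not an exact test of the
  Pearson statistic.
* Absolute CC/CP magnitudes on real slides have no packaged reference;
  correctness rests on closed forms, brute-force oracles and invariants.
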