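# Methods

## Pipeline model

The package estimates the Ki-67 proliferation index of one exported
region-of-interest image (a "pROI": an 8-bit RGB raster of a pathologist's
hot-spot selection) in four stages.

**Fragment classification.** The image is tiled with a square window of
side `w` ∈ {48, 96, 192} px. For evaluation the stride is 16 px so windows
overlap heavily; for classifier training the stride equals the window, so
fragments are disjoint and near-duplicates do not inflate the pool. A
fragment's training label is 1 when at least one annotated tumor-nucleus
*center point* falls in its half-open extent `[r, r+w) × [c, c+w)` — both
stain classes count, since this stage detects tumor-cell presence, not
Ki-67 status. Right/bottom margins narrower than the window are not tiled:
padding would invent pixels, and margin pixels are handled explicitly by
the membership stage instead.

**Fuzzy ROI defuzzification.** Each pixel belongs to two fuzzy classes,
"tumor cluster" and "irrelevant", with linear membership functions
μ_tumor = (positive covering windows)/(covering windows) and
μ_irr = 1 − μ_tumor. With a 96 px window on a 16 px stride an interior
pixel is covered by (96/16)² = 36 windows, the maximum membership count.
Assigning every pixel to its best class (the argmax of the two linear
memberships) is exactly the μ_tumor > 0.5 rule, which is how the crisp ROI
mask is produced; the cutoff is exposed for experimentation. Two documented
choices where the procedure is underdetermined:

* *Border normalization.* Coverage is counted per pixel rather than fixed
  at the interior constant; otherwise border pixels (covered by fewer than
  36 windows) could never reach full membership. Pixels outside every
  window get membership 0 and an `uncovered` flag.
* *Ties.* μ exactly equal to the cutoff goes to background, favoring
  specificity — the ROI exists to exclude doubtful content such as stain
  artifacts.

**Stain segmentation and the area-ratio PI.** RGB pixels are unmixed by
color deconvolution with the standard hematoxylin–eosin–DAB stain matrix
(scikit-image's implementation; the eosin channel is unused). Stain
densities are in the HED space's normalized absorbance units, where 1.0
corresponds to near-total light absorption; a well-stained nucleus sits
around 0.08–0.13. Each channel is thresholded by Otsu's criterion computed
on a 256-bin histogram of the ROI pixels only — restricting the histogram
to the ROI is what keeps out-of-ROI artifacts from biasing the cut.
Density comparisons are strict (`>`), with ties to background. Each channel
mask is binary-closed then dilated (disk structuring elements, radius 1 by
default, configurable) and

    PI = |DAB mask| / |DAB mask ∪ hematoxylin mask|.

The union denominator is a deliberate choice: DAB-positive nuclei are weak
in the hematoxylin channel, so "all relevant cells" measured by the
hematoxylin mask alone would undercount, and the union is the only
composition that makes `dab_area ≤ relevant_area` structurally true.
Morphology is applied per channel before the union (the alternative order
is noted as open; applying it before keeps each channel's cleanup
independent of the other's). If the ROI stage returns an empty mask the
slide is assumed non-tumorous rather than rejected: segmentation falls back
to the whole image and the estimate carries a `roi_fallback` flag.

*Degenerate channels.* Otsu's criterion assumes a bimodal histogram. On a
slide with no DAB staining at all, the DAB channel contains only sensor
noise, and the maximal-variance cut would promote half of that noise to
"stained". A channel is therefore treated as unstained when the separation
between its sub- and supra-threshold means falls below 0.015 density units
(an order of magnitude above the noise scale, several times below true
stain levels); its mask is then empty. The guard applies only to
thresholds computed on the slide itself, never to explicit reference
thresholds.

**Threshold biasing.** Per-slide Otsu fails on slides whose histogram is
atypical — in particular heterogeneous staining, where a weakly stained
nucleus subpopulation sits between background and the strong mode and the
maximal-variance cut lands above it. Reference thresholds are the
per-channel arithmetic means of per-slide Otsu thresholds computed inside
training slides' ground-truth ROIs; in a k-fold layout each chunk's
references come from the complementary chunks only. The default biasing
rule is outright replacement (convex weight 1.0 toward the reference),
since references exist precisely for slides whose own histogram misleads;
the weight is exposed because a blend is equally defensible.

**Ensembling.** Three same-window models vote per fragment; a fragment is
positive when at least two models agree. Mean scores are reported for
inspection but labels come from the vote. Mixed window sizes are rejected.

## Classifiers

The trainable classifier (`tiny_cnn`) is a compact convolutional network —
3×3 conv (8, 16, 32 channels) with ReLU, 2×2 max-pooling after the first
two blocks, global average pooling, and a single-logit head — implemented
directly on numpy. That choice makes training bit-reproducible from a seed
on any machine and keeps a full 50-epoch run on a few hundred fragments
within a couple of CPU-minutes; it is sized for the synthetic data, not for
clinical material. Training follows the pipeline's fixed recipe: Adam at
learning rate 0.001, batch size 128, up to 50 epochs, binary cross-entropy,
a stratified 4:1 train/validation split (stratification prevents a
single-class validation subset on small pools), and a checkpoint kept only
when validation loss improves — the returned artifact always carries the
best-validation weights. Inputs are per-channel scaled to [0, 1]; no other
normalization or augmentation is applied. The `bn_momentum` configuration
field is echoed for provenance but unused, as this architecture contains no
batch normalization.

The deterministic heuristic classifier labels a fragment positive when the
fraction of its pixels with DAB or hematoxylin density above 0.02 reaches
`min_stained_fraction`. It has two useful operating points: the default
0.18 rejects compact artifact blobs and isolated lymphocytes (both small
relative to a 96 px window) while dense tumor clusters pass — emulating
what the trained model learns from texture — whereas a cut near the area of
a single nucleus (~0.01) approximates the "at least one relevant cell"
labeling rule itself and agrees with annotation-derived labels on ≥ 99% of
fragments on clean synthetic slides. The default trades cluster-edge
sensitivity for artifact rejection; the trimmed edge windows cost little
because the area *ratio* inside the detected ROI is insensitive to losing
a symmetric margin of nuclei.

## Synthetic data

The generator emulates the statistical structure of annotated Ki-67 pROIs:

* tumor nuclei as mildly eccentric filled ellipses (radius 5–8 px) packed
  without overlap into circular clusters (2 clusters of radius 80 px with
  40–70 nuclei each on a 448×448 canvas by default — a desk-scale stand-in
  for multi-megapixel pROIs that keeps a 20-slide experiment in seconds);
* each nucleus independently DAB-positive with probability `target_pi`;
  the *realized* labels are what the annotations and stored true PI record,
  so ground truth is exact by construction, not by expectation;
* isolated lymphocytes (smaller, darker, hematoxylin-only, never annotated
  — single cells outside clusters are skipped by the annotation protocol)
  and irregular stain-blob artifacts, both placed strictly outside the
  cluster footprints that define the ground-truth ROI;
* a pale stromal wash and per-pixel noise, an order of magnitude below
  stain levels.

Rendering goes through the inverse HED transform, so the colors seen by the
downstream deconvolution are physically consistent with the densities laid
down; forward deconvolution recovers them to within 8-bit quantization
(mean absolute density error < 0.005). All randomness flows from the single
config seed through one generator instance; identical configs give
bit-identical slides. The `dab_weak_fraction` knob renders a fraction of
positive nuclei at faint intensity (0.025–0.038), reproducing the
heterogeneous-staining failure mode that motivates threshold biasing.

What the generator does *not* model — chromatin texture, nuclear grade
variation, scanner color profiles, vessels and fibers, uneven section
thickness — bounds what passing tests show: they validate the pipeline's
logic and its qualitative claims (artifact robustness, biasing direction),
not clinical accuracy on real material. Lymphocyte and artifact densities
are chosen for test discrimination, not realism, as no quantitative
reference for them exists.

## Evaluation

Fragment classification is scored by accuracy, precision, recall and F1
from confusion counts; zero-denominator ratios are reported as undefined
(`None`) rather than 0, since silent zeros would bias averaged summary
tables. AUROC equals the Mann–Whitney statistic (ties counted half). PI
estimates are scored by MAE and RMSE over slides; an estimate missing truth
by more than 0.2 absolute (strict) counts as *invalid*, a reliability
criterion. The 95% confidence interval of the MAE is a seeded percentile
bootstrap over slides (10,000 resamples) with the lower bound clipped at 0,
a distribution-free choice that honors the MAE's non-negativity.

## Numerical choices and limitations

* Masked Otsu uses scikit-image's `threshold_otsu` on the masked pixel
  values (256 bins over the observed range). Between-class variance is
  exactly constant across empty histogram bins between well-separated
  modes, so the argmax bin within such a plateau is determined by
  floating-point summation order; tests therefore compare thresholds by the
  variance they achieve, not by bin identity.
* 16-bit scanner exports are rescaled to 8-bit by keeping the high byte
  (logged), not rejected.
* Cell Counter marker XML coordinates are 1-based and converted to the
  package's 0-based, x = column / y = row, pixel-center convention at the
  I/O boundary.
* The membership accumulation uses a summed-area (integral image) scheme,
  O(pixels) regardless of overlap depth; tests verify it against the
  direct per-pixel covering-window definition.
* Cluster and object placement is dart throwing with bounded retries; an
  infeasible request (too much content for the canvas) raises an explicit
  error rather than silently truncating.
* Published stain vectors are assumed; per-scanner stain calibration is out
  of scope, as are whole-slide pyramids, hot-spot selection (pROIs are
  inputs), and nucleus instance counting (the area ratio replaces it).
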