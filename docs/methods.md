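# Methods

`bundleseg` detects and characterizes fiber bundles — regions of a histological
section where tracer-labeled axons travel closely together — on dark-field
photomicrographs of coronal brain sections. This note documents the model, the
training procedure, the post-processing priors, the density estimator, the
synthetic-data generator the tests rely on, and the numerical choices made
where the design was genuinely open.

## Segmentation model

The model is a dual-head 2D U-Net:

* **FSeg** — a standard encoder/decoder with skip connections, per-level
  channel doubling, batch normalization and ReLU, ending in a 1×1 convolution
  with two output classes (fiber bundle vs background, softmax). Output
  resolution always equals input resolution, which makes tiled whole-section
  inference safe.
* **FClass** — a classification arm attached to the encoder bottleneck:
  a downsampling module of two rounds of (2×2 max-pool → two 3×3 conv layers),
  global average pooling, then fully connected layers fc(1024) → fc(256) →
  fc(2). The fc(256) activations double as the embedding used by the
  contrastive loss; a config switch (`contrastive_features = embedding|logits`)
  selects the 2-node output instead. Cosine similarity on a 2-logit output is
  unusual, so the 256-d embedding is the default.

Because no deep-learning framework is available in the target environment, the
layers live in a small in-house numpy framework (`bundleseg.nn`) with manual
backward passes. Every layer's gradient, and the composed model's, is verified
against central finite differences in the test suite. Global average pooling
bridges the conv feature map to the fully connected stack so the arm is
input-size independent.

The 1×1 output convolution uses a *prior-probability* bias initialization
(fiber prior ≈ 1%), the standard companion of the focal loss: the abundant
background class starts near-correct, so early gradients concentrate on the
rare fiber class. Without it, a from-scratch model spends most of a short CPU
training budget pulling the background away from p = 0.5.

## Losses

**Focal loss** (segmentation): `FL(p_t) = −α_t (1−p_t)^γ log(p_t)` with
`p_t = p` for fiber pixels and `1−p` otherwise, `α_t = α` for fibers and `1−α`
for background (the focal-loss literature's convention — only `α = 0.25`,
`γ = 2` are given). Probabilities are clamped at 1e-7 for log stability.

**Contrastive loss** (classification arm): the NT-Xent objective of SimCLR over
a batch of N positive pairs, temperature τ = 0.5. Feature rows are interleaved
((2m, 2m+1) form pair m) and the loss is the mean over all 2N *ordered* pairs
(the SimCLR convention; whether the original averaged ordered or unordered
pairs is not stated). The printed form of the loss omits the −log of the
softmax ratio; the implementation uses the standard −log form, as the stated
SimCLR ancestry requires.

## Positive pairs and augmentation

A positive partner for an anchor patch is cropped at a center displaced by at
most 20 µm (sub-pixel at coarse working resolutions — the partner then simply
shares the anchor's center), constrained to white matter: if a white-matter
mask is available, ≥ 80% of the candidate's pixels must be white matter;
otherwise candidates are resampled (up to 50 times) until their mean intensity
falls in a configured band. The band's synthetic default brackets the
generator's background mean; for real data it should be calibrated to typical
white-matter background. After acceptance the partner receives additive
Gaussian noise (σ = 0.02 of full scale — amplitude unstated, exposed as
config) and Gaussian blur with σ ∈ [0.05, 0.3]. Only the partner is perturbed
by default (switchable): perturbing one side suffices to create an invariance
target. If no candidate passes, the anchor itself is used, with a logged
warning.

Segmentation training uses one joint geometric transform per patch:
translation ∈ [−50, 50] px, rotation ∈ [−20°, 20°], horizontal/vertical
flips, scale ∈ [0.9, 1.2]; bilinear for the image, nearest-neighbour for the
label map.

## Training

**Pretraining** uses only the manually charted sections: focal loss on FSeg
plus weighted NT-Xent on FClass pairs, Adam with learning rate 1e-3 (the
source prints "(ϵ=10⁻³)", read as the learning rate — Adam's numerical epsilon
is conventionally 1e-8), batch size 8. Patches are sampled uniformly over the
tissue area; a patch is class-labeled *fiber* when ≥ 5% of its area overlaps a
bundle (the patch-level labeling rule is not given by the source; 5% is a
documented choice). 10% of patches form a validation split; early stopping
uses patience 25 and the best-validation weights are restored.

**Temporal ensembling (TE)** then adds unlabeled sections. Each unlabeled
section contributes a fixed, deterministic grid of patches (stride = patch
size, centers inside tissue) so that per-epoch predictions stay aligned;
random sampling would make prediction histories incoherent. The pseudo-label
of a patch is the mean of its last r = 3 prediction maps thresholded at 0.5
(ties positive); until r post-pretraining predictions exist, the thresholded
pretrained prediction is used. Labeled patches keep their manual labels;
both kinds contribute focal + contrastive terms. Contrastive learning is
confined to labeled sections during pretraining (the source is ambiguous; the
most literal reading was chosen).

Early stopping treats the *incoming* weights as the baseline: if no TE epoch
improves the validation focal loss, the pretrained weights are what
"best-validation weights" means. This matters at desk scale — a briefly
pretrained model produces unsaturated probability maps, its thresholded
pseudo-labels inherit the boundary uncertainty, and self-training can erode
the bundles (the classic confirmation-bias failure of pseudo-labeling). The
fallback keeps TE from ever costing more than noise; with long pretraining
(the full-scale regime) TE improves validation and is adopted.

## Inference and post-processing

Whole sections are predicted in one pass when they fit in a tile (1024 px by
default; desk-scale runs use 512), otherwise on a tile grid with optional
overlap averaging; edge tiles are reflection-padded. Binary maps use a 0.4
threshold (≥, documented tie rule).

False positives are removed with two priors:

1. **Cross-section continuity.** Sections are downsampled ×10 and aligned by
   translation on a landmark — the centroid of the largest interior dark
   cavity (a ventricle proxy), else the tissue bounding-box center; alignment
   is deliberately approximate. A pluggable consensus stage produces a low-res
   3D segmentation of persistent bundles; the default z-averages neighbouring
   probability maps with a 3×3×3 mean kernel and thresholds at the inference
   threshold. (The literature's triplanar 3D U-Net for this stage is *not*
   re-implemented; any 3D segmenter with the same signature can be plugged
   in.) A detected region is deleted when its minimum in-plane Euclidean
   distance to the thresholded mean of its up-to-two neighbouring sections'
   consensus masks exceeds 0.5 mm. Minimum pixel-to-foreground distance is
   used rather than centroid distance, which would wrongly delete large
   elongated bundles; an empty reference deletes the region. The distance is
   measured in-plane: consecutive annotated sections are 1.2 mm apart, which
   already exceeds the threshold.
2. **Morphology.** Regions with area < 2 mm² or closer than 0.5 mm to the
   tissue outline are deleted. Areas and distances are computed at full
   resolution in physical units via the µm/pixel calibration.

Filters only ever delete regions — survivor masks are byte-identical to their
inputs.

## Fiber density

FD of a bundle = fraction of its pixels whose CLAHE-enhanced luminance
(Rec. 601) strictly exceeds the 95th percentile of values *within that region*
(region-level percentiles are a documented reading; whole-section percentiles
would couple a bundle's FD to unrelated image content). With CLAHE disabled
the rule depends only on intensity ranks, so FD is invariant under monotone
intensity transforms. CLAHE uses 8×8 tiles and clip limit 0.02 in
scikit-image's [0, 1] convention (the OpenCV-style "2.0" has no direct
equivalent; both are exposed in config). Note the percentile rule marks ≈ 5%
of region pixels by construction — FD values cluster near 5% and the
interesting signal is *which* pixels exceed the threshold and how FD shifts
with boundary tightness.

Regions are assigned to a white-matter pathway (internal capsule, corpus
callosum, uncinate fasciculus) when the largest fractional overlap
(intersection / region area) exceeds 0.4; ties break by absolute intersection,
then by the fixed order IC, CC, UF. Pathway FD differences are tested with a
one-way ANOVA (scipy), reported as F, p and per-group mean ± SE.

## Evaluation

A manual bundle counts as detected when some predicted region covers ≥ 20% of
its area; a prediction is a false positive when it covers < 20% of its own
area of every manual bundle. The matching fraction is the single most
consequential unstated choice of the evaluation protocol: 0.2 is deliberately
low because automated boundaries hug the fibers more tightly than manual
outlines, and it is exposed in config. Counting is non-exclusive (one
prediction may validate two manual bundles). TPR pools manual bundles across
test sections; FPavg is total FPs over section count; ΔFD is the mean of
(manual FD − predicted FD) over matched pairs in percentage points — negative
when automatic regions are denser, i.e. tighter. FROC curves sweep the
binarization threshold and report (FPavg, TPR) pairs.

## Synthetic data

The generator emulates what the method assumes about dark-field tracer
sections, not their photorealism:

* dark tissue (mean 0.08, smooth gradient ±0.04, slight channel correlation)
  inside an elliptical section on a near-black background, with a ventricle
  cavity for the alignment landmark and a bright tissue rim;
* three fixed elongated white-matter ROIs standing in for IC, CC and UF;
* bundles: anti-aliased quadratic-Bézier strokes with a per-bundle dominant
  orientation plus jitter, clustered in (and clipped to) an elongated support.
  The ground-truth region is the morphological closing (disk radius 10 px) of
  the stroke union followed by a 3 px dilation — mimicking manual outlines
  being looser than the fibers. Strokes are added adaptively: placed in sparse
  territory they grow and dilute the region, placed on existing cover they
  densify it, so the bright-pixel fraction lands inside the configured 2–20%
  band (asserted per region) while the region area reaches ≈ 5.5 mm². The
  floor keeps true bundles well clear of the 2 mm² noise filter even though
  automatic boundaries are tighter than the ground truth — mirroring real
  data, where manual bundle outlines are far larger than the noise-filter
  scale. Bundle supports are confined inside the tissue with a 0.7 mm margin
  so no true bundle falls in the border filter's 0.5 mm deletion zone;
* confounders placed outside bundle regions: isotropic terminal-field speckle
  at bundle-like brightness (the dominant false-positive source; its true
  brightness is unquantified, so it is a parameter), smooth glare blobs, and
  the bright rim;
* bundle centroids walk along their ROI's major axis by at most the configured
  drift (0.3 mm/section) so cross-section continuity holds; in stacks of ≥ 4
  sections the last bundle terminates at 3/4 of the stack, so bundle birth and
  death are represented.

Defaults describe a 512×512 px section at 40 µm/px (≈ 20 mm across — a
macaque-scale coronal section at a coarse working resolution), 20 sections
1.2 mm apart. At this calibration the physical post-processing constants
(2 mm², 0.5 mm) are meaningful on a desk-scale image. What a green synthetic
test does **not** establish: robustness to staining variability, registration
distortions, real terminal-field morphology, or scanner artifacts beyond
glare/gradient — real sections differ in all of these.

## Numerical and degenerate-input choices

* All tensors float32; losses accumulate in float64. One fixed integer seed
  reproduces every output byte-for-byte (generator, patch sampling,
  augmentation, training, inference).
* Threshold ties: binarization and TE thresholds use ≥; the FD percentile
  uses strict >. A region of constant intensity therefore has FD 0.
* Empty cases: empty labeled set → error; empty unlabeled set → TE warns and
  degenerates to supervised continuation; empty continuity reference →
  region removed; empty region → FD error; regions under 20 px → warning.
* `n_sections = 1` disables the continuity prior (it is undefined).
* Max-pool gradients split equally among tied maxima (measure-zero in
  practice).

## Scaled-down benchmark

The reference experiment (`bundleseg.benchmark.run_synthetic_benchmark`, also
behind `scripts/acceptance.py`) generates 20 sections, trains a base-width-8 /
depth-3 model with 10 pretraining + 4 TE epochs on 5 labeled + 15 unlabeled
sections (96 px patches, 64 per section), and scores region-level detection
on the 15 label-withheld sections before and after post-processing. It is a
direction-of-effects surrogate for the full-scale experiment — numbers from
it are not comparable to full-scale results.

## Known limitations

* No JPEG2000 reading unless Pillow carries an openjpeg codec; PNG/TIFF are
  the supported interchange formats. Proprietary Neurolucida/IMOD contours
  must be pre-exported to label masks or CSV polygons.
* Alignment is translation-only and landmark-based; heavily distorted stacks
  would need real registration upstream.
* Training runs single-threaded numpy; it is meant for desk-scale validation
  and method study, not full-resolution production training.
* The continuity prior is applied only at post-processing time, not during
  training.
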