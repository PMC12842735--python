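# Methods

## The pre-training objective

The model is a masked autoencoder over non-overlapping P×P image
patches. Patches are flattened row-major and mapped by an affine
tokenizer to D_enc-dimensional embeddings E. A uniformly random subset
of exactly `round(r·N)` of the N patches is masked (mask ratio r); the
transformer encoder sees only the visible tokens, each with a fixed 2-D
sine-cosine position code added. A lightweight decoder receives the
full-length sequence: visible latents projected to D_dec, plus one
shared learnable mask token at every masked slot, each with its
decoder-side position code. A linear head predicts, per masked patch:

* **pixel head** — the P²·C raw pixel values, scored with mean squared
  error (the classic masked-autoencoder baseline), or
* **embedding head** — the D_enc-dimensional deep embedding of the
  original (uncorrupted) patch, scored with a mean L1 loss over
  (masked patches × embedding coordinates). This is the
  masked-deep-embedding (MDE) objective the package exists for.

The embedding targets come from the model's *own current tokenizer*
applied to the original patches, with gradient flow into the target
branch severed (stop-gradient). With the targets detached, the
tokenizer cannot shrink the loss by moving its own targets inside an
optimizer step; it only receives gradient through the visible-token
path. A frozen-at-init tokenizer target is available behind a config
switch for ablation. There is no per-patch target normalization by
default (also switchable).

"Self"-pre-training means the pre-training corpus is the downstream
task's own training images; no external image corpus is involved
anywhere in this package.

**Routing.** Two readings of the architecture exist: (a) the encoder
sees visible tokens only and the corrupted full-length sequence Ec is
the *decoder* input; (b) the corrupted sequence is fed to the encoder
itself. The package defaults to (a), which matches the
encoder-on-visible-patches design and keeps the decoder an auxiliary
that is discarded after pre-training; a `simmim_routing` switch
implements (b) for comparison.

**Decoder discard.** Exported backbone checkpoints contain tokenizer,
encoder and final-norm weights only; decoder, mask token and head
never leave pre-training. This is asserted by test.

## Parameters

Full-scale defaults (`RunConfig()` / `TrainConfig()`):

| parameter | default | notes |
|---|---|---|
| image size | 416×416 px | the radiograph protocol size |
| patch size P | 16 px | 26×26 = 676 tokens per image |
| mask ratio r | 0.25 | low ratios suit radiographs, whose informative structures are small; masked count is round-half-up of r·N, exact by construction |
| optimizer | AdamW, β₁ = 0.9, β₂ = 0.95 | |
| base lr | 1.5×10⁻⁴ (pre-training), 1×10⁻⁴ (fine-tuning) | |
| weight decay | 0.05 | decoupled; skipped for 1-D params (norms, biases) |
| schedule | 10-epoch linear warmup, then cosine decay to 0 | continuous at the boundary, non-increasing after it |
| augmentation | noise on ≤6 % of pixels, h/v flip, ±90° rotation | noise fraction drawn uniformly in [0, 0.06] per image; geometric ops transform boxes with pixels |

Test-scale preset (`RunConfig.tiny()`): 64×64 images, P = 8 (64
tokens), 2-layer D = 64 encoder with 4 heads, 1-layer D = 64 decoder.
The bundled experiments and the acceptance script run this preset with
base lr 1×10⁻³, batch 16, warmup 10 of 50 epochs, and 200 optimizer
steps for pre-training; fine-tuning uses lr 1×10⁻³ for 30 epochs.
These are the package's CPU-scale choices: small transformers trained
from scratch on tens of images need a larger step size than the
full-scale protocol, and the decoder width is kept equal to the encoder
width so the embedding head is not capacity-limited.

Everything random descends from one root seed via named substreams
(mask sampling, scene generation, batch order, weight init, splits), so
any stage reproduces in isolation.

## The two-stage detector

**Stage 1 — part detection.** The pre-trained encoder provides a
stride-P token map. A minimal anchor-free dense head predicts per cell
an objectness logit, design-class logits, and a box regression
(center offsets and log sizes relative to the stride). A cell is a
positive target when its center lies inside a ground-truth part box;
ties go to the smallest box. Training uses binary cross-entropy on
objectness, focal loss (γ = 2) with inverse-frequency class weights on
positive-cell classification — the imbalance treatment for the heavily
skewed design-class distribution — and an L2 loss on box parameters.
Inference thresholds scores (default 0.3) and applies greedy
per-category NMS (default IoU 0.5).

This head deliberately replaces a full Mask R-CNN + FPN stack. The
scientific content under test is the pre-training objective and the
part-to-implant assembly; the detector is a pluggable contract — any
tool emitting scored part boxes can feed stage 2. A simple feature
pyramid (strides P/4 … 2P by nearest-neighbour upsampling and average
pooling of the stride-P map, identity lateral projection) is provided
for detectors that want multi-scale features; the bundled head reads
the stride-P level.

**Stage 2 — implant assembly.** The number of implants k is estimated
as the number of detected coronal-level parts (every implant exposes
exactly one platform), falling back to ⌈n/3⌉ when no coronal part is
found; a literal mode with k equal to the number of detected parts is
selectable, though it degenerates to singleton groups. Parts are then
grouped by k-means (k-means++ seeding, ≤300 iterations, 10 restarts)
on box centers that are anisotropically scaled before clustering:
lateral offsets are divided by 0.5× the median coronal width and axial
offsets by 1.5× the median implant extent. The scaling encodes the
prior that parts of one implant string out along the implant axis but
stay laterally aligned; without it, an isotropic k-means cuts elongated
implants across rather than between them. The same two tolerances
drive refinement: members offset from their group centroid by more than
the thresholds are discarded with a logged reason, and duplicate levels
keep the highest score. Groups covering fewer than two levels are
dropped.

Missing levels are inferred along the implant axis (principal direction
of member centers, vertical for degenerate groups): a missing middle
spans the gap between coronal and apical (linear interpolation — the
degenerate spline); a missing end part is extrapolated beyond its
neighbour with height set by the 0.25 : 0.50 : 0.25
coronal:middle:apical ratios. The final implant box is the tight union
of member and inferred boxes; its score is the mean member score, and
the system class is a highest-total-score vote over member hints.

## Evaluation

AP follows the COCO recipe: greedy matching in descending score,
one-to-one per ground truth at IoU ≥ threshold, 101-point interpolated
precision-recall integration, reported ×100. Both AP50 and the average
over IoU 0.50:0.05:0.95 are always computed; AP50 is the headline since
the single-threshold value is the conventional summary in this
literature. Classes without ground truth are skipped. Crowd/ignore
regions are not supported.

Cross-validation splits at the patient level: patients are packed
greedily by descending image count, the first n−1 sets targeting
⌊n_images/n_sets⌋ images and the last set absorbing the remainder.
The last set is the designated constant test set, and each remaining
set rotates as validation. With 5,572 single-image patients and five
sets this yields four sets of 1,114 and a 1,116-image test set. The
mask-ratio/epoch sweep driver repeats
pre-train → fine-tune → AP50 per (ratio, epochs, seed) cell and reports
mean ± sd over seeds; failed cells (e.g. a mask ratio whose rounded
count is 0 or N) are marked and skipped.

## The synthetic generator

Real implant radiographs are available only on request, so the
generator emulates the *structure* of such a dataset: vertically
oriented screw-like implants composed of a wide coronal platform, a
threaded middle body (alternating intensity bands), and a tapering
apical tip with an optional darker hole, rendered as additive bright
silhouettes over a smoothed-noise background (radiopacity without a
physics model). Three synthetic systems differ deterministically in
body width and platform ratio (0.26/1.25, 0.40/1.10, 0.33/1.40 of a
nominal implant height), keeping a nearest-centroid width classifier
above 90 % accuracy — a separability floor the downstream tests rely
on. Widths scale with the nominal rather than the sampled height so
length variation does not wash out the class gap. Design-class
frequencies default to the observed clinical imbalance (coronal
bone : tissue : microthread : no-threads = 1240 : 870 : 410 : 208, and
analogously for middle and apical categories); only a representative
subset of design attributes is rendered distinguishably, the rest are
label-only aliases. Implants occupy 65–80 % of the frame height, as in
periapical views; per-image implant count (default 1–3) and images per
patient (default 2) are parameters, since neither is fixed by the
protocol the generator emulates.

Annotations are exact by construction: one box per rendered part and
one implant box that is the exact union of its three part boxes, all
written as detection-dialect COCO JSON with a `patient_id` image field.

What the generator does *not* model: peri-implant anatomy, bone
texture, superstructures, projection geometry, device/exposure
variation, overlapping implants, non-axis-aligned implants (rotations
are multiples of 90°). Passing tests therefore demonstrate the
correctness and trainability of the machinery — exact losses and
masking, visibility isolation, convergence, assembly geometry — not
clinical detection performance; no claim is made that synthetic-scale
trends transfer to clinical data.

## Numerical choices and degenerate inputs

* All model arithmetic runs in float64 on a small reverse-mode
  autograd; tiny models make the extra precision cheap and the
  determinism tests strict.
* Masked-count rounding is half-up; masks whose count would be 0 or N
  are rejected as degenerate.
* LayerNorm uses ε = 1e-6; AdamW uses ε = 1e-8; box log-sizes are
  clipped to e^±6 at decode time to guard against early-training
  extremes.
* Position tables require the embedding dimension divisible by 4
  (2-D sin/cos construction); images must divide evenly into patches —
  no implicit padding.
* k-means ties and restarts are fixed by the seeded k-means++
  initialisation; `estimate_implant_count` never exceeds the number of
  detections.
* Empty scenes, empty detection lists and zero-epoch training runs are
  all valid inputs with well-defined outputs.

## Known limitations

* The detector is single-scale and minimal by design; absolute AP
  numbers at full clinical scale are out of scope.
* Assembly assumes near-axis-aligned implants; arbitrary rotation
  angles would need oriented boxes.
* The sweep driver's synthetic trends are illustrative only.
* Patient grouping in the generator is block-wise, not a model of
  clinical revisit patterns.
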