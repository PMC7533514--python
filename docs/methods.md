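# Methods

## Scope and data model

The toolkit analyzes one staged photograph of a placenta at a time.
Everything flows through the `LabelMap` contract: an H×W integer map
with classes 0 background, 1 disc, 2 cord, 3 ruler, in 0-based
(row, col) coordinates with rows increasing downward. Stage II never
sees network internals, only label maps and a keypoint, so oracle label
maps (from the generator) and predicted label maps are interchangeable.
Where an x/y convention is needed (image moments), x is the column
axis and y the row axis, evaluated at pixel centers (col+0.5, row+0.5);
angles are measured from +x, counterclockwise in image coordinates.

## Synthetic scenes

Clinical photo archives are private, so all development and testing
uses generated scenes that reproduce the *geometry* the pipeline
relies on, not the photometry of real tissue:

* a disc rendered as a filled ellipse (semi-axes A ≥ B, random
  inclination), optionally star-perturbed by a sinusoidal radial
  modulation `r ↦ r·(1 + a·cos(kθ))` (amplitude a ≤ 0.5, k lobes) to
  emulate irregular specimens;
* a cord rendered as a constant-halfwidth tube around an integrated
  curving path. Fetal-side scenes run the cord from the periphery to
  an insertion point inside the disc and paint it *over* the disc
  (class precedence cord > disc > ruler > background), reproducing the
  occlusion that disc recovery must undo. The path leaves the disc
  radially and steers gently (turn rate ≤ 0.05 rad per 2 px step, with
  border/disc lookahead) so the tube never folds onto itself; maternal
  scenes keep the cord clear of the disc;
* coil fold-crevices as short dark wedges crossing one cord boundary
  at 55–72° to the local axis, with depth 1.25–1.55 halfwidths — deep
  enough for edge detection, short of the far boundary, matching how
  inter-coil grooves appear in photographs;
* a ruler as a light rectangle at arbitrary orientation with one dark
  tick per centimeter at a known pixel pitch (the scale ground truth),
  placed disjoint from disc and cord or a generation error is raised.

Defaults model a 768×1024 frame; `SceneConfig.for_size` rescales all
lengths for smaller canvases (tests mostly use 384×512 and 288×384).
The label map is a pure function of the stored ground truth, and
generation is deterministic per seed with no global random state.
What passing tests show is therefore that the *procedures* are correct
on well-posed inputs; they do not certify robustness to real-photo
nuisances (texture, specularity, blood, shading) which the generator
deliberately omits.

## Stage I network

Encoder: Conv-BN-ReLU (stride 1) → Conv-BN-ReLU (stride 2) → three
residual blocks (3×3 convs with stride 2 then 1, 1×1 projection
shortcut), yielding a pyramid f1..f5 at strides 1/2/4/8/16 and widths
W..16W. The segmentation decoder mirrors it with four expanding
blocks (2× transposed convolution, skip concatenation, 3×3 conv) and a
1×1 score layer + channel softmax; the side classifier applies one
residual block to f5 then FC-256 → FC-2; the insertion-point decoder
uses two expanding blocks over {f5, f4, f3} with a 1×1 score layer
after each, giving heatmaps at 1/8 and 1/4 of the crop. Inputs must be
multiples of 16 so decoder shapes match exactly. Unprinted details
(Conv-1/Conv-2 kernels = 3×3, FC widths 256/2, shortcut type) are
recorded in the checkpoint sidecar as architecture hyperparameters.

Training follows the staged transfer-learning schedule: (1)
encoder+segmentation with the 4-class dice loss, SGD lr 0.1, momentum
0.9, weight decay 5e-4, batch 2; (2) side classifier, batch 10, with
the encoder frozen; (3) insertion-point decoder, batch 10, encoder
frozen. Augmentation applies a shared random rotation (±30°) and
horizontal/vertical flips to image, label map and keypoints. "Training
from scratch with parameters initialized to zero" is implemented as
no-pretraining with seeded He-normal weights and zero biases — a
literal all-zero start cannot break symmetry in a conv net.

Desk-scale numerical choices (defaults; all config-exposed):

* the two-head heatmap objective is optimized as *pixel-mean* MSE —
  the printed summed form times a constant 1/N. At width 8 the summed
  loss with lr 0.1 produces O(10³) gradients and diverges in float32;
  the public `plax.heatmaps.ip_loss` keeps the summed form;
* head phases use lr 0.01 (side) and 0.03 (heatmaps); lr 0.1 at this
  width makes the heads oscillate or collapse. Phase 1 keeps lr 0.1;
* the frozen encoder runs in BatchNorm *eval* mode during phases 2–3,
  making it literally a fixed feature extractor; otherwise train/eval
  feature statistics diverge and head validation sits at chance;
* Gaussian heatmap σ is 7 px at a 512 crop, scaled with resolution and
  floored at 2 px so coarse-head targets keep usable support;
* batch-norm running statistics use momentum 0.1; validation selects
  checkpoints by mean IoU / accuracy / PCK@0.1 per phase.

The small abnormality classifier is a 6-layer CNN (four 3×3 valid
convs with 2×2 max-pool, channels 32/64/128/256, then FC-1024 and
FC-1 + sigmoid). The conv arithmetic is back-derived from its printed
feature sizes: a 200×200 input is the canonical (and only accepted)
size giving the 99/48/23/10 ladder. Default optimizer RMSProp lr
0.001, momentum 0.9, batch 10.

## Stage II procedures

**Disc recovery.** Disc-boundary pixels with an 8-neighbor in the cord
class, ordered along the disc contour (nearest-contour-index sort),
define a polygon that is filled and unioned with the disc, then closed
morphologically (disk radius 5) to remove small holes. The result is
always a superset of the raw disc. With no disc–cord junction the
step degrades to the closing alone. All downstream measurements
(axes, margin distance, irregularity) use the recovered disc, since
recovery precedes them in the measurement chain.

**Ruler scale.** A minimum-area rotated rectangle (rotating calipers
via shapely) is fitted to the ruler class; intensities inside are
binarized by Otsu's threshold, the minority side taken as tick-marker
pixels; marker coordinates are projected on the long edge and a 1-D
Gaussian KDE fitted. Bandwidth is Silverman's rule capped at half the
smallest expected tick pitch (default cap 3 px — Silverman on
near-uniform projections is always far too wide, so the cap binds);
crests are density maxima with prominence ≥ 10% of the peak, refined
to sub-grid accuracy by parabolic interpolation; the scale is the
median crest spacing (× 10 if the ruler is declared mm-ticked).
Fewer than two crests raises "ruler unreadable", and the pipeline then
reports pixel-only measurements with a no-scale flag.

**Caliper axes.** The long/short axis of the disc are support-line
(Feret) widths of the boundary pixels over orientations at 1° steps:
the long axis is the maximum width, the short axis the width at the
perpendicular orientation — a digital vernier caliper.

**Insertion category.** ratio = (distance from insertion point to the
nearest recovered-disc boundary pixel) / (mean of long and short
axis). marginal if ratio < t₁, central if ratio ≥ t₂ (boundary
assigned upward), else eccentric. The clinically fitted thresholds
are unpublished; defaults (0.10, 1/3) are placeholders and
`fit_thresholds` — exhaustive accuracy maximization over midpoints of
sorted unique ratios, lexicographically smallest tie-break — is the
supported route.

**Shape irregularity.** The inclination/axis formulas are evaluated on
*central, per-area* second moments (μ_pq/m00): as printed with raw
moments they are dimensionally inconsistent, while the central form
recovers an ellipse's exact semi-axes (per-area central moments a²/4,
b²/4). α = ½·atan2(2μ̄₁₁, μ̄₂₀−μ̄₀₂) ∈ (−π/2, π/2], α = 0 for circular
masks. The fitted ellipse is rasterized by pixel-center inclusion
(boundary included); I = (n₂+n₃)/n₁ with the strict decision I > 0.14.

**Cord coiling.** The cord skeleton (scikit-image skeletonization →
longest path by double BFS) is trimmed by the local half-width at each
end, extended along the end tangents to the cord rim, and box-smoothed
(window 7) to remove 8-connectivity stair-casing, which otherwise
inflates curved-cord arc length by ~7%. The mask contour is split at
the skeleton endpoints into the two boundary polylines. Canny edges
(σ = 1.2; high threshold = 90th percentile of the in-cord gradient,
floored at 6 gray-levels/px so featureless cords yield nothing; low =
0.4·high) inside the 2-px-eroded cord are linked within a 2-px radius
into segments, then filtered: (i) length < 0.3 × local cord width,
(ii) geometric crossing with the previously kept segment (the later
segment is dropped), (iii) principal direction within 30° of the local
skeleton tangent. For each segment: e1 = entry point on the nearer
boundary, e2 = far-boundary hit or, as real crevices rarely span the
full width, the deepest pixel; e4 = the intersection of the
perpendicular-to-skeleton line through e2 with e1's boundary;
T = |arc(e1, e4)| on that boundary (e1's boundary — the construction
is ambiguous between the two, and this choice degrades gracefully).
Counting walks segments in order of skeleton arc position; a segment
is a new coil only when its spacing from the last *counted* segment
exceeds 2T of that segment. Spacing and ordering use skeleton arc
positions rather than boundary arc length because entry points on
opposite boundaries have no shared boundary parametrization; both are
pixel arc lengths of comparable magnitude. Coilness C = n·10/l with
l the skeleton length in cm; hypercoiled iff C ≥ 4 (inclusive).

## Evaluation metrics

Confusion-matrix metrics: pixel accuracy Σᵢ C_ii / Σᵢ Tᵢ, mean class
accuracy (1/k) Σᵢ C_ii/Tᵢ, mean IoU (1/k) Σᵢ C_ii/(Tᵢ+FPᵢ) with FPᵢ
the column sum of off-diagonal entries — the standard TP/(TP+FN+FP).
The row-sum variant (which double-counts false negatives and is not a
true IoU) is kept behind `variant="as_printed"` for comparison.
Classes absent from both maps are dropped from the class means.
PCK@x is the fraction of keypoints with ‖p̂−p‖₂/d strictly below x,
with d the ground-truth disc's long caliper axis (the "disc diameter"
of a non-circular disc is otherwise undefined).

## Test-scale choices

Property tests and the acceptance suite run on 384×512 scenes
(morphometry, coiling, ruler at 576×768), a width-8 network at
128×128 with 40 scenes for the staged-training smoke run, and 50-80
case batteries per geometric property — sizes chosen so the whole
suite completes in minutes on one CPU while every tolerance stays at
the value stated for the full-scale procedure.

## Known limitations

* The generator's flat-color rendering makes segmentation nearly
  separable by color; Stage-I results on synthetic scenes say nothing
  about accuracy on clinical photos.
* Disc recovery assumes the cord crosses the disc rim roughly
  radially; a cord grazing tangentially carves a wide notch whose
  polygon fill undershoots the true rim.
* The coil counter needs crevices resolvable at the image scale
  (cord halfwidth ≳ 8 px); thinner cords lose crevices to the
  interior-erosion margin.
* Insertion-type and shape thresholds other than the published 0.14 /
  C ≥ 4 constants must be fitted to labeled data; the defaults are
  placeholders.
* Retained-placenta detection, meconium/abruption/chorioamnionitis
  classification training, and knot detection are out of scope; only
  the small classifier's architecture and the disc-masking
  preprocessing are provided.
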