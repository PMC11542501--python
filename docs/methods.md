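# Methods

## Problem and scope

`octseg` implements semi-supervised semantic segmentation of retinal OCT
B-scans into a 14-class scheme: ten anatomical layers (ILM, RNFL, GCL, IPL,
INL, OPL, ELM, PR1, PR2, RPE, top to bottom), the pre-retinal space above the
ILM, the background below the RPE, collapsed outer layers, and cysts.
Networks learn the first thirteen classes; cysts (class 13) are added to
predictions by intensity-based post-processing of diseased scans only.

The package targets the regime where labeled scans are scarce but unlabeled
scans are plentiful — typical of rare retinal disease such as macular
telangiectasia type 2, whose OCT hallmarks (hyporeflective intraretinal
cysts, outer-layer disruption and collapse) defeat segmenters trained on
common pathology. Everything runs on CPU at "desk scale" (64x64 scans by
default); all sizes are configurable up to clinical resolution (512x512).

## Annotation model

Layer annotations are per-column boundary lines: for each of the 11
interfaces (the top of each layer plus the lower RPE edge) a real-valued row
coordinate per image column. Rasterization assigns each pixel the class of
the boundary line that precedes it from above; pixels above the first line
are pre-retinal space and pixels at/below the last line are background.
Fractional depths are floored, so the boundary row itself belongs to the
class its line introduces. `mask_to_boundaries` inverts this exactly (first
row whose label >= k), which the tests exploit as a round-trip invariant.
Masks with pathology classes have no consistent layer ordering and are
rejected by the inverse.

## Synthetic B-scans

The simulator emulates the gross appearance of macular OCT, not its physics:

* **Geometry.** Cumulative mean layer thicknesses give flat boundary
  baselines; a shared low-frequency profile (Gaussian-filtered white noise,
  sd = `boundary_smoothness` px) undulates the whole retina, small
  independent wiggles (one third of that amplitude) decorrelate neighbouring
  interfaces, and a Gaussian-shaped foveal dip displaces the inner
  boundaries, tapering linearly to zero by the ELM so the inner layers thin
  at the fovea. Non-crossing is enforced by a cumulative
  maximum with a 1 px minimum layer thickness.
* **Optics.** Each class has a mean reflectivity in [0, 1]; speckle is
  multiplicative, `clean * (1 + strength * g)` with `g` i.i.d. standard
  normal, clipped to [0, 1]. This is the simplest OCT-like noise; it is not
  a physically calibrated speckle model (no Rayleigh/gamma statistics, no
  depth-dependent attenuation, no shadowing), so tests passing here say
  nothing quantitative about clinical scans.
* **Pathology.** Diseased scans carry at least one of: cysts —
  hyporeflective ellipses placed strictly inside the retinal band (classes
  2-9), pairwise separated by >= 2 px so connected components remain
  countable; collapse — a contiguous column range in which the outer layers
  (ELM/PR1/PR2) are replaced by the collapsed-layers class. Cyst size and
  count ranges are free parameters of the generator, not claims about any
  disease's morphometry.
* **Patients.** A patient is a group of scans sharing one draw of layer
  thicknesses and reflectivities (relative sd 0.12). This within-patient
  correlation is what makes the 80:10:10 *patient-level* split (largest-
  remainder rounding) meaningful, and is asserted by a leakage test.

Defaults (64x64, ten layers summing to ~39 px, speckle 0.15, disease
prevalence 0.5, cyst semi-axes 2-5 x 3-8 px, collapse probability 0.5) were
chosen once to make layers several pixels thick and pathology clearly
visible at desk scale.

## Networks

No GPU framework is used; `octseg.nn` is a compact numpy layer library with
explicit backpropagation (3x3/1x1 convolutions via im2col, optional
dilation, ReLU, 2x2 max-pool, nearest upsampling, Adam). Convolutions use
replicate ("edge") padding, so a spatially constant input remains constant
through the stack — this avoids an artificial dark frame and makes the
uniform-softmax sanity test exact. Gradients of every layer are verified
against finite differences.

Three architectures share one interface (normalized image in, H x W x 13
score map out, argmax ties broken toward the lowest class id):

* `unet` — encoder/decoder with skip connections, one conv per stage,
  width 8 and depth 2 by default (~7k parameters);
* `double_unet` — two chained U-Nets; the softmax of the first (interim)
  prediction is concatenated with the input image and fed to the second.
  Both maps are supervised with equal weight — the chaining description
  leaves the interim-loss weight open, and 1:1 is the symmetric choice;
* `dilated_encdec` — an encoder-decoder of dilated convolutions (rates
  1, 2, 4, 8) standing in for DeepLab-style context aggregation at desk
  scale. The training frameworks are architecture-agnostic, so conclusions
  about CPS/Mean Teacher do not hinge on this substitution.

Weight initialization is He-normal seeded per model; the CPS pair uses
seeds (s, s+1) so the two models are "the same but differently initialized".

## Losses

* Weighted cross-entropy: mean over pixels of `w[y] * -log p[y]`,
  normalized by the mean pixel weight so unit weights reduce to plain CE.
  Default weights are inverse mean class thickness (pixels per column)
  measured on the labeled training masks, clipped to [0.5, 20] and
  renormalized to mean 1 — this up-weights thin structures (ELM,
  photoreceptor bands, collapse) without an arbitrary hand-set table.
* Soft Dice with epsilon 1e-6 (absent classes contribute Dice 1), and a
  CE+Dice sum at fixed 1:1.
* CPS: labeled term `CE(s1,y) + CE(s2,y)` (unweighted — whether the
  labeled CPS term shares the supervised class weights is left open
  upstream; unweighted is the default, and the supervised loss remains
  switchable), unlabeled term `CE(s1, argmax s2) + CE(s2, argmax s1)` with
  hard argmax pseudo-labels treated as constants, total
  `labeled + lambda * unlabeled` with lambda = 1 by default (the plain sum),
  exposed because the original CPS method tunes it.
* Mean Teacher: MSE between student and teacher softmax maps, applied to
  labeled and unlabeled batches alike with weight 1 and no ramp-up schedule
  (none is specified upstream; a schedule can be added via config); teacher
  update `t <- d*t + (1-d)*s` with decay 0.99.

## Training

Adam at a fixed learning rate 2e-3, batch size 2 labeled + 2 unlabeled, one
labeled and one unlabeled batch per step (the alternating style of the
original CPS recipe). The unlabeled pool is subsampled once per run, at the
scan level, to the configured fraction with the run seed. Model selection is
by best validation mean IOU over the learned classes (no selection rule is
prescribed upstream); for CPS only the first model is checkpointed for
prediction and the second is kept as an extra. Training never touches the
test split, which a test asserts via the manifest's access log.

## Cyst post-processing

The upstream procedure lives in unavailable supplementary material, so the
rule here is a reconstruction from the description of cysts as
hyporeflective cavities within the retinal layers: a pixel is a cyst
candidate if its predicted class lies strictly inside the retinal band
(classes 2-9, or collapse) and its intensity falls below `k * median_c`,
where `median_c` is the median intensity of that class's pixels *in the same
image* and `k` is a dimensionless contrast factor (default 0.5 — a candidate
must be less than half as reflective as its class). A purely relative
threshold needs no spread estimate, so it is untouched by speckle strength
and intensity clipping, and the median stays calibrated while cysts cover
under half of a class; at default noise the speckle left tail of every layer
sits well above half its median, so clean scans pass unaltered. Connected
candidate components smaller than `min_area = 10` px are discarded.
Relabeling only ever writes class 13 and only for scans flagged diseased
(the flag comes from the manifest; automatic disease detection is out of
scope). Which classes are open to relabeling is configurable.

## Evaluation

Per-class IOU per test image; a class absent from both masks is undefined
and excluded from that class's statistics rather than scored 1 — a trivially
correct absence earns no credit. Summary tables report mean and standard
error (sample sd / sqrt(n defined)).

Model comparison uses a one-sided paired signed-rank test per class on
per-image IOU differences: zeros dropped, midranks for ties, W+ = rank sum
of positive differences. For n <= 20 the p-value is exact over all 2^n sign
assignments (computed by doubling the rank-sum array; ranks are doubled to
stay in integers); beyond that, a normal approximation with tie-corrected
variance and 0.5 continuity correction. Degenerate classes (no nonzero
difference, including self-comparison) get p = 1. No multiple-testing
correction is applied — p-values are reported per class, and readers should
treat the per-class stars accordingly.

## Desk-scale benchmark

The central qualitative claim — leveraging unlabeled scans improves
segmentation when labels are scarce — is tested end to end: 64x64 scans,
8 labeled training scans (4 patients), 200 unlabeled (100 patients), 10
validation, 30 test (mixed diseased/healthy); small U-Net; CPS at unlabeled
fractions {0, 0.5, 1.0}; three seeds; 150 epochs (4 steps per epoch). The
fraction-0 arm trains on labeled data only and therefore *is* the
seed-matched supervised baseline. Pass criteria: the median-over-seeds mean
test IOU of CPS-100% is at least the supervised baseline's, and the median
Spearman correlation between fraction and mean IOU is non-negative. The
benchmark runs in roughly ten minutes on one CPU; individual seeds can go
either way (pseudo-labels from a weak partner can hurt early), which is why
the criterion is a median over seeds.

## Numerical choices and degenerate inputs

* Population (divide-by-N) standard deviation for per-image normalization;
  constant images map to exact zeros (divisor 1).
* Trailing partial tiles are dropped, never padded; with a fovea anchor the
  anchored crop is placed first (clipped to the image) and both sides are
  tiled outward without overlap — how an anchored crop composes with
  left-to-right tiling is an interpretation made here.
* Argmax ties break toward the lowest class id everywhere.
* Softmax is computed with max subtraction; CE clips probabilities at
  1e-300 before the log.
* float32 network arithmetic, float64 loss accumulation.

## Known limitations

* The simulator omits vasculature, shadowing, motion artifacts, real speckle
  statistics and 3-D context; benchmark results demonstrate the *relative*
  behaviour of training regimes, not clinical accuracy.
* Networks are orders of magnitude smaller than clinical segmenters and are
  trained from scratch; no pretrained backbones.
* The cyst post-processing rule is a reconstruction, with all constants
  configurable; it assumes cysts are darker than their surrounding class by
  several robust standard deviations.
* Single-device, full-batch-in-memory training only.
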