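# Methods

`fissuremap` detects outer annular fissures of lumbar intervertebral
discs (IVDs) from a small stack of midsagittal T2-weighted MRI slices
and localizes them within the disc. Ground truth of the kind the method
is built for comes from CT discography: contrast injected into the
nucleus pulposus (NP) spreads into annular fissures, graded on the
Dallas Discogram Description (DDD) scale; grades 2–3 (fissure reaching
the outer third of the annulus fibrosus, AF) define the positive class.
Because clinical discography data cannot be redistributed, the package
ships a phantom generator that reproduces the statistical structure the
analysis depends on, so the whole pipeline is testable end to end.

## Disc phantoms

Each phantom is a `(slices, rows, cols)` stack, default `(5, 48, 96)`
voxels at `(4.4, 0.59, 0.59)` mm spacing (a five-slice sagittal slab
with 4 mm slices + 0.4 mm gap and ~0.59 mm in-plane resolution). The
disc is a 2D ellipse replicated over slices with mild per-slice
shrinkage (8 % per slice off-center): a bright NP (elliptical radius
ρ ≤ 0.55) inside a darker AF (0.55 < ρ ≤ 1). Compartment means are 40
(AF) and `100 − 15·(grade − 2)` (NP) in arbitrary intensity units, so
the NP signal decays with the Pfirrmann-like degeneration grade 2–5;
additive Gaussian noise (`noise_sd`, default 1.0) is applied everywhere.

A fissure is a two-voxel-thick streak running radially from the NP
boundary into the outer third of the AF (ρ 0.55 → 0.97) with a small
sinusoidal wiggle, at intensity `AF mean + fissure_contrast` noise-SD
units (default contrast 6). Column index increases ventral → dorsal:
ventral fissures sit in the left third of the ROI columns, dorsal in
the right third. Label distributions default to the reference lumbar
cohort the generator emulates: prevalence 94/123, positions (ventral
4 %, dorsal 81 %, both 12 %, lateral 3 %), degeneration grades
(16/39/41/3 %), DDD grades drawn 87:7 (2:3) among positives and 8:21
(0:1) among negatives, and a high-intensity-zone (HIZ) flag carried by
63 % of in-plane-fissured discs (the sensitivity regime of the HIZ
marker), provided the streak contrast exceeds the visibility cutoff
(3 noise SDs).

Two deliberate phenotypes limit what the phantoms claim about real
data:

* **lateral-only fissures** leave no in-plane footprint at all — they
  are invisible to a sagittal analysis by construction, which caps
  attainable classification and localization performance exactly the
  way out-of-plane pathology does clinically;
* **severely disrupted** discs (default 20 % of fissured discs) replace
  the delimitable streak with diffuse brightening of the outer AF.
  They are detectable as fissured but carry `attention_eligible=False`
  (the analogue of "<50 % continuously intact outer third AF") and are
  excluded from the localization analysis.

The phantoms do **not** model vertebral bodies/endplates, MR physics
(coil profiles, bias fields, partial volume), segmentation error, or
anatomical variation beyond the ellipse; passing recovery tests shows
the algorithmic chain is sound under its own assumptions, not that the
stated clinical accuracy transfers to scanners and patients.

## Texture features

Features are computed inside the binary disc ROI only. Intensities are
discretized to a fixed bin number (32) between the masked min and max —
scanner-scale-free and invariant to global shifts/scales. Matrix
features use Chebyshev distance 1: GLCMs are symmetric with 4 unique
in-plane directions (per slice) or 13 unique 3D directions, and pairs
are counted only when both voxels are masked. Aggregation follows the
standard conventions: per-slice-per-direction averaged (`2Davg`),
direction-merged within slice (`2Dmrg`), slice-merged per direction
(`2DDmrg`), all-merged (`2Dvmrg`), and the 3D analogues
(`3Davg`/`3Dmrg`); empty matrices (no valid pair) are excluded from
averages. NGTDM complexity and NGLDM dependence-count energy (α = 0)
use the same neighbourhood conventions. Geary's C uses inverse physical
distance (mm) weights over exact voxel pairs up to 3000 masked voxels
and a seeded uniform subsample beyond (O(N²) cost bound); intensities
are centred before the quadratic form for conditioning. Undefined
values (constant ROI, empty matrices) are imputed as 0 with a warning
so classifier inputs stay dense.

The fissure-sensitive 22-feature registry — Geary's C, first-order
maximum/range, intensity-at-volume-fraction-90, histogram 10th
percentile and mode, eleven GLCM difference features across five
aggregation modes, NGTDM complexity (2D-merged and 3D) and NGLDM
dependence-count energy — responds to local intensity, heterogeneity
and gradient structure near a streak rather than to NP state, which is
what makes it usable for occlusion mapping. The `full` registry expands
every implemented family × aggregation combination and is extensible by
registering further `FeatureDef` entries.

## Classifier

One network: input layer (one node per feature), five tanh hidden
units, two-node softmax output; cross-entropy loss on one-hot targets
(the natural pairing with a softmax read-out). Training is full-batch
gradient descent with momentum 0.9 and an adaptive learning rate
(initial 0.01, ×1.05 after an improving epoch, ×0.7 with the step
reverted and the momentum buffer cleared when the loss grows by more
than ×1.04), capped at 5000 epochs. The weights of the first epoch
achieving the minimum early-stop-set loss are kept. Features are
z-scored with statistics from the ensemble's training data — required
for gradient-descent stability across features whose scales differ by
orders of magnitude.

The ensemble averages the fissure-class probability of many members
(default 1000, tests use 4–50) that differ only in seed: member *i*
initializes uniformly in ±1/√fan-in from seed `base_seed + i` and, by
default, carves its own stratified 20 % early-stop split (which also
diversifies members). A `paper_faithful` mode instead early-stops every
member on the held-out fold itself; both modes are provided because the
protocol the package models is ambiguous on this point. A disc is
called fissured when the averaged probability is ≥ 0.5 (boundary
positive).

## Cross-validation and the HIZ arm

Folds are assigned at patient level (default k = 10): patients are
shuffled (seeded), ordered by descending positive-disc count, and
greedily packed into the fold with the fewest positives (ties: fewest
discs, then lowest index), so per-fold positive counts are balanced to
within the largest single patient's count. Each fold is scored by a
fresh ensemble trained on the other folds; standardization statistics
never see held-out discs. The comparison arm predicts "fissure" exactly
when the disc carries a ventral or dorsal HIZ, and the two classifiers
are compared on paired accuracy with the exact mid-p McNemar test
(`2·P(X ≤ min(b,c)) − P(X = min(b,c))`, X ~ Binomial(b+c, ½)).

## Attention mapping

A full-height, all-slice vertical slab (width 5 columns) sweeps the ROI
one column at a time. Slab voxels are replaced by the **median** ROI
intensity of the original image: on a bimodal disc the median sits at
the AF signal level, so the fill erases a bright streak without
painting a bright artefact of its own (the ROI *mean* lies between the
compartments and was observed to do exactly that, shifting the response
to the NP boundary instead of the fissure). Occluding twice at one
position is therefore idempotent.

After each placement the 22 features are re-extracted and re-scored by
the 22-input classifier of the disc's own cross-validation fold (so the
mapped disc was never in that model's training data). The map records,
at the slab's center column, the **drop of the classification score on
the log-odds scale** — the mean over ensemble members of the
pre-softmax score difference z₁ − z₀, a monotone transform of the
softmax output — relative to the unoccluded baseline (negative drops
clipped to zero). Log-odds rather than raw probability matters in
practice: a well-trained ensemble saturates at p = 1 on clearly
fissured discs and the probability drop under occlusion collapses to
exactly zero, while the pre-softmax response never saturates. The raw
occluded score and the probability scale remain available
(`map_mode="score"`, `score_space="probability"`).

The per-column profile is min-max normalized onto the ROI; columns
reaching at least 80 % of the map's peak form the highlighted mask —
magnitude-relative rather than rank-based, because the occluding slab
produces a small edge-erasure ridge wherever it crosses the
nucleus/annulus border, and a rank quantile would highlight that
secondary ridge on every disc no matter how weak it is beside the
fissure peak. A localization is judged correct when every true
in-plane fissure's mask (dilated by a 3-pixel tolerance) intersects the
highlight, and no highlighted component lies beyond tolerance of every
fissure. Lateral-only fissures are always judged incorrect
(`lateral_fissure`); a disc the classifier got wrong is judged on the
classification alone (`misclassified`); a fissure-free disc correctly
predicted negative needs no map and counts as correct. The localization
rate is reported over all attention-eligible discs.

## Numerical and design notes

* Determinism: every stochastic stage derives from explicit seeds
  (cohort, fold assignment, member initialization, Geary subsampling);
  reruns of the pipeline are byte-identical.
* Histogram mode ties break to the lowest level; the intensity-volume
  threshold is the smallest masked intensity γ with fraction(≥ γ) ≤
  0.90; discretization maps the masked maximum into the top bin;
  constant ROIs discretize to level 1 and make Geary's C undefined
  (imputed 0 with a warning).
* Problem sizes in the test suite are chosen to keep a laptop run
  comfortable: the recovery surface uses a 67-patient / 201-disc cohort
  with contrast 6, 50-member ensembles, and 10 patient-level folds;
  unit-level model tests use toy ensembles of 3–10 members. The
  null-calibration check averages the out-of-fold AUC over five
  independent noise-feature draws because a single draw's null AUC has
  a sampling SD of ~0.05 at this cohort size.
* Training length on phantoms: recovery runs cap members at 80 epochs
  (the 45-disc demo uses 300). Phantom feature sets at contrast 6 are
  nearly separable, so validation early stopping never halts weight
  growth; members trained well past convergence become so overconfident
  that the occlusion response degenerates into amplified edge artefacts
  while classification AUC stays unchanged — and the epoch count at
  which this sets in shrinks as the training set grows (more data fits
  tighter per epoch). Epochs are the only capacity control in this
  training rule (it has no weight decay), so the cap is the
  regularizer. On noisy real data the early-stop criterion itself plays
  this role.
* Known limitations: no axial/coronal sweeps (lateral fissures are
  unlocalizable by design), no nested hyperparameter search
  (hyperparameters are fixed across folds), no confidence intervals on
  AUC, and the full ~480-feature radiomics surface is represented by
  the extensible family × aggregation registry rather than a fixed
  third-party feature list.
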