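# Methods

## Problem setting

`travelnet` studies the *traveling model* (also called cyclical weight
transfer) for training a 3D convolutional disease classifier across many
healthcare centers without pooling their images.  A single network, together
with its optimizer state, is trained sequentially: it visits every center
once per *cycle*, trains for a fixed number of *local epochs* on that
center's data, and moves on.  The order of visits is a seeded permutation —
either drawn once and reused (*fixed* order) or redrawn every cycle with an
incrementing seed (*random* order), the latter emulating the batch
shuffling of centralized training at the center level.  The reference point
is a *centralized* baseline trained on the pooled, globally shuffled data
with early stopping on the test loss.

The regime of interest is strongly non-IID: a long-tailed center-size
distribution (a couple of multi-site studies plus many single-site studies,
several centers holding fewer than 5 scans), systematic differences in
label mix, demographics, scanner vendor and field strength.  The motivating
application is Parkinson's disease vs healthy classification from
T1-weighted brain MRI gathered by 83 real centers (1,817 scans, 1,410
train / 407 test); those restricted images are replaced here by synthetic
phantoms with controllable class signal and center nuisance.

## Cohort model

A cohort is a list of participant records (center, binary label, sex, age,
vendor, field strength).  The generator is organised in *center groups*
(one per study): each group fixes a center count and a joint size sampler.
The default profile mirrors the published database: 14 studies over 83
centers; study sample totals are rescaled by largest-remainder rounding so
the cohort totals exactly 1,817 records (the published per-study totals
over-count the final cohort because some scans were excluded downstream);
multi-site studies allocate their total across centers with normalised
lognormal weights (sigma = 1), reproducing the long tail including
sub-5-sample centers.  Per-study label, sex and age-band fractions follow
the published demographic cells; studies contributing only one class (e.g.
an all-healthy aging study) yield centers with extreme label skew, which is
part of the intended heterogeneity.

**Split.**  Centers with at least 25 records are split 80/20 within-center
with round-half-up on the train count.  Smaller centers are pooled and
assigned greedily: small centers in descending size order, records within a
center in seed-shuffled order, each record going to the side (train or
test) whose (sex, age-band) cell is further below its target share, with
test assignment capped at 20% of the small-center pool.  The rule is
deterministic given the split seed, and empirically balances sex at least
as well as random assignment.  Age bands use strict <60 vs 60+.

## Phantoms

Each volume is a pure function of `(master_seed, participant_id)`:

1. an ellipsoidal tissue template (semi-axes 0.42/0.36/0.30 of the
   half-grid; baseline intensity 1, background 0) with a spherical
   "atrophy" region (radius 0.12, offset from center) strictly inside it;
2. the region is scaled by `1 − class_effect_size` for disease-positive
   participants (default 0.15, i.e. a 15% regional signal) and by an age
   drift of `age_effect_slope` per decade relative to age 60 (default −1%);
3. a per-center multiplicative gain `N(1, center_gain_sd)` (default 0.10)
   and a per-center multiplicative bias field `exp(b·r)` with linear
   coefficients of scale `bias_field_amplitude/2` (default 0.10) — the real
   preprocessing pipeline *removes* bias fields, so adding one is a
   deliberate center nuisance;
4. additive white Gaussian noise with a vendor-specific SD
   (Siemens 0.05, GE 0.06, Philips 0.07).

Volumes are z-scored per volume before entering the network (the input
normalisation is not specified by the protocol; per-volume z-scoring is the
package's choice).  Defaults were set so that a threshold classifier on the
mean region intensity is clearly better than chance but the task still
requires learning a localisation: the "separability dial" property test
verifies that this threshold AUROC grows monotonically with the class
effect and is ≈0.5 at zero effect.

What the phantoms do **not** model: anatomy, registration error,
partial-volume effects, site-specific artefacts beyond smooth gain/bias,
or any correlation between demographics and scanner.  Passing the
benchmark therefore shows that the *training paradigm* behaves as reported
under controlled heterogeneity — not that the classifier would reach any
particular accuracy on real MRI.

## Network

A scaled-down simple fully convolutional network: `n_conv_blocks` blocks of
{3x3x3 convolution (stride 1, pad 1) → instance norm → ReLU → 2x max pool},
then dropout 0.20 (before the flattening stage, per the protocol), flatten,
and one linear layer to two logits; the disease score is the softmax
probability of the positive class.  Defaults: 4 blocks, channels
8/16/32/32, grid 24 (45,474 parameters).

Numerical choices:

* **Instance norm instead of batch norm.**  Batch statistics are degenerate
  for the 1-sample batches tiny centers produce, and running means would
  make train/eval forward passes differ.  Instance norm is per-sample, so
  evaluation is deterministic and identical to the training-mode forward
  (up to dropout).
* **Loss**: softmax cross-entropy (the protocol does not state its loss;
  this is the standard choice for a 2-class softmax head).
* **Optimizer**: Adam (beta1 0.9, beta2 0.999, eps 1e-8) with bias
  correction, implemented in numpy alongside the layers; all tensors are
  float32, gradients are verified against central differences in float64.
* **Max pooling** uses floor mode (odd trailing voxels dropped) and routes
  gradients to the first voxel attaining each window maximum.
* An optional stride-2 input convolution halves the working grid; the
  input layer skips its (unused) input gradient.

## Training protocols

All hyperparameter defaults follow the published protocol: Adam; batch
size 5, or the center size when smaller; dropout 0.20; 30 cycles/epochs.

* **Centralized**: initial lr 0.001, exponential decay 0.97 per epoch (the
  decay *rate* is unspecified in the protocol; 0.97 is the package
  default), early stopping with patience 10 on the pooled test loss,
  best epoch = lowest test loss, earliest on ties.
* **Traveling**: initial lr 0.0001, no early stopping; lr decays once per
  full cycle (one cycle is the traveling analog of one epoch); the travel
  schedule uses base seed 42 — fixed order draws one permutation with seed
  42, random order uses seed 42 + (cycle − 1), i.e. 42, 43, 44, … with
  cycle 1 on 42.  Permutations are drawn by an explicit Fisher–Yates over
  lexicographically sorted center ids so schedules replay on any platform.
* **Optimizer state travels with the model** and is not reset at center
  boundaries (resetting would be a different algorithm; a
  `reset_optimizer_per_center` switch exposes the alternative).
* Per-epoch batch shuffling and dropout masks are driven by one PRNG
  seeded by a SHA-256 hash of `(data_seed, cycle, center_id, epoch)`.
  The centralized loop uses the same derivation with a configurable pooled
  center key, which is why traveling on a single center reproduces
  centralized training bit for bit when seeds and learning rates are
  matched — an exact oracle the test suite exercises.
* Evaluation (pooled test AUROC and loss) happens once per cycle, in
  evaluation mode (dropout off).

AUROC is computed by mid-ranks (Mann–Whitney), ties counting 1/2.  The
*instability index* summarises cycle-to-cycle variability as the population
standard deviation of successive differences of the AUROC series (0 for a
constant series; windowed from the end, full series by default).

## The 12-center benchmark

Desk-scale analog of the full experiment (see `travelnet.benchmark`):
12 centers, 300 participants with lognormal long-tail sizes (min 1),
per-center disease fraction Beta(6, 6); phantom and network settings as
above except channels 4/8/16 with a stride-2 input convolution (4,546
parameters) to keep 30-cycle runs in the tens of seconds on one CPU core.
~240 training and ~60 test volumes per replicate.

Two deliberate scale adjustments, fixed before any benchmark acceptance
run and not revisited:

* The published traveling lr (1e-4) was chosen for ~1,410 training scans
  per cycle.  At 240 scans per cycle the same lr yields 6x less parameter
  displacement per cycle, so the benchmark rescales it by the data ratio,
  `1e-4 x 1410/240 ≈ 5.9e-4`, keeping per-cycle displacement comparable
  and preserving traveling-lr < centralized-lr.  The centralized baseline
  keeps the published protocol verbatim.
* Five replicate seeds (fresh cohort, phantoms, initialisation and data
  order each) for the headline comparisons; the 2- and 5-local-epoch
  stability runs use the first three replicates.  All runs are assessed
  over the same 30 cycles.  Comparisons are *paired within replicate*
  (each replicate shares its cohort and initialisation across runs) and
  reduced by the median over replicates.

Reported quantities: final-cycle AUROC of random- and fixed-order traveling
(1 local epoch), best-cycle AUROC of the centralized baseline, the paired
|traveling − centralized| gap, the paired random − fixed difference, and
the instability index for 1/2/5 local epochs under random order.

## Known limitations

* The numpy network is adequate for 24³ grids and thousands of parameters;
  it is not a general-purpose deep-learning stack (no GPU, no autograd
  graph, single-threaded conv kernels).
* Bit-exact reproducibility holds within a platform/BLAS build; across
  different BLAS implementations, floating-point reductions may reorder.
* The benchmark's AUROC levels depend on the phantom effect sizes and are
  not comparable to the published accuracy on real MRI; only the
  *relative* behaviour of the training paradigms is meaningful.
* Real-data mode (NIfTI volumes + manifest) exercises the same training
  loops but is only smoke-tested against synthetic files.
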