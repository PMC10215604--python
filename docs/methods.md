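# Methods

This note documents the models, the defaults and why they hold, the
synthetic-data assumptions, and the numerical choices. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem and encoding

The package searches for the cheapest combination of ECG leads and input
window length that preserves classification quality. A candidate is the
chromosome `C = [T_L, L_1..L_12]` with `T_L ∈ {1..9}` seconds and a binary
lead mask in the canonical order I, II, III, avR, avL, avF, V1–V6 (gene *i*
is lead *i*; the all-zero mask is invalid). Fitness is

    fitness = α·F1 + β·Acc − γ·T_L − σ·Σ L_i,
    α = β = 1, γ = 0.002, σ = 0.01,

with F1 and Acc on the 0–1 scale. F1 is the macro average over classes and
Acc the overall accuracy; macro is used for consistency with the metric
tables, and the choice is confined to one helper should a pooled variant be
wanted. The penalties are small relative to attainable quality differences,
so they act as tie-breakers among near-equivalent solutions — one extra lead
costs exactly 0.01, one extra second 0.002.

## Preprocessing

Each lead is denoised with a Daubechies-6 discrete wavelet transform:
decomposition to the level whose approximation band lies below ≈2 Hz
(level 8 at 1000 Hz), the approximation coefficients are zeroed (baseline
wander), and the two finest detail bands are soft-thresholded with the
universal threshold `σ̂·√(2 ln n)`, `σ̂ = MAD/0.6745` estimated from the
finest band. Signals are padded symmetrically to a multiple of `2^level`
so the periodized transform is exactly invertible; on such lengths the
operator is an exact projection (idempotent to machine precision), while on
other lengths re-application differs only by boundary effects. With
thresholding disabled the operator is exactly linear, which the property
tests exploit.

Records are cut sequentially from sample 0 into non-overlapping windows of
`T_L` seconds; the trailing partial window is discarded and no beat
detection is performed. Every window inherits its record's label. Each lead
of each window is then z-scored independently (guard: sd < 1e-8 maps the
row to zeros). Per-segment normalisation removes local baseline offset;
note it also removes pure amplitude-scaling differences between classes, so
planted synthetic effects must be morphological (e.g. polarity) rather than
purely multiplicative.

## Feature extraction model

One network per (lead, segment length): a 1-D residual CNN with a 64-filter
kernel-13 stem (stride 1, then max-pool stride 2) and six two-convolution
stages of widths 64, 64, 128, 256, 512, 512 — thirteen convolutions in
total. Within a stage the first convolution has stride 1, the second
stride 2, followed by an average pool of stride 2; a kernel-1 stride-2
projection convolution with batch norm forms the shortcut (shortcuts are
not counted in the 13). All convolutions use "same" padding and are
followed by batch norm and ReLU. Global average pooling over the final 512
channels yields the feature vector; a fully connected head (5-unit softmax
for the five-class task, 2-unit sigmoid with argmax decision for the binary
task) drives training with Adam (lr 0.001), batch 128, 40 epochs, and
cross-entropy — class-weighted (inverse frequency, normalised to mean 1)
for imbalanced binary data. Features are extracted in inference mode
(batch-norm running statistics frozen).

The implementation is a self-contained numpy layer library
(`galslo.nn`) with manual backprop, verified against central finite
differences in the tests. One subtlety: the true gradient of a convolution
bias feeding directly into batch norm is identically zero (the
normalisation removes per-channel constants), so numerical checks compare
with a mixed absolute/relative tolerance.

`width_scale` shrinks every width proportionally. Desk-scale runs use 1/8
(tests) or 1/16 (end-to-end runs) with correspondingly narrower features;
topology and code paths are identical to full width, which remains the
default. The feature cache records its width and enforces uniformity.

## Classification heads

Selected leads' feature vectors are stacked as rows of an
`(n_leads × width)` block. The lead attention module applies a shared 1-D
convolution (16 filters, kernel 3) along the feature axis of each lead,
global-averages it to one 16-vector per lead, and maps the concatenation
through a fully connected layer with exactly `n_leads` units and a softmax,
yielding weights `w ≥ 0, Σw = 1`. Features are residually re-weighted,
`f_i ← f_i(1 + w_i)`, and flattened into an MLP (hidden 128/64 by default,
ReLU, softmax output). Whether the attention convolution should run across
leads or across features is not uniquely determined by the architecture
sketch it follows; the per-lead reading used here is isolated behind
`lead_weights` so it can be swapped. Forcing `w = 0` reduces the network
exactly to the pure-MLP baseline on the same input, which is how the
attention ablation is controlled.

Heads train with Adam on softmax cross-entropy (optionally class-weighted),
early-stopped on a held-out tail of the shuffled training data (patience 5,
up to 30 epochs by default). For small desk-scale feature sets the search
harnesses raise the learning rate to 0.01 and the epoch budget to 40 so
every head converges — otherwise fitness differences between chromosomes
reflect optimisation noise rather than lead information, and the search
degenerates into selecting lucky training seeds.

## Genetic search

Population 100; up to 20 generations. Each generation evaluates everyone,
keeps the 50 fittest as parents (ties broken toward fewer leads, then
shorter windows, then insertion order), and rebuilds the population as
50 parents + 40 crossover children (20 uniformly drawn parent pairs) +
10 mutants — the counts only reach 100 with elitist parent carry-over,
which is therefore used. Crossover exchanges genes atomically within seven
groups — `[T_L]`, `[L1,L5]`, `[L2,L3,L6]`, `[L4]`, `[L7,L8]`, `[L9,L10]`,
`[L11,L12]` — with probabilities `[0.8, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]`; the
lead groups collect leads that view the same anatomical region, so a
child's information about one heart part always comes from one parent.
Mutation resamples `T_L` uniformly among the other allowed lengths with
probability 0.8 and flips each gene with probability 0.5. Invalid (all-zero)
masks are repaired by setting one uniformly chosen allowed gene; under a
fixed-lead-count constraint masks are repaired by random add/remove, and a
fixed `T_L` excludes the length slot from both operators. The search stops
early when the population maximum fitness is bit-identical for three
consecutive generations — meaningful because evaluation is memoized — and
returns the best individual ever evaluated.

Fitness is measured on a validation split carved inter-patient from the
training patients (20 % of each class's patients, fixed once per
evaluator); the test split is reserved for the final report, for which the
head is retrained on the full training data. Each chromosome's head
training is seeded by a CRC32 hash of the chromosome combined with the
evaluator seed, making evaluations reproducible, memoizable, and
independent of visit order.

## Metrics

One-vs-rest per class: `Sen = TP/(TP+FN)`, `Spe = TN/(TN+FP)`,
`Ppr = TP/(TP+FP)`, `Acc = (TP+TN)/total`, `F1 = 2·Sen·Ppr/(Sen+Ppr)`.
Macro rows are unweighted means of the *unrounded* per-class values; macro
F1 is the mean of per-class F1 values, not the F1 of macro Sen/Ppr — the
two disagree at the second decimal on the bundled binary worked example,
and only the former reproduces it. All computation is in doubles; rounding
(half-up, two decimals) happens only at presentation. `0/0` cells are
defined as 0 with a warning so macro averages stay defined on degenerate
splits. Confidence intervals are deliberately not implemented: no defensible
procedure is fixed by the quantities the package computes.

## Synthetic data

`generate_records` emits 12-lead records at 1000 Hz whose beats are
Gaussian bumps (sd 40 ms) at a class-dependent rate — tachycardia-like
classes >100 bpm, bradycardia-like <60 bpm, premature-beat classes add
random early ectopic bumps — with a fixed per-lead amplitude profile whose
class deltas (scaling and/or polarity inversion) are planted only on a
configurable informative-lead subset, plus sinusoidal baseline wander
(0.2 mV at 0.3 Hz) and white noise (0.05 mV sd). Default record lengths are
drawn from 11–92 s (32–120 s for the binary preset), one record per
patient. This emulates the data shapes and the lead-selectivity structure
the search needs, not cardiac electrophysiology: there are no P/T waves, no
realistic lead projections, and no pathological morphology, so passing
tests demonstrate that the selection/attention machinery recovers planted
structure — not clinical performance.

`generate_feature_fixture` skips signals entirely: class-conditional
Gaussian features (512-wide by default; 64 in the desk-scale harnesses)
where each class mean on an informative lead is displaced `effect_size`
within-class standard deviations from the grand center along a seeded
random direction, non-informative leads share identical means, and each
patient carries a small random offset (sd 0.3) so inter-patient structure
exists. At `effect_size = 3` a single informative lead is almost perfectly
linearly separable; the planted-recovery harness uses 1.5 so that one lead
alone is imperfect and combining both planted leads pays for the 0.01/lead
penalty.

## Problem sizes for verification runs

The packaged checks are desk-scale by design: the GA/brute-force
equivalence uses 3 lengths × 4 leads (45 chromosomes) with 64-wide
features; planted-lead recovery searches 3 lengths × 12 leads (12 285
chromosomes) with 16 train / 6 test patients per class; the end-to-end run
uses 8 patients per class, 20–40 s records, lengths {1, 2} s, 1/16-width
extractors trained 10 epochs, and at most 15 windows per record. Full-width
networks, 40-epoch training, and all nine lengths are the defaults for real
deployments of the library.

## Known limitations

* The wavelet recipe (depth, threshold rule, suppressed bands) is one
  standard choice among several; it is isolated behind `denoise`.
* The attention convolution's orientation and size are a design choice (see
  above), as is the MLP head's shape.
* Weighted cross-entropy uses inverse-frequency weights; other weightings
  are injectable via `class_weights`.
* The WFDB reader supports single-file interleaved format-16 records only —
  sufficient for the targeted public 12-lead 1000 Hz data, not a general
  WFDB implementation.
* Fitness estimated on a finite validation split is noisy; with weak class
  structure the complexity penalty (0.01/lead) is smaller than that noise,
  and spurious leads can survive the search. The recovery harness sizes its
  validation split so this does not dominate.
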