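# Methods

This note documents the models and procedures implemented in
`adherence_da`, the assumptions behind them, and the choices made where
the design was genuinely open.

## Problem and data model

Participants in tablet-based cognitive-training trials are prescribed a
weekly schedule (5 play days out of 7, 45–60 minutes per day). Four
variables are recorded per participant-day: minutes played, number of
sessions, maximum task level reached, and tasks completed. A day is
*adherent* when the participant played at least 10 minutes (the
threshold separates real engagement from accidentally opened sessions;
exactly 10 minutes counts as adherent). The prediction task: given the
four variables over a window of N consecutive days, classify day N+1 as
adherent or not. A separate model is fitted per participant — playing
patterns are individual, so a single cohort-wide model would blur them.

Each participant's record is split chronologically: days 1–30 train the
model, days 31–60 test it; later days are unused. Thirty days of
training yields only `30 − N = 23` windows at N = 7, which is the data
scarcity that motivates borrowing windows from other participants.

## Window size from the dominant cyclic period

N is chosen as the dominant cyclic period of the daily play-time series:
the series is mean-centered, zero-padded to 8× its length, and the
discrete-Fourier amplitude spectrum is maximized over frequencies whose
periods lie in [2, T/2] days; the winning period is rounded to the
nearest integer day. Zero-padding matters: a 30-day record is not an
integer number of weeks, and without padding the coarse frequency grid
puts the weekly peak at 30/4 = 7.5 days, which would round to 8. With
padding the 5-on/2-off prescription yields N = 7 for all record lengths
we tested (28–60 days). The DC bin is excluded (the mean is not a
periodicity), periods above T/2 are unresolvable, and a flat spectrum
(e.g. a constant series) falls back to N = 7 — one week — with a
warning. Selection defaults to a single study-wide N (7), matching the
protocol; a per-participant mode is available by calling
`select_window_size` on individual series.

## Features and normalization

Within each participant, the four features are z-scored using statistics
of that participant's *training days only*; the same affine transform is
applied to their test days. Zero-variance features map to zero. No
statistic of any test day ever enters a transform (asserted by tests).
Per-participant normalization is applied before pooling windows across
participants, so a source participant's raw scale (45- vs 60-minute
prescriptions, fast vs slow task rates) does not leak into the pooled
input distribution. This is worth stating clearly: per-participant
standardization is itself a simple form of domain alignment, and it
raises the bar for what adversarial adaptation can add (see
*Benchmark*, below).

## Classifier

The per-participant classifier is a small 1-D convolutional network over
the (N × 4) window: two blocks of valid-mode convolution (kernel 2,
stride 1; 8 then 16 filters) each followed by max-pooling (pool 2), then
flatten, a 16-unit ReLU dense layer, and a 2-class softmax. For N = 7
the trunk reduces to a single 16-channel position, i.e. a week summary.
Convolution layers use the standard unflipped (cross-correlation)
parameterization — equivalent for learned kernels to the flipped
sliding-sum definition, which the exported `convolve1d` primitive
implements and pins with tests.

Training minimizes cross-entropy with Adam (learning rate 1e-3, batch
8), for at most 200 epochs with early stopping; the final 20% of the
target's training windows (chronological) form the validation split, the
checkpoint with the best validation loss is kept, and patience is 20
epochs. These hyperparameters are package choices; only the block
structure of the architecture is fixed by the protocol being
implemented. Inverse-frequency class weighting is available but off by
default. The network engine is NumPy with manual backpropagation: the
models have O(10³) parameters and O(10²) training samples, so a
dependency-free engine keeps every training run bit-reproducible under a
fixed seed (weight initialization and batch order derive from separate
seed streams of one root seed).

## Gramian angular fields and clustering

For clustering, each participant's daily play-time series is encoded as
a Gramian angular field: rescale the series x into an interval within
[−1, 1], map to polar angles θ_i = arccos(x_i) (radii i/T), and form
G_ij = cos(θ_i + θ_j) — the summation (GASF) form. Min–max rescaling is
used rather than z-scoring because arccos requires |x| ≤ 1.

Two rescaling intervals are supported. The full interval [−1, 1] is the
default for the core transform and gives the classical identities
(symmetry, entries in [−1, 1], diagonal 2x² − 1, outer form
x_i x_j − √(1−x_i²)√(1−x_j²)). It is, however, not monotone in play
time: both no-play pairs (θ = π) and long-play pairs (θ = 0) map to
G = +1. The participant-image pipeline therefore uses the unit interval
[0, 1] (angles in [0, π/2]), under which the field increases
monotonically from no-play pairs (−1) to long-play pairs (+1); rendered
with the default yellow→blue colormap, days without play are light and
sustained play is dark, and lapse runs appear as light bands. This keeps
the images directly readable and gives the clustering a monotone
engagement signal.

Participant features are extracted from the GAF by flattening the matrix
and projecting onto principal components fitted on the cohort (16
components by default). This extractor is deterministic and captures
exactly the pattern-block structure the images exhibit; a pretrained
deep-image extractor ("vgg16") is an accepted plug-in name but requires
externally supplied weights and raises a clear error otherwise.
K-means (K = 4, ten restarts, fixed seed) groups the participants;
K-means++ seeding is order-sensitive, so the rows are fitted in a
canonical lexicographic order to make the assignment invariant to
participant listing. K = 4 follows the protocol's visual-inspection
choice; silhouette scores are reported so users can assess other K.
By default GAFs are computed over the full 60-day structured phase (the
span used for grouping similar playing patterns); a train-days-only mode
exists for workflows that must not touch test-period play time, at the
cost of clustering on half the information.

## Adversarial domain adaptation

For a target participant, the source pool is the other members of their
cluster (cross-study protocol: only cluster members from the *other*
study). Three arms are compared:

1. *no source, no DA* — train on the target's 23 windows;
2. *with source, no DA* — train on target + source windows pooled;
3. *with source, with DA* — the same union, plus a domain head
   (dense 8 → 2) reading the shared flattened features through a
   gradient-reversal layer (identity forward, −λ× gradient backward).

The label head sees all labeled windows (the target's training days are
labeled, so this is supervised domain adaptation); the domain head
classifies target vs source. Because source windows outnumber the
target's roughly tenfold, the domain cross-entropy is weighted by
inverse domain frequency — without this the domain game degenerates into
always-predict-source and the reversed gradient carries almost no
signal. λ defaults to 1.0 (fixed), with an optional annealing schedule
λ·(2/(1+e^(−10p)) − 1) over training progress p. Model selection uses
the target-validation label loss, as in the other arms.

Two contracts pin the implementation. With λ = 0 the reversed gradient
into the extractor is exactly zero and the domain head's parameters are
initialized and updated on separate streams, so the adversarial arm's
per-epoch label losses equal pooled training's bit-for-bit. And the
analytic gradients equal finite differences of the joint objective:
label CE for the label head, domain CE for the domain head, and
(label CE − λ·domain CE) for the shared extractor. An empty source pool
(singleton cluster) degrades both source arms to the baseline with a
warning.

## Evaluation and statistics

Accuracy, precision, recall and F1 are computed per target on the 30
test days' windows, with class 1 (adherent) as positive; zero
denominators score 0 and are flagged; a macro-averaging switch exists.
Cohort results are means and SDs across participants. Paired arm
comparisons use (a) the exact two-sided binomial sign test on
per-participant F1, ties dropped, and (b) one-way repeated-measures
ANOVA computed from the sums-of-squares decomposition with subject as
the blocking factor (no sphericity correction; for two conditions
F = t² of the paired t test).

## Synthetic cohorts

No human data accompany the package, so cohorts are simulated with the
structure the analysis assumes. Four archetypes emulate the playing
patterns such trials report: non-players (play probability 0.05),
consistent players (0.95, 45 ± 8 min), consistent-with-lapses players
(long-run scheduled-day play fraction 0.75 with geometric missed-day
runs of mean 3 days — play runs alternate with lapses, giving the
contiguous light bands seen in GAF images and a Markov-persistent,
hence partially predictable, adherence sequence), and erratic players
(0.5, 25 ± 18 min, schedule-ignoring). Durations on played days are
zero-truncated Gaussians; sessions are 1–2; tasks scale with duration
(Poisson noise, 0.35 tasks/min); the maximum level ramps monotonically
on played days. The study-level 45- vs 60-minute prescriptions scale
durations multiplicatively.

The `shift` knob creates per-participant distribution shift: additive
jitter on play probability (±0.25 at shift 1) and mean duration (±15
min), and log-uniform (±0.6 nats) jitter on duration SD, task rate,
level growth, and session splitting. The first group changes adherence
base rates (label shift); the second changes how the observed features
relate to each other (covariate shift). What the generator does *not*
model: within-day timing, game content and difficulty adaptation,
long-term trends (fatigue, holidays), or correlated drop-out — so
passing tests show that the pipeline recovers the designed structure,
not that it would attain any particular accuracy on real trial data.

## Benchmark and expected behavior

The transfer benchmark (`adherence_da.benchmark`) fixes a 20-participant
mixed cohort (30% consistent, 45% with-lapses, 25% erratic; shift 1.0)
and repeats the three-arm protocol over 10 training/clustering seeds
(120 epochs, patience 20). Mean accuracies are averaged over
participants and repetitions; per-participant F1 (averaged over
repetitions) feeds the paired tests.

Two properties are expected and tested at different strengths. The arm
*ordering* — baseline ≤ pooled ≤ adversarial in mean accuracy — reflects
that 23 windows are too few (baseline worst) and that addressing the
residual source/target disparity should not hurt. The *per-participant
consistency* of the adversarial arm's F1 advantage over pooling is a
much stronger property: at 20 participants a significant sign test
requires the adversarial arm to win for ≥ 15 of 20 targets. Because
per-participant z-normalization already removes most raw-scale
disparity, the residual shift in this simulation is dominated by
adherence-base-rate differences — label shift — which feature-marginal
alignment does not correct; the adversarial benefit here is therefore
real but small and not uniform across targets. The benchmark reports
both the ordering and the paired-test p-values as computed.

## Numerical and degenerate-input conventions

Constant series rescale to the interval midpoint (GAF of an all-equal
series is well defined). Polar mapping clamps |x| ≤ 1 within 1e−9 and
rejects larger violations by index. Prediction ties (softmax exactly
0.5) resolve to class 0. Empty clusters are permitted and logged.
Calendar gaps in a play log are zero-filled (a day not played is an
informative non-adherent day, not missing data) and flagged per
participant. All randomness flows from explicit integer seeds through
separate spawned streams (cohort assignment, per-participant generation,
weight initialization, batch order), so every pipeline stage is
bit-reproducible on one platform; training is single-threaded.
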