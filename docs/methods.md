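# Methods

`riskreplay` implements an online hypertension risk predictor for
few-shot, nonstationary streams of multivisit EHR data, together with
the synthetic stream generator used to exercise it and the evaluation
metrics. This note records the model, its assumptions, the defaults
that matter, and the design choices made where the design was open.

## Problem setting

The data are longitudinal physical-examination records: one row per
visit, 20 attributes per visit (17 numeric vitals/exam values and 3
three-level categorical pattern descriptors), and a binary tag
(`is_hyper`) marking hypertension. Records arrive in yearly batches of
a few hundred patients whose attribute distributions drift from year
to year, so a model fitted once goes stale, while each individual
batch is too small to retrain a good model from scratch. The package's
answer is continual learning: keep one model alive across batches,
replay synthetic *latent features* of past data when updating it, and
gate the update on a fit test between the incoming batch and the
generator's feature distribution.

## Input representation

A visit is embedded as the concatenation, in schema order, of z-scored
numeric attributes and one-hot categorical blocks, giving d = 17 + 3x3
= 26 dimensions. The numeric normalizer (per-attribute mean/sd, sd
floored at 1e-6) is fitted on the first batch's training split and
frozen thereafter (a per-batch refresh is configurable; the `retrain`
ablation always refits). Freezing is the honest online choice — at
deployment time future batches are unseen — and it is also what gives
distribution drift a mechanism to degrade a stale model.

The agent's state at a patient's t-th visit is
`concat(current embedding, mean of embeddings of visits 1..t-1)`,
length 2d = 52; the history half is the zero vector at the first
visit. The mean is maintained incrementally and is permutation-
invariant in the history by construction.

## The risk agent

Prediction is cast as a sequential decision problem: one episode per
patient, one step per visit, actions `1` (flag risk) / `0` (no risk).
The Q-function is a small feed-forward pipeline: a feature extractor
(52 -> 64 -> 32, rectifier hidden) into a two-output Q head
(32 -> 32 -> 2). The networks are plain numpy MLPs with hand-written
backprop (`_nn.py`); the same primitive serves the generator and the
critic, so losses can be chained across networks.

The reward has two parts: a correctness term of +1/-1, and a
confidence term `sigmoid(1 / (D + eps))` with
`D = (||(left, right) - onehot(label)||^2) / 2` computed on the
softmax-normalised action scores, `eps = 1e-6`. Since `D <= 1`, the
confidence term lies in (0.5, 1], and the total in (-0.5, 2].

Experience goes into two FIFO buffers (capacity 10,000 each) keyed by
whether the prediction was correct; training steps strictly alternate
between the buffers (falling back when one is empty). Within a buffer,
transitions are sampled by a softmax over absolute TD errors, so
poorly fitted experiences are replayed more often. The TD error is
`r + y * max_a' Q_target(s', a') - Q(s, a)` with discount y = 0.9 and
no bootstrap on terminal (last-visit) transitions; the loss is the
mean squared TD error of the sampled batch, minimised with Adam
(lr 1e-3, batch 32), with the target network hard-synced every 100
steps. Exploration is epsilon-greedy with a linear decay from 0.5 to
0.01 over each batch's training budget; greedy ties break toward
"no risk".

Priorities are refreshed for the whole scheduled buffer every 25
training steps (the sampled batch's priorities are refreshed every
step). Between refreshes the softmax uses slightly stale priorities;
this is purely a cost trade-off and is config-exposed
(`priority_refresh_period = 1` recovers exact laziness).

## Generative feature replay

The generator is conditioned on the label: input `concat(z, onehot)`
with `z ~ N(0, I)` (z_dim 32), three linear layers (hidden 64) with
rectifier activations and a scaled-tanh output (scale 3.0). The output
bound keeps generated features in the standardized range the extractor
produces; a plain tanh would pin them to (-1, 1), which is narrower
than z-scored features actually occupy. The critic takes
`concat(onehot, feature)` through two linear layers (hidden 64) to an
unbounded validity score.

Losses, all Wasserstein-style (no log/sigmoid):

* generator: `-E[D(label, G(label, z))]`;
* critic: `E[D(fake)] - E[D(real extracted feature)]`, with weight
  clipping (default 0.05) after every critic step;
* replay alignment: `E ||G_t(label, z) - G_s(label, z)||^2` with the
  *same* z and labels fed to the current generator and its frozen
  pre-update copy (weight 1.0);
* feature distillation: `E ||F_t(state) - F_{t-1}(state)||^2` between
  the live extractor and its frozen pre-update copy (weight 1.0),
  added to the agent's TD gradient during replay-phase training.

Training alternates `n_critic` critic minibatch steps (default 5) with
one generator step, using RMSProp for both (generator lr 5e-4, critic
lr 5e-3) — the conventional recipe for weight-clipped critics, where
momentum tends to destabilise training. Moment-recovery experiments in
the test suite use a stronger setting (1500 rounds, n_critic 20, clip
0.1) because exact mean recovery needs the critic to stay well ahead
of the generator; the pipeline default (200 rounds, n_critic 5) only
has to produce features good enough for replay.

## The update gate

Before updating on batch t >= 2, a per-label diagonal Gaussian is
fitted to m = 2,000 features sampled from the current generator, and
the incoming batch's mean negative log-likelihood under that density
is compared with the NLL recorded at the last accepted batch. The
update is accepted when `NLL_new <= NLL_prev + margin` with a default
margin of 0.5 nats/sample. The margin exists because a batch NLL is a
sample mean with O(1/sqrt(N)) noise: a strict comparison would reject
roughly half of perfectly matched batches, while distribution shifts
of practical size move the NLL by several nats per affected dimension,
far above the margin. `margin = 0` recovers the strict rule. On
acceptance, the replay update runs (fusion training + adversarial
phase); on rejection, the generator is kept unchanged and the agent
trains on the new batch only.

The fusion set pairs the real batch 1:1 (round half up,
config-exposed) with generated features whose labels mirror the real
batch's label frequencies; generated features enter the agent as
one-step terminal episodes that bypass the extractor.

## Synthetic stream generator

The simulator emulates the summary structure of the yearly screening
cohorts this method targets, and its defaults are those conditions:

* 12 yearly batches of 550 patients (a few hundred patients and
  1.2-1.6k records per year);
* a multivisit count distribution in which ~69% of patients have 2
  visits, ~17% have 3, and long histories are rare (banded counts
  assigned to representative values 5, 7, 9, 12, 16);
* class-conditional numeric means that differ by clinically small
  deltas (defaults: +2.2 years of age, +5.2 mmHg systolic, -4.2 bpm
  heart rate for the hypertensive class), with within-class standard
  deviations set once to standard clinical ranges;
* balanced classes (0.5), labels assigned at patient level and
  constant across visits (a per-visit flip probability exists for
  stress tests);
* per-attribute Gaussian random-walk drift on the batch means, step
  0.3 sd per batch (plus an optional deterministic trend), seeded;
  categorical level probabilities are class-tilted but do not drift;
* patient-level vs visit-level variance split 0.6^2 / 0.8^2 of the
  attribute variance, so repeated visits of one patient correlate.

What the simulator does *not* reproduce: missing data, informative
visit timing, attribute correlations beyond the shared patient offset,
coding changes, or real class imbalance. Passing tests therefore show
that the machinery behaves as specified under controlled drift and
effect sizes — not that any particular clinical accuracy transfers to
a real cohort, which would require restricted-access clinical data.

## Evaluation

Metrics are computed per batch on a held-out patient-level test split
(train : test : validation = 3 : 1 : 1, largest-remainder allocation;
all visits of a patient stay together, so the history-dependent state
never leaks across splits). Accuracy, precision, recall and FPR come
from the standard 2x2 counts with 0/0 ratios defined as 0 and flagged.
PR-AUC uses step-wise (rectangular) integration over tie-grouped
thresholds — identical to average precision, avoiding the optimism of
linear PR interpolation; with all scores tied the curve is the single
point (recall 1, precision = prevalence). ROC-AUC is the trapezoid
integral over tie-grouped points, which equals the pairwise
concordance U-statistic with half credit for ties exactly — the test
suite asserts that equality. Reported run averages are plain means of
the per-batch values. A repeated-seeded-split mode (`run_repeats`)
reports mean and sd across run seeds.

## Ablation variants

* `retrain` — all learned state (agent, generator, normalizer) is
  discarded before every batch; measures the pure few-shot baseline.
* `no_replay` — the updating module is removed: the batch-1 model is
  reused frozen for all later batches. This is the "stale model"
  reading; a config flag (`no_replay_keeps_training`) switches to the
  alternative reading in which the agent keeps training on new batches
  without replay.
* `no_gate` — every batch gets a replay update, the fit test never
  runs.
* `full` — the complete method.

On the default drifting stream the expected ordering of mean accuracy
is full >= no_gate >= retrain >= no_replay: the frozen model decays
with drift, retraining pays the few-shot price each year, gate-free
replay occasionally updates on ill-fitting batches, and the full
method does best.

## Problem sizes used in the shipped studies

The acceptance script and the ordering test run the study at 12
batches x 100 patients, 4 agent epochs, 60 adversarial rounds, and 5
run seeds; the generator-recovery study uses n = 2,000 points. These
are the package's own study sizes for the shipped experiments; the
simulator defaults (550 patients/batch, 20 epochs, 200 adversarial
rounds) remain the full-scale conditions and can be run through the
CLI unchanged.

## Numerical choices and degenerate inputs

* Softmax priorities and the two-action normalisation use
  max-subtraction; the scalar sigmoid is branch-safe.
* Fitted sds and density variances are floored (1e-6) so constant
  attributes and degenerate generator outputs cannot divide by zero.
* Greedy ties (left == right) resolve to "no risk"; the priority
  softmax over an all-zero gap list is uniform.
* Empty record sets, empty buffers, single-class score lists, invalid
  labels and malformed CSV rows raise named errors (`ConfigError`,
  `ParseError`, `ValueError`) rather than propagating NaNs; an
  all-empty dual buffer makes a training step a no-op with a warning.
* Patient splits with fewer patients than partitions are rejected;
  largest-remainder allocation guarantees every partition at least one
  patient.

## Known limitations

* The NN layer is deliberately minimal (dense MLPs, Adam/RMSProp,
  no GPU); runs scale linearly with records x epochs.
* The generator's density is approximated by a per-label diagonal
  Gaussian fitted to its samples (an adversarial generator has no
  tractable likelihood); multimodal feature distributions would need
  the KDE option or a mixture fit.
* No importance-sampling correction accompanies the prioritized
  sampling, and no gradient-penalty critic variant is provided.
* The simulator's drift is a random walk on means; variance or
  correlation drift is not modelled.
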