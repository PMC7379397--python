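# Methods

## Data model

A cohort row is one participant: a binary group label (CASE/CONTROL), 12
continuous attention-test indices (complete by design — participants
without the attention test are outside the data model), and ordinal
responses 0–3 on up to 107 items across four rating scales (SNAP-IV
parent/teacher, 26 items each; Conners short-form parent 27 / teacher
28). Missingness only affects items. The registry fixes each item's
scale, informant, position, symptom domain, and an
oppositional-defiant (ODD) flag: SNAP positions 19–26 and the Conners
oppositional-subscale positions (parent {2,6,11,16,20,24}, teacher
{2,6,10,15,20}). Conners items outside the oppositional subscale are
labelled by their published subscale family (cognitive
problems–inattention, hyperactivity–impulsivity, ADHD index); domain
labels feed only reporting and simulation, no numerical step depends on
item wording. Canonical order (scale, then position) is the global
tie-break everywhere.

## Per-item network

Each candidate item is fit by a multilayer perceptron: inputs are the
current feature set (12 indices plus previously merged items), 15
hidden ReLU layers in three bands of five — widths 2n, n, ⌊n/2⌋
(clamped at ≥1) for n inputs — and a 4-unit softmax output. Dropout
follows every hidden layer. Training minimizes cross-entropy with Adam
(β₁=0.9, β₂=0.999); rows are split 80/20 into train/validation,
stratified by target class when every observed class has at least two
rows. Early stopping: training halts when validation loss has not
improved for `patience_epochs` consecutive epochs (the monitored
quantity is held-out, not training, loss — the held-out accuracy must
be honest for greedy selection to mean anything), and the best-loss
weights are restored. Batch regimes: full batch, mini-batch 8, or
stochastic (batch size 1).

Numerical choices that required a decision:

* **Initialization.** Glorot-uniform. With He initialization the
  variance gain of √2 per layer, compounded over 15 layers and
  perturbed by dropout noise, reliably drives the narrow ⌊n/2⌋ tail
  layers into permanent ReLU death; the smaller Glorot scale keeps them
  trainable at every width this package uses (n from 12 to 118).
* **Restarts.** A 15-deep plain ReLU stack of these widths sits near
  the edge of trainability: a minority of initializations either never
  leave the uniform-softmax plateau or converge with a collapsed class
  boundary. Training therefore collects `n_init_attempts` fits whose
  validation loss moved off its untrained value (up to two extra runs
  replace stuck ones) and keeps the best validation loss. A stuck run
  on a genuinely unpredictable item is observationally equivalent to a
  converged one, so the cap mostly bounds wasted work.
* **Learning rate.** Default 1e-3 (mini-batch/stochastic). A full-batch
  epoch is a single gradient step, so full-batch configurations in the
  tests use 1e-2 to reach convergence within a few hundred epochs.
* **Feature scaling.** The continuous index columns are standardized
  with statistics fit on the training split only; merged item columns
  enter as raw 0–3 scores (bounded already, and standardizing them
  would rescale imputation artifacts).
* **Ties.** Softmax ties predict the lower score; accuracy ties between
  candidate items select the earlier item in canonical order.
* **Degenerate items.** An item constant on its observed rows
  short-circuits to a constant predictor with held-out accuracy 1. An
  item with fewer than 8 observed rows is, by default, deferred and
  filled with its observed mode after all evaluable items (flagged in
  its record); a strict mode raises instead.

## Greedy loop

Iteration k trains one network per remaining item (from scratch — the
feature set changed) on the rows where that item is observed, selects
the highest held-out accuracy, imputes that item's missing cells, and
merges the completed column into the feature set, so networks at
iteration k have exactly 12 + (k − 1) inputs. Previously imputed values
do feed later networks; that merge is the core of the framework.
Observed cells are never modified. The finished order is cut into
⌊N/3⌋ / remainder / ⌊N/3⌋ tiers (35/37/35 at N=107). An option drops
ODD-flagged items before the loop for the sensitivity analysis, and
`compare_orders` reports the Spearman correlation of two orders
restricted to their shared items.

## Baselines

* **Mean imputation:** observed per-item mean, rounded to the nearest
  score (halves up), clipped to 0–3.
* **Interpolation:** the family name alone does not pin down a
  procedure; here it is linear interpolation over item position within
  each participant × scale, nearest-value extension at the ends,
  rounded as above, with per-item mean fallback for a fully missing
  scale. This positional reading is one defensible interpretation.
* **Multiple imputation:** chained equations — mean-impute to
  initialize, then 10 cycles refitting a linear regression of each item
  on all other columns and redrawing missing cells with Gaussian
  residual noise, rounded to 0–3; m independent chains give m tables.

## Effectiveness evaluation

The reference set is the complete-case subset of the original cohort;
the imputed set is the complement, read from the completed cohort. Both
are classified (all item columns plus the 12 indices) by an RBF-kernel
SVM, C = 1, gamma scaled, features standardized inside each training
fold, stratified 10-fold cross-validation. The two fold-accuracy
vectors are compared with a pooled-variance independent t-test — the
sets are disjoint participants, so an unpaired test is the right one.
Zero variance in both samples with equal means is defined as t=0, p=1.

## Synthetic cohort generator

The generator emulates the study regime, not any particular dataset.
Each participant draws one latent trait per symptom domain from a
unit-variance normal; CASE means are shifted by the domain effect size
(default 1.5 SD on every domain — large, as expected when the traits
are the diagnostic symptoms themselves). An item's latent response is
loading × trait + N(0, noise_sd²), discretized at fixed cutpoints
(default 0.5/1.5/2.5, putting controls mostly at scores 0–1, the skewed
endorsement pattern of community ratings). Item loadings draw once from
a configurable range, with per-item overrides for planting known
signals. The 12 indices are distinct positive mixtures of the traits at
correlation `ccpt_loading` plus independent noise. Block missingness
drops whole scales per participant; surviving cells drop at an MCAR
rate; an optional MAR mode scales CASE block probabilities. Cohort
generation and masking use separate seeded streams so one cohort can
receive many masks.

Default calibration: loadings U(0.15, 1.3) and ccpt_loading 0.45 put a
complete cohort's 10-fold SVM accuracy near 0.89 — the regime reported
for clinical ADHD cohorts of this size — rather than saturating at 1,
and spread item predictability from well above chance to chance,
which is what makes imputation-order recovery a meaningful test. The
2:1 case:control default mirrors clinic-enriched sampling.

What the generator does **not** emulate: informant disagreement beyond
separate loadings (parent and teacher items share the same domain
traits), item-specific wording effects, non-MCAR cell-level mechanisms,
and the real (uncharacterized) process deciding which families return
which scales. Passing tests therefore show the machinery is correct and
behaves as designed under a plausible generative regime; they are not
evidence about any specific clinical dataset.

## Test problem sizes

The suites run the full loop at reduced scale: order-recovery cohorts
of n=300 with 12 items (three planted signals of graded
signal-to-noise over a pure-noise background, symmetric cutpoints so
noise items sit near chance), effectiveness cohorts of n=400 with 20
items across two scales (block missingness 0.3 per scale, cell rate
0.05), 5–10 seeded replicates per experiment. A full 107-item run is
supported (the width invariant is exercised up to n=118) but is a
long-running configuration, flagged as such in the CLI.

## Known limitations

* Downstream classification is a weak lens on imputation quality under
  MCAR: with all observed variables available to the classifier, a
  completion cannot add information, so methods differing greatly in
  cell-level reconstruction accuracy (the network imputer recovers
  roughly half of masked cells exactly, mean imputation far fewer) can
  still tie downstream. The package reports both views.
* The deep stack at width 6 remains initialization-sensitive despite
  the restart logic; held-out accuracies of individual item networks
  carry sampling noise of a few points, which is why order-recovery
  claims are made over seeds, not single runs.
* `interpolate_impute` is one reading of an under-specified family
  name; alternatives (e.g. temporal interpolation) would need a
  different data model.
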