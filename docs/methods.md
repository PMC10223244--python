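# Methods

This note documents the statistical model implemented by `mtqsar`, the
choices made where the method leaves room, and what the synthetic benchmark
does and does not demonstrate.

## Data model

A compound is described by its affinity spectrum: minimum docking energies
ΔE (kCal/mol, negative; more negative = stronger predicted binding) over *k*
target binding sites, obtained by minimum-aggregation of repeated docking
runs (`aggregate_docking_energies`).  Activity is ordinal on five grades.
Quantitative assay values are graded per assay group by k-means with k = 5;
because the values are one-dimensional, we solve the k-means problem
*exactly* by dynamic programming (optimal within-cluster sum of squares)
rather than by random-restart heuristics.  This makes grading deterministic
and invariant to the initialization seed; restart-based k-means is used only
as a cross-check in the test suite (the exact partition can never have
larger SSQ).  Clusters are ranked by centroid; for potency-style measures
(ED50, IC50) the ranking direction is reversed via `higher_is_better=False`.

When one compound has several graded records, grades are encoded
high = 3, moderate = 2, low = 1, inactive = 0, averaged and rounded half-up.
Records that say only "active" carry no potency level: they are excluded
from the average but still force the compound into the active (`a`) class.
A compound with only such records keeps the grade "active".

## Ensemble and consensus

Per binary gradation (`h`, `hm`, `a`) and per cyclic 5:1:1 sampling variant
(seven of them, each shifted one row), a pool of `MLP k-m-2` perceptrons is
trained: softmax output, cross-entropy loss, hidden activation enumerated
over identity / logistic / tanh / exponential (exponential is e^x with the
pre-activation clamped to ±30 for stability).  Training is full-batch Adam
(default rate 0.02, ≤ 400 epochs) with early stopping on the variant's test
subset (patience 40) and weight restore to the best epoch.  Inputs are
standardized with mean/sd computed **from the training rows of the variant
only** — the test and validation rows never leak into the statistics.

Weight decay: an L2 penalty of α = 0.1 on the two weight matrices (not
biases).  This is deliberately strong for two reasons: n is small (hundreds
of rows) and the docking descriptors of jointly relevant sites are
correlated, so an unpenalized network tends to put all its credit on an
arbitrary subset of them.  Shrinkage spreads the fitted function over
correlated inputs, which stabilizes both generalization and the
variable-importance analysis below.  α is configurable.

Selection replaces the original protocol's manual step with a deterministic
two-stage criterion: (1) if the pool exceeds 600 candidates it is cut to the
top 600 by minimum subset accuracy; (2) the top 5 by
min(train, test, validation accuracy) are short-listed and the short-list
member with the highest general-set F₀ wins.  Ties break by fewer hidden
units, then lower seed, making selection permutation-invariant.

Prediction: each network votes by the argmax of its softmax pair; level-1
consensus is the ≥ 4-of-7 majority (always defined for seven binary votes);
level-2 maps the verdict triple to the final class and declares the four
non-nested triples `undefined`.  Undefined predictions are first-class
outputs: they are excluded from confusion counts and reported separately —
they are never coerced to a class.

The applicability domain uses the sample (n − 1) standard deviation:
per-site bands mean ± 3σ, global bounds the extrema of all band edges.  The
global mode (default) flags any component outside the pooled range; the
per-site mode checks each site against its own band.

## Sensitivity analysis

The sensitivity index of input *i* for a trained network is the
mean-substitution error ratio: the cross-entropy loss with column *i*
replaced by its training-subset mean, divided by the baseline loss.  The
substitution mean comes from the network's own training subset; the **loss
ratio is evaluated on the general (full) set**, consistent with every other
general-set estimate of the model.  Evaluating it on the training subset
instead is ill-conditioned — a well-fitted network has near-zero training
loss, the ratio becomes winner-take-all, and redundant informative inputs
are erased from the ranking.  Indices are normalized to percent of the
per-network sum (so one inert-input network scores ≈ 100/k everywhere); a
site is significant when its percentage strictly exceeds round(100/k)
(6 % at k = 17 — note 6.0 itself does not count), and consensus significant
when significant in at least 5 of the ensemble's 7 networks.

## Pharmacophore consensus

Point identity is (ligand fragment, interaction type); residues are evidence
annotations, not identity, because different targets bind the same fragment
through different residues.  A monotarget pharmacophore keeps points
supported by at least ⌈0.75 n⌉ of the n group compounds (3 of 4 by default).
The multitarget superposition is an annotated union by default — every
fragment retained by any monotarget pharmacophore appears, carrying the
per-target interaction types and residues — with `min_targets` available for
strict intersections.  Serialization is canonical JSON (sorted keys), so
re-serializing a loaded pharmacophore is byte-identical.

## Synthetic benchmark

`mtqsar.synthgen` emulates the study conditions: 216 compounds × 17 sites,
ΔE clipped to [−11.8, −0.5] kCal/mol, grade marginals 30/64/67/34/21
(high/moderate/low/active/inactive).  Four designated sites are informative:
their mean shifts linearly with the activity score (high = 3, moderate = 2,
low = active = 1, inactive = 0), scaled so the standardized mean separation
between the active class and the inactive class equals `effect_size`
(default 1.5); the remaining 13 sites are grade-independent noise.  Docking
pools are built so their minima equal a pre-drawn matrix; activity groups
have five clusters spaced ten within-cluster standard deviations apart;
interaction tables plant points at ≥ 3-of-4 support with ≤ 2-of-4
distractors.

What the generator does **not** emulate: real docking-score distributions
(heavy tails, site-specific scales), inter-site correlation beyond the
shared class signal, label noise in the activity grades, and structural
similarity between compounds.  Passing tests on this benchmark therefore
show that the pipeline recovers a known signal of the stated size under
clean conditions, not that it would achieve any particular accuracy on
experimental data.

### Parameter recovery

With four planted sites at effect size 1.5 and a desk-scale pool
(8 candidates per cell; tanh/logistic; 4 or 8 hidden units), the full
train → sensitivity → consensus pipeline recovers exactly the four planted
sites in about 9 of 10 generator seeds.  The occasional miss is a property
of the data, not the optimizer: in those realizations the weakest planted
site's realized high-vs-rest separation falls below ~1 sd and its normalized
sensitivity lands at 5.8–6.0 %, just under the strict 6 % threshold.  With
effect size 0 the consensus-significant set is empty in essentially every
seed — the 5-of-7 rule is a strong guard against false positives.

## Numerical conventions

* Display rounding is half-up to one decimal (2.55 → 2.6); internal values
  stay unrounded.  Summary rows of the accuracy report average the rounded
  per-row values, matching the convention of printed tables.
* ROC AUC is the rank statistic with ties averaged; for binary verdicts it
  reduces exactly to (F_a + F_n)/2.
* Zero-denominator metrics (e.g. F_a with no positives) are reported as
  undefined (`None`), never as 0.
* MCC is 0 by convention when a marginal is empty.
* A constant input column gets sd 1 during standardization (it carries no
  information either way).
* All randomness flows through `numpy.random.SeedSequence` children of one
  master seed; rebuilding a model with the same seed and configuration is
  bit-identical, and the model JSON round-trips losslessly.

## Problem sizes used in the shipped analyses

The test suite trains ensembles at n = 35–70 compounds with 2–8 candidates
per cell; the acceptance script uses the full 216 × 17 scale with
8 candidates per cell for the recovery study.  The original protocol's
6000-candidate pools per cell are reachable through `TrainConfig`
(`n_candidates`), whose enumeration is covered by tests without training at
that scale.

## Known limitations

* The two-stage selection criterion is a deterministic stand-in for a
  manual expert selection; it reproduces the *shape* of that protocol, not
  its judgment.
* The exponential hidden activation can saturate the clamp on far
  out-of-domain inputs; predictions there are still produced but the
  applicability-domain flag should be respected.
* The sensitivity index is a single-input substitution measure; it does not
  decompose interactions between sites (no Shapley-style attribution).
* Class imbalance in the `h` gradation (≈ 30 of 216 positives) caps the
  achievable sensitivity F_a at moderate effect sizes; the consensus is
  conservative there by design.
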