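# Methods

## The prediction problem

`protfun` treats protein function prediction as hierarchical
multi-label classification.  A protein's functional annotations —
Enzyme Commission (EC) numbers or Gene Ontology (GO) terms — live in a
rooted `is_a` hierarchy: EC numbers form a four-level tree
(EC:3.2.1.2 → EC:3.2.1.- → EC:3.2.-.- → EC:3.-.-.-), while GO terms
form a DAG in which a term can have many parents.  Databases record
only the most specific (leaf) labels, so all targets are
**ancestor-closed** at corpus-build time: a record annotated with a
leaf also carries every ancestor of that leaf.  Without closure a
model would be trained to call a sequence-specific DNA binder
"not DNA binding".  Closure happens before train/test splitting.

A protein may carry zero leaf labels (a non-enzyme), one, or several
(a multi-functional enzyme), so the model is trained with independent
per-label sigmoid outputs rather than a softmax.

## Network

The network maps a one-hot encoded sequence (alphabetical one-letter
amino-acid order) of any length L to per-residue features, then
collapses them:

1. an initial convolution (kernel `kernel_size`, dilation 1) lifts the
   20-dim one-hot input to `filters` channels;
2. `num_res_layers` pre-activation bottleneck residual blocks
   `x + P(ReLU(N(D(ReLU(N(x))))))`, where `D` is a dilated convolution
   to `filters x bottleneck_factor` channels, `P` a width-restoring
   kernel-1 convolution and `N` a per-position layer normalisation;
3. block k (1-indexed) uses dilation
   `dilation_rate ** (k - first_dilated_layer + 1)` for
   k ≥ `first_dilated_layer` and 1 before — with the full-scale
   defaults the schedule is 1, 3, 9, 27, 81, so receptive fields grow
   geometrically with depth;
4. mean pooling over (unmasked) positions produces a fixed-length
   embedding e regardless of L;
5. a single affine head maps e to one logit per vocabulary label;
   probabilities are element-wise sigmoids.

Full-scale defaults (5 residual layers, 1100 filters, kernel 9,
bottleneck 0.5) are shipped on `ModelConfig`; the desk-scale
experiments in this repository use 2 residual layers and 64 filters.

All convolutions are zero-padded "same", and padded batch positions
are re-zeroed after every layer, so a sequence produces identical
outputs (to float32 tolerance) whether it is run alone or padded
inside a batch of longer sequences.  This padding invariance is a
tested invariant, as is the receptive-field bound (residues beyond the
theoretical radius cannot influence a position's features).

The network, its backward pass, and the optimiser are implemented
directly on NumPy in float32.  Convolutions are expressed as K shifted
matrix products so the heavy lifting is BLAS; gradients are
hand-derived per layer and verified against finite differences during
development, with the training-facing invariants (loss decrease,
single-record overfit, determinism) covered by the test suite.

### Why the CAM identity is exact

Because pooling is a plain mean and the head is affine,

    logit_c = mean_i (W[:, c] · F_i) + b_c

holds exactly.  The per-residue term `W[:, c] · F_i` is the
class-activation map (CAM): a decomposition of the logit over
positions that needs no gradient computation and no approximation.
The test suite asserts this identity to 1e-4 relative tolerance on
randomly initialised models of several shapes; it is what makes the
interpretation module exact rather than heuristic.

## Training

Multi-label binary cross-entropy, averaged over the vocabulary (not
summed — so learning rates transfer across vocabulary sizes), with
Adam (β1 0.9, β2 0.999, ε 1e-8) and gradient clipping to global norm
1.  The learning-rate schedule is linear warmup to the peak rate
followed by exponential decay `peak · decay_rate^((step − warmup)/decay_steps)`
with a continuous exponent (a staircase variant is a config switch).
Batches are formed dynamically under a token budget: records are
shuffled, sorted by length, and packed so that
`max_length × batch_size ≤ token_budget`, which keeps padding waste
small for short sequences and trains long sequences in small batches.

Two recipes are shipped:

* `TrainConfig()` defaults: peak 1.5e-3, decay 0.997 per 1000 steps,
  warmup 3000 — the full-scale schedule, appropriate for
  half-million-step runs;
* `desk_scale_config()`: peak 1e-2, warmup 250, token budget 4000,
  5000 steps — for the small single-CPU models used here.  At a few
  thousand steps the full-scale schedule spends most of the run in
  warmup and, at its low peak rate, fails to move the convolution
  filters off their random initialisation (training loss stays at the
  label-prior entropy); a shorter warmup and a higher peak rate are
  the standard adaptation for short runs on small models.

Training is deterministic given the seed on a single device.
Non-finite loss aborts with a diagnostic rather than continuing.

## Evaluation

Predictions are scored micro-averaged over example-label pairs.  The
threshold sweep visits every distinct confidence value (up to 10^6
pairs, after which a 501-point grid on [0, 1] is used); at threshold t
a pair is predicted iff its score ≥ t.  Precision at thresholds where
nothing is predicted is defined as 1 (the usual PR-curve endpoint
convention).  The summary statistic is **Fmax**, the maximum
F1 = 2PR/(P+R) over the sweep, with ties broken toward the higher
threshold.  (F1 is occasionally misdescribed as the geometric mean of
precision and recall; the conventional harmonic mean is implemented.)
Confidence intervals are nonparametric percentile bootstraps over test
accessions (default 1000 replicates, seeded).

A label never scored for an accession is never predicted at any
threshold — this is how alignment-transfer predictors, which only
score labels inherited from a hit, enter the same machinery.

The **naive frequency control** assigns every test protein the same
score map: score(label) = training-set frequency of the label.  It
encodes prevalence and nothing else; the distance between it and a
model is the part of performance actually attributable to reading the
sequence.

## Alignment baseline and ensemble

The homology-transfer baseline annotates a query with *all* labels of
its single highest-scoring training sequence, each scored with the
hit's bit-score.  The built-in backend is Smith-Waterman (BLOSUM62,
affine gaps open 11 / extend 1, via Biopython's pairwise aligner) with
the Karlin-Altschul transform S' = (λS − ln K)/ln 2, λ = 0.267,
K = 0.041; an external `blastp` backend is available when the BLAST+
suite is installed, and the tests cross-check the two on top-hit
subjects.  Ties in score break toward the lexicographically smallest
subject accession.

The ensemble multiplies each transferred label's bit-score by the
CNN's predicted probability for that label (probability 0 if the CNN
does not score it).  By default only top-hit labels are admitted — the
literal reading of the procedure; `--union` optionally admits labels
the CNN predicts at ≥ 0.5 that the hit lacks.

## Interpretation

For multi-functional proteins the raw CAM columns are sharpened by
**cross-class normalisation**: at each residue, subtract the mean
score of the other predicted classes (with two classes this is the
pairwise difference, and the two normalised columns are exactly
antisymmetric).  Each class's coarse location is the **centre of
mass** of its normalised map with negative scores clipped to zero
(signed weights make a centre of mass ill-defined when the weight sum
nears zero; if no score is positive the raw scores shifted to
non-negative are used, and a constant vector is an error).  The
N-to-C order of the two centres is the predicted domain order.
Candidate sequences are restricted to those with exactly two most-specific
labels predicted at threshold 0.5; all others are rejected.

The pooled embedding doubles as a general-purpose representation; a
seeded random-forest probe trained on a small labelled subset of
embeddings measures how much extra functional structure they carry.

## The synthetic study

Real-scale benchmarks need a curated protein database and multi-GPU
training, so the package ships a generator in which ground truth is
known by construction:

* a complete label tree (default 4 levels, per-level branching
  (2, 3, 4): 24 leaves, 33 labels) with EC-style ids (`S:2.1.3`);
* one motif per leaf, i.i.d. uniform over the 20 letters, default
  length 40 — domain scale, matching the biological units whose order
  the CAM experiment predicts (protein domains are typically tens to
  hundreds of residues).  Short signature-style motifs (~10 aa) carry
  too little mean-pooled signal for a 5000-step desk-scale run and
  model the wrong biological object for the ordering experiment;
* records of uniform random background, lengths uniform in 100-600;
  20% non-enzymes (no motif, no labels), 10% bifunctionals, the rest
  monofunctional;
* bifunctional leaf pairs come from a fixed set of recurrent "domain
  architectures" (disjoint consecutive pairs of the sorted leaves)
  rather than uniformly from all pairs — real bifunctional enzymes
  concentrate heavily in a few recurring architectures, and this
  recurrence is what lets a homology-transfer baseline find same-pair
  neighbours for bifunctional queries.  The two motifs are planted at
  non-overlapping uniform positions with uniform N-to-C order, so
  chance ordering accuracy is 50%;
* motifs are planted with i.i.d. per-position substitutions (default
  rate 0.05, substituting to a uniformly chosen *different* residue so
  realised substitution counts are Binomial and testable);
* leaf labels follow the planted motifs and are ancestor-closed;
  spans are recorded 0-based half-open.

Everything is a deterministic function of the seed, and a motif table
can be reused across corpora so that held-out evaluation sets (for
example the all-bifunctional ordering set) live in the same motif
universe as the training corpus.

What the generator does **not** emulate: realistic amino-acid
composition or length distributions, indels, phylogenetic correlation
between records (every record is independent, so a random split is an
honest evaluation here in a way it is not for real proteins),
incomplete or noisy annotation, and label co-occurrence structure
beyond the planted hierarchy.  Passing the synthetic study shows the
pipeline is correct and that the architecture can learn
sequence-localised, hierarchy-consistent function from scratch; it
does not certify real-data accuracy.

## Desk-scale study sizes

The shipped experiments (test suite and `scripts/acceptance.py`) use:
n = 2000 records split 80/10/10 by salted accession hash; a
2-residual-layer, 64-filter network trained 5000 steps with
`desk_scale_config`; 300 dedicated bifunctional sequences for
ordering (scored on the candidate subset whose predicted pair matches
the planted pair — only sequences whose functions are correctly
identified can have their order scored);
100 monofunctional test sequences for CAM localisation; a
300-train / 60-query subset for the quadratic-cost alignment baseline
and ensemble; and 1000 bootstrap replicates.  These sizes were chosen
so the whole study runs end to end on a single CPU in minutes while
leaving clear margins on the behavioural thresholds it asserts.

## Known limitations

* Single-device training only; no data parallelism.
* The aligner computes scores, not E-values; database-size corrections
  are irrelevant to the ranking-based use here.
* Cross-class normalisation averages over the model's other *predicted*
  classes (threshold 0.5), the natural reading when more than two
  functions are present.
* `approximate_clusters` (single-linkage on edit-distance identity) is
  quadratic and intended only to fabricate cluster tables for small
  synthetic corpora; real UniRef-style tables are consumed, never
  computed.
* The clustered split balances whole clusters into three near-equal
  folds by greedy largest-first assignment; other balancings are
  admissible under the same invariant (no cluster straddles folds).
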