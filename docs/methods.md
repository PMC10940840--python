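# Methods

## Problem and model

`pairzyme` predicts whether an enzyme can catalyze the conversion of a
substrate A into a product C — enzyme promiscuity prediction posed as binary
classification of (substrate–product pair, enzyme) combinations.  The model
is a transformer encoder–decoder:

- the **encoder** self-attends over per-residue enzyme features (an L×100
  matrix from a CBOW embedding, projected to hidden width H);
- the **decoder** self-attends over the reaction-pair token features
  (a frozen reaction encoder's T×D output passed through a trainable adapter
  head), then **cross-attends** to the encoder output; the cross-attention
  weights, averaged over layers, heads and pair positions, are the
  per-residue importance read-out;
- decoder outputs are mean-pooled and a fully connected 2-way softmax yields
  the catalysis probability.

Two deliberate departures from the standard transformer: **no positional
encoding** anywhere (sequence order enters only through kernel-3
convolutions), and every position-wise feed-forward pair is replaced by
**two 1-D convolutions** (kernel 3, GELU between).  Residual-block weights
use **fixup initialization** — N(0, (σ_l/√n_l)²) with σ_l = √2 for a block's
first layer, √0.5 for its last, 1 otherwise — while layer normalization
(norm shape = H) is retained.  The attention-block weights treat Q/K/V
projections as the first fixup layer and the output projection as the last.

Default architecture: 12 encoder and 12 decoder blocks, 8 heads, H = 64,
dropout 0.1 (attention weights and feed-forward outputs, disabled at
inference).  `ModelConfig.small()` (2+2 blocks, 2 heads, H = 32) is the
desk-scale instance used throughout the test suite.

## Data pipeline

**Pair extraction.**  Atom-mapped reaction SMILES are parsed with RDKit;
map numbers link each heavy product atom to its source substrate.  A pair
(A, C) is kept iff strictly more than 50% of C's heavy atoms derive from A.
Conventions the rule's prose leaves open, fixed here: atom counts are
heavy-atom counts (hydrogens are implicit in SMILES and mappers map heavy
atoms); unmapped product atoms count in the denominator and never in a
numerator; the comparison is strict, so an exactly-50% pair is rejected;
agents (the middle reaction-SMILES field) are dropped with a warning.
Pairs whose substrate or product has a single heavy atom (e.g. H+) or
matches a cofactor list are removed.  The shipped cofactor list (canonical
SMILES, user-overridable) covers ATP, ADP, AMP, NAD(P)+/NAD(P)H, CoA,
acetyl-CoA, FAD, FADH2, phosphate, diphosphate, CO2, H2O, O2, H+ and NH3;
only ATP, ADP and H+ are forced by the procedure itself, the remainder is a
documented extension.

**Triads.**  Every surviving pair is combined with each enzyme annotated on
its source reaction (EC match) as a *positive*; enzymes longer than 1000
residues are excluded from the dataset altogether (positives and the
unlabeled pool alike).  For each reaction, 20 enzymes whose four-level EC
differs from all of the reaction's ECs are drawn uniformly without
replacement and attached to all of that reaction's pairs as *unlabeled*
(treated as negatives during training).  "Different EC" is resolved at the
full four-level resolution; a flag optionally excludes same-three-level ECs.
Deduplication keys on (canonical pair string, enzyme sequence, label); a
(pair, enzyme) present as both positive and unlabeled keeps only the
positive.  Test splits sample the configured number of positives and
unlabeled uniformly; the full-scale default is 5000 + 5000.

**Sequence identity.**  Reported with Biopython's global aligner (BLOSUM62,
gap open 10, extend 0.5), identity = matches / alignment length × 100.  The
exact tool behind published SI numbers is not specified closely enough to
clone, so those numbers are characterized, not matched.

## Training

Positive–unlabeled undersampling: each epoch draws as many unlabeled triads
as there are positives (uniform, without replacement, fresh per epoch) and
minimizes a label-smoothed binary cross-entropy with ε = 0.1.  The default
loss smooths the targets to y′ = y(1−ε) + ε/2.  The literal published
hybrid, −mean[(ε·y)·log p + (1−(1−ε)·y)·log(1−p)], is implemented behind
`loss_variant="as_printed"`: for y = 1 both of its terms carry ε, so the
positive-class loss is minimized near p = 0.5 rather than p = 1, and at
ε = 0 its log p term vanishes entirely — we read this as a typo and default
to the standard form, keeping the literal one for fidelity experiments.

Once the validation ROC-AUC exceeds 0.9, unlabeled pool members the model
scores above 0.8 are purged permanently (they are presumed hidden
positives); the purge is re-evaluated every epoch and the pool size is
monotone non-increasing.  The trigger AUC is computed on a fixed validation
slice carved from the training set before the first epoch: 5% of positives,
with a floor of 8 positives (capped at a third of them) and 3× as many
unlabeled — on desk-scale datasets a literal 5% slice is too coarse an AUC
to drive the trigger or checkpoint selection.  The best-validation-AUC
checkpoint is kept, with ties resolved toward the later epoch.

Optimization: rectified Adam with decoupled weight decay (plain Adam behind
a flag), global gradient-norm clipping at 1.0 (a stability addition), all
randomness seeded.  Full-scale defaults follow the published schedule
(64 epochs, batch 64, lr 5e-6, weight decay 1e-5).  `TrainConfig.small()`
(30 epochs, batch 8, lr 1e-2 with cosine decay to 5%) is the package's own
desk-scale schedule: the published learning rate is tied to a multi-GPU,
multi-day run and does not move a small model on a small corpus in 30
epochs, while a constant 1e-2 can destabilize late in training.  Besides
the best-validation checkpoint, a stochastic weight average over the final
third of epochs is evaluated as a second candidate; whichever scores the
higher validation AUC (ties to the average) becomes the returned model.

The tensor backend is numpy with reverse-mode differentiation via HIPS
`autograd`; parameters and activations are float32, which keeps the
differentiation tape compact.  Training is CPU-oriented and batches are
grouped by enzyme length (randomized tie-break, shuffled batch order) so the
L² attention cost tracks true lengths rather than the batch maximum.

## Feature extraction

**Enzyme embedding.**  A CBOW model over the 21-token alphabet (20 amino
acids + X catch-all): each 3-residue window predicts its center from the
C = 2 flanking residues, h = (1/C)·WᵀX, y = Uh, full softmax (V = 21 makes
negative sampling unnecessary).  N = 100 dimensions.  The per-residue
feature is the residue's input-embedding row, giving L×100 per enzyme; this
reading (rather than window-level hidden vectors) preserves the one-to-one
residue/attention correspondence that makes the importance map meaningful.
The phrase "every three amino acids" is implemented as the 3-residue window;
3-mer *tokens* would require a 21³ vocabulary and contradict V = 21.

**Pair embedding.**  A frozen reaction encoder maps "A>>C" to T×D token
features.  The shipped encoder is a seeded, randomly initialized
character-level embedding + 2-layer self-attention network with
standardized outputs — deterministic, download-free, and exposing the same
interface a pretrained reaction-fingerprint model would plug into (D = 256
for the published pretrained base; 64 for the built-in).  Its parameters are
never updated; tests pin this with a SHA-256 hash of the weights.  The
trainable adapter head is a residual block — conv(k=3) → GELU → conv(k=3),
added back to the input — followed by a position-wise linear map to H.  The
second convolution starts at zero and the linear map at (truncated)
identity, so the fresh head is exactly the identity when D = H.  The
intermediate activations of every two-convolution stack (adapter and block
feed-forwards) are re-masked because the stacked receptive field of 5 would
otherwise let padded positions relay information between valid neighbours
and break padding invariance.

## Screening

`screen` scores every library enzyme against one pair, ranks descending
(ties by enzyme id for determinism) and reports rank and relative rank
(rank / library size).  `multi_pair_screen` handles multi-step conversions:
an enzyme survives only if it clears the threshold for every pair, and
survivors are ordered by their minimum per-pair score — the conservative
aggregate that reproduces the intersection of per-pair shortlists.  The
positive-call threshold defaults to 0.5 and is configurable; no published
value pins it.

## Synthetic data

The generator emulates the *shape* of curated reaction-database inputs, not
their chemistry: templated, map-conserving reactions (alcohol oxidations
and ether condensations with globally unique chain lengths so no pair
occurs in two classes, plus an exactly-50/50 condensation and a
decarboxylation that the filters must remove), one four-level EC per class,
and enzyme pools where each class's enzymes carry a planted 6-residue motif
at a random position.  Decoys are motif-free with ECs disjoint from every
class; two motif-free sequences of exactly 1000 and 1001 residues exercise
the length cap.  Default scale: 3 classes × 4 reactions × 20 enzymes, 6
enzymes attached per reaction (curated reactions typically list a handful
of annotated enzymes, not a family), 400 decoys, sequence lengths 80–200.
The motif is sequence-detectable by construction, so attention maps have a
ground-truth region and a pair-conditioned bag-of-3-mer logistic baseline
separates the labels almost perfectly — the baseline validates the fixture,
not the transformer.

What the fixture does *not* emulate: real substrate chemistry and its
correlation with sequence families, homology structure within a class
(class enzymes share only the motif), annotation noise, and realistic EC
imbalance.  Passing the learnability bar therefore shows the architecture
and PU loop can extract a planted pair-conditioned sequence signal at small
scale; it does not certify performance on curated reaction databases.
About 9% of unlabeled draws carry another class's motif, so a
sequence-only discriminator plateaus near 0.92 held-out ROC-AUC; scores
above that require using the pair stream.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [1e-7, 1−1e-7] inside the loss.
- Fully masked attention rows yield zero weights and zero output, with a
  warning (rather than NaN from an empty softmax).
- Scores are exactly padding-invariant by construction (masked softmax,
  re-masked conv intermediates, masked mean-pool); tests assert agreement
  to 1e-5 between solo and batched scoring in float32.
- Ranking ties break lexicographically on enzyme id.
- Divergent (non-finite) training loss aborts with a diagnostic rather than
  continuing silently.
- The purge threshold applies to raw softmax outputs (no calibration step).

## Desk-scale problem sizes

The validation suite and the reproduction script run everything end to end
at reduced scale, the package's own choice of study size: the planted-signal
dataset above (~70 positive and ~240 unlabeled triads after splitting), the
small model, 30 training epochs, and a held-out slice of 12 positives + 48
unlabeled.  The published headline numbers (test ROC-AUC 0.993 on 5000+5000
triads from ~20M mined examples, the 14-day multi-GPU schedule, proteome
screens) require multi-database downloads and pretrained weights and are
out of scope; the package reproduces the *procedure* and its desk-checkable
constants, not those endpoints.

## Known limitations

- The numpy/autograd backend is single-process and CPU-bound; it is sized
  for method validation and small screens, not for the full-scale corpus.
- The built-in reaction encoder is untrained; it provides deterministic,
  structure-sensitive features, and the interface accepts a pretrained
  drop-in, but absolute scores with the built-in encoder are not chemically
  meaningful beyond the trained task.
- Checkpoint selection and the purge trigger share one validation slice; on
  very small datasets the slice is necessarily a noticeable fraction of the
  positives.
- EC-mismatch negatives are presumed, not verified — the PU machinery
  (smoothing + purging) mitigates but cannot eliminate hidden positives.
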