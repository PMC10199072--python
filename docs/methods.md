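# Methods

## Overview

`npforge` implements a generate–curate–characterize workflow for
natural-product-like molecular libraries.  A token-level LSTM language model
is trained on SMILES strings of known natural-product-like molecules, new
SMILES are sampled from it, the raw samples are curated (syntactic validity,
deduplication, standardization, parent extraction, structure-quality
checking), and the curated library is characterized against the training
distribution (natural-product-likeness scores, molecular descriptor panels,
KL divergence, held-out recovery, 2-D chemical-space embedding).

## Corpus preparation

Input corpora are filtered to syntactically valid SMILES; a string is valid
only if parsing, canonical-SMILES writing, InChI writing and InChIKey
writing all succeed.  Stereochemistry is removed before modelling: it
roughly halves the token inventory the model must order correctly, and a
stereo-free library can be expanded to stereoisomers downstream when needed.
Duplicates are removed by canonical form, keeping first occurrences.

The filtered corpus is split into training (72%), validation (8%) and
held-out (20%) partitions.  The held-out and validation counts are computed
as `round(0.20·N)` and `round(0.08·N)` with training taking the remainder;
this exact rounding rule was chosen because it is the unique simple rule
reproducing all three partition sizes of the 406,919-molecule corpus the
full-scale model was built from (292,981 / 32,554 / 81,384).

Training and validation molecules can be augmented: each molecule is
replaced by `factor` randomized SMILES writings obtained by renumbering the
molecule's atoms with a seeded random permutation and writing non-canonical
SMILES from that ordering.  The canonical writing is not force-included;
duplicates among the `factor` writings are permitted (small symmetric
molecules admit few distinct writings).  Augmentation happens strictly
after splitting, so no molecular graph leaks across partitions.  The
held-out partition is never augmented.

## Tokenization

SMILES are split into: bracket atoms `[...]` (one token), the two-letter
halogens `Cl`/`Br`, two-digit ring closures `%NN`, and single characters
otherwise.  This is the minimal class set that round-trips every SMILES the
toolkit writes; token concatenation reproduces the input exactly.  The
vocabulary is the sorted set of observed tokens preceded by three reserved
specials (START, END, PAD at indices 0, 1, 2).  Strings containing tokens
unseen at vocabulary-build time are excluded from loss computations and
logged.

## Language model

The model is a stacked LSTM over learned token embeddings with a softmax
output head, trained by teacher forcing on next-token prediction.  It is
implemented directly in NumPy: explicit forward and backward-through-time
passes, verified against finite-difference gradients, with Adam as the
optimizer.  Input projections for a whole sequence are computed as single
matrix products per layer; only the recurrent term is stepwise.

Defaults mirror the full-scale configuration: 3 layers, hidden size 512, no
dropout, batch size 128, learning rate 0.001, Adam, up to 1,000 epochs with
early stopping after 10,000 minibatches without validation improvement.
Parameters the full-scale description leaves open are config-exposed with
these defaults: embedding size 128, validation evaluation every 500
minibatches, sampling cap 250 tokens.  Sequences in a batch are padded to
the batch maximum and PAD positions are masked out of the loss; because
padded outputs carry zero loss, gradients through post-END states vanish
without special casing.  Losses are mean per-token cross-entropies in nats.
Minibatches are drawn with pooled length bucketing (shuffle, sort within
pools of 16 batches, cut, reshuffle batch order) to limit padding waste
while retaining stochasticity.  Initialization is uniform with 1/√fan-in
scaling, forget-gate biases at 1, and a 1/√H output head — small enough
that an untrained model's predictive distribution is near-uniform (loss
≈ ln V), large enough that useful gradient reaches the recurrent layers
from the first updates.

Sampling is autoregressive from START: multinomial draws over the
temperature-scaled next-token distribution until END or the length cap.
Temperature defaults to 1.0.  All randomness (init, shuffling, sampling) is
funneled through seeded generators; runs are exactly reproducible.

## Curation cascade

Raw sampled strings pass through, in order: the four-stage syntactic
validity test; stereochemistry stripping; dual-key deduplication (a record
is a duplicate if its canonical SMILES **or** its InChI matches an earlier
kept record; InChIKey-only collisions are logged, not removed);
standardization (functional-group normalization, neutralization by
(de)protonation where a complementary site allows, explicit-H cleanup);
parent extraction (fragments on a packaged salt/solvent list are dropped,
the largest remaining fragment is kept, isotope labels are cleared and
labelled atoms returned to standard valence form); and a structure-quality
checker.

The checker evaluates a fixed, transparent rule table with integer
penalties that grow with severity; a record whose maximum penalty exceeds 5
is removed, so removal is triggered exactly by rules of penalty ≥ 6:

| rule | penalty |
|---|---|
| undefined_stereo (unassigned stereocentre) | 2 |
| needs_neutralization (removable charge) | 2 |
| isotope_present | 2 |
| salt_or_multifragment | 2 |
| roundtrip_mismatch (canonical SMILES re-parse differs) | 5 |
| valence_error (radical / unfilled valence) | 6 |
| polymer_or_unsupported (dummy atom) | 7 |

The penalty-6 class is detected via radical electrons because the SMILES
parser already rejects textbook over-valence at the syntactic stage;
unfilled valence is the severe structural defect that survives parsing and
InChI generation.  Molecules whose fragments are all on the drop list
("no parent") are counted among the checker removals so the conservation
identity `n_output = n_input − invalid − duplicates − checker_removed`
holds on every run.  The cascade is idempotent on its own output.

## Natural-product-likeness score

Each heavy atom contributes its circular (Morgan) environment of radius 2
as an atom-centred fragment; the fragment multiset is invariant under atom
renumbering, so scores do not depend on how a SMILES was written.  A score
table is trained from a natural-product corpus and a reference corpus:

    contribution(f) = log10( ((n_f^NP + 1)/(N_NP + 1)) / ((n_f^ref + 1)/(N_ref + 1)) )

where `n_f` counts molecules containing `f` (Laplace smoothing keeps every
contribution finite; swapping the corpora negates every contribution).  A
molecule's raw score is the mean contribution over its heavy atoms, with
unseen fragments contributing 0; raw values beyond ±4 are compressed as
`±(4 + log10(|raw| − 4 + 1))`, keeping scores in roughly [−5, 5].  Absolute
values are table-dependent: only distribution shapes are comparable across
differently trained tables.

## Library characterization

Descriptor panels follow the standard toolkit definitions: a 10-descriptor
panel (aromatic/aliphatic ring counts, Wildman–Crippen logP, molecular
weight, H-bond donors/acceptors, heteroatom count, TPSA, rotatable bonds,
valence electrons) used for distribution comparison and embedding, and a
27-descriptor annotation panel carried on records.

Distributions are compared with D(P‖Q) = Σ P(x) ln(P(x)/Q(x)) in nats,
P being the reference (training) set and Q the candidate, summed over P's
support.  Continuous properties are binned at width 0.1 anchored at 0;
categorical properties (e.g. biosynthetic pathway labels) use the union of
observed labels with "none" as a first-class category.  When Q assigns zero
probability inside P's support — common at desk-scale sample sizes — one
pseudo-count is added to every Q bin in P's support and Q is renormalized;
with no empty in-support bins the plain summation is returned unchanged.

Held-out recovery is |generated ∩ heldout| / |heldout| over canonical,
stereo-free forms.  Chemical-space maps use t-SNE (2 components, PCA
initialization, random_state 7) on the z-scored 10-descriptor matrix;
constant columns are dropped with a warning.  Whether to standardize before
embedding was an open choice; z-scoring was adopted because the panel mixes
units spanning three orders of magnitude (valence electrons vs. ring
counts).  Density maps count points on a 50×50 grid over the embedding's
bounding box.

## Synthetic fixtures

The fixture generator assembles molecules by bonding 2–4 building blocks
drawn from curated pools — a natural-product-flavoured pool (sugar rings,
phenols, lactones, polyketide chains, terpene fragments) and a druglike
pool (aryl amides, sulfonamides, heteroaryls, fluorinated aromatics) — with
seeded random single bonds at free-valence positions.  Every uncorrupted
fixture is therefore chemically valid by construction, stereo-free, and
typically 15–50 heavy atoms.  Corruption operators plant exactly one
defect each: unparseable strings (deleted ring digit or parenthesis),
duplicate rewrites (a different writing of a clean molecule already in the
corpus), appended counter-ions, isotope labels, (de)protonated sites,
stereo marks, and radicals.  The manifest records every planted corruption,
giving curation tests exact expected counts.

What the fixtures do **not** emulate: biosynthetic plausibility, the scale
and diversity of a real natural-product collection (hundreds of thousands
of molecules from dozens of structural classes), tautomer-rich chemistry,
and rare-element vocabulary.  Passing tests therefore demonstrate that the
pipeline's accounting, invariants and learning dynamics are correct at desk
scale — not that the full-scale library statistics are reproduced.

## Desk-scale study configuration

The full-scale study (≈400k training molecules, 3×512 LSTM, 100M samples,
GPU-days of compute) is emulated by a single pinned desk-scale
configuration (`npforge.deskscale`): 2,000 fixture molecules split
72/8/20, a 2-layer 64-unit LSTM with 64-dimensional embeddings trained on
their canonical SMILES (batch 128, learning rate 0.001, validation
evaluated every 250 minibatches, early stopping after 1,500 minibatches
without improvement, epoch cap 700), and 5,000 sampled strings at
temperature 1.0.  Two layers rather than three were chosen after the
three-layer variant at the same hidden size showed no better sampled
validity for half again the runtime.  Canonical-form training is used at
this scale; randomized-writing augmentation, whose contract is tested
separately, slows desk-scale convergence without improving the quality of
what a 64-unit model can learn in minutes of CPU time.

## Known limitations

- Sampled-SMILES validity at the desk scale plateaus well below the ≈89%
  the full-scale model attains: a 64-unit model trained for minutes on two
  thousand polycyclic molecules does not master long-range ring-closure
  bookkeeping.  The test suite documents the measured rate.
- The checker rule table is a transparent approximation of a full
  registration-pipeline rule catalogue; tautomer canonicalization is not
  performed.
- NP scores from desk-trained tables are not numerically comparable to
  scores from externally trained tables.
- t-SNE coordinates depend on the library version and are only
  seed-reproducible, not portable across environments.
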