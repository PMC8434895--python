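# Methods

## Problem setting

A terminology-integration system ("metathesaurus") collects terms from many
source vocabularies and clusters synonymous occurrences — *atoms* — into
concepts. The input available to the clustering process is the tuple
*(str, src, scui, sg)*: the term string, its source, the optional concept
identifier that source assigns (SCUI), and a semantic group inherited from
the source (or from a top-level subdivision of a heterogeneous source).
The ground truth is the concept identifier (CUI) assigned by human
editors; it is never an input to prediction.

`metasyn` implements two predictors of atom synonymy over this input — a
rule-based approximation (RBA) of the editorial process, and a supervised
Siamese recurrent network — together with the identifier model, the
similarity machinery, the pair-dataset generator the network is trained
on, and a synthetic corpus generator that provides license-free ground
truth.

## Identifier model and normalizers

Atoms carry three minted identifiers: AUI (unique per occurrence), SUI
(shared iff strings are character-identical) and LUI (shared iff the
*normalized* strings are identical). Identifier literals are surrogates;
only the equality structure matters.

Two normalizers are deliberately distinct:

* **Lexical-variant normalization** (behind LUIs and the Jaccard index):
  lowercase, strip punctuation except hyphen, singularize each token by
  rule, sort tokens. The singularizer is a small rule set (`-ies` → `-y`;
  a sibilant-stem exception list dropping `-es`; otherwise a final `-s`
  is dropped unless the token ends in `-ss`/`-us`/`-is`). The full
  normalizer is deterministic, idempotent and insensitive to case,
  punctuation, simple plural inflection and word order. It approximates
  the behavior of a full lexical-variant toolchain well enough to
  reproduce the intended lexical classes, and it is a pluggable seam: a
  heavier normalizer can be substituted without touching the rule
  engine. Terms that normalize to the empty string (punctuation-only)
  get no LUI and are excluded from the word index, avoiding a degenerate
  all-match class.
* **Embedding tokenization** (input to the network): lowercase, strip
  punctuation except hyphen, split on whitespace. Order-preserving, no
  singularization — the recurrent encoder is meant to see inflection and
  word order.

## Rule-based approximation

Two pairwise rules formalize the editorial principles:

* **SS** — source synonymy: both atoms carry the same SCUI *from the same
  source*. Scoping equality to the source prevents accidental identifier
  collisions across vocabularies from firing the rule.
* **LS_SC** — lexical similarity and semantic compatibility: equal LUIs
  and intersecting semantic-group sets. The group intersection blocks
  homonyms ("nail" as anatomy vs. device).

`SS_LS_SC` is their disjunction, and `SS_LS_SC_TRANS` its transitive
closure. The closure is computed as connected components of the rule
graph with union-find over rule edges: SS edges come from grouping atoms
by (source, SCUI); LS_SC edges from grouping by (LUI, group). Bucketing
by each single shared group is exact under closure, because a chain of
bucket-mates is itself a valid rule chain. The closure is always taken
over the full atom universe supplied, so chains may pass through atoms
that are not in the evaluated pair set. A brute-force oracle
(Floyd–Warshall over the pairwise rule matrix, and an independent
networkx-components route in `synthgen.expected_rba_metrics`) checks the
engine in the tests.

## Lexical similarity and candidate generation

Pair similarity is the Jaccard index of normalized word *sets*
(duplicates collapse). Scores are exact `Fraction`s so that ordering and
tie-breaking are well defined: top-N selection sorts by score descending
with ties broken by candidate AUI ascending, making dataset generation
reproducible. An inverted word index maps tokens to atoms; an atom's
candidates are exactly the atoms sharing at least one token, which is
complete because all other pairs score zero.

## Pair-dataset generation

Positives are all ordered same-concept pairs: an atom in a concept of
size *n* contributes *k = n − 1* pairs. Negatives are drawn per atom in
three mutually exclusive lexical-similarity regimes — `TOPN_SIM` (the 2k
top-scoring candidates, deterministic), `RAN_SIM` (2k uniform draws from
the remaining similar candidates), `RAN_NOSIM` (2k uniform draws from
token-disjoint atoms, by seeded rejection sampling with a complement
fallback) — and `ALL` is their union (≤ 6k per atom). A singleton-concept
atom (k = 0) gets one `TOPN_SIM` and one `RAN_SIM` pair when any similar
candidate exists. Twice as many negatives as needed for training are
drawn so each regime splits evenly between the learning and
generalization sides; positives split 80:20 by *unordered* pair (mirrors
stay together), and the learning side splits 75:25 into training and
validation.

Design choices where the design was genuinely open:

* Pairs are ordered, matching the per-atom quota formulas; an optional
  `dedupe_unordered` switch collapses mirrors (default off).
* Learning/generalization disjointness is enforced as *unordered* pair
  sets: a registry pins the mirror of an already-placed negative to the
  same side. Without it, independent per-atom sampling can leak a pair
  across sides as its mirror.
* Regime exclusivity is enforced before the union into `ALL`; `RAN_SIM`
  samples from the similar candidates minus the (deterministic)
  `TOPN_SIM` picks, so the top-N membership never depends on the seed.
* The split is by pair, not by concept; atoms recur across sides. This
  is intentional: generalization here means unseen *pairs*, not unseen
  terms, and it is part of what makes hard-negative exposure effective.

## Siamese network

Twin LSTM encoders (50 hidden units, shared weights) read the two token
sequences, each padded or truncated to 30 positions; the pair score is
`exp(−‖h_A − h_B‖₁)` of the final hidden states, in (0, 1]. Training
minimizes mean squared error between score and 0/1 label — the loss
conventionally paired with this architecture — using Adam (default
learning rate 1e-3, batch size 256 at desk scale). Embeddings are either
loaded from a word2vec text file or randomly initialized and trained
(default dimension 200, matching common biomedical pre-trained vectors);
the padding embedding is fixed at zero and masked timesteps leave the
recurrent state unchanged. The implementation is plain numpy with
hand-written backpropagation through time, which keeps runs exactly
reproducible from the seed (a fixed seed reproduces the epoch-1 loss to
the bit). A bidirectional switch exists (two directions, concatenated
final states) but defaults off, matching the unidirectional architecture
description; the hidden state fed to the similarity is the final state,
per the cited Manhattan-similarity design, and both choices are recorded
as substitutable. Optional early stopping monitors validation loss and
restores the best weights.

Numerical notes: the sigmoid is computed in a stable split form; the
sign of a zero coordinate difference contributes no gradient; training
metrics per epoch are the conventional running estimates from pre-update
batch predictions.

## Evaluation

Predictions are thresholded inclusively (score ≥ t), so binary rule
outputs are evaluable at 0.5 without special-casing. Zero-denominator
ratios are reported as 0 with an explicit flag. `best_f1` sweeps a
0.00–1.00 grid at step 0.01, ties resolving to the lowest threshold;
accuracy is reported both at the best-F1 threshold and at 0.5, since a
best-F1 sweep need not optimize accuracy. The prediction-difference
breakdown stratifies disagreeing pairs by (label, model prediction, rule
prediction, SIM/NOSIM flag) — at most eight strata.

## Synthetic corpus

The generator emulates the structure the method assumes, with knobs for
each feature (all defaults chosen once as the package's study
conditions):

* 500 concepts over six sources in three semantic groups (two sources
  per group), ~4 atoms per concept (shifted Poisson), giving a corpus of
  about 2,000 atoms — small enough for exact all-pairs oracles in
  seconds.
* Base terms are 3–5 tokens (modifiers + a group-specific head) from a
  packaged synthetic lexicon with a one-to-one synonym map whose keys
  and values are globally disjoint.
* Within-concept variants apply seeded operators: pluralization, token
  reorder, case change, qualifier insertion ("(disorders)"-style),
  whole-term synonym substitution, and a *loose-variant* modifier swap.
  The swap models source entry terms that are synonymous without being
  lexical variants; it is what makes single-token substitution an
  ambiguous signal rather than a reliable negative marker.
* A `sibling_rate` of 0.5 derives concepts from an earlier concept's
  base term by swapping exactly one token, populating the high end of
  the negative similarity range ("lung disease" vs "head disease"
  siblings). Cross-concept uniqueness is enforced on synonym-class
  roots, so no string can appear in two concepts of the same group.
* Homonym injection (rate 0.05) copies a base string into a concept of a
  *different* group, each donor at most once — the "nail" pattern that
  only the semantic-group filter can block.
* SCUI clusters per (concept, source) with coverage 0.9 (else the SCUI
  is absent) and a 0.02 cross-concept disagreement rate, making source
  synonymy strong but fallible, as in real integration.

Per-atom provenance (base term, operators) and per-positive-pair tags
(`ss_derivable`, `lssc_derivable`, `lexically_similar`) are recorded by
running the rule and similarity engines at generation time, so tag
soundness is by construction and the corpus doubles as an analytic
oracle for the rule variants.

What the generator does *not* emulate: realistic term-length and
frequency distributions, misspellings and morphology beyond simple
plurals, multi-group atoms (supported by the model, not emitted by
default), and non-English text. Passing tests therefore demonstrate that
the machinery is correct and that the qualitative regimes behave as
described — not that the measured scores transfer to a real
metathesaurus.

## Desk-scale problem sizes

All shipped experiments run on one CPU. Unit tests use a 50-concept
corpus; the end-to-end checks use the 500-concept default. Network
checks train with embedding dimension 50, batch 256, an epoch budget of
60 with early stopping (patience 5), three seeds for the
learning-sanity check and one seed per variant for the ordering
comparison. On the 500-concept corpus this reproduces the qualitative
findings: the transitive-closure rule variant has the best rule recall
and F1 but the lowest precision; a model trained on the `ALL` variant
reaches validation F1 ≈ 0.92 and generalization best-F1 ≈ 0.89,
outperforming the best rule variant (≈ 0.80); and models trained without
lexically similar negatives collapse in precision on the full
generalization set (best-F1 ≈ 0.54), recovering the ordering
ALL ≥ TOPN_SIM > RAN_NOSIM.

## Known limitations

* The lexical-variant normalizer is a rule approximation; derivational
  variants ("arthritic"/"arthritis") are not folded.
* The loss and the final-state choice for the similarity are
  conventional defaults for this architecture, not identified
  requirements; both are isolated behind the model class.
* Rejection sampling for token-disjoint negatives falls back to
  materializing the complement on dense corpora; at much larger scales a
  streaming design would be needed.
* The all-pairs rule oracle is limited to corpora of a few thousand
  atoms by its dense matrices; beyond that, evaluate sampled pair lists.
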