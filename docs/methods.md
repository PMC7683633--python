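# Methods

`eventbtm` learns research topics from full-text neuroimaging literature by
treating *events* — not isolated words — as the unit of topic modelling.
The pipeline has three stages: (1) recognise event elements (triggers and
typed argument spans) in sentences with a BiLSTM-CNN tagger, (2) classify
each trigger–argument pair's role with a softmax over lexical and
sentence-level convolutional features and assemble validated event
mentions, and (3) fit a biterm topic model over the discretised events by
collapsed Gibbs sampling and score the topics by document-co-occurrence
coherence and mean pairwise KL divergence.

## Event schema

Neuroimaging research is described by three topic events (cognitive
response, experiment, analysis) refined into ten meta-events.  Nine
trigger categories signal nine of the meta-events; *co-occur* has no
trigger category and is therefore not extracted from text.  Nine argument
categories (gross brain anatomy GRO, cognitive function COG, subject SUB,
medical problem MDI, sensory stimuli/response SEN, experimental task TSK,
experimental measurement MEA, analytical tool/method TOL, brain network
RLT) type the argument spans; each category has a term dictionary whose
1-based index doubles as the tagger's terminology feature.

Only the deduce-result entry of the event-role table is fully prescribed
by the event definitions (an optional "research object" over
{TSK, COG, MDI} and an optional "biological mechanism" over the
physiological-feature categories, which resolve to GRO/RLT in this
taxonomy).  The remaining meta-events ship with one agent/object-style
role pair each, chosen to match the categories their definitions mention;
co-occur and include relate two members of the same span category
("member 1"/"member 2" style).  The table is serialised as editable YAML
and every role carries a globally unique index so the role-classifier's
scalar feature `r` is total.  Cardinalities default to `0..1`; `0..n` is
supported for future schema edits.

An event's distributed representation is the elementwise product of the
trigger vector and all argument vectors in the word-embedding space;
multi-token spans use the mean of their token vectors so the dimension is
fixed.  These vectors are used for reporting and similarity only — topic
inference operates on discretised event keys (below).

## Event recognition

Each token is the concatenation of four parts, in order: a word embedding
(dimension 100 by default; a pretrained text-format table may be supplied,
otherwise a seeded uniform table on [−0.5, 0.5] is used, with a shared
trainable unknown row), a one-hot case vector, the terminology-dictionary
scalar, and a character-CNN feature (25-dimensional character embeddings
initialised uniformly on [−0.5, 0.5], width-3 convolution, max pooling to
30 outputs).  The case classifier is total and single-valued: first match
among numeric, allLower, allUpper, initialUpper, mainly_numeric (more than
half digits), contains_digit, other.  Seven categories are implemented —
the full listed inventory — giving a 138-dimensional combined vector at
the defaults (100 + 7 + 1 + 30).

A bidirectional LSTM (200 hidden units per direction, so h_i has 400
dimensions) reads the combined vectors; a linear projection with
log-softmax scores each token over the joint 37-tag BIO inventory (B/I per
trigger and argument category, plus O).  Triggers, trigger types and
arguments are recognised by this single joint tagger; the tag inventory
can be subset to train separate trigger-only/argument-only models.
Decoding is per-token argmax with I→B repair of illegal transitions —
there is no CRF layer, matching the per-token log-softmax design.
Training minimises mean per-token negative log-likelihood for 50 epochs
(default) with Adam (learning rate 1e−3) and global-norm gradient clipping
at 5.0, shuffling sentence order with a seeded generator: the same data
and seed give bit-identical parameters.  All networks are implemented in
numpy with handwritten backpropagation; layers are float64 throughout, so
checkpoints reload exactly.

## Role extraction

Candidate pairs are every (trigger, argument) combination within a
sentence; events never cross sentences.  The lexical feature vector
concatenates six word vectors — trigger, argument, and the tokens
immediately before/after each — plus the candidate role index, for
6·d_w + 1 = 601 dimensions at the defaults.  A neighbour slot is the
all-zero NULL vector when it falls outside the sentence or inside the
paired span, which reproduces the documented adjacency behaviour exactly.
The sentence-level feature concatenates, per token, its word vector and
two trainable 5-dimensional distance embeddings (signed token offsets to
the trigger's and the argument's first token, clipped to ±30), applies a
width-3 convolution with max-over-time pooling (30 filters), then a tanh
hidden transform — two matrices, as the feature definition writes them.

The classifier is a softmax over the global role inventory plus a "none"
class at index 0, added so non-argument pairs can be rejected.  Because
the features are conditioned on the candidate role index, inference
evaluates the classifier once per candidate role of the trigger's
meta-event (plus none) and renormalises the per-role scores.  Training
uses cross-entropy: a gold pair contributes a positive example under its
gold role and none-target examples under each wrong candidate role;
unrelated pairs contribute none-target examples throughout.  Assembly
attaches arguments best-probability first, drops any whose category the
role table does not admit or whose role is already filled, and the result
always validates against the table.

## Event-BTM

Events are discretised by a canonical key: meta-event type, stemmed
trigger, and the sorted stemmed argument phrases, joined by a reserved
separator (granularity configurable: type, type+trigger, or full).  This
is the largest interpretive decision in the package: the topic model needs
a discrete vocabulary, and the canonical key preserves exactly the
information the extraction stage produced while collapsing repeated
mentions.  Stemming uses a handwritten classic Porter stemmer (no stemmer
ships with the installed scientific stack).

Each document contributes all unordered pairs of its event tokens
(*biterms*) to a corpus-level pool B; a sliding window over w consecutive
events is available for very long documents.  Documents with fewer than
two events contribute nothing, with a warning; a corpus-wide empty pool is
an error.  The generative model draws one topic distribution
θ ~ Dir(α) for the whole pool, per-topic event distributions
φ_k ~ Dir(β), and for each biterm a topic z ~ Multi(θ) and two events
i.i.d. from φ_z, so P(b) = Σ_z θ_z φ_i|z φ_j|z.

Fitting integrates θ and φ out and Gibbs-samples each biterm's topic from
the exact collapsed conditional, including the +1 correction in the second
event factor when a biterm pairs an event key with itself.  Defaults:
α = 50/K, β = 0.01, 1000 iterations with 500 burn-in (standard biterm
practice; K = 2 is the pipeline default).  Point estimates come from
post-burn-in averaged counts: θ_k = (n_k + α)/(|B| + Kα) and
φ_e|k = (n_e|k + β)/(n_·|k + W_e β).  Biterms are pooled corpus-wide for
sampling but kept per document for inference:
P(z|d) = Σ_b p(z|b) p(b|d) with p(b|d) the document's empirical biterm
frequencies.  Sampler correctness is tested against brute-force
enumeration of all K^|B| assignments on tiny instances, comparing both
topic marginals and pairwise co-assignment probabilities (the latter are
invariant to label switching, which the tests otherwise handle by
alignment, never by assumption).

## Evaluation

Topic coherence scores a ranked unit list by Σ over ranked pairs of
log((D(v_i, v_j) + ε)/D(v_j)) with ε = 1 by default, where D counts
documents (not occurrences) containing the unit(s).  Event topics are
expanded into their constituent lexical terms before scoring (the
meta-event type label is schema vocabulary, not corpus text, and is
excluded), with 2 topic words per topic by default.  Unit lookup matches
a document if it contains the word's stem, or the word itself when the
word is already a stem — Porter stemming is not idempotent, so restemming
a stemmed unit would miss.

Mean pairwise KL averages KL(p‖q) = Σ p(x) log(p(x)/q(x)) (natural log)
over all ordered pairs of distinct topic–event distributions.  q receives
additive smoothing of 1e−12 and renormalisation so the divergence is
finite; the implementation enforces KL ≥ 0, which the definition
guarantees — a negative mean KL cannot arise from this formula, so
reported negative baseline values elsewhere are not reproducible by it.

## Synthetic corpus

The generator plants K_true topics (default 2) that own disjoint
inventories of *event species* — fixed lexical realisations of the nine
extractable meta-events, built from the taxonomy's printed example terms
(five per argument category, three trigger terms per category, lexicons
disjoint).  Each document has a dominant topic carrying 0.9 of its
mixture; each sentence is event-free filler with probability 0.2
(defaults), otherwise it realises one sampled species through one of
three templates, one of which opens with the argument adjacent to the
trigger so the NULL-vector logic is exercised by construction.  All gold
layers (tokens, BIO, role tuples, event mentions, document mixtures) are
emitted mutually consistently and reproducibly per seed.

The corpus emulates structure, not style: dictionary-separable spans,
unambiguous triggers, no nested or cross-sentence events, no real prose
statistics.  Tagger and role-classifier scores on it demonstrate that the
machinery learns and decodes correctly, not that real-literature accuracy
reaches the same level.

## Problem sizes and numerical choices

The test suite runs the tagger check at 120 training / 30 held-out
sentences with the full reference hyperparameters (50 epochs, hidden 200,
word 100, char 25, conv width 3, char-CNN out 30); the topic-recovery
check uses 200 documents, 400 Gibbs iterations with 200 burn-in.  These
sizes are the package's chosen study conditions for its own regression
checks.  Degenerate inputs are defined rather than crashed on: empty
sentences vectorise to empty sequences, sentences shorter than a
convolution width are zero-padded, K > |B| fits with a warning, documents
without biterms raise on topic inference (their distribution is
undefined).  Ties in top-event ranking break lexicographically on the
event key.  Equal-length distant-supervision matches resolve by a fixed,
configurable category priority (GRO > COG > MDI > TSK > RLT > SEN > SUB >
MEA > TOL); invalid BIO read from disk is repaired (I→B) rather than
rejected, to tolerate hand annotation.

## Known limitations

- The co-occur meta-event is defined in the schema but not extracted
  (no trigger category exists for it).
- The event-role table beyond deduce-result is a shipped default, not a
  prescribed standard; users with their own role inventory should edit the
  YAML serialisation.
- Token spans are 0-based inclusive everywhere; annotation files produced
  under other coordinate conventions must be converted, not reinterpreted.
- No transformer encoders, no CRF decoding, no variational or online
  topic inference — the pipeline deliberately stays with the
  BiLSTM-CNN + collapsed-Gibbs design it documents.
- Training is single-threaded CPU numpy; it is sized for the small
  dictionary-driven corpora of this domain, not for web-scale text.
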