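# Methods

`famgraph` extracts family-history information — family members with their
side of the family, observations (diseases/conditions) with negation
status, and living status with an Alive×Healthy score — from clinical
text, treating named-entity recognition and relation extraction as one
arc-factored parsing problem.

## The graph schema

Each sentence receives a dummy ROOT node at position 0; tokens are
addressed 1..n as arc heads. Annotations map onto one head index and one
arc label per token:

- tokens inside a multi-token entity point to the token on their right
  with the label `app` (so an entity collapses onto its last token);
- the last token of an entity carries the entity-type label; its head is
  ROOT, unless the entity is the dependent of a relation, in which case
  its head is the last token of the governing family-member entity;
- all other tokens attach to ROOT with label `NULL`.

The schema is single-head by construction: an entity that is the
dependent of two relations is not representable, and `encode_graph`
rejects such annotations (the synthetic generator never emits them).
Relations crossing sentence boundaries are not representable either; the
`Relation` type forbids them.

Two label schemes are supported. `three_type` uses {FamilyMember,
Observation, LivingStatus} and leaves side-of-family to the rules;
`five_type` splits the family-member label by side into {FM-NA,
FM-Maternal, FM-Paternal}. The parser is agnostic to the choice — only
the label-vocabulary size changes.

Decoding is a total function on arc graphs, because model output need not
be consistent. The repair policy: a maximal run of `app`-labeled tokens
followed by an entity-type-labeled token forms one entity; `app` runs
with no such terminator are dropped; an entity-type token always yields
an entity (possibly single-token); a non-`app`, non-ROOT arc yields a
relation only when it connects the last token of a family-member entity
to the last token of a non-family entity. This maximizes recovered
structure, is deterministic, and makes decode(encode(·)) the identity on
valid annotations (property-tested, and tested exhaustively over all
3-token graphs against an independent reference decoder).

## Representation layer

Tokens are represented by the concatenation of two streams:

1. **Char-CNN → BiLSTM.** Character embeddings (dim 25) pass through one
   convolution per kernel size (3, 4, 5), each with 50 filters and
   max-over-positions pooling; tokens shorter than a kernel are
   zero-padded so at least one window exists (the PAD character embedding
   is fixed at zero). The pooled features feed a bidirectional LSTM
   (256 units per direction). No extra nonlinearity is applied between
   convolution and pooling; the LSTM supplies the nonlinearity.
2. **Contextual encoder (a contract).** Any object with `dim` and
   `encode(tokens) -> (n, dim)` aligned vectors. A production deployment
   would plug in a pretrained uncased sub-word transformer with
   first-sub-word alignment (dim 768). The packaged implementation is
   `HashedContextualEncoder`: frozen, deterministic per-token vectors
   derived from a BLAKE2b hash of the lowercased token. It provides
   stable lexical identity (case-normalized, reproducible across
   processes with no weight files); sentence context then comes from the
   BiLSTM stream. The checkpoint stores a fingerprint of the contextual
   encoder and refuses to load under a different one.

A learned ROOT vector is prepended as row 0 so ROOT can be scored as a
head. Dropout (0.5 in the production configuration) applies to the
concatenated token representations and inside each MLP.

## Biaffine attention

Four single-hidden-layer ReLU MLPs project each row to arc-head/arc-dep
spaces (dim p = 500) and label-head/label-dep spaces (dim q = 100). Arc
scores use the biaffine form s[i,j] = hᵢᵀ U_arc dⱼ + u_arcᵀ hᵢ — the bias
term multiplies the *head* projection, following the standard deep
biaffine parser formulation. Label scores add a per-label bilinear term,
a linear term over the concatenated projections, and a bias:
s[i,j,l] = hᵢᵀ U_lab[l] dⱼ + W_lab[l]·[hᵢ;dⱼ] + u_lab[l].

Training minimizes the mean cross-entropy of the head distribution
(softmax over ROOT + n candidate heads per token), the label distribution
on the arc into each token, or their sum:

- **joint** — one model, arc + label loss;
- **pipeline** — a first model trained on the arc loss alone; a second,
  fully separate model trained on the label loss conditioned on the first
  model's *predicted* heads (the two stages share nothing);
- **ner_only** — targets from the NER-only conversion (all heads ROOT,
  labels as usual), so the graph degenerates to sequence labeling.

The label loss conditions on gold heads during joint training (teacher
forcing) and on predicted heads at inference — standard for biaffine
parsers. Decoding is per-token argmax over heads, then argmax over labels
given the chosen head; ties break to the lowest index. No spanning-tree
constraint is imposed: the downstream graph decoder repairs non-tree
output, and greedy argmax is what the scoring model defines.

Optimization uses Adam. The production defaults (learning rate 2e-5,
batch 32, up to 100 epochs, dropout 0.5) suit fine-tuning a pretrained
contextual encoder; the desk-scale configuration used throughout the test
suite trains from scratch, so it uses a learning rate of 5e-3, dropout
0.1, and toy dimensions (char 12, filters 12, kernels (2,3), BiLSTM 24,
contextual 24, arc MLP 48, label MLP 24). Early stopping monitors
micro-F1 of decoded entities+relations (unlabeled head accuracy for the
pipeline's arc stage) on a 10% development split; the exact criterion is
deliberately exposed as configuration. All randomness — initialization,
batch order, dropout — derives from a single seed, making loss curves
bitwise reproducible.

The whole network stack (autodiff, CNN, LSTM, biaffine, Adam) is
implemented on NumPy inside the package and verified against central
finite differences and triple-loop brute-force scoring oracles at 1e-5.

## Rule-based postprocessing

Five groups, all pure functions over editable lexicon files:

1. **Structure conversion** — the graph decoder above.
2. **Family-member normalization** — surface forms map to the normalized
   inventory (degree 1: Father, Mother, Parent, Sister, Brother,
   Daughter, Son, Child; degree 2: Grandmother, Grandfather, Grandparent,
   Cousin, Sibling, Aunt, Uncle). Compound possessives resolve
   left-to-right through a composition table over relation classes
   (parent∘parent→grandparent, parent∘sibling→aunt/uncle,
   aunt/uncle∘child→cousin, parent∘child→sibling); compositions without a
   normalized name (niece/nephew, grandchild, third degree) and non-blood
   relatives (in-laws, partner-side kin, step-relations) are EXCLUDED, as
   is anything mentioned under a partner/in-law section heading.
3. **Side of family** (three-type scheme) — priority order: first-degree
   relatives are NA; a "maternal/paternal family history" section decides;
   a "maternal"/"paternal" indicator within a window (default 3 tokens to
   the left, configurable) decides; otherwise NA.
4. **Living-status scoring** — keyword lookup per property. Alive: 2 for
   {alive, living}, 0 for {dead, die, deceased, death, died, stillborn,
   passed away}, else 1. Healthy: 2 for {good, health, without problems,
   healthy, well}, else 1. Matching is case-insensitive and
   word-boundary-anchored; multiword keywords match as phrases. The total
   is alive × healthy, hence always in {0, 1, 2, 4}.
5. **Observation negation** — a cue from {no, never, not, none, negative,
   neither, nor, unremarkable, deny} among the tokens left of the
   observation within its sentence marks it Negated; a reversal phrase
   ("apart from", "except for"; user-extensible) between the cue and the
   observation flips it back. The nearest cue (rightmost before the
   observation) is the one checked against reversal phrases.

The negation context scope (the observation's sentence, cue search to the
left, reversal search between cue and observation) is a design choice:
it reproduces both canonical examples and keeps the rule local and
testable. The kinship composition table is the deterministic closure of
the two canonical compound examples under degree arithmetic.

## Evaluation protocol

Entity-level (subtask 1): family members match on exact (normalized name,
side); observations match if the predicted text is a contiguous token
subsequence of the gold text, case-insensitively (partial matching — a
predicted "diabetes" against gold "type 2 diabetes" counts). Whether the
converse containment also counts, and whether negation participates at
the entity level, are configuration flags (defaults: no and no).
Relation-level (subtask 2): (family member, side, living-status score)
exactly; (family member, side, observation, negation) with partial
observation matching. Matching is one-to-one and greedy in document
order, exact matches consumed before partial ones. Document-level results
are fact sets, so duplicate identical items collapse on both sides before
counting. Precision, recall and F1 use the 0-on-zero-denominator
convention. Reports break out FM by side, OB, FM-OB by side, and FM-LS by
side.

## Synthetic corpus

The generator emits documents from weighted sentence templates: FM+OB,
FM+LS, FM+OB+LS, negated observation, reversal phrase, compound kinship,
inline side indicator, side-section-headed, partner-section (exclusion
pathway), and entity-free distractors; a "hard" split adds two-family-
member sentences and pronoun subjects. Surface pools cover every
normalized kin name, every living-status keyword, every negation cue and
both reversal phrases; the ~100-condition disease list includes multiword
terms to exercise partial matching. Gold attributes are derived by
running the rule system on the generated surface forms, so generator and
rules are mutually consistent by construction, and every gold annotation
is encodable as an arc graph (single-head, sentence-internal,
non-overlapping). Seeded runs are bitwise reproducible.

What the synthetic data does *not* emulate: real EHR formatting and
abbreviations, tokenization noise, coreference ("His father" meaning the
patient's grandfather — a known failure mode of the rule system),
cross-sentence relations, and the lexical diversity of real clinical
narrative. Passing the recovery experiment therefore demonstrates that
the model, codec, rules and scorer compose correctly and that the
architecture can fit the schema — not that the published corpus-level
scores transfer.

## Desk-scale experiment sizes

The packaged experiments use the toy configuration: 2 000 easy-template
training sentences (~400 documents), 40 held-out documents, up to 20
epochs with early stopping (patience 5), seeds {0, 1, 2} for the
joint-vs-pipeline comparison. The recovery criterion — entity F1 ≥ 0.95
and relation F1 ≥ 0.90 after postprocessing, joint ≥ pipeline on relation
F1 — is evaluated on the held-out documents with the full challenge-style
scorer.

## Known limitations

- The hashed contextual encoder carries no distributional semantics;
  accuracy on real clinical text requires plugging a pretrained
  transformer into the contextual contract.
- Greedy argmax decoding can emit non-tree graphs; the repair policy
  resolves them but may drop structure.
- One observation can attach to only one family member (single-head
  schema); shared observations are rejected at encoding time rather than
  silently re-encoded.
- The rule system is keyword-based: hedged negation ("unlikely"),
  rare kinship surface forms, and coreference are out of scope.
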