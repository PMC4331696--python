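# Methods

## Problem and model

The package performs chemical named-entity recognition as sequence
labelling: each sentence is a token sequence and each token receives one
of the labels B (begin), I (inside) or O (outside a chemical name). The
labeller is a first-order linear-chain conditional random field with
categorical presence features and a transition matrix. Two transitions
are structurally forbidden — a sequence may not start with I and I may
not follow O — by adding a large negative mask to their scores in
training and decoding alike, so every decoded sequence is a valid BIO
chain by construction. Decoding uses Viterbi; per-token confidences are
posterior marginals of the emitted labels from forward–backward, under
the same constrained model, so the marginal distribution of each token
sums to one.

Training maximises the L2-penalised conditional log-likelihood with
L-BFGS. The optimisation is deterministic for a fixed corpus: features
are indexed in sorted order, weights start at zero and no sampling is
involved, so refitting on the same input reproduces the same weights.
The `seed` parameter on the recogniser is recorded for provenance and
threading into data generation, not consumed by the optimiser.

## Pre-processing

Sentence splitting and tokenisation are rule-based, with two variants
each. The *scientific* splitter accepts a sentence boundary whose next
sentence begins with any non-space character, accommodating lower-case
starts such as protein names (p53); the *general* splitter requires an
ASCII upper-case letter after the boundary. Both skip a closed list of
abbreviations (e.g., i.e., et al., Fig., …). The *chemistry* tokeniser
splits on whitespace, peels leading/trailing punctuation (a closing
bracket is peeled only when unbalanced inside the chunk, preserving
names like `In(0.2)Ga(0.8)As`), and keeps digit/comma/hyphen-laden
chemical spans as single tokens; the one internal split is a hyphen
followed by a plain English word from a closed suffix list (induced,
treated, mediated, …), with the hyphen kept on the following fragment
(`GSK214a` + `-induced`). The *general* tokeniser splits at every
punctuation character. Rule sets were chosen to reproduce the intended
behavioural contrasts rather than to replicate any specific external
tool.

Lemma/POS/chunk annotation goes through a pluggable tagger interface
(surfaces in, three parallel sequences out). The default is a
deterministic rule tagger: closed-class word lists plus suffix rules for
POS, plural/past-tense stripping for lemmas, and a POS-driven chunker
producing B/I tags for NP, VP and PP. A statistical tagger can be
injected through the same interface; tests also use a replay tagger that
serves reference annotations from a table.

## Knowledge-rich features

All features are namespaced strings over a context window fixed at two
tokens either side. The default set: character n-grams (n = 2, 3, 4) of
the active token; surface, normalised-surface (per-character word
shape), lemma, POS and lemma:POS unigrams and bigrams across the window;
the active token's chunk tag and the surface of the final token of its
enclosing chunk; and 21 orthographic flags (case profile, digits,
bracket/punctuation content, Greek-letter-name substring). The
normalised surface form maps each character to A/a/0/_ without collapsing
runs; the brief word-shape variant collapses runs and both variants are
separate enriched features.

The enriched set adds: a Unicode Greek-character flag; full/brief word
shapes; per-lexicon dictionary features; affix matches; a bucketed
basic-segment count; and an element-symbol flag. Dictionary matching
normalises entries and token lemmas (lower-case letters, digits to `0`,
everything else to `_`) and takes greedy leftmost-longest matches over
the normalised lemma sequence, encoded as B/I/O per lexicon; features are
label unigrams/bigrams and surface:label unigrams/bigrams within the
window. Matching on lemmas rather than raw surfaces lets plural heads
(`microspheres`) meet singular dictionary entries. Affix matching is
case-insensitive against prefix/suffix lists partitioned by length 2–4,
one slot per (side, size). Element matching is exact and case-sensitive
against the 118 periodic-table symbols (`Fe` matches, `fe` and `NO` do
not). The segment count is capped into six buckets (0–4, ≥5) to keep the
categorical feature space bounded.

## Basic name segments

A token is decomposed at letter/digit/punctuation boundaries; each
maximal ASCII letter run is covered left-to-right by greedy longest
matches against a segment dictionary (case-insensitive), any residue
becoming an unmatched fragment. Digit runs are numeric fragments,
punctuation runs delimiters. The segment *count* includes matched,
unmatched and numeric fragments but not delimiters
(`10-acetoxyactinidine` → 10 | acet | oxy | actin | idine = 5;
`methylergonovine` → methyl | ergo | novi | ne = 4). The *composition
ratio* divides only dictionary-matched characters by the token's total
length, so digits and punctuation count in the denominator only
(`2-methoxyestradiol` → 16/18 ≈ 0.89). This split — numerics in the
count, not in the ratio numerator — is the only reading consistent with
both statistics at once. Greedy covering without backtracking is used;
when a longer cross-boundary match exists (`methyl` inside `methyl+…`)
the greedy choice stands and any residue is a fragment.

The packaged dictionary is a 15-entry fixture (acet, oxy, actin, idine,
methyl, ergo, novi, interleukin, poly, calcium, meth, estra, di, ol,
toxin) sufficient for the worked examples and the synthetic generator;
production use should supply the full basic-name-segment dictionary via
`load_segment_dictionary(path)`.

## Post-processing

Both heuristics only ever turn O tokens into single-token B mentions, so
the set of chemical-labelled tokens grows monotonically and token-level
recall cannot decrease.

*Abbreviation recognition*: for a decoded mention ending at token *i*,
if token *i+1* is `(`, token *i+3* is `)` and token *i+2* is labelled O,
token *i+2* is a candidate short form; it is verified by scanning its
characters left-to-right for an in-order (not necessarily contiguous)
occurrence within the mention text, case-insensitively. On success,
every occurrence of that surface in the document — across title and
abstract — is relabelled B. Relabelled tokens take the triggering
mention's confidence. Multi-token short forms are out of scope because
the pattern fixes `)` at *i+3*.

*Composition relabelling*: an O token with confidence strictly below
`t1` whose composition ratio strictly exceeds `t2` becomes B, with the
ratio as its confidence. Defaults `t1 = 0.93`, `t2 = 0.9` (the
precision/F1-optimal operating point; recall-optimal operation uses
`t1 = 0.96`, `t2 = 0.5`). Adjacent relabelled tokens are deliberately
not merged into multi-token mentions: the heuristic reasons about
tokens, and merging would fabricate span structure it has no evidence
for.

CDI ranking deduplicates predicted mentions per document by exact
(case-sensitive) surface string, keeps each string's maximum confidence,
and sorts by descending confidence with ties broken alphabetically.
Mention confidence is the minimum of member-token marginals — a
conservative score appropriate for ranking.

## Evaluation conventions

CEM counts a predicted mention as a true positive iff its
(section, start, end) triple exactly matches a gold mention; matching is
type-agnostic. Micro averaging pools TP/FP/FN over documents; macro
averaging means per-document P/R/F1, excluding documents that have
neither gold nor predicted mentions (otherwise their 0/0 metrics would
drag the mean toward zero without measuring anything). All 0/0 ratios
are defined as 0. Duplicate identical predictions in one document are an
error rather than a silent merge. The false-negative breakdown groups
unmatched gold mentions by subtype and reports counts and percentages
(2 dp) of the FN total.

## Synthetic corpus generator

The generator emulates CHEMDNER-style sectioned abstracts at desk scale:
template sentences with slots filled either by generated chemical-like
names (gold mentions with exact offsets) or by non-chemical distractor
nouns, at a configurable distractor rate. Names concatenate 2–5 segments
from the fixture dictionary, optionally a numeric locant prefix and an
affix-list suffix, and are rejection-sampled to guarantee a composition
ratio above 0.5 — so the knowledge-rich features are informative by
construction. Abbreviation documents embed `long name (ABBR)` patterns
whose short form is the segment initials (a subsequence of the long form
by construction) plus a later standalone `ABBR` occurrence; templates
also contain fixed non-chemical acronyms (ELISA, WHO, HPLC) so models
learn that acronyms are not chemical per se. One template reproduces the
`{name}-induced` hyphen pattern to exercise the tokeniser. Generation is
fully deterministic per seed.

Defaults: 100 documents, 2–5 names per document, abbreviation rate 0.25,
distractor rate 0.3. What passing tests on this corpus shows is that the
pipeline is wired correctly end to end — offsets, features, training,
decoding, post-processing and scoring all agree; what it does not show
is performance on real chemical text, whose name distribution, ambiguity
(umbrella terms, ambiguous element/drug senses) and annotation
idiosyncrasies the generator makes no attempt to model. Real-corpus
scores require real training data and the full segment dictionary and
lexicons.

## Reference experiment

`chemner.experiments.end_to_end_experiment` trains the knowledge-rich
recogniser on 400 generated documents with abbreviation rate 0 (so short
forms never appear in the training vocabulary), evaluates CEM micro
scores on 100 held-out documents (rate 0.25), and measures token-level
recall with and without abbreviation recognition on a 100-document
abbreviation-heavy variant (rate 1.0). The sizes keep a full run around
half a minute on one CPU while leaving the test set large enough (~400
mentions) for stable scores. Because short forms are out-of-vocabulary,
the CRF misses most standalone abbreviations and the heuristic recovers
them, raising token recall by roughly 35 percentage points under the
default seed.

## Numerical choices and limitations

* CRF regularisation `c2 = 1.0`, optimiser cap 150 iterations, gradient
  tolerance 1e-5; the forbidden-transition mask is −1e4, large enough to
  zero the probabilities in double precision without overflowing
  exponentials.
* Confidence serialisation uses six decimal places; prediction files are
  byte-stable across runs, and ranks break confidence ties by
  (section, start, end).
* Offsets are 0-based half-open Unicode code points; title and abstract
  are separate coordinate spaces (`T`/`A`). Files are UTF-8 without BOM.
* Composition ratios are compared at two decimals with standard rounding.
* Gold mentions whose boundary falls inside a token are expanded to the
  whole token with a warning; overlapping gold mentions are rejected.
* The rule tagger is intentionally minimal; its POS/lemma errors are
  absorbed by the feature set on synthetic data but a learned tagger
  should be injected for real text.
* Word-shape and orthographic classes are ASCII; non-ASCII letters map
  to the "other" class, with a separate flag for Unicode Greek
  characters.
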