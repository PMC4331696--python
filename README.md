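# chemner

Chemical named-entity recognition (NER) for scientific abstracts: a
linear-chain conditional random field (CRF) over a chemistry-aware feature
set, two rule-based recall heuristics, and BioCreative-style evaluation.

## Who this is for

Text-mining practitioners who need to locate chemical entity mentions
(systematic names, trivial names, formulas, identifiers, abbreviations)
in titles and abstracts, and to score recognisers in the two standard
modes: **CEM** (exact-span mention retrieval) and **CDI** (ranked unique
mention strings per document, locations ignored).

## The model

Sentences are tokenised with chemistry-preserving rules (long systematic
names such as `4,9-Diazadodecane-1,12-diamine` stay intact; a hyphen
joining a chemical prefix to a plain English word splits, as in
`GSK214a` + `-induced`). Each token *x&#8321; … x&#8345;* is labelled
**B**/**I**/**O** (begin / inside / outside a chemical name) by a CRF

$$p(y \mid x) \propto \exp\Big(\sum_t w^\top f(x, t, y_t) + \sum_t A_{y_{t-1}, y_t}\Big)$$

whose feature functions *f* combine weakly chemical-indicative signal
(character 2–4-grams, surface/lemma/POS context n-grams within a window
of two, 21 orthographic flags) with chemical knowledge: word shapes
(`10-amino-20(S)-camptothecin` → `00_aaaaa_00_A__aaaaaaaaaaaa` /
`0_a_0_A_a`), longest-match dictionary tagging over user-supplied
lexicons, prefix/suffix matches of length 2–4 (`di…yl`, `fluo…ate`),
periodic-table symbol membership, and the number of *basic name
segments* from a segment dictionary.

Two monotone post-processing steps then recover false negatives:

* **Abbreviation recognition** — after `entity ( x )` where `x` is
  labelled O and its characters occur in order within the entity
  (`STMP` ⊂ `sodium trimetaphosphate`), every occurrence of `x` in the
  document is relabelled chemical.
* **Composition-based relabelling** — an O token with marginal
  confidence below `t1 = 0.93` whose *segment composition ratio*
  (dictionary-matched characters / all characters; e.g.
  `2-methoxyestradiol` → 16/18 = 0.89) exceeds `t2 = 0.9` is relabelled
  chemical.

Scoring reports micro- and macro-averaged precision, recall and F1 with
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)` (0/0 → 0), plus a
false-negative breakdown by mention subtype.

## Worked example

```python
from chemner import (SynthConfig, generate_corpus, ChemicalEntityRecognizer,
                     count_segments, composition_ratio, load_segment_dictionary)
from chemner.evaluate import evaluate_cem

sd = load_segment_dictionary()          # packaged fixture segment dictionary
print(count_segments("10-acetoxyactinidine", sd))
print(round(composition_ratio("2-methoxyestradiol", sd), 2))

train = generate_corpus(SynthConfig(n_documents=100, abbreviation_rate=0.0, seed=1))
test = generate_corpus(SynthConfig(n_documents=25, seed=2))
rec = ChemicalEntityRecognizer(seed=1).fit(train)
report = evaluate_cem(test, rec.predict(test), scope="micro")
print(f"CEM micro: P={report.precision:.3f} R={report.recall:.3f} F1={report.f1:.3f}")
for m in rec.predict(test[:1])[0].mentions[:3]:
    print(m.section, m.start, m.end, m.text, f"{m.confidence:.3f}")
```

prints

```
5
0.89
CEM micro: P=1.000 R=1.000 F1=1.000
T 11 26 10,7-actinactin 0.980
A 10 28 oxyolpolymethestra 0.999
A 74 98 6,1-toxinidineidinetoxin 0.999
```

`5` is the number of basic name segments of `10-acetoxyactinidine`
(`10, acet, oxy, actin, idine`); `0.89` is the composition ratio of
`2-methoxyestradiol`. The recogniser then recovers every synthetic gold
mention exactly (the generator's names are built from the same segment
vocabulary the knowledge-rich features see, so the task is separable by
construction). Each predicted mention carries its section (`T`itle /
`A`bstract), character span and marginal-probability confidence.

The same pipeline is scriptable from the shell:

```bash
chemner synth --out-dir corpus --n-docs 100 --seed 1
chemner train --abstracts corpus/abstracts.tsv --annotations corpus/annotations.tsv \
              --model-out model.json
chemner tag --abstracts corpus/abstracts.tsv --model model.json \
            --cem-out pred.cem.tsv --cdi-out pred.cdi.tsv
chemner evaluate --abstracts corpus/abstracts.tsv --annotations corpus/annotations.tsv \
                 --cem pred.cem.tsv --cdi pred.cdi.tsv --out report.json
```

## Layout

- `src/chemner/` — `io` (corpus/prediction formats), `preprocess`
  (splitters, tokenisers, pluggable tagger), `lexicons`, `segments`,
  `features`, `crf` (the `ChainCRF` estimator), `pipeline` (BIO
  encode/decode), `postprocess`, `evaluate`, `synthetic` (corpus
  generator), `recognizer` (the end-to-end `ChemicalEntityRecognizer`
  estimator), `experiments`, `cli`.
- `docs/methods.md` — modelling and design notes.
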