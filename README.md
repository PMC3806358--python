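# attributor

Character-based authorship attribution for short forum posts, built around a
PPM5 (prediction by partial matching, order 5) statistical text model used
as a minimum cross-entropy classifier.

## Why

People who post about sensitive topics — fertility treatment, mental
health, chronic disease — often do so under pseudonyms, assuming the
nickname protects their identity. Writing style undermines that
assumption: character-level habits (letter combinations, punctuation,
capitalization, emoticons) are distinctive enough that short anonymous
posts can frequently be matched to a known author. This package implements
that attack end to end so that privacy researchers can measure it: given a
set of candidate authors with known posts, it attributes anonymous posts
to candidates and quantifies accuracy under controlled conditions (number
of candidates, training volume, test-text length, character set).

## The method

One PPM5 model is trained per candidate author: for every character
context `c` of length 0–5 it counts how often each symbol followed `c` in
the author's posts. The probability of symbol `s` after context `c`
blends all context orders through the escape mechanism with PPMD
accounting — order `k` contributes `(2·n_k(s) − 1) / (2·T_k)` when it has
seen `s`, weighted by the escape masses `d_j / (2·T_j)` of all longer
orders, bottoming out in a uniform distribution over the alphabet.

A test document `d` is scored under each author model by cross-entropy in
bits per symbol,

> H(d, a) = −(1/N) · Σᵢ log₂ P(sᵢ | sᵢ₋₅ … sᵢ₋₁),

giving an entropy matrix (test documents × authors). Each column is
divided by its mean over the test batch — authors differ in how
compressible their text is, and this normalization removes that bias —
and each document is attributed to the author with minimum normalized
entropy. Evaluation uses balanced k-fold cross-validation and
macro-averaged precision, recall and F; paired t-tests compare methods on
identical folds. Word-based PPM, multinomial Naive Bayes and a linear SVM
over frequent-word/punctuation/5-gram feature tables are included as
baselines.

Real forum corpora of this kind cannot be redistributed, so the package
ships a seeded synthetic corpus generator with controllable stylometric
separation between authors (see `docs/methods.md` for the model and its
limits).

## Worked example

Generate a 5-author corpus, evaluate attribution accuracy by
cross-validation, then train a model bundle and attribute documents:

```
$ attributor synth --seed 7 --authors 5 --posts 40 --delta 0.4 \
      --mean-words 60 --sd-words 20 --out corpus.jsonl
wrote 200 posts by 5 authors (mean 57.7 words/post) to corpus.jsonl

$ attributor evaluate --corpus corpus.jsonl --n-per-author 40 --k 5 \
      --seed 7 --out eval
macro-F 0.995 (precision 0.996, recall 0.995)

$ attributor train --corpus corpus.jsonl --out bundle
trained 5 author models into bundle

$ attributor attribute --bundle bundle --docs corpus.jsonl --out attributions.csv
attributed 200 documents -> attributions.csv

$ head -3 attributions.csv
doc_id,predicted,entropy,margin,ranking
doc00000,author000,0.143155,1.009899,author000|author002|author001|author004|author003
doc00001,author000,0.124545,1.067752,author000|author001|author002|author003|author004
```

The evaluate line is the headline number: with 5 candidate authors whose
character sources are moderately separated (`--delta 0.4`), 5-fold
cross-validation attributes held-out posts with macro-F 0.995. In the
attributions CSV, `entropy` is the winner's normalized cross-entropy
(values below 1 mean "fits this author better than typical"), `margin` is
the gap to the runner-up, and `ranking` orders all candidates from best
to worst fit. Every command writes a `manifest.json` (config hash, seed,
package version, input digests) so runs can be repeated bit-identically.

The `experiment` subcommand drives full studies from one YAML/JSON config:
`kind: variants` (letters-only vs lowercase vs original capitalization),
`kind: factor` (sweeps over author count, training files, or test-chunk
words), `kind: methods` (PPM5 vs word-PPM vs Naive Bayes vs SVM with
paired t-tests) and `kind: cross_group` (train on one subforum, test on
the others).

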