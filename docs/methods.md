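# Methods

## The model

`attributor` treats closed-set authorship attribution as minimum
cross-entropy classification with prediction-by-partial-matching (PPM)
character models.  For each candidate author a variable-order context model
is trained on that author's known posts: for every context `c` of length
0..5 (PPM5) it stores how often each symbol followed `c` in the training
stream.  The predictive probability of symbol `s` after context `c` blends
all context lengths through the escape mechanism with PPMD accounting:

```
P(s | c) = sum over matched orders k of  w_k * (2 n_k(s) - 1) / (2 T_k)   [if n_k(s) > 0]
         + w_(-1) / |A|
```

where `n_k(s)` is the count of `s` after the length-`k` suffix of `c`,
`T_k` the total successor count of that suffix, `w_k` the product of the
escape masses `d_j / (2 T_j)` (`d_j` = distinct successors) of all longer
matched orders, and `w_(-1)` the full escape-chain product reaching the
uniform order(−1) model over the alphabet `A`.  Contexts never seen in
training are skipped without consuming escape mass.  No exclusions are
applied; the additive escape-chain blend guarantees that the distribution
sums to exactly 1, which the test suite checks to 1e-9.

A test document of `N` symbols is scored under author `a`'s model by its
cross-entropy in bits per symbol,

```
H(d, a) = -(1/N) * sum_i log2 P(s_i | s_{i-5} .. s_{i-1}),
```

and the batch of test documents yields an entropy matrix (documents ×
authors).  Because authors differ in how predictable their training text
is, each column is divided by its mean over the batch, making every
author's entropies average 1; the document is attributed to the author
with minimum normalized entropy, ties broken by the lexicographically
smallest label.  Note the normalization is transductive — it uses the
whole test batch — so a single-document batch is degenerate (every value
becomes 1) and attribution refuses it.

### Modeling choices

- **Escape estimator.** PPMD accounting (symbol shares `(2c-1)/(2T)`,
  escape mass `d/(2T)`).  It is the standard modern escape variant, needs
  no tuning, and keeps every probability strictly positive.
- **Exclusions.** Not implemented.  Full PPM exclusion complicates the
  contract without changing the classifier's behavior much at these text
  sizes; the exclusion-free blend is exactly testable against a longhand
  recursion, which the suite exploits.
- **Document boundaries.** Training posts are joined with one reserved
  boundary symbol that participates in contexts, so the model pays for
  crossing a document edge instead of inventing spurious cross-post
  statistics.  Scoring starts from the empty context.
- **Out-of-vocabulary symbols.** One reserved alphabet slot; any unseen
  test symbol maps to it, so entropies are always finite.
- **Frozen models.** No adaptation during scoring; results are exactly
  reproducible and scoring documents is embarrassingly independent.
- **Numerics.** Probabilities are accumulated in linear space per symbol
  (each term is a product of at most 7 factors, all ≥ ~1e-40 at realistic
  alphabet sizes) and summed in log space across symbols; nothing can
  underflow to 0 because the uniform term is always present.
- **Word unit.** The same machinery runs over lowercased alphabetic word
  tokens (`unit="word"`), default `max_order=2`: word streams from ~90
  short posts are far too sparse for order 5.

### Text variants

Preprocessing offers three character sets: `LETTERS_ONLY` (Unicode
letters, lowercased, non-letter runs collapsed to one space),
`LOWERCASE_ALL_CHARS` (everything kept, letters lowercased) and
`ORIGINAL` (everything kept).  Input is NFC-normalized; CR/LF runs
collapse to a single retained newline, since line-breaking habits are
stylometric signal.  Posts carrying quote-span markup
(`[quote]…[/quote]` or an HTML `blockquote`) embed another author's text
and are removed before modeling; plain-text quoting heuristics are
deliberately not attempted because false positives on short posts are
worse than the occasional missed quote.

## Evaluation protocol

Every author is balanced to the same number of posts (shuffled once with
the run seed, surplus dropped), and the retained posts are dealt
round-robin into k folds, so across folds each post is tested exactly
once.  Per fold the pipeline trains one model per author, scores,
normalizes and attributes the held-out posts, and accumulates a confusion
matrix.  Precision, recall and F (`2PR/(P+R)`) are computed one-vs-rest
per class and macro-averaged (unweighted mean over authors); zero
denominators yield 0 with a logged warning.  Both the pooled-confusion
metrics and the mean of per-fold metrics are reported; the fold-averaged
numbers are the headline because the per-fold values are the paired
replicates that the paired t-test consumes when two methods are compared
on identical splits.  The t-test is the classical two-sided paired test;
with zero variance of the differences it reports `t = ±inf, p = 0` for a
nonzero mean and `t = 0, p = 1` otherwise.

Factor experiments rerun the cross-validation sweeping one factor:
number of candidate authors (first N in sorted label order), number of
training files per author (per-fold training lists truncated after the
seeded shuffle), or test-text size (each fold's per-author test posts are
merged, split on whitespace and re-cut into chunks of exactly the
requested word count, the trailing partial chunk dropped).  For the
chunk-size factor the fold models are shared across levels — training
does not depend on the chunk size, so this is free of statistical cost.

## Baselines

The word-feature pipeline mirrors common practice: a vocabulary of all
word tokens with training-corpus frequency strictly greater than 10
(`FREQ_WORDS`), optionally extended with 24 ASCII punctuation-character
counts plus digit and capital-letter counts (`FREQ_WORDS_PLUS`), or all
character 5-grams above the same threshold (`CHAR5_SEQS`).  Vocabularies
are built from the training split only.  Classifiers are a native
multinomial Naive Bayes (add-one smoothing over raw counts — checked
against an independent posterior enumeration and a reference
implementation in the tests) and a linear SVM behind a thin adapter
(scikit-learn's `LinearSVC`, one-vs-rest, seeded); when no SVM
implementation is importable the comparison proceeds without SVM rows.
Feature values are raw counts, as period word-vector practice used;
per-length normalization is available behind a flag.  The exact 24
punctuation marks are a documented, configurable choice
(`.,!?;:'"()-/@#$%&*+=<>[]`), not a canonical set.

## Synthetic corpora

Real forum corpora of this kind cannot be redistributed, so all tests run
on a seeded generator whose difficulty is controllable:

- A base order-2 character chain (letters + space) is estimated from a
  small bundled English text.  Author `i`'s chain is a row-wise Dirichlet
  perturbation with concentration `c(δ) = 30 (1-δ)/δ`: mean-preserving,
  identical to the base at `δ = 0`, increasingly author-specific as
  `δ → 1`.
- On top of the chain each author has a capitalization rate and
  punctuation-mark preferences whose spread across authors is set by
  `style_delta` (default: equal to `δ`).  These habits survive in the full
  character stream but are destroyed by letters-only preprocessing, which
  is what makes the text-variant comparison meaningful.
- Post lengths are lognormal in words, truncated at 3; the default mean
  126.2 and SD 47.5 words emulate the descriptive statistics of the
  medical-forum corpora this generator stands in for.  Tests that sweep
  design factors use mean 80 (SD 30) to keep runtimes proportionate.
- Group labels give each author a home subforum with ~90% of their posts,
  so cross-group train/test experiments are runnable; `inclusion_rate`
  wraps an exact fraction of posts in `[quote]` markup quoting another
  generated post, exercising the cleaning stage.  The default is 0: the
  generator's default output emulates the corpus *after* quote removal,
  and inclusion injection is switched on specifically to test cleaning.

What the generator does **not** emulate: semantics and topicality (the
text is letter-soup English), author-specific vocabulary, misspellings,
emoji beyond a fixed emoticon, post-length dependence on thread position,
and the heavy-tailed post-count imbalance of real forums (post counts per
author are exact by construction).  Passing tests therefore demonstrate
that the pipeline recovers character-level stylometric signal when it
exists; they do not certify accuracy on any real forum.

## Study conditions used by the tests and the acceptance script

- Parameter recovery: 10 authors, 100 posts each (~100 words), `δ = 0.5`,
  10-fold CV (90 train / 10 test per author per fold); macro-F ≥ 0.90 is
  expected on every seed, and `δ = 0` must sit at chance (0.1).
- Factor sweeps (at `δ = 0.2`, 80-word posts): authors 10→30 with 50
  posts each (5-fold); training files 20→180 with 200 posts per author
  (10-fold); chunk sizes 25→500 words with 200 posts per author
  (5-fold, 160/40 split per fold).  These reduced sizes keep each sweep
  in the minutes range while leaving the accuracy range wide enough for
  the trends to be visible.
- Variant ordering: authors separated mainly by style habits
  (`δ = 0.1`, `style_delta = 0.5`), 50 posts each, 5-fold, averaged over
  5 seeds.

## Known limitations

- The per-class mean normalization is transductive; batch composition
  affects attributions, and the single-document case is rejected rather
  than approximated.
- Closed-set only: the system always names some candidate; there is no
  "none of the above" verification.
- PPM models store every observed n-gram up to order 5; memory grows
  roughly linearly with training characters (~tens of MB per author for
  ~50k characters).  This is fine for forum-scale authors and not tuned
  for book-scale corpora.
- The bundled base text is small; the synthetic language has realistic
  letter-pair statistics but unrealistically low long-range structure, so
  absolute entropies are not comparable to real English.
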