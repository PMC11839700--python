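# Methods

## Scope and model

`lexneigh` computes similarity-neighborhood measures for word forms
against a reference lexicon in three dimensions:

* **orthographic** — units are extended graphemes (a base character
  plus its combining marks, after NFC normalization), so composed and
  decomposed spellings of an accented letter are one symbol;
* **phonological** — units are phoneme tokens segmented from an IPA
  string;
* **phonographic** — a word pair is related only when it is related in
  *both* of the above channels simultaneously.

All distances are unit-cost Levenshtein distances (substitution,
addition, deletion) over those symbol sequences. A transposition counts
as two edits; weighted or feature-based phoneme distances are out of
scope. Comparisons are case-insensitive (forms are lower-cased on
ingest) and diacritic-sensitive.

Per dimension the package reports:

* **N** (Coltheart-style neighborhood size): entries of equal symbol
  length differing at exactly one position. In the phonographic
  dimension both channels must satisfy this simultaneously.
* **density**: entries at edit distance exactly 1. The density relation
  is also the edge relation of the lexical network used by the two
  measures below.
* **OLD20 / PLD20 / PGLD20**: mean distance from the target to its 20
  nearest entries. When fewer than 20 comparison entries exist, the
  mean runs over all available distances and the count actually used is
  reported in a `*_k` companion column rather than returning a missing
  value; this keeps small corpora usable while remaining visible in the
  output. The phonographic per-pair distance is
  max(orthographic distance, phonological distance), so phonographic
  density-1 neighbors sit at distance exactly 1 under the same metric.
* **clustering coefficient** C = 2E / (k(k−1)), where k is the target's
  density and E the number of density-neighbor pairs among the target's
  neighbors. Undefined (missing, not 0) when k < 2: a 0 would be
  indistinguishable from "no interconnection".
* **2-hop density**: with 1-hop = the target's density neighbors and
  2-hop = entries adjacent to at least one 1-hop node (excluding the
  target and the 1-hop set), the ratio of realized 1-hop/2-hop cross
  edges to |1-hop|·|2-hop|. Missing when either set is empty. By
  construction every 2-hop node has at least one cross edge, so the
  value lies in [1/|1-hop|, 1] whenever defined.
* **neighbor-frequency statistics** on both the per-million (fpm) and
  Zipf scales: mean, sample (n−1) standard deviation, and separate
  means over neighbors strictly more and strictly less frequent than
  the target. Ties count in neither split; nonword targets have no
  frequency, so their split means are missing.

**Self-exclusion.** A target never counts itself, and entries at
distance 0 in the relevant dimension (homographs orthographically,
homophones phonologically) are excluded from every measure. This
prevents OLD20 deflation by duplicate forms and makes the phonological
neighborhood of a homophone-rich lexicon genuinely diverge from the
orthographic one.

**Nonwords** are scored identically to words except that no frequency
fields are produced. An ad-hoc target node contributes no edges among
corpus words, so network measures for nonwords describe the corpus
graph around the insertion point.

## Neighbor retrieval

Distance-1 retrieval uses a deletion-variant index: every sequence is
keyed by itself and by each of its one-symbol deletions. Two sequences
at distance ≤ 1 necessarily share a key, but key sharing can also occur
at distance 2 (e.g. "abc"/"bca" share "bc"), so all candidates are
verified with the exact DP distance. Tests assert the index equals a
full O(n²) pairwise scan, and that the DP distance equals an exhaustive
recursive edit search on all short strings over a 3-symbol alphabet.

## IPA segmentation

No authority defines phoneme boundaries for raw IPA strings, so
segmentation is an explicit policy (configurable per language):
primary/secondary stress marks and syllable dots are stripped; length
marks and combining diacritics attach to the preceding base symbol;
tie-barred pairs (t͡ʃ) form a single token. Tone marks encoded as
combining diacritics therefore attach to their vowel by default.

## Corpus cleaning

A raw frequency list becomes a reference lexicon in five fixed steps:
script filter (every character must belong to the language's valid
set), stopword removal, length bounds (default 2–25 letters, with
documented per-language maxima: Hindi 17; English/French/Spanish 20;
German 27; Dutch 28), a frequency floor of 0.34 per million, and a cap
at the 30,000 most frequent types. Every input type is either retained
or counted in exactly one removal bucket, and the pipeline is
idempotent.

Numerical choices:

* fpm = raw count / corpus token total × 10⁶, with the *raw* corpus
  total as denominator throughout — filtering removes types, not
  tokens — so a cleaned lexicon re-cleaned yields identical values.
* Zipf = log₁₀(fpm) + 3, i.e. log₁₀ of the per-billion count, mapping
  everyday vocabulary onto roughly 1 (very rare) to 7 (function
  words). No zero-frequency smoothing: Zipf is undefined at fpm ≤ 0
  (the built pipeline removes such entries at the 0.34 floor anyway).
* The frequency floor keeps entries at the threshold and excludes only
  strictly rarer ones; the comparison carries a 10⁻⁹ relative
  tolerance so a count landing on the threshold up to float rounding
  (34 occurrences in 100 M tokens vs 0.34) counts as on the boundary.
* Ties at the cap boundary break by ascending lexicographic order of
  the form — the deterministic choice.

## Transcription provisioning

Phonological measures need word→IPA mappings, but no
grapheme-to-phoneme engine is bundled. Any object with a
`transcribe(word) -> str | None` method can be plugged in; the package
ships a lookup transcriber over the lexicon's own IPA column and a
per-letter substitution-table transcriber (used by the synthetic
generator; many-to-one tables create homophony on purpose). An external
engine adapter can satisfy the same protocol without becoming a
dependency. A profile computed from query-supplied IPA is identical to
one computed through a transcriber returning the same strings.

## Synthetic data

The lexicon generator emulates a cleaned subtitle-style frequency
list: `n_words` distinct forms over a small alphabet (default 10
letters, lengths 2–7 uniform), rank-law raw frequencies
(count ∝ rank^(−s), default s = 1, scaled to 10⁶ corpus tokens with a
floor of one occurrence), and transcriptions from a default phoneme
table whose e→i merger creates homophones. It does **not** model real
phonotactics, morphology, length–frequency covariance, or any
particular language's grapheme inventory — so passing tests demonstrate
correctness of the computations and the statistical machinery, not
linguistic fidelity.

The behavioral generator produces response times linear in Zipf
frequency, word length, and one measure column, plus Gaussian noise, in
standardized (z-score) units: the defaults (β_freq = −0.3 per Zipf
unit, β_len = +0.15 per symbol, residual SD = 1) encode the dominant
facilitatory frequency effect and a smaller inhibitory length effect as
effect sizes relative to unit residual noise. Accuracy is a logistic
transform of the negated, standardized linear predictor (fast predicted
words are accurate words) plus clipped Gaussian noise — a bounded
monotone link handled with the same linear regression machinery as
response times, mirroring common practice with word-level accuracy
norms.

## Validation machinery

* **Reliability**: Spearman rank correlation (average ranks for ties,
  via scipy) between two per-word value sets after an inner join on
  word form; undefined for constant vectors or fewer than three shared
  words. The suite's reliability analog recomputes OLD20 on a
  1,000-word synthetic lexicon before and after deleting a random 20%
  of entries and requires rho > 0.7 over shared words — a conservative
  floor; observed values run ≈ 0.99.
* **Hierarchical regression**: OLS with baseline predictors Zipf +
  length, then the same model plus one measure, compared by adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1). In the linear case the measure
  enters on its own scale so its coefficient is directly interpretable
  and recoverable in simulation; with the quadratic flag the measure is
  standardized first and its square added, which limits collinearity
  between a term and its square. Rank-deficient designs and analyses
  with fewer than 10 complete cases are rejected.
* **Recovery study design**: the parameter-recovery simulation (β = 0.5
  on the added measure, n = 500 words, 100 noise seeds) uses a
  controlled standardized measure column generated independently of the
  baseline predictors. This isolates the regression machinery from the
  collinearity structure of any particular lexicon: real
  neighborhood measures such as OLD20 share most of their variance with
  word length, which shrinks their unique contribution without saying
  anything about the correctness of the estimator. With the controlled
  design the mean recovered coefficient is unbiased and the
  adjusted-R² gain is positive in ≥ 95% of seeds, while a null (β = 0)
  measure's gain distribution centers at ≈ 0.

## Problem sizes

The shipped test suite and the acceptance script use desk-scale
problems chosen to exercise every code path: exhaustive distance
verification over all strings of length ≤ 4 on a 3-symbol alphabet,
20 × 500-word lexicons for index-vs-scan equivalence, 100 random
30-word graphs for network-formula conformance, and 500–1,000-word
lexicons for the validation analogs.

## Known limitations

* The cross-database reliability and megastudy regression results that
  motivate the validation analogs require external behavioral datasets
  and are not reproduced here; the analogs establish internal
  consistency, not external validity.
* Cross-linguistic phonological neighborhoods are out of scope: a
  subtitle-derived lexicon retains foreign words, which would inflate
  such counts.
* Damerau-style transposition neighbors are not modeled.
* The table transcriber is strictly per-letter; context-dependent
  grapheme-to-phoneme rules require an external engine behind the
  transcriber protocol.
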