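# Methods

This note records the model, the parameter choices and the numerical
conventions behind `reportriage`, and what the synthetic corpus does and
does not establish about behavior on real reports.

## Problem setting and assumptions

The task is binary triage of free-text brain-CT reports: does the report
describe signs of intracranial hemorrhage?  The pipeline assumes the
reporting style that motivates keyword/stop-phrase weak supervision:

* affirmative hemorrhage findings are expressed with a small, stable
  vocabulary (hemorrhage/hematoma terms and the SAH/SDH/EDH/ICH
  abbreviations);
* absence of hemorrhage is very often expressed with *formulaic*
  negation sentences (stop-phrases) rather than free negation;
* reports are semi-structured into a descriptive body and a conclusion,
  and a mention in either field is equally informative.

No general negation-scope inference (NegEx-style windows), spelling
correction or fuzzy matching is attempted: the stop-phrase lexicon is
an explicit, auditable list, and matching is exact at token level.

## Record-level exclusions

A record is kept iff both text fields are non-blank, age is present and
`min_age <= age <= max_age`, and it is not a complete duplicate
(all seven fields equal after trimming, case-sensitively, since report
text case can be meaningful) of an earlier-kept record.  Choices:

* `min_age = 18` (inclusive: "under 18" excludes only < 18), and an
  "abnormal age" cutoff of `max_age = 120` years — data-entry artifacts
  in radiology exports show ages like 976 or 1000; 120 is a generous
  bound on plausible human age.  Both are configurable.
* Per-record checks run in a fixed order (blank text, missing age,
  underage, abnormal age) so each record gets exactly one reason;
  duplicate detection runs last, over otherwise-valid records only.
  The kept/excluded sets always partition the input and the operation
  is idempotent on its own output.

## Text normalization and lexicon matching

All matching happens on a shared normalization: case folding, every
punctuation character except intra-token hyphens mapped to a space,
whitespace runs collapsed.  The normalizer carries a per-character
offset map, so every hit is reported as a span into the original field
text; this is what lets the weak labeler test whether a keyword lies
inside or outside a stop-phrase occurrence.

Keyword *word stems* match as token prefixes — `hemorrhage` covers
`hemorrhages` without a lemmatizer, which suits lexicons that list stems
with optional plural endings.  *Abbreviations* match only as whole
tokens, because prefix matching would fire inside ordinary words
(`sah` in `sahara`).  Stop-phrases match when their normalized token
sequence occurs contiguously at token boundaries.  Both lexicons are
plain UTF-8 files and fully user-replaceable, so a lexicon in another
language (the scheme originates in Russian-language reporting) drops in
without code changes.  Of the 33 packaged stop-phrases, 7 are real
report boilerplate and 26 are synthesized in the same style; the file
marks the synthesized block.

## Weak labels

Any stop-phrase hit forces `ICH_NEGATIVE` (stop-phrase dominance); the
*conflict* flag marks records where a keyword hit lies outside every
stop-phrase span.  Rationale: the stop-phrase is a report-level negative
marker, but a conflicting affirmative mention elsewhere is precisely the
case that needs human review, so the label stays negative while the flag
and the full match provenance surface it.  Final classes are therefore
modeled as weak labels plus an expert-override table rather than a
closed-form rule — the rule alone cannot adjudicate conflicts.

## Featurization

Bag-of-words token counts over body + conclusion, vocabulary frozen on
the training split only, tokens in fewer than `min_document_frequency = 2`
training documents dropped (bounds vocabulary size; configurable), OOV
tokens ignored at test time, optional bigrams off by default.  The
deliberately plain representation keeps the classifier auditable: every
tree split is a readable token-count threshold.

## Decision tree

A from-scratch binary CART tree: Gini impurity `1 − Σ p_k²`, exhaustive
search over features with thresholds at midpoints between consecutive
distinct sorted values, count-weighted impurity decrease, recursion
stopping at purity, `max_depth` (default 15), `min_samples_split`
(default 2) or zero decrease.  Default depth 15 is the conventional
depth cap for this triage task; no pruning or class weighting is applied.

Determinism is a design requirement (it makes the trainer testable
against an exhaustive reference): ties in impurity decrease break to the
lowest feature index, then the lowest threshold, and a tied leaf
predicts the negative class.  Internally the split score is compared as
a ratio of integers by cross-multiplication, so floating-point rounding
can never flip a tie-break; `reportriage.reference` re-implements the
identical rule naively with exact rational arithmetic and the two must
produce identical trees on every instance.  The `random_seed` field of
`TrainConfig` exists for interface symmetry; training uses no
randomness.

## Evaluation

Unstratified seeded permutation split with train size
`round_half_up(0.7 · n)` — for n = 3980 this gives exactly 2786/1194.
Metrics: sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, PPV
`tp/(tp+fp)`, NPV `tn/(tn+fn)`, F-score for the positive class
`2·PPV·sens/(PPV+sens)`.  Zero-denominator metrics are reported as
undefined (NaN), never 0.  Confidence intervals use the Wilson score
method (via statsmodels): it is well-behaved near 0 and 1 and needs no
normality assumption; no interval is computed for F-scores.  A
macro-averaged F-score (mean of the positive- and negative-class
F-scores) is reported alongside the positive-class one because both
conventions circulate in clinical-NLP reporting.

## Synthetic corpus generator

The generator emulates the *statistical structure* the pipeline assumes,
with per-record independent Bernoulli scenario draws:

| parameter | default | meaning |
|---|---|---|
| `n_records` | 4000 | corpus size |
| `prevalence` | 0.25 | fraction of valid records with true hemorrhage |
| `negation_rate` | 0.6 | fraction of true negatives carrying a stop-phrase |
| `distractor_rate` | 0.05 | fraction of true negatives with an extracranial-hemorrhage mention |
| `conflict_rate` | 0.05 | fraction of true positives also containing a stop-phrase |
| `invalid_record_rate` | 0.05 | records violating one exclusion criterion |

Prevalence 0.25 mirrors a realistic candidate-set class balance (about
one quarter positive); negation_rate 0.6 reflects how routinely
normal reports use formulaic negation; the 5% conflict/distractor rates
keep the two error modes present but rare, as they are in practice.
Valid ages are uniform on [18, 99].  Distractor records carry a
stop-phrase with probability `negation_rate`; the stop-phrase-free ones
are, by construction, exactly the weak labeler's false positives, and
conflict positives exactly its false negatives.  Invalid records violate
exactly one criterion chosen uniformly (duplicates clone an
earlier-generated valid record verbatim) and carry their expected
exclusion reason so the filter's log can be verified record by record.
Generation is a pure function of the seed.

Templates are a packaged JSON bank of English paraphrases of report
boilerplate; a bank for another language substitutes by file.  What the
generator does **not** emulate: real lexical diversity and typos,
correlated comorbid findings, multi-hemorrhage subtype descriptions,
inter-radiologist style drift.  Green tests on synthetic corpora
therefore certify the *mechanics* (rules fire exactly as specified; the
tree learns the weak-label mapping; metrics are computed correctly), not
clinical-grade accuracy on hospital data.

## Problem sizes used in checks

The automated checks run the tree-vs-reference comparison exhaustively
on all binary instances up to 4 rows × 2 features plus 300 sampled
instances up to 8 rows × 3 features; weak-label exactness on a
2000-record clean corpus; error modes on a 500-record corpus; and the
end-to-end run on a 4000-record corpus (≈2400 candidates), which
completes in seconds.  The split-arithmetic check uses n = 3980, the
size at which the 7:3 ratio yields the canonical 2786/1194 partition.

## Known limitations

* Stop-phrase dominance means a genuinely positive report that also
  contains a negation sentence is weak-labeled negative; the conflict
  flag only *surfaces* it.  Downstream users must route conflicts to
  review or supply overrides.
* Token-prefix stem matching can overreach on lexicons with very short
  stems; abbreviation entries exist precisely to opt out of prefix
  semantics.
* The unstratified split can produce class-imbalanced test sets at small
  n; stratification is deliberately not offered because the evaluation
  convention here is a plain random split.
* The tree inherits every bias of the weak labels it is trained on; with
  expert overrides it approaches the override quality, not ground truth.
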