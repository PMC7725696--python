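# Methods

## The generation procedure

A factorial design over a lexicon of N words is given by ordered *splits*
(independent variables; each a set of ≥ 2 pairwise-disjoint closed
intervals for numeric variables, or disjoint category sets), *controls*
(variables that must not differ between conditions beyond an inclusive
tolerance [lo, hi] with lo ≤ 0 ≤ hi; categorical controls require
equality), optional pool *filters*, and a match-null policy. Conditions
are the Cartesian product of split levels, labelled `A1_B1 …` in
row-major order; k denotes the number of conditions.

Generation proceeds set by set:

1. **Match-null allocation.** Under the default `balanced` policy the
   anchor ("match-null") condition of each future set is fixed up front:
   each condition receives ⌊n/k⌋ or ⌈n/k⌉ sets — the over-represented
   conditions drawn at random — and the sequence is shuffled. `fixed:<c>`
   anchors every set at one condition; `random_per_set` draws i.i.d.
   uniform anchors; `inclusive` allocates like `balanced` but changes the
   constraint (below).
2. **Set construction.** A word is drawn uniformly from the anchor
   condition's eligible pool (passes filters, inside the condition's
   levels, unused, non-missing on all control variables). For every other
   condition, the candidate pool is restricted to words within every
   control tolerance of the anchor word's values; one is drawn uniformly.
   There is no optimization of closeness — fidelity to a simple, analyzable
   sampling scheme is preferred over greedy match quality, which the
   tolerances already bound.
3. **Discard and retry.** If any condition's pool is empty the iteration
   is discarded and a different untried anchor word is drawn from the same
   condition. Words consumed by failed iterations return to the pool; a
   failed anchor word is excluded from further anchor attempts within the
   run (it may still appear as a match). When the anchor condition has no
   untried words left, an n-request returns the partial list with
   `exhausted=True` and a warning; `"all"` mode stops there by design.
4. **Inclusive matching.** Under `inclusive`, every pair of words in a set
   must satisfy every control pairwise. A pair has no anchor to orient an
   asymmetric interval, so the constraint is symmetrized:
   |Δ| ≤ min(hi, −lo). This makes validity order-independent, which the
   independent audit relies on.

Random splits (levels carrying no word property) are assigned per matched
set after generation, balanced like match-nulls, and appended to the
condition label.

Determinism: all randomness flows from one `numpy` Generator seeded by the
design (or an override); identical inputs give bit-identical outputs.

## Derived metrics

* **Zipf** = log₁₀(frequency per billion words) = log₁₀(fpmw·10³);
  bounded 1–8 for observed words. Non-positive frequencies map to missing
  — no smoothing, no −∞.
* **Bigram probability.** Each adjacent character pair of each word
  contributes the word's fpmw to that bigram's weighted count; counts are
  normalized by their **total**, yielding a true probability distribution
  (min–max scaling is available as a config alternative but does not
  produce probabilities). A word's score is the mean probability of its
  adjacent pairs, repeats counted each time.
* **Coltheart's N** counts equal-length words differing in exactly one
  position; the word itself never counts.
* **OLD20/PLD20** is the mean of the 20 smallest unit-cost Levenshtein
  distances (edlib's banded alignment) to other entries; strings identical
  to the target are excluded, ties at the cut are broken by distance then
  lexicographic order (the mean is unaffected when tied values are equal),
  and a pool smaller than 20 triggers a warning and a mean over what
  exists. Applied to one-symbol-per-phoneme transcriptions these same
  operations yield the phonological neighborhood measures.
* **Phonological counts** operate on transcriptions with exactly one
  symbol per phoneme (diphthongs and affricates included), so phoneme
  count is sequence length, syllable count is the number of vowel symbols,
  and the rhyme category is the suffix from the last vowel symbol.

## The matcher

`match_word` filters the lexicon to entries satisfying every tolerance
(inclusive, relative to the target's values), exact equality for numeric
variables named without an interval, and category equality — then orders
by Euclidean distance. Deltas in different units are incommensurable, so
each numeric variable is divided by its standard deviation over the whole
lexicon (ddof = 1) before the distance is taken; `raw` and
tolerance-width scaling are selectable. Ties are broken lexicographically.
Post-hoc subsetting of the candidate table preserves the distance order.

## The matching statistic

For a finished list, each numeric control variable is standardized by its
SD **over the words of that list** — not the generating lexicon, so
externally sourced published lists remain comparable — and the Euclidean
distance is computed for every unordered pair of words within each
matched set: n·k(k−1)/2 observations. Variables with zero variance over
the list carry no information and are dropped with a warning. Summaries
are the box-plot statistics (median, quartiles, whiskers at 1.5 × IQR
clamped to observed values); comparing two lists reports side-by-side
summaries and their difference, deliberately without a hypothesis test.
Because each variable is scaled by its own SD, the report is invariant to
affine rescaling of any control variable.

## Synthetic lexicons

The generator emulates the statistical shape of merged lexical databases:
unique alphabetic strings with a unimodal length distribution (3–8
characters by default), numeric variables with arbitrary bounded marginals
(ratings on 1–5/1–9 scales, Zipf-like normals, proportion-known piled up
near 1 the way familiarity ratings are) coupled through a Gaussian copula
so target rank correlations survive skewed marginals, categorical
variables, and a toy transcription column (letter → symbol, vowels to
dedicated vowel symbols). It does **not** emulate English phonotactics,
real frequency–length dependence, or the sparse cross-corpus coverage of
real merged datasets — so passing tests demonstrate the algorithms'
correctness and the pipeline's behavior under controlled feasibility, not
performance on any particular language's statistics.

`plant_matched_sets` rewrites k chosen rows per set so that one row falls
in each condition, numeric control values are exactly equal within the set
(equality satisfies any tolerance containing zero under every policy),
categorical controls share a category, and filter variables sit inside
their windows. When a control column equals actual string length, rows of
equal length are selected instead of rewriting the column, keeping the
table self-consistent. The planted assignment is recorded in hidden
`_planted_*` columns, giving tests a certificate that a requested number
of sets is achievable.

The worked-example lexicon (`example_lexicon`) uses 10,000 words, uniform
bigram-probability and concreteness marginals spanning both bins of each
split, Zipf ~ N(4, 1) truncated to [1, 8], proportion-known ~ Beta(5, 1)
with rank correlation 0.4 to Zipf, and 60 planted sets — sized so that a
50-per-cell request completes in under a second while leaving genuine
search work to do.

## Numerical and design choices

* All interval bounds are closed; `0:0` therefore means exact equality.
* Word strings are lowercased once at load; comparisons afterwards are
  case-sensitive. "Non-alphabetic" means any character outside the
  configured alphabet (default a–z): hyphens, apostrophes, digits and
  spaces all exclude.
* The hapax filter removes entries whose raw counts sum to ≤ 1 across the
  configured count columns; with only per-million columns available it is
  disabled (per-million rates cannot recover raw counts).
* Any computation needing a variable skips entries missing it rather than
  erroring; merged lexicons are sparse by construction.
* The audit checker (`audit_stimulus_list`) re-derives every constraint
  from the design definition and shares no code with the search; the test
  suite additionally checks the metrics and matcher against brute-force
  oracles (full DP Levenshtein, exhaustive filter-then-sort).
* Problem sizes in the test suite (lexicons of 300–3,000 words, 100
  oracle lexicons up to 1,000 words, 50 random audited designs, 20-seed
  tolerance trends) were chosen to exercise every code path at desk scale.

## Known limitations

Failure to reach n sets triggers no backtracking across completed sets; a
maximal matching is not guaranteed (global assignment optimization is an
explicit non-goal). Map-controls are evaluated per candidate pair and can
be slow on very large pools. Planting does not support map-controls, and
grapheme-to-phoneme conversion, stress analysis and frequency smoothing
are out of scope — transcriptions are consumed as input columns.
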