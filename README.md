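# stimgen

Controlled generation of word stimuli for factorial experimental designs.

Psycholinguistic experiments need word lists in which the manipulated
properties differ sharply between conditions while everything else is held
constant — e.g. high- vs low-concreteness nouns matched item-by-item on
length and frequency. Assembling such lists by hand from large lexical
databases is slow and error-prone. `stimgen` automates it over **any**
tabular lexicon (CSV/TSV with one row per word and numeric or categorical
variable columns):

* **generate pipeline** — declare independent variables as *splits*
  (disjoint level intervals or category sets), *controls* (inclusive
  tolerances around a match-null word, e.g. Zipf ± 0.2, length 0:0 =
  exact), pool *filters*, and a *match-null policy*; the generator
  pseudo-randomly allocates match-null conditions with equal frequency,
  then iteratively builds matched sets of k words (one per factorial
  cell) by discard-and-retry sampling from the pool of unused words —
  either a requested number of sets or as many as possible.
* **single-word matcher** — `match_word` returns every word within the
  stated tolerances of a target, ordered by Euclidean distance over the
  SD-standardized numeric matching variables (for bespoke jobs such as
  finding a sentence-plausible replacement).
* **derived metrics** — Zipf frequency (log10 of frequency per billion
  words), corpus-weighted character bigram probability, Coltheart's N,
  OLD20/PLD20 (mean Levenshtein distance to the 20 nearest neighbors),
  phoneme/syllable counts, rhyme (rime) categories and pronunciation
  counts over one-character-per-phoneme transcriptions.
* **diagnostics** — per-condition distribution summaries, and the
  matching statistic for a finished list: the SD-scaled Euclidean
  distance over all numeric control variables between every pair of words
  in each matched set (n·k(k−1)/2 observations for n sets over k cells),
  with box-plot summaries and side-by-side list comparison.
* **synthetic lexicons** — no corpus is redistributed; `stimgen.synthetic`
  builds lexicons with chosen marginals, copula-imposed correlations, toy
  transcriptions and *planted* matched sets, so every feature is testable
  offline.

All randomness is seeded: a pipeline plus a seed reproduces a stimulus
list exactly; a new seed yields a fresh list satisfying the same design.

## Worked example

A 2×2 design crossing character bigram probability (low: 0–0.003, high:
0.009–0.013) with concreteness (low: 1–2, high: 4–5), controlling length
exactly and Zipf frequency within ±0.2, restricted to words known by at
least 90% of people, 50 words per cell:

```python
from stimgen import generate, matched_distance_report
from stimgen.synthetic import example_design, example_lexicon

lex = example_lexicon(seed=1)          # ~10,000-word synthetic lexicon
stim = generate(example_design(1), lex, n=50, seed=1)
long = stim.to_long(lex)
print(long.head(8).to_string(index=False))
```

```
 item condition word  is_match_null  bigram_prob  concreteness  length     zipf
    0     A2_B1  nyc           True     0.009768      1.468649     3.0 2.802729
    0     A1_B1  kqa          False     0.001380      1.981797     3.0 2.913499
    0     A1_B2  ghb          False     0.001347      4.754746     3.0 2.951604
    0     A2_B2  olj          False     0.010515      4.306542     3.0 2.818934
    1     A1_B1 wzwr           True     0.002894      1.582129     4.0 4.828173
    1     A1_B2 jagj          False     0.002043      4.340981     4.0 4.888767
    1     A2_B1 dlfa          False     0.010109      1.818262     4.0 4.885347
    1     A2_B2 tfxy          False     0.011728      4.723906     4.0 4.746556
```

Each `item` is one matched set: four words, one per factorial cell
(`A1_B1` = low bigram probability × low concreteness, ... `A2_B2` = high ×
high), identical in length and within ±0.2 Zipf of the set's match-null
word. The full list has 50 sets × 4 conditions = 200 words and
`stim.exhausted` is `False` (the request was met in full).

How tightly is the list matched?

```python
rep = matched_distance_report(stim, lex, ["zipf", "length"])
print(len(rep.distances), rep.summary)
```

```
distance observations: 300
median SD-scaled distance: 0.090 (Q1 0.037, Q3 0.151)
```

300 = 50·4·3/2 pairwise distances; a median of 0.09 SD units means
matched words are nearly interchangeable on the control variables.

The same workflow is available from the shell:

```bash
stimgen simulate --spec synth.yaml --seed 1 --out lexicon.csv
stimgen generate --design design.yaml --lexicon lexicon.csv --n 50 --seed 1 --out stim.csv
stimgen validate --stimuli stim.csv --lexicon lexicon.csv --controls zipf,length --out report.json
```

Every output CSV carries a `#`-comment manifest (tool version, design
hash, seed, input digests) plus a JSON sidecar, so any list can be traced
to the exact specification that produced it.

For bespoke matching — say, replacing "butterfly" in a sentence with a
later-acquired word matched on length (exactly), Zipf (±0.2), concreteness
(±0.25) and part of speech — use `match_word(lex, "butterfly",
{"zipf": (-.2, .2), "concreteness": (-.25, .25)}, ["pos"], ["length"])`
and then `.subset(lex, "aoa", low=9)`; candidates come back nearest-first.

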