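"""Derived lexical, orthographic and phonological variables.

Implements the standard psycholinguistic measures computed from raw lexicon
columns:

* the Zipf word-frequency scale, ``log10(frequency per billion words)``,
  bounded 1–8 for observed words;
* corpus-weighted character bigram probability (a word's mean constituent
  bigram probability under a frequency-weighted bigram distribution);
* orthographic neighborhood sizes — Coltheart's N (words at Hamming
  distance 1) and OLD20 (mean Levenshtein distance to the 20 nearest
  neighbors);
* phonological measures over one-character-per-phoneme transcriptions:
  phoneme and syllable counts, rhyme (rime) category, pronunciation counts,
  and the phonological analogues of the neighborhood measures (PN, PLD20),
  which are the same string operations applied to transcription symbol
  sequences.

Levenshtein distance is unit-cost (insertion / substitution / deletion each
cost 1) and delegated to edlib's banded alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .lexicon import DEFAULT_ALPHABET, Lexicon

logger = logging.getLogger("stimgen")

ZIPF_PER_MILLION_TO_BILLION = 1000.0


# ---------------------------------------------------------------------------
# Lexical: Zipf scale
# ---------------------------------------------------------------------------


def zipf_from_fpmw(fpmw):
    """Zipf frequency from frequency per million words.

    Zipf = log10(frequency per billion words) = log10(fpmw * 1000).
    One occurrence per million maps to 3.0; the scale runs from 1 (10 per
    billion) to 8 (one word in ten) for observed words.

    Accepts a scalar or array.  Non-positive frequencies yield a missing
    value (NaN), logged, never an exception — zero frequency has no finite
    log and no smoothing is applied.
    """
    arr = np.asarray(fpmw, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    bad = ~(arr > 0)
    n_bad = int(np.sum(bad & ~np.isnan(arr)))
    if n_bad:
        logger.info("zipf_from_fpmw: %d non-positive frequencies set missing", n_bad)
    out = np.full(arr.shape, np.nan)
    ok = ~bad
    out[ok] = np.log10(arr[ok] * ZIPF_PER_MILLION_TO_BILLION)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Orthographic: bigram probability
# ---------------------------------------------------------------------------


@dataclass
class BigramTable:
    """Corpus-weighted character-bigram probability distribution.

    ``probs`` holds only pairs observed in the corpus; absent pairs have
    probability 0.  Probabilities sum to 1: the frequency-weighted bigram
    counts are normalized by their total (sum-normalization — min–max
    scaling would not yield probabilities; see ``scaling``).
    """

    probs: dict[str, float]
    source_var: str = ""
    alphabet: str = DEFAULT_ALPHABET
    scaling: str = "sum"

    def __getitem__(self, pair: str) -> float:
        return self.probs.get(pair, 0.0)


def _word_bigrams(word: str) -> list[str]:
    # all adjacent character pairs, repeats counted each time they occur
    return [word[i : i + 2] for i in range(len(word) - 1)]


def build_bigram_table(
    lex: Lexicon,
    freq_var: str,
    alphabet: str = DEFAULT_ALPHABET,
    scaling: str = "sum",
) -> BigramTable:
    """Build a bigram probability table weighted by word frequency.

    Each bigram occurrence in a word contributes that word's frequency
    (fpmw) to the bigram's count; counts are then normalized to a
    probability distribution.  Words containing characters outside
    `alphabet`, or with missing/negative frequency, are skipped.

    ``scaling="minmax"`` is available as a documented alternative (divide by
    the maximum weighted count instead of the total); the default produces a
    true probability distribution.
    """
    if len(lex) == 0:
        raise ValueError("cannot build a bigram table from an empty lexicon")
    allowed = set(alphabet)
    counts: dict[str, float] = {}
    freqs = lex.values(freq_var)
    for word, f in zip(lex.words, freqs):
        if not isinstance(word, str) or not set(word) <= allowed:
            continue
        if not np.isfinite(f) or f < 0:
            continue
        for bg in _word_bigrams(word):
            counts[bg] = counts.get(bg, 0.0) + float(f)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError(f"no usable bigram mass under frequency {freq_var!r}")
    if scaling == "sum":
        denom = total
    elif scaling == "minmax":
        denom = max(counts.values())
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    probs = {bg: c / denom for bg, c in counts.items()}
    return BigramTable(probs, source_var=freq_var, alphabet=alphabet, scaling=scaling)


def word_bigram_probability(word: str, table: BigramTable) -> float:
    """Mean probability of a word's constituent bigrams.

    Words shorter than 2 characters have no bigrams and yield NaN.
    """
    if len(word) < 2:
        return float("nan")
    bgs = _word_bigrams(word)
    return sum(table[bg] for bg in bgs) / len(bgs)


# ---------------------------------------------------------------------------
# Neighborhood measures (orthographic and, on transcriptions, phonological)
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two symbol strings."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def coltheart_n(word: str, neighborhood: Iterable[str]) -> int:
    """Coltheart's N: neighbors at Hamming distance exactly 1.

    Counts entries of equal length differing from `word` in exactly one
    position (a one-character substitution).  The word itself never counts;
    duplicate occurrences in the collection each count.
    """
    L = len(word)
    n = 0
    for cand in neighborhood:
        if len(cand) != L or cand == word:
            continue
        diffs = 0
        for x, y in zip(word, cand):
            if x != y:
                diffs += 1
                if diffs > 1:
                    break
        if diffs == 1:
            n += 1
    return n


def oldn(word: str, neighborhood: Iterable[str], n: int = 20) -> float:
    """Mean Levenshtein distance to the `n` closest neighbors (OLD20/PLD20).

    The target string itself — and any entry identical to it — is excluded:
    otherwise every word has a distance-0 neighbor.  Ties at the n-th
    smallest distance are broken deterministically (distance, then
    lexicographic); the mean is unaffected when tied values are equal.
    Fewer than `n` candidates triggers a warning and a mean over all of
    them; an empty neighborhood yields NaN.
    """
    cands = sorted(c for c in neighborhood if c != word)
    if not cands:
        return float("nan")
    dists = sorted(levenshtein(word, c) for c in cands)
    if len(dists) < n:
        logger.warning(
            "oldn(%r): only %d neighbors available (n=%d); mean over all",
            word,
            len(dists),
            n,
        )
    top = dists[:n]
    return sum(top) / len(top)


# ---------------------------------------------------------------------------
# Phonological measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcription:
    """A phonemic transcription, one symbol per phoneme.

    One-character encodings assign a single ASCII symbol to every phoneme —
    diphthongs and affricates included — so sequence length equals phoneme
    count ('how' -> 'hW', 'china' -> 'CYN@').  Multi-character schemes must
    be converted to this form first.
    """

    phonemes: str
    vowels: frozenset[str] = frozenset()
    inventory: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.inventory:
            extra = set(self.phonemes) - set(self.inventory)
            if extra:
                raise ValueError(f"symbols outside inventory: {sorted(extra)}")
            if not self.vowels <= self.inventory:
                raise ValueError("vowel set must be a subset of the inventory")


def count_phonemes(t: Transcription) -> int:
    """Number of phonemes: the length of the one-symbol-per-phoneme sequence."""
    return len(t.phonemes)


def count_syllables(t: Transcription) -> int:
    """Syllable count: the number of vowel (or diphthong) phonemes."""
    return sum(1 for p in t.phonemes if p in t.vowels)


def rhyme_category(t: Transcription) -> str | None:
    """Rime: phonemes from the final vowel to the end of the word.

    'partake' /pɑteɪk/ belongs to /-eɪk/, shared with 'steak' and 'opaque'.
    Returns None (missing) for a transcription with no vowel symbol.
    """
    for i in range(len(t.phonemes) - 1, -1, -1):
        if t.phonemes[i] in t.vowels:
            return t.phonemes[i:]
    return None


def count_pronunciations(
    word: str, dictionary: Mapping[str, Sequence[str]]
) -> int:
    """Number of pronunciations listed for `word`; 0 when absent.

    Listed entries are counted as given — duplicates are not collapsed,
    since variant stress patterns may share a segmental transcription.
    """
    return len(dictionary.get(word, ()))


# ---------------------------------------------------------------------------
# Bulk column computation
# ---------------------------------------------------------------------------


def append_metrics(
    lex: Lexicon,
    fpmw_var: str | None = None,
    bigram_freq_var: str | None = None,
    neighborhood: bool = False,
    transcription_var: str | None = None,
    vowels: str = "aeiou",
    old_n: int = 20,
) -> Lexicon:
    """Append computed metric columns to a lexicon.

    Adds, as requested: ``zipf`` (from `fpmw_var`), ``bigram_prob`` (table
    weighted by `bigram_freq_var`), ``coltheart_n`` and ``old20`` over the
    lexicon's own word strings, and — when `transcription_var` is given —
    ``n_phonemes``, ``n_syllables``, ``rhyme``, ``pld20`` and ``pn`` from
    the transcription column.
    """
    from .lexicon import NUMERIC, CATEGORICAL, VariableMeta

    df = lex.data.copy()
    metas = list(lex.variables)

    def add(name: str, values, kind: str, units: str = "") -> None:
        df[name] = values
        metas.append(VariableMeta(name, kind, units, source="computed"))

    if fpmw_var is not None:
        add("zipf", zipf_from_fpmw(lex.values(fpmw_var).to_numpy()), NUMERIC, "Zipf")
    if bigram_freq_var is not None:
        table = build_bigram_table(lex, bigram_freq_var)
        add(
            "bigram_prob",
            [word_bigram_probability(w, table) for w in df[lex.word_key]],
            NUMERIC,
        )
    if neighborhood:
        pool = df[lex.word_key].tolist()
        add("coltheart_n", [coltheart_n(w, pool) for w in pool], NUMERIC, "count")
        add("old20", [oldn(w, pool, old_n) for w in pool], NUMERIC, "edits")
    if transcription_var is not None:
        vset = frozenset(vowels)
        trs = [
            Transcription(t, vset) if isinstance(t, str) else None
            for t in df[transcription_var]
        ]
        add(
            "n_phonemes",
            [count_phonemes(t) if t else math.nan for t in trs],
            NUMERIC,
            "count",
        )
        add(
            "n_syllables",
            [count_syllables(t) if t else math.nan for t in trs],
            NUMERIC,
            "count",
        )
        add(
            "rhyme",
            [rhyme_category(t) if t else None for t in trs],
            CATEGORICAL,
        )
        seqs = [t.phonemes if t else None for t in trs]
        pool = [s for s in seqs if s]
        add(
            "pn",
            [coltheart_n(s, pool) if s else math.nan for s in seqs],
            NUMERIC,
            "count",
        )
        add(
            "pld20",
            [oldn(s, pool, old_n) if s else math.nan for s in seqs],
            NUMERIC,
            "edits",
        )
    return Lexicon(df, metas, lex.word_key)
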