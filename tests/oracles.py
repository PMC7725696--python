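"""Independent brute-force oracles, sharing no code with the implementation.

Everything here is written the slow, obvious way: full dynamic-programming
Levenshtein, exhaustive filter-then-sort matching, and exhaustive
backtracking search for matched sets on tiny lexicons.
"""

from __future__ import annotations

import math

import pandas as pd


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def brute_coltheart_n(word: str, pool) -> int:
    n = 0
    for cand in pool:
        if cand == word or len(cand) != len(word):
            continue
        if sum(x != y for x, y in zip(word, cand)) == 1:
            n += 1
    return n


def brute_oldn(word: str, pool, n: int = 20) -> float:
    dists = sorted(dp_levenshtein(word, c) for c in pool if c != word)
    if not dists:
        return math.nan
    top = dists[:n]
    return sum(top) / len(top)


def brute_match_word(
    df: pd.DataFrame,
    target: str,
    numeric_specs: dict,
    categorical_specs=(),
    exact_numeric=(),
    word_col: str = "word",
):
    """Exhaustive filter + SD-scaled distance sort over a plain DataFrame.

    Returns the ordered candidate word list (ties broken lexicographically).
    """
    tgt = df[df[word_col] == target].iloc[0]
    numeric_vars = list(numeric_specs) + list(exact_numeric)
    sds = {}
    for v in numeric_vars:
        sd = df[v].std(ddof=1)
        sds[v] = sd if (sd and sd > 0 and math.isfinite(sd)) else 1.0
    rows = []
    for _, row in df.iterrows():
        if row[word_col] == target:
            continue
        if any(pd.isna(row[v]) for v in numeric_vars + list(categorical_specs)):
            continue
        ok = True
        for v, (lo, hi) in numeric_specs.items():
            if not (tgt[v] + lo <= row[v] <= tgt[v] + hi):
                ok = False
        for v in exact_numeric:
            if row[v] != tgt[v]:
                ok = False
        for v in categorical_specs:
            if row[v] != tgt[v]:
                ok = False
        if not ok:
            continue
        d = math.sqrt(
            sum(((row[v] - tgt[v]) / sds[v]) ** 2 for v in numeric_vars)
        )
        rows.append((d, row[word_col]))
    rows.sort()
    return [w for _, w in rows]


def max_matched_sets(
    df: pd.DataFrame,
    conditions: dict,
    tolerances: dict,
    word_col: str = "word",
) -> int:
    """Maximum number of disjoint matched sets, by exhaustive backtracking.

    `conditions` maps condition label -> list of row indices eligible for
    that condition; `tolerances` maps variable -> (lo, hi) inclusive
    tolerance anchored pairwise symmetrically (|delta| <= min(hi, -lo)).
    Only viable for tiny instances.
    """
    labels = sorted(conditions)

    def compatible(group):
        for var, (lo, hi) in tolerances.items():
            m = min(hi, -lo)
            vals = [df.at[i, var] for i in group]
            if max(vals) - min(vals) > m:
                return False
        return True

    best = 0

    def extend(used: set, count: int):
        nonlocal best
        best = max(best, count)
        # build one more set: choose a row per condition, mutually compatible
        def choose(pos: int, group: list):
            nonlocal best
            if pos == len(labels):
                extend(used | set(group), count + 1)
                return
            for i in conditions[labels[pos]]:
                if i in used or i in group:
                    continue
                if compatible(group + [i]):
                    choose(pos + 1, group + [i])

        choose(0, [])

    extend(set(), 0)
    return best
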