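"""Bespoke single-word matching.

``match_word`` suggests control words for a given target: every lexicon
entry within the stated tolerances on each numeric variable (inclusive,
relative to the target's value), equal on each categorical variable, and
exactly equal on variables named with no interval (e.g. length).  Candidates
are returned ordered by Euclidean distance over the numeric matching
variables, nearest first — the researcher then picks the closest match that
is, say, a plausible replacement in the sentential context.

Distance scaling: raw deltas on variables with different units (characters
vs Zipf) are not commensurable, so each numeric matching variable is
standardized by its standard deviation over the whole lexicon before the
Euclidean distance is computed (the default; ``raw`` and
``tolerance``-width scaling are available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .lexicon import CATEGORICAL, NUMERIC, Lexicon, LexiconError


@dataclass
class MatchCandidateList:
    """Ordered candidate matches for one target word.

    ``candidates`` has one row per candidate: the word, a ``<var>_delta``
    column per numeric matching variable (candidate minus target), and
    ``euclidean_distance``, non-decreasing down the table.
    """

    target: str
    candidates: pd.DataFrame
    numeric_specs: dict[str, tuple[float, float]]
    categorical_specs: tuple[str, ...]
    exact_numeric: tuple[str, ...]
    scaling: str = "sd"

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def words(self) -> list[str]:
        return self.candidates["word"].tolist()

    def subset(
        self,
        lex: Lexicon,
        variable: str,
        low: float | None = None,
        high: float | None = None,
        categories: Iterable[str] | None = None,
    ) -> "MatchCandidateList":
        """Post-hoc filter of the candidate list (order preserved) — e.g.
        keep only late-acquired words after matching."""
        from .lexicon import subset_lexicon

        kept = set(
            subset_lexicon(lex, variable, low, high, categories).words
        )
        df = self.candidates[self.candidates["word"].isin(kept)].reset_index(
            drop=True
        )
        return MatchCandidateList(
            self.target,
            df,
            self.numeric_specs,
            self.categorical_specs,
            self.exact_numeric,
            self.scaling,
        )


def match_word(
    lex: Lexicon,
    target: str,
    numeric_specs: Mapping[str, tuple[float, float]] | None = None,
    categorical_specs: Iterable[str] = (),
    exact_numeric: Iterable[str] = (),
    scaling: str = "sd",
) -> MatchCandidateList:
    """Find candidate matches for `target` within tolerances.

    Parameters
    ----------
    lex
        The lexicon to search.
    target
        Word to match; must be present with non-missing values on every
        named variable.
    numeric_specs
        Mapping variable -> inclusive tolerance ``(lo, hi)`` around the
        target's value, ``lo <= 0 <= hi`` (e.g. ``{"zipf": (-0.2, 0.2)}``).
    categorical_specs
        Variables that must equal the target's category exactly.
    exact_numeric
        Numeric variables named with no interval — exact equality required
        (they still enter the distance with delta 0).
    scaling
        ``"sd"`` (default: per-variable standardization by the lexicon-wide
        SD), ``"raw"``, or ``"tolerance"`` (delta divided by the tolerance
        width; exact variables contribute 0).

    Candidates exclude the target itself; rows missing any named variable
    are excluded.  Ties in distance are broken lexicographically by word.
    """
    numeric_specs = dict(numeric_specs or {})
    categorical_specs = tuple(categorical_specs)
    exact_numeric = tuple(exact_numeric)
    if scaling not in ("sd", "raw", "tolerance"):
        raise ValueError(f"unknown scaling {scaling!r}")

    tgt = lex.entry(target)  # raises if absent
    all_vars = list(numeric_specs) + list(exact_numeric) + list(categorical_specs)
    for v in all_vars:
        kind = lex.kind(v)
        if v in categorical_specs and kind != CATEGORICAL:
            raise LexiconError(f"{v!r} is not categorical")
        if v not in categorical_specs and kind != NUMERIC:
            raise LexiconError(f"{v!r} is not numeric")
        if pd.isna(tgt[v]):
            raise LexiconError(f"target {target!r} missing value on {v!r}")
    for v, (lo, hi) in numeric_specs.items():
        if not (lo <= 0.0 <= hi):
            raise ValueError(f"tolerance for {v!r} must contain 0")

    df = lex.data
    mask = (df[lex.word_key] != target).to_numpy()
    for v in all_vars:
        mask &= df[v].notna().to_numpy()
    for v, (lo, hi) in numeric_specs.items():
        col = df[v].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mask &= (col >= tgt[v] + lo) & (col <= tgt[v] + hi)
    for v in exact_numeric:
        with np.errstate(invalid="ignore"):
            mask &= df[v].to_numpy(dtype=float) == float(tgt[v])
    for v in categorical_specs:
        mask &= (df[v] == tgt[v]).to_numpy()

    numeric_vars = list(numeric_specs) + list(exact_numeric)
    cand = df[mask]
    deltas = {
        v: cand[v].to_numpy(dtype=float) - float(tgt[v]) for v in numeric_vars
    }
    dist2 = np.zeros(len(cand))
    for v in numeric_vars:
        d = deltas[v]
        if scaling == "sd":
            sd = float(df[v].std(ddof=1))
            scale = sd if sd > 0 and math.isfinite(sd) else 1.0
        elif scaling == "tolerance":
            lo, hi = numeric_specs.get(v, (0.0, 0.0))
            width = hi - lo
            scale = width if width > 0 else math.inf  # exact vars contribute 0
        else:
            scale = 1.0
        dist2 += (d / scale) ** 2

    out = pd.DataFrame({"word": cand[lex.word_key].to_numpy()})
    for v in numeric_vars:
        out[f"{v}_delta"] = deltas[v]
    out["euclidean_distance"] = np.sqrt(dist2)
    out = out.sort_values(
        ["euclidean_distance", "word"], kind="mergesort"
    ).reset_index(drop=True)
    return MatchCandidateList(
        target, out, numeric_specs, categorical_specs, exact_numeric, scaling
    )
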