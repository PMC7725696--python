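"""The matched-set generation algorithm.

Given a factorial design and a lexicon, builds matched sets of k words (one
per condition) such that every word fits its condition's split levels and
every control variable is matched item-wise within tolerance.

The algorithm mirrors the published procedure:

1. Match-null conditions are allocated up front — pseudo-randomly, so each
   condition anchors an equal share of sets in random order (counts differ
   by at most 1 when the request is not divisible by k, with the
   over-represented conditions chosen at random).
2. Each iteration draws a random untried word from the current match-null
   condition, then identifies, per other condition, the pool of unused
   words matched to it on every control variable; one word is drawn
   uniformly from each pool (no greedy optimization of closeness).
3. If any condition's pool is empty, the iteration is discarded and another
   untried null word from the same condition is drawn.  Words consumed by
   failed iterations return to the pool — only successful sets consume
   words — but a failed null word is not retried as a null this run.
4. On success the set is stored and the next match-null condition is
   attempted, until the requested count is reached, the null condition runs
   out of untried words (partial result, ``exhausted=True``, with a
   warning — never a silent truncation), or, in "all" mode, until no
   further matched set can be generated.

Under the ``inclusive`` policy, every pair of words in a set must satisfy
every control pairwise, not just null-versus-rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    Control,
    DesignSpec,
    MapControl,
    RandomSplit,
    _apply_filters,
    enumerate_conditions,
)
from .lexicon import Lexicon

logger = logging.getLogger("stimgen")

ALL = "all"


# ---------------------------------------------------------------------------
# Output containers
# ---------------------------------------------------------------------------


@dataclass
class StimulusSet:
    """One matched set: exactly one word per condition, anchored at the
    match-null condition's word."""

    set_id: int
    words: dict[str, str]
    match_null: str


@dataclass
class StimulusList:
    """A generated stimulus list.

    ``exhausted`` is True when generation stopped because no further
    matched set could be built (always True in "all" mode, and in n-mode
    when fewer than n sets were found).
    """

    sets: list[StimulusSet]
    design: DesignSpec | None
    seed: int
    exhausted: bool = False
    random_levels: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def conditions(self) -> list[str]:
        """Condition labels — from the design, or (for a list reloaded
        without one, e.g. from CSV) the labels observed in the sets."""
        if self.design is not None:
            return enumerate_conditions(self.design)
        return sorted({c for s in self.sets for c in s.words})

    def to_long(self, lex: Lexicon | None = None) -> pd.DataFrame:
        """Canonical long format: one row per word with set id, condition,
        word, match-null flag — plus all split/control variable values when
        a lexicon is supplied, for auditability."""
        rows = []
        for s in self.sets:
            suffix = self.random_levels.get(s.set_id, "")
            for cond, word in s.words.items():
                label = f"{cond}_{suffix}" if suffix else cond
                rows.append(
                    {
                        "item": s.set_id,
                        "condition": label,
                        "word": word,
                        "is_match_null": cond == s.match_null,
                    }
                )
        df = pd.DataFrame(
            rows, columns=["item", "condition", "word", "is_match_null"]
        )
        if lex is not None and not df.empty:
            aud_vars = audit_variables(self.design)
            cols = [lex.word_key] + [v for v in aud_vars if v in lex.data.columns]
            df = df.merge(
                lex.data[cols], left_on="word", right_on=lex.word_key, how="left"
            )
            if lex.word_key != "word":
                df = df.drop(columns=[lex.word_key])
        return df

    def to_wide(self) -> pd.DataFrame:
        """One row per set, one column per condition (a view of the long form)."""
        rows = []
        for s in self.sets:
            row = {"item": s.set_id, "match_null": s.match_null}
            row.update(s.words)
            rows.append(row)
        return pd.DataFrame(rows)


def audit_variables(spec: DesignSpec) -> list[str]:
    out = [s.variable for s in spec.fixed_splits]
    out += [c.variable for c in spec.controls if isinstance(c, Control)]
    return out


# ---------------------------------------------------------------------------
# Match-null allocation
# ---------------------------------------------------------------------------


def allocate_match_nulls(
    n: int,
    conditions: Sequence[str],
    policy: str,
    rng: np.random.Generator,
) -> list[str]:
    """Allocate the match-null condition for each of ``n`` sets.

    ``balanced`` (and ``inclusive``, which only changes constraint
    checking): each condition appears floor(n/k) or ceil(n/k) times — the
    over-represented conditions are chosen at random — and the sequence
    order is random.  ``fixed:<cond>``: constant.  ``random_per_set``:
    i.i.d. uniform.
    """
    conditions = list(conditions)
    k = len(conditions)
    if n == 0:
        return []
    if policy.startswith("fixed:"):
        cond = policy.split(":", 1)[1]
        if cond not in conditions:
            raise ValueError(f"fixed match-null condition {cond!r} not in design")
        return [cond] * n
    if policy == "random_per_set":
        return [conditions[i] for i in rng.integers(0, k, size=n)]
    # balanced / inclusive
    base, extra = divmod(n, k)
    counts = np.full(k, base)
    if extra:
        counts[rng.choice(k, size=extra, replace=False)] += 1
    seq = np.repeat(np.arange(k), counts)
    rng.shuffle(seq)
    return [conditions[i] for i in seq]


# ---------------------------------------------------------------------------
# Candidate pools
# ---------------------------------------------------------------------------


class _Pools:
    """Vectorized eligibility state for one generation run."""

    def __init__(self, spec: DesignSpec, lex: Lexicon):
        self.spec = spec
        self.lex = lex
        self.df = lex.data
        self.n = len(self.df)
        eligible = _apply_filters(lex, spec.filters).to_numpy()
        # non-missing on every plain control variable
        for c in spec.controls:
            if isinstance(c, Control):
                eligible &= self.df[c.variable].notna().to_numpy()
        # vectorized condition assignment (level disjointness => unique)
        parts = np.full(self.n, "", dtype=object)
        in_design = eligible.copy()
        for s in spec.fixed_splits:
            letter = spec.split_letter(s)
            idx = np.full(self.n, -1)
            if s.is_numeric:
                vals = self.df[s.variable].to_numpy(dtype=float)
                for i, lev in enumerate(s.levels):
                    with np.errstate(invalid="ignore"):
                        idx[(vals >= lev.low) & (vals <= lev.high)] = i
            else:
                vals = self.df[s.variable].to_numpy(dtype=object)
                for i, lev in enumerate(s.levels):
                    idx[np.isin(vals, list(lev))] = i
            in_design &= idx >= 0
            lab = np.array([f"{letter}{i + 1}" for i in range(len(s.levels))] + [""])
            sep = "_" if s is not spec.fixed_splits[0] else ""
            parts = np.array(
                [p + (sep + lab[i] if i >= 0 else "") for p, i in zip(parts, idx)],
                dtype=object,
            )
        cond = np.where(in_design, parts, None)
        self.condition = cond
        self.cond_masks = {
            lab: (cond == lab) for lab in enumerate_conditions(spec)
        }
        self.used = np.zeros(self.n, dtype=bool)
        self.ctrl_arrays = {
            c.variable: self.df[c.variable].to_numpy()
            for c in spec.controls
            if isinstance(c, Control)
        }

    def eligible_indices(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.cond_masks[condition] & ~self.used)

    def matched_to(
        self, condition: str, anchors: list[int], symmetric: bool = False
    ) -> np.ndarray:
        """Indices in `condition`, unused, within every control tolerance of
        every anchor row (one anchor for null-based policies; all chosen
        words so far under the inclusive policy).

        With ``symmetric=True`` (inclusive policy) an asymmetric tolerance
        [lo, hi] must hold in both orientations of the pair, i.e.
        |delta| <= min(hi, -lo) — pairwise matching has no anchor to orient
        the interval."""
        mask = self.cond_masks[condition] & ~self.used
        for c in self.spec.controls:
            if isinstance(c, Control):
                col = self.ctrl_arrays[c.variable]
                for a in anchors:
                    av = col[a]
                    if c.tolerance is None:
                        mask = mask & (col == av)
                    else:
                        lo, hi = c.tolerance
                        if symmetric:
                            m = min(hi, -lo)
                            lo, hi = -m, m
                        with np.errstate(invalid="ignore"):
                            mask = mask & (col >= av + lo) & (col <= av + hi)
        idx = np.flatnonzero(mask)
        map_controls = [c for c in self.spec.controls if isinstance(c, MapControl)]
        if map_controls and len(idx):
            keep = []
            for i in idx:
                row = self.df.iloc[i]
                ok = all(
                    mc.tolerance[0] <= mc.distance(self.df.iloc[a], row) <= mc.tolerance[1]
                    for mc in map_controls
                    for a in anchors
                )
                if ok:
                    keep.append(i)
            idx = np.array(keep, dtype=int)
        return idx


def candidate_pool(
    condition: str,
    spec: DesignSpec,
    lex: Lexicon,
    used: set[str] = frozenset(),
) -> pd.DataFrame:
    """Entries eligible for `condition`: pass all filters, belong to the
    condition's split levels, are not in `used`, and have non-missing
    values on every control variable."""
    pools = _Pools(spec, lex)
    if used:
        pools.used = lex.words.isin(list(used)).to_numpy()
    return lex.data.iloc[pools.eligible_indices(condition)]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _build_set(
    null_cond: str,
    pools: _Pools,
    spec: DesignSpec,
    conditions: list[str],
    rng: np.random.Generator,
    tried_nulls: set[int],
) -> dict[str, int] | None:
    """Attempt one matched set anchored at `null_cond`.

    Returns condition -> row index on success; None once every untried null
    word is exhausted.  Failed null words are added to `tried_nulls`.
    """
    inclusive = spec.match_null_policy == "inclusive"
    while True:
        null_candidates = np.array(
            [i for i in pools.eligible_indices(null_cond) if i not in tried_nulls]
        )
        if len(null_candidates) == 0:
            return None
        null_idx = int(rng.choice(null_candidates))
        chosen = {null_cond: null_idx}
        ok = True
        for cond in conditions:
            if cond == null_cond:
                continue
            anchors = list(chosen.values()) if inclusive else [null_idx]
            pool = pools.matched_to(cond, anchors, symmetric=inclusive)
            pool = pool[~np.isin(pool, list(chosen.values()))]
            if len(pool) == 0:
                ok = False
                break
            chosen[cond] = int(rng.choice(pool))
        if ok:
            return chosen
        tried_nulls.add(null_idx)  # discard iteration; null word not retried


def generate(
    spec: DesignSpec,
    lex: Lexicon,
    n: int | str = ALL,
    seed: int | None = None,
) -> StimulusList:
    """Generate a matched stimulus list.

    Parameters
    ----------
    spec
        The factorial design (splits, controls, filters, match-null policy).
    lex
        Candidate lexicon.
    n
        Number of matched sets per condition to request, or ``"all"`` to
        generate items until no further matched set can be built.
    seed
        Overrides ``spec.seed`` when given.  Identical (spec, lexicon, n,
        seed) yield bit-identical output.

    Returns a :class:`StimulusList` of up to n sets (n·k words in long
    form).  A shortfall is reported through ``exhausted=True`` plus a
    logged warning, never silently.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    conditions = enumerate_conditions(spec)
    pools = _Pools(spec, lex)

    empty = [c for c in conditions if not pools.cond_masks[c].any()]
    if empty:
        logger.warning(
            "condition(s) with zero eligible words: %s — empty result",
            ", ".join(empty),
        )
        return StimulusList([], spec, seed, exhausted=True)

    exhaustive = n == ALL
    if exhaustive:
        nulls = iter(_cycled_nulls(conditions, spec.match_null_policy, rng))
    else:
        nulls = iter(allocate_match_nulls(int(n), conditions, spec.match_null_policy, rng))

    sets: list[StimulusSet] = []
    tried_nulls: dict[str, set[int]] = {c: set() for c in conditions}
    exhausted = False
    for null_cond in nulls:
        chosen = _build_set(
            null_cond, pools, spec, conditions, rng, tried_nulls[null_cond]
        )
        if chosen is None:
            exhausted = True
            if not exhaustive:
                logger.warning(
                    "requested %s sets but only %d could be generated "
                    "(match-null condition %s exhausted)",
                    n,
                    len(sets),
                    null_cond,
                )
            break
        for idx in chosen.values():
            pools.used[idx] = True
        words = {c: str(pools.df.iloc[i][lex.word_key]) for c, i in chosen.items()}
        sets.append(StimulusSet(len(sets), words, null_cond))
    else:
        exhausted = exhaustive  # n-mode completed in full
    return StimulusList(sets, spec, seed, exhausted=exhausted)


def _cycled_nulls(conditions, policy, rng):
    """Endless match-null stream for "all" mode: balanced shuffled blocks
    (or the degenerate streams for fixed / random_per_set policies)."""
    k = len(conditions)
    if policy.startswith("fixed:"):
        cond = policy.split(":", 1)[1]
        while True:
            yield cond
    while True:
        if policy == "random_per_set":
            yield conditions[int(rng.integers(0, k))]
        else:
            order = rng.permutation(k)
            for i in order:
                yield conditions[i]


def generate_random_split_assignment(
    slist: StimulusList, rs: RandomSplit, rng: np.random.Generator
) -> StimulusList:
    """Assign each matched set one level of a random split, balanced as
    integer counts allow (the over-represented level is random), and record
    it as an extra condition-label component."""
    if len(slist) == 0:
        raise ValueError("cannot assign random-split levels to an empty list")
    if rs in slist.design.splits:
        letter = slist.design.split_letter(rs)
    else:
        letter = chr(ord("A") + len(slist.design.splits))
    labels = [f"{letter}{i + 1}" for i in range(rs.n_levels)]
    assignment = allocate_match_nulls(len(slist), labels, "balanced", rng)
    random_levels = dict(slist.random_levels)
    for s, lab in zip(slist.sets, assignment):
        prev = random_levels.get(s.set_id, "")
        random_levels[s.set_id] = f"{prev}_{lab}" if prev else lab
    return StimulusList(
        slist.sets, slist.design, slist.seed, slist.exhausted, random_levels
    )
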