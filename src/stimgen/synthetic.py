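"""Synthetic lexicons with controlled distributions and planted structure.

No corpus ships with this package, so every test and example runs on
generated lexicons.  :func:`make_lexicon` produces unique word strings with
a chosen length distribution, numeric variables with arbitrary marginals
coupled through a Gaussian copula to hit a target correlation matrix
(psycholinguistic variables are routinely skewed and intercorrelated —
e.g. familiarity-type ratings pile up at the high end), categorical
variables, and a toy one-symbol-per-phoneme transcription column.

:func:`plant_matched_sets` injects guaranteed-feasible matched sets for a
given factorial design: groups of k words, one per condition, mutually
within every control tolerance, recorded in hidden ``_planted_*`` audit
columns.  This makes generator success a testable property instead of a
matter of luck.

Toy transcriptions map each letter to itself except the vowels a, e, i, o,
u, which map to dedicated vowel symbols — enough for the phoneme-sequence
metrics, with no pretense of phonotactic realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, Control, MapControl, Filter, Split, enumerate_conditions
from .lexicon import CATEGORICAL, NUMERIC, Lexicon, VariableMeta

logger = logging.getLogger("stimgen")

#: audit columns recording planted structure (underscore prefix = not a variable)
PLANTED_SET = "_planted_set"
PLANTED_CONDITION = "_planted_condition"


@dataclass(frozen=True)
class NumericVar:
    """Marginal specification for one synthetic numeric variable.

    ``dist`` is a scipy.stats name among {normal, lognormal, uniform,
    beta}; ``params`` are its shape parameters; ``low``/``high`` truncate
    the marginal to a closed interval (ratings live on bounded scales).
    """

    name: str
    dist: str = "normal"
    params: tuple[float, ...] = (0.0, 1.0)
    low: float | None = None
    high: float | None = None

    def frozen(self):
        if self.dist == "normal":
            loc, scale = self.params
            return stats.norm(loc, scale)
        if self.dist == "lognormal":
            s, scale = self.params
            return stats.lognorm(s, scale=scale)
        if self.dist == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        if self.dist == "beta":
            a, b = self.params
            lo = self.low if self.low is not None else 0.0
            hi = self.high if self.high is not None else 1.0
            return stats.beta(a, b, loc=lo, scale=hi - lo)
        raise ValueError(f"unknown marginal {self.dist!r}")


@dataclass(frozen=True)
class CategoricalVar:
    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ValueError("categories and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")


@dataclass
class SynthSpec:
    """Full recipe for a synthetic lexicon."""

    n_words: int = 1000
    numeric_vars: tuple[NumericVar, ...] = ()
    correlation: np.ndarray | None = None
    categorical_vars: tuple[CategoricalVar, ...] = ()
    length_dist: dict[int, float] = field(
        default_factory=lambda: {3: 0.15, 4: 0.2, 5: 0.25, 6: 0.2, 7: 0.12, 8: 0.08}
    )
    alphabet: str = "abcdefghijklmnopqrstuvwxyz"
    vowel_symbols: str = "AEIOU"
    transcription_var: str | None = "transcription"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length distribution must sum to 1")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            p = len(self.numeric_vars)
            if C.shape != (p, p):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")
            self.correlation = C


# ---------------------------------------------------------------------------
# Word strings and transcriptions
# ---------------------------------------------------------------------------


def _unique_words(spec: SynthSpec, rng: np.random.Generator) -> list[str]:
    lengths = np.array(sorted(spec.length_dist))
    probs = np.array([spec.length_dist[l] for l in lengths])
    # capacity check: expected demand per length vs available strings
    for l, p in zip(lengths, probs):
        if spec.n_words * p > len(spec.alphabet) ** l:
            raise ValueError(
                f"cannot draw ~{spec.n_words * p:.0f} unique words of length {l} "
                f"from a {len(spec.alphabet)}-letter alphabet"
            )
    letters = np.array(list(spec.alphabet))
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < spec.n_words:
        attempts += 1
        if attempts > 200 * spec.n_words:
            raise ValueError("could not generate enough unique word strings")
        L = int(rng.choice(lengths, p=probs))
        w = "".join(rng.choice(letters, size=L))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


def toy_transcription(word: str, vowel_symbols: str = "AEIOU") -> str:
    """Fixed one-letter -> one-phoneme map: vowels a,e,i,o,u become the
    corresponding symbol in `vowel_symbols`; consonants map to themselves."""
    table = dict(zip("aeiou", vowel_symbols))
    return "".join(table.get(ch, ch) for ch in word)


# ---------------------------------------------------------------------------
# Lexicon synthesis
# ---------------------------------------------------------------------------


def make_lexicon(spec: SynthSpec) -> Lexicon:
    """Generate a lexicon from a :class:`SynthSpec`, deterministically under
    its seed.

    Numeric columns hit the target correlation matrix through a Gaussian
    copula: correlated standard normals are pushed through their CDF and
    then each marginal's quantile function (truncated to its bounds), so
    rank correlations survive arbitrary marginal shapes.  A ``length``
    column (actual string length) is always included.
    """
    rng = np.random.default_rng(spec.seed)
    words = _unique_words(spec, rng)
    n = spec.n_words
    df = pd.DataFrame({"word": words})
    metas: list[VariableMeta] = []

    p = len(spec.numeric_vars)
    if p:
        C = spec.correlation if spec.correlation is not None else np.eye(p)
        # tiny jitter keeps a semidefinite matrix factorizable
        L = np.linalg.cholesky(C + 1e-12 * np.eye(p))
        Z = rng.standard_normal((n, p)) @ L.T
        U = stats.norm.cdf(Z)
        for j, nv in enumerate(spec.numeric_vars):
            marg = nv.frozen()
            lo = marg.cdf(nv.low) if nv.low is not None else 0.0
            hi = marg.cdf(nv.high) if nv.high is not None else 1.0
            u = lo + U[:, j] * (hi - lo)
            df[nv.name] = marg.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            metas.append(VariableMeta(nv.name, NUMERIC, source="synthetic"))

    for cv in spec.categorical_vars:
        df[cv.name] = rng.choice(cv.categories, size=n, p=cv.probs)
        metas.append(VariableMeta(cv.name, CATEGORICAL, source="synthetic"))

    df["length"] = df["word"].str.len().astype(float)
    metas.append(VariableMeta("length", NUMERIC, "characters", "computed"))

    if spec.transcription_var:
        df[spec.transcription_var] = [
            toy_transcription(w, spec.vowel_symbols) for w in words
        ]
        metas.append(
            VariableMeta(spec.transcription_var, CATEGORICAL, source="synthetic")
        )
    return Lexicon(df, metas, "word")


# ---------------------------------------------------------------------------
# Planted matched sets
# ---------------------------------------------------------------------------


def _is_length_column(lex: Lexicon, var: str) -> bool:
    col = lex.data[var]
    return bool((col == lex.words.str.len()).all())


def _interval_draw(rng, low, high, filt: Filter | None):
    if filt is not None:
        if filt.low is not None:
            low = max(low, filt.low)
        if filt.high is not None:
            high = min(high, filt.high)
    if low > high:
        raise ValueError("filter contradicts a split/control interval")
    return rng.uniform(low, high)


def plant_matched_sets(
    lex: Lexicon,
    design: DesignSpec,
    n_sets: int,
    rng: np.random.Generator | int = 0,
) -> Lexicon:
    """Inject `n_sets` guaranteed-valid matched sets for `design`.

    For each set, k unused rows are chosen (rows of equal word length when
    a control column equals the actual string length, so the table stays
    self-consistent) and their values rewritten: split variables land
    inside each condition's level, numeric control values are set equal
    across the set (equality satisfies any tolerance containing 0, null-
    anchored or pairwise), categorical controls get one shared category,
    and filter variables are moved inside their filter windows.  The
    planted assignment is recorded in hidden audit columns
    ``_planted_set`` / ``_planted_condition``.

    Map controls cannot be planted (word strings are not rewritten); a
    design containing one is rejected.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if any(isinstance(c, MapControl) for c in design.controls):
        raise NotImplementedError("cannot plant sets for map controls")
    conditions = enumerate_conditions(design)
    k = len(conditions)
    df = lex.data.copy()
    if PLANTED_SET not in df.columns:
        df[PLANTED_SET] = np.nan
        df[PLANTED_CONDITION] = None

    filt_by_var = {f.variable: f for f in design.filters}
    plain_controls = [c for c in design.controls if isinstance(c, Control)]
    length_controls = [
        c.variable for c in plain_controls if _is_length_column(lex, c.variable)
    ]

    free = df[PLANTED_SET].isna()
    by_length: dict[float, list[int]] = {}
    if length_controls:
        for i in df.index[free]:
            by_length.setdefault(len(df.at[i, lex.word_key]), []).append(i)
    free_idx = list(df.index[free])
    rng.shuffle(free_idx)

    for set_id in range(n_sets):
        if length_controls:
            # a length with at least k unused rows
            avail = [(L, ids) for L, ids in by_length.items() if len(ids) >= k]
            if not avail:
                raise ValueError(
                    f"not enough same-length rows to plant set {set_id}"
                )
            L, ids = avail[int(rng.integers(len(avail)))]
            pick = [ids.pop() for _ in range(k)]
        else:
            if len(free_idx) < k:
                raise ValueError(f"not enough free rows to plant set {set_id}")
            pick = [free_idx.pop() for _ in range(k)]

        # shared control values
        shared: dict[str, object] = {}
        for c in plain_controls:
            if c.variable in length_controls:
                continue
            col = df[c.variable]
            if c.tolerance is None:
                cats = col.dropna().unique()
                shared[c.variable] = cats[int(rng.integers(len(cats)))]
            else:
                lo = float(col.min())
                hi = float(col.max())
                shared[c.variable] = _interval_draw(
                    rng, lo, hi, filt_by_var.get(c.variable)
                )

        for cond, row_i in zip(conditions, pick):
            for var, val in shared.items():
                df.at[row_i, var] = val
            # split variables into this condition's levels
            for s in design.fixed_splits:
                letter = design.split_letter(s)
                part = next(p for p in cond.split("_") if p[0] == letter)
                level = s.levels[int(part[1:]) - 1]
                if s.is_numeric:
                    df.at[row_i, s.variable] = _interval_draw(
                        rng, level.low, level.high, filt_by_var.get(s.variable)
                    )
                else:
                    opts = sorted(level)
                    df.at[row_i, s.variable] = opts[int(rng.integers(len(opts)))]
            # remaining filter variables inside their windows
            for f in design.filters:
                if any(s.variable == f.variable for s in design.fixed_splits):
                    continue
                if any(c.variable == f.variable for c in plain_controls):
                    continue
                if f.categories is not None:
                    df.at[row_i, f.variable] = f.categories[0]
                else:
                    col = df[f.variable]
                    lo = f.low if f.low is not None else float(col.min())
                    hi = f.high if f.high is not None else float(col.max())
                    df.at[row_i, f.variable] = rng.uniform(lo, hi)
            df.at[row_i, PLANTED_SET] = set_id
            df.at[row_i, PLANTED_CONDITION] = cond
    return Lexicon(df, list(lex.variables), lex.word_key)


def planted_assignment(lex: Lexicon) -> pd.DataFrame:
    """The hidden planted structure as (set, condition, word) rows."""
    df = lex.data
    mask = df[PLANTED_SET].notna()
    out = df.loc[mask, [PLANTED_SET, PLANTED_CONDITION, lex.word_key]].copy()
    out.columns = ["item", "condition", "word"]
    out["item"] = out["item"].astype(int)
    return out.sort_values(["item", "condition"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# The worked 2x2 example (bigram probability x concreteness)
# ---------------------------------------------------------------------------


def example_design(seed: int = 0) -> DesignSpec:
    """The worked 2x2 factorial design: character bigram probability
    (low 0–0.003 vs high 0.009–0.013) crossed with concreteness rating
    (low 1–2 vs high 4–5), controlling word length exactly and Zipf
    frequency within ±0.2, over words at least 90% of people know."""
    from .design import LevelInterval

    return DesignSpec(
        splits=(
            Split(
                "bigram_prob",
                (LevelInterval(0.0, 0.003), LevelInterval(0.009, 0.013)),
            ),
            Split("concreteness", (LevelInterval(1.0, 2.0), LevelInterval(4.0, 5.0))),
        ),
        controls=(
            Control("length", (0.0, 0.0)),
            Control("zipf", (-0.2, 0.2)),
        ),
        filters=(Filter("prop_known", low=0.9),),
        match_null_policy="balanced",
        seed=seed,
    )


def example_lexicon(seed: int = 0, n_words: int = 10_000, n_planted: int = 60) -> Lexicon:
    """A synthetic lexicon sized and shaped for the worked 2x2 design.

    ~10,000 unique words with bigram-probability and concreteness values
    covering both bins of each split, Zipf frequencies on the observed 1–8
    scale, a proportion-known variable skewed toward 1 (most words are
    known to most people), and `n_planted` planted matched sets so a
    50-per-cell request is feasible by construction.
    """
    spec = SynthSpec(
        n_words=n_words,
        numeric_vars=(
            NumericVar("bigram_prob", "uniform", (0.0, 0.013)),
            NumericVar("concreteness", "uniform", (1.0, 5.0)),
            NumericVar("zipf", "normal", (4.0, 1.0), low=1.0, high=8.0),
            NumericVar("prop_known", "beta", (5.0, 1.0), low=0.0, high=1.0),
        ),
        # knowing a word tracks how frequent it is; the rest uncorrelated
        correlation=np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.4],
                [0.0, 0.0, 0.4, 1.0],
            ]
        ),
        categorical_vars=(
            CategoricalVar("pos", ("noun", "verb", "adjective"), (0.6, 0.25, 0.15)),
        ),
        seed=seed,
    )
    lex = make_lexicon(spec)
    return plant_matched_sets(
        lex, example_design(seed), n_planted, np.random.default_rng(seed + 1)
    )
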