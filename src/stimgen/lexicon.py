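"""Tabular lexicon container, I/O, and dataset-hygiene filters.

A :class:`Lexicon` wraps a :class:`pandas.DataFrame` with one row per unique
word string plus typed variable columns (numeric ratings/frequencies, or
categorical labels such as part of speech).  Variables are declared through
:class:`VariableMeta`; the declared kind decides which design roles a variable
may take (numeric -> interval splits and tolerance controls, categorical ->
set splits and exact-equality controls).

Missing values are first-class: any downstream computation that needs a
variable skips entries where it is missing rather than erroring, because
merged lexical databases have sparse coverage by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stimgen")

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: default alphabet against which "non-alphabetic" is judged
DEFAULT_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: word forms longer than this many characters are dropped by filter_wordforms
DEFAULT_MAX_LENGTH = 28


class LexiconError(ValueError):
    """Structural problem with a lexicon (duplicates, missing columns...)."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one lexicon column.

    Parameters
    ----------
    name
        Column name in the lexicon table.
    kind
        ``"numeric"`` or ``"categorical"``.
    units
        Free-text unit tag, e.g. ``"Zipf"``, ``"fpmw"``, ``"rating 1-7"``.
    source
        Free-text provenance tag.
    """

    name: str
    kind: str
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, CATEGORICAL):
            raise LexiconError(
                f"variable {self.name!r}: kind must be "
                f"'numeric' or 'categorical', got {self.kind!r}"
            )


@dataclass
class Lexicon:
    """A table of word entries keyed by a unique word string.

    Attributes
    ----------
    data
        One row per word.  Numeric variable columns are float dtype with NaN
        for missing; categorical columns are object dtype with NaN/None for
        missing.  Columns without a :class:`VariableMeta` are carried along
        but cannot be used in designs.
    variables
        Declared variable metadata.
    word_key
        Name of the column holding the unique word strings.
    """

    data: pd.DataFrame
    variables: list[VariableMeta] = field(default_factory=list)
    word_key: str = "word"

    def __post_init__(self) -> None:
        if self.word_key not in self.data.columns:
            raise LexiconError(f"word_key column {self.word_key!r} not in table")
        words = self.data[self.word_key]
        dup = words[words.duplicated()].unique().tolist()
        if dup:
            shown = ", ".join(map(repr, dup[:10]))
            raise LexiconError(f"duplicate word strings: {shown}")
        for v in self.variables:
            if v.name not in self.data.columns:
                raise LexiconError(f"declared variable {v.name!r} not in table")
        self.data = self.data.reset_index(drop=True)

    # -- introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def words(self) -> pd.Series:
        return self.data[self.word_key]

    def meta(self, name: str) -> VariableMeta:
        for v in self.variables:
            if v.name == name:
                return v
        raise LexiconError(f"unknown variable {name!r}")

    def kind(self, name: str) -> str:
        return self.meta(name).kind

    def has_variable(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def entry(self, word: str) -> pd.Series:
        hit = self.data[self.data[self.word_key] == word]
        if hit.empty:
            raise LexiconError(f"word {word!r} not in lexicon")
        return hit.iloc[0]

    def values(self, var: str) -> pd.Series:
        """Column of `var`, indexed like ``data``."""
        self.meta(var)
        return self.data[var]

    def with_data(self, data: pd.DataFrame) -> "Lexicon":
        return replace(self, data=data.reset_index(drop=True))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_meta(df: pd.DataFrame, word_key: str) -> list[VariableMeta]:
    metas = []
    for col in df.columns:
        if col == word_key or col.startswith("_"):
            continue
        kind = NUMERIC if pd.api.types.is_numeric_dtype(df[col]) else CATEGORICAL
        metas.append(VariableMeta(col, kind))
    return metas


def read_variable_meta(path: str | Path) -> list[VariableMeta]:
    """Read a YAML sidecar declaring kind/units/source per column.

    Format::

        variables:
          - {name: zipf, kind: numeric, units: Zipf, source: synthetic}
          - {name: pos, kind: categorical}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        VariableMeta(
            d["name"], d["kind"], d.get("units", ""), d.get("source", "")
        )
        for d in doc["variables"]
    ]


def write_variable_meta(variables: Sequence[VariableMeta], path: str | Path) -> None:
    doc = {
        "variables": [
            {"name": v.name, "kind": v.kind, "units": v.units, "source": v.source}
            for v in variables
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_lexicon(
    path: str | Path,
    format: str | None = None,
    meta: Sequence[VariableMeta] | str | Path | None = None,
    word_key: str = "word",
    lowercase: bool = True,
) -> Lexicon:
    """Load a delimited lexicon table.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.  Lines starting with ``#``
        (reproducibility headers) are ignored.
    format
        ``"csv"`` or ``"tsv"``; inferred from the suffix when omitted.
    meta
        Variable declarations: a list of :class:`VariableMeta`, the path of a
        YAML sidecar, or None to infer kinds from the column dtypes.
    word_key
        Name of the unique word-string column; its absence is a hard error.
    lowercase
        Normalize word strings to lowercase once at load time.  All later
        comparisons are case-sensitive; silent case mismatch is a common
        stimulus-prep bug, so normalization happens exactly here.

    Cells declared numeric that fail to parse become missing, with a logged
    count.  Duplicate word strings are a hard error naming the duplicates.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    if word_key not in df.columns:
        raise LexiconError(f"word_key column {word_key!r} missing from {path}")
    df = df.replace({"": np.nan})
    if lowercase:
        df[word_key] = df[word_key].str.lower()
        logger.info("word strings lowercased at load (case policy: lowercase, a-z)")

    if meta is None:
        # parse every non-word column numerically; columns that parse in full
        # (ignoring missing) are numeric, the rest categorical
        metas = []
        for col in df.columns:
            if col == word_key:
                continue
            parsed = pd.to_numeric(df[col], errors="coerce")
            if parsed.notna().sum() == df[col].notna().sum():
                df[col] = parsed
                metas.append(VariableMeta(col, NUMERIC))
            else:
                metas.append(VariableMeta(col, CATEGORICAL))
        meta_list = metas
    else:
        if isinstance(meta, (str, Path)):
            meta_list = read_variable_meta(meta)
        else:
            meta_list = list(meta)
        for v in meta_list:
            if v.name not in df.columns:
                raise LexiconError(f"declared variable {v.name!r} not in {path}")
            if v.kind == NUMERIC:
                parsed = pd.to_numeric(df[v.name], errors="coerce")
                bad = int((parsed.isna() & df[v.name].notna()).sum())
                if bad:
                    logger.warning(
                        "%d unparseable numeric cell(s) in %r set to missing",
                        bad,
                        v.name,
                    )
                df[v.name] = parsed
    return Lexicon(df, meta_list, word_key)


def write_lexicon(
    lex: Lexicon,
    path: str | Path,
    format: str | None = None,
    header_comment: str | None = None,
) -> None:
    """Write the lexicon as CSV/TSV, optionally with ``#`` header lines."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[format]
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # pandas' default float repr is the shortest string that round-trips
        lex.data.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Dataset-hygiene filters
# ---------------------------------------------------------------------------


def filter_wordforms(
    lex: Lexicon,
    max_len: int = DEFAULT_MAX_LENGTH,
    count_vars: Iterable[str] = (),
    alphabet: str = DEFAULT_ALPHABET,
) -> Lexicon:
    """Apply the standard word-form exclusion rules.

    A word entry is dropped when it

    1. contains any character outside `alphabet` (hyphens, apostrophes,
       digits and spaces all exclude),
    2. is longer than `max_len` characters (the boundary itself survives), or
    3. is a hapax: the sum of its raw occurrence counts across `count_vars`
       is <= 1.  With no `count_vars` the hapax rule is disabled — frequency
       per million words cannot recover raw counts, so pass count columns
       only.

    Exclusion counts per rule are logged.  Idempotent by construction.
    """
    df = lex.data
    words = df[lex.word_key].astype(str)
    allowed = set(alphabet)
    nonalpha = words.map(lambda w: not set(w) <= allowed)
    toolong = words.str.len() > max_len
    count_vars = list(count_vars)
    if count_vars:
        for v in count_vars:
            if lex.kind(v) != NUMERIC:
                raise LexiconError(f"count variable {v!r} is not numeric")
        total = df[count_vars].sum(axis=1, skipna=True)
        hapax = total <= 1
    else:
        hapax = pd.Series(False, index=df.index)
    drop = nonalpha | toolong | hapax
    logger.info(
        "filter_wordforms: dropped %d non-alphabetic, %d over-length, %d hapax "
        "(%d total of %d)",
        int(nonalpha.sum()),
        int(toolong.sum()),
        int(hapax.sum()),
        int(drop.sum()),
        len(df),
    )
    return lex.with_data(df[~drop])


def subset_lexicon(
    lex: Lexicon,
    variable: str,
    low: float | None = None,
    high: float | None = None,
    categories: Iterable[str] | None = None,
) -> Lexicon:
    """Keep rows whose `variable` lies in [low, high] (inclusive) or in
    `categories`.  Rows missing the variable are dropped."""
    kind = lex.kind(variable)
    col = lex.data[variable]
    keep = col.notna()
    if kind == NUMERIC:
        if low is not None:
            keep &= col >= low
        if high is not None:
            keep &= col <= high
        if categories is not None:
            raise LexiconError(f"{variable!r} is numeric; use low/high bounds")
    else:
        if low is not None or high is not None:
            raise LexiconError(f"{variable!r} is categorical; use categories")
        if categories is None:
            raise LexiconError("categorical subset needs a category set")
        keep &= col.isin(list(categories))
    return lex.with_data(lex.data[keep])
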