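"""Factorial design specification: splits, controls, filters, match-null policy.

A design is an ordered list of splits (independent variables with >= 2
disjoint levels each), a list of controls (variables that must not differ
between conditions beyond a tolerance, matched item-wise against a
"match-null" word), optional filters on the candidate pool, and a seed.

Conventions
-----------
* All interval bounds — level bins and tolerances — are closed/inclusive:
  a tolerance of ``0:0`` means exact equality.
* Tolerances may be asymmetric, written ``[lo, hi]`` with ``lo <= 0 <= hi``
  (e.g. ``-0.2:0.2``).
* Categorical controls mean exact category equality with the match-null.
* Condition labels are generated, never user-supplied: splits are lettered
  A, B, C... by position and levels numbered from 1, so a 2x2 design yields
  A1_B1, A1_B2, A2_B1, A2_B2 (row-major over the splits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import pandas as pd
import yaml

from .lexicon import CATEGORICAL, NUMERIC, Lexicon
from .metrics import levenshtein


class DesignError(ValueError):
    """Structural violation in a design specification."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelInterval:
    """Closed numeric interval [low, high] defining one split level."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise DesignError(f"interval bounds out of order: {self.low}:{self.high}")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    def overlaps(self, other: "LevelInterval") -> bool:
        return self.low <= other.high and other.low <= self.high


@dataclass(frozen=True)
class Split:
    """An independent variable with ordered, pairwise-disjoint levels.

    Numeric splits take :class:`LevelInterval` levels; categorical splits
    take disjoint category sets (frozensets of labels).
    """

    variable: str
    levels: tuple

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DesignError(f"split {self.variable!r} needs >= 2 levels")
        kinds = {type(l) for l in self.levels}
        if kinds == {LevelInterval}:
            for i, a in enumerate(self.levels):
                for b in self.levels[i + 1 :]:
                    if a.overlaps(b):
                        raise DesignError(
                            f"split {self.variable!r}: overlapping levels "
                            f"{a.low}:{a.high} and {b.low}:{b.high}"
                        )
        elif kinds == {frozenset}:
            seen: set = set()
            for s in self.levels:
                if seen & s:
                    raise DesignError(
                        f"split {self.variable!r}: category sets overlap"
                    )
                seen |= s
        else:
            raise DesignError(
                f"split {self.variable!r}: levels must be all intervals "
                "or all category sets"
            )

    @property
    def is_numeric(self) -> bool:
        return isinstance(self.levels[0], LevelInterval)

    def level_of(self, value) -> int | None:
        """0-based level index containing `value`, or None (gap / missing)."""
        if pd.isna(value):
            return None
        for i, lev in enumerate(self.levels):
            if self.is_numeric:
                if lev.contains(value):
                    return i
            elif value in lev:
                return i
        return None


@dataclass(frozen=True)
class RandomSplit:
    """A split whose levels are allocated at random to matched sets,
    independent of any word property (e.g. counterbalancing across tasks)."""

    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise DesignError("random split needs >= 2 levels")


@dataclass(frozen=True)
class Control:
    """A variable that must not differ between conditions.

    Numeric controls carry an inclusive tolerance ``(lo, hi)`` around the
    match-null word's value, with ``lo <= 0 <= hi``; ``(0, 0)`` is exact.
    Categorical controls carry ``tolerance=None`` and require category
    equality with the match-null.
    """

    variable: str
    tolerance: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.tolerance is not None:
            lo, hi = self.tolerance
            if not (lo <= 0.0 <= hi):
                raise DesignError(
                    f"control {self.variable!r}: tolerance [{lo}, {hi}] "
                    "must contain 0"
                )


#: named pairwise distance functions usable in a MapControl; each maps
#: (entry_a, entry_b, column) -> non-negative symmetric float
MAP_DISTANCE_FUNCTIONS: dict[str, Callable[[pd.Series, pd.Series, str], float]] = {
    "levenshtein": lambda a, b, col: float(levenshtein(str(a[col]), str(b[col]))),
    "absdiff": lambda a, b, col: abs(float(a[col]) - float(b[col])),
}


@dataclass(frozen=True)
class MapControl:
    """A control computed pairwise at generation time, relative to the word
    selected as the match-null — e.g. orthographic or phonological
    Levenshtein distance between candidate and null."""

    function: str
    column: str
    tolerance: tuple[float, float]

    def __post_init__(self) -> None:
        if self.function not in MAP_DISTANCE_FUNCTIONS:
            raise DesignError(
                f"unknown map-control function {self.function!r}; "
                f"available: {sorted(MAP_DISTANCE_FUNCTIONS)}"
            )
        lo, hi = self.tolerance
        if not (lo <= 0.0 <= hi):
            raise DesignError("map-control tolerance must contain 0")

    def distance(self, a: pd.Series, b: pd.Series) -> float:
        return MAP_DISTANCE_FUNCTIONS[self.function](a, b, self.column)


@dataclass(frozen=True)
class Filter:
    """A pool filter: numeric interval [low, high] or category membership."""

    variable: str
    low: float | None = None
    high: float | None = None
    categories: tuple[str, ...] | None = None


MATCH_NULL_POLICIES = ("balanced", "random_per_set", "inclusive")


@dataclass(frozen=True)
class DesignSpec:
    """A complete factorial design.

    ``match_null_policy`` is one of ``balanced`` (each condition anchors an
    equal share of sets, in random order), ``random_per_set`` (i.i.d.
    uniform anchor per set), ``fixed:<condition>`` (one condition anchors
    every set), or ``inclusive`` (every pair of words in a set must satisfy
    every control pairwise, not just null-vs-rest).
    """

    splits: tuple[Union[Split, RandomSplit], ...]
    controls: tuple[Union[Control, MapControl], ...] = ()
    filters: tuple[Filter, ...] = ()
    match_null_policy: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(isinstance(s, Split) for s in self.splits):
            raise DesignError("design needs at least one non-random split")
        split_vars = {s.variable for s in self.splits if isinstance(s, Split)}
        ctrl_vars = {c.variable for c in self.controls if isinstance(c, Control)}
        both = split_vars & ctrl_vars
        if both:
            raise DesignError(f"variable(s) in both a split and a control: {sorted(both)}")
        if len(split_vars) < sum(isinstance(s, Split) for s in self.splits):
            raise DesignError("a variable appears in more than one split")
        if len(ctrl_vars) < sum(isinstance(c, Control) for c in self.controls):
            raise DesignError("a variable appears in more than one control")
        pol = self.match_null_policy
        if pol not in MATCH_NULL_POLICIES and not pol.startswith("fixed:"):
            raise DesignError(f"unknown match-null policy {pol!r}")

    # -- labels --------------------------------------------------------

    @property
    def fixed_splits(self) -> tuple[Split, ...]:
        return tuple(s for s in self.splits if isinstance(s, Split))

    @property
    def random_splits(self) -> tuple[RandomSplit, ...]:
        return tuple(s for s in self.splits if isinstance(s, RandomSplit))

    def split_letter(self, split: Union[Split, RandomSplit]) -> str:
        return chr(ord("A") + self.splits.index(split))

    def hash(self) -> str:
        """Stable digest of the serialized design, for manifests."""
        blob = json.dumps(design_to_dict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def enumerate_conditions(spec: DesignSpec) -> list[str]:
    """All condition labels in row-major order of the (non-random) splits.

    k = product of level counts; a 2x2 design gives
    ``[A1_B1, A1_B2, A2_B1, A2_B2]``.
    """
    labels: list[str] = [""]
    for s in spec.splits:
        if not isinstance(s, Split):
            continue
        letter = spec.split_letter(s)
        # prefix outer, level inner -> last split varies fastest (row-major)
        labels = [
            (f"{prefix}_" if prefix else "") + f"{letter}{i + 1}"
            for prefix in labels
            for i in range(len(s.levels))
        ]
    return labels


def condition_of(entry: pd.Series, spec: DesignSpec) -> str | None:
    """The unique condition containing this entry, or None.

    None when any split variable is missing or falls between level bins.
    Level disjointness guarantees uniqueness.
    """
    parts = []
    for s in spec.splits:
        if not isinstance(s, Split):
            continue
        idx = s.level_of(entry[s.variable])
        if idx is None:
            return None
        parts.append(f"{spec.split_letter(s)}{idx + 1}")
    return "_".join(parts)


@dataclass
class ValidationReport:
    """Outcome of checking a design against a lexicon.

    Structural violations raise :class:`DesignError` before a report is
    produced; the report carries non-fatal findings (empty cells — cells
    with zero eligible words after filters — still permit an attempt)."""

    conditions: list[str]
    cell_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def _apply_filters(lex: Lexicon, filters: Sequence[Filter]) -> pd.Series:
    keep = pd.Series(True, index=lex.data.index)
    for f in filters:
        col = lex.data[f.variable]
        keep &= col.notna()
        if f.categories is not None:
            keep &= col.isin(list(f.categories))
        else:
            if f.low is not None:
                keep &= col >= f.low
            if f.high is not None:
                keep &= col <= f.high
    return keep


def validate_design(spec: DesignSpec, lex: Lexicon) -> ValidationReport:
    """Check a design against a lexicon.

    Unknown variables and kind mismatches raise :class:`DesignError`
    (structural); empty factorial cells produce warnings naming the cell.
    """
    for s in spec.fixed_splits:
        kind = lex.kind(s.variable)  # raises on unknown variable
        if s.is_numeric and kind != NUMERIC:
            raise DesignError(f"split {s.variable!r}: interval levels on a "
                              "categorical variable")
        if not s.is_numeric and kind != CATEGORICAL:
            raise DesignError(f"split {s.variable!r}: category levels on a "
                              "numeric variable")
    for c in spec.controls:
        if isinstance(c, Control):
            kind = lex.kind(c.variable)
            if c.tolerance is not None and kind != NUMERIC:
                raise DesignError(f"control {c.variable!r}: numeric tolerance "
                                  "on a categorical variable")
        else:
            if c.column not in lex.data.columns:
                raise DesignError(f"map-control column {c.column!r} not in lexicon")
    for f in spec.filters:
        lex.meta(f.variable)

    eligible = _apply_filters(lex, spec.filters)
    sub = lex.data[eligible]
    conditions = enumerate_conditions(spec)
    counts = dict.fromkeys(conditions, 0)
    for _, row in sub.iterrows():
        lab = condition_of(row, spec)
        if lab in counts:
            counts[lab] += 1
    warnings = [
        f"cell {lab} has no eligible words" for lab, n in counts.items() if n == 0
    ]
    return ValidationReport(conditions, counts, warnings)


# ---------------------------------------------------------------------------
# Serialization (YAML-able dicts; parse(serialize(spec)) == spec)
# ---------------------------------------------------------------------------


def design_to_dict(spec: DesignSpec) -> dict:
    splits = []
    for s in spec.splits:
        if isinstance(s, RandomSplit):
            splits.append({"random": True, "n_levels": s.n_levels})
        elif s.is_numeric:
            splits.append(
                {
                    "variable": s.variable,
                    "levels": [[lev.low, lev.high] for lev in s.levels],
                }
            )
        else:
            splits.append(
                {
                    "variable": s.variable,
                    "levels": [sorted(lev) for lev in s.levels],
                }
            )
    controls = []
    for c in spec.controls:
        if isinstance(c, MapControl):
            controls.append(
                {
                    "map": c.function,
                    "column": c.column,
                    "tolerance": list(c.tolerance),
                }
            )
        elif c.tolerance is None:
            controls.append({"variable": c.variable})
        else:
            controls.append({"variable": c.variable, "tolerance": list(c.tolerance)})
    filters = []
    for f in spec.filters:
        d: dict = {"variable": f.variable}
        if f.categories is not None:
            d["categories"] = list(f.categories)
        else:
            if f.low is not None:
                d["min"] = f.low
            if f.high is not None:
                d["max"] = f.high
        filters.append(d)
    return {
        "splits": splits,
        "controls": controls,
        "filters": filters,
        "match_null": spec.match_null_policy,
        "seed": spec.seed,
    }


def design_from_dict(doc: dict) -> DesignSpec:
    splits: list[Union[Split, RandomSplit]] = []
    for d in doc.get("splits", []):
        if d.get("random"):
            splits.append(RandomSplit(int(d["n_levels"])))
            continue
        levels = d["levels"]
        if levels and isinstance(levels[0], (list, tuple)) and len(levels[0]) == 2 \
                and all(isinstance(x, (int, float)) for x in levels[0]):
            lv = tuple(LevelInterval(float(a), float(b)) for a, b in levels)
        else:
            lv = tuple(frozenset(map(str, grp)) for grp in levels)
        splits.append(Split(d["variable"], lv))
    controls: list[Union[Control, MapControl]] = []
    for d in doc.get("controls", []):
        if "map" in d:
            controls.append(
                MapControl(d["map"], d["column"], tuple(map(float, d["tolerance"])))
            )
        else:
            tol = d.get("tolerance")
            controls.append(
                Control(d["variable"], tuple(map(float, tol)) if tol else None)
            )
    filters = []
    for d in doc.get("filters", []):
        filters.append(
            Filter(
                d["variable"],
                low=d.get("min"),
                high=d.get("max"),
                categories=tuple(d["categories"]) if "categories" in d else None,
            )
        )
    return DesignSpec(
        splits=tuple(splits),
        controls=tuple(controls),
        filters=tuple(filters),
        match_null_policy=doc.get("match_null", "balanced"),
        seed=int(doc.get("seed", 0)),
    )


def read_design(path: str | Path) -> DesignSpec:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def write_design(spec: DesignSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(spec), fh, sort_keys=False)
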