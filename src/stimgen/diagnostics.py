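"""Evaluation of generated stimulus lists.

Two complementary checks:

* :func:`condition_summaries` — per-condition distribution summaries of the
  independent and control variables (the data behind violin-plot style
  design checks), plus the matched-set pairing table that supports line
  overlays between matched items.
* :func:`matched_distance_report` — the list-level matching statistic: for
  every matched set, the Euclidean distance over all numeric control
  variables (each standardized by its SD over the stimulus list, for
  comparability across units) between every unordered pair of the set's k
  words.  An item-wise matched list of n sets across k cells yields exactly
  n·k(k−1)/2 distance observations; tighter matching shifts the whole
  distribution toward zero.

:func:`audit_stimulus_list` independently re-verifies every constraint of a
generated list directly from the design definition — it shares no code with
the generator's search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Control, DesignSpec, MapControl, _apply_filters, condition_of
from .generator import StimulusList
from .lexicon import Lexicon

logger = logging.getLogger("stimgen")


# ---------------------------------------------------------------------------
# Per-condition summaries
# ---------------------------------------------------------------------------


@dataclass
class ConditionSummaries:
    """Per-condition descriptive statistics plus the matched-set pairing
    table (word, set id, condition) used to draw lines between matched
    items."""

    stats: pd.DataFrame
    pairs: pd.DataFrame


def condition_summaries(
    slist: StimulusList, lex: Lexicon, variables: list[str]
) -> ConditionSummaries:
    """Summarize each numeric variable per generated condition.

    Returns count, mean, sd, min, quartiles, and max for every
    (condition, variable) pair.  An empty stimulus list gives empty tables.
    """
    for v in variables:
        if lex.kind(v) != "numeric":
            raise ValueError(f"{v!r} is not a numeric variable")
    long = slist.to_long()
    if long.empty:
        cols = ["condition", "variable", "count", "mean", "sd",
                "min", "q25", "median", "q75", "max"]
        return ConditionSummaries(pd.DataFrame(columns=cols), long)
    merged = long.merge(
        lex.data[[lex.word_key] + variables],
        left_on="word",
        right_on=lex.word_key,
        how="left",
    )
    rows = []
    for cond, grp in merged.groupby("condition", sort=True):
        for v in variables:
            vals = grp[v].dropna()
            rows.append(
                {
                    "condition": cond,
                    "variable": v,
                    "count": int(vals.count()),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "min": vals.min(),
                    "q25": vals.quantile(0.25),
                    "median": vals.median(),
                    "q75": vals.quantile(0.75),
                    "max": vals.max(),
                }
            )
    pairs = long[["item", "condition", "word"]]
    return ConditionSummaries(pd.DataFrame(rows), pairs)


# ---------------------------------------------------------------------------
# Matched-distance report
# ---------------------------------------------------------------------------


@dataclass
class DistanceReport:
    """SD-scaled pairwise Euclidean distances within matched sets.

    ``distances`` has one row per unordered within-set pair:
    n·k(k−1)/2 rows for a complete list of n sets over k cells.
    ``summary`` holds the box-plot statistics: median, Q1, Q3, and whisker
    bounds at 1.5 × IQR from the box (clamped to observed values).
    """

    distances: pd.DataFrame
    n: int
    k: int
    control_vars: tuple[str, ...]
    summary: dict[str, float]


def _box_summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
    }


def matched_distance_report(
    slist: StimulusList,
    lex: Lexicon,
    control_vars: list[str],
) -> DistanceReport:
    """Compute within-set pairwise Euclidean distances on control variables.

    Each variable is standardized by its standard deviation over the words
    of this stimulus list (not the generating lexicon — published lists are
    comparable even when their source dataset is unavailable).  A variable
    with zero variance over the list carries no distance information and is
    dropped with a warning.  Every word must have non-missing values on all
    `control_vars`.
    """
    if len(slist) == 0:
        raise ValueError("empty stimulus list")
    k = len(slist.conditions)
    long = slist.to_long()
    merged = long.merge(
        lex.data[[lex.word_key] + list(control_vars)],
        left_on="word",
        right_on=lex.word_key,
        how="left",
    )
    missing = merged[control_vars].isna().any(axis=1)
    if missing.any():
        bad = merged.loc[missing, "word"].tolist()
        raise ValueError(f"missing control values for: {bad[:5]}")

    kept: list[str] = []
    scaled = {}
    for v in control_vars:
        sd = merged[v].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning(
                "control %r has zero variance over the list; dropped from "
                "the distance report",
                v,
            )
            continue
        kept.append(v)
        scaled[v] = merged[v].to_numpy(dtype=float) / sd
    Z = np.column_stack([scaled[v] for v in kept]) if kept else np.zeros(
        (len(merged), 0)
    )

    rows = []
    for item, grp_idx in merged.groupby("item").groups.items():
        idx = list(grp_idx)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ia, ib = idx[a], idx[b]
                d = float(np.sqrt(np.sum((Z[ia] - Z[ib]) ** 2)))
                rows.append(
                    {
                        "item": item,
                        "condition_a": merged.at[ia, "condition"],
                        "condition_b": merged.at[ib, "condition"],
                        "distance": d,
                    }
                )
    dist = pd.DataFrame(rows)
    return DistanceReport(
        distances=dist,
        n=len(slist),
        k=k,
        control_vars=tuple(kept),
        summary=_box_summary(dist["distance"].to_numpy()),
    )


def compare_lists(a: DistanceReport, b: DistanceReport) -> pd.DataFrame:
    """Side-by-side box summaries of two distance reports.

    Rows ``a`` and ``b`` carry each report's median and quartiles; row
    ``difference`` is b − a on those statistics (positive median difference
    = list b less tightly matched).  No hypothesis test is performed.
    """
    if a.control_vars != b.control_vars:
        raise ValueError(
            f"control variable sets differ: {a.control_vars} vs {b.control_vars}"
        )
    if a.distances.empty or b.distances.empty:
        raise ValueError("cannot compare empty distance reports")
    stats = ["median", "q1", "q3"]
    rows = {
        "a": {s: a.summary[s] for s in stats},
        "b": {s: b.summary[s] for s in stats},
    }
    rows["difference"] = {s: rows["b"][s] - rows["a"][s] for s in stats}
    for lab, rep in (("a", a), ("b", b)):
        rows[lab]["iqr"] = rep.summary["q3"] - rep.summary["q1"]
        rows[lab]["n_observations"] = len(rep.distances)
    rows["difference"]["iqr"] = rows["b"]["iqr"] - rows["a"]["iqr"]
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Independent audit of a generated list
# ---------------------------------------------------------------------------


def audit_stimulus_list(
    slist: StimulusList, lex: Lexicon
) -> list[str]:
    """Re-verify every constraint of a stimulus list from first principles.

    Checks, knowing nothing of the generator's search: split-level
    membership per condition, filter satisfaction, item-wise control
    tolerances (pairwise under the inclusive policy, null-anchored
    otherwise), no word reuse across sets or conditions, and match-null
    balance under the balanced policy.  Returns a list of violation
    messages (empty = clean).
    """
    spec: DesignSpec = slist.design
    problems: list[str] = []
    eligible = _apply_filters(lex, spec.filters)
    by_word = lex.data.set_index(lex.word_key, drop=False)

    all_words: list[str] = []
    for s in slist.sets:
        if set(s.words) != set(slist.conditions):
            problems.append(f"set {s.set_id}: conditions {sorted(s.words)} != design")
        if s.match_null not in s.words:
            problems.append(f"set {s.set_id}: match-null {s.match_null} has no word")
            continue
        for cond, word in s.words.items():
            all_words.append(word)
            if word not in by_word.index:
                problems.append(f"set {s.set_id}: {word!r} not in lexicon")
                continue
            row = by_word.loc[word]
            if condition_of(row, spec) != cond:
                problems.append(
                    f"set {s.set_id}: {word!r} does not belong to {cond}"
                )
            pos = lex.data.index[lex.words == word][0]
            if not eligible.loc[pos]:
                problems.append(f"set {s.set_id}: {word!r} fails a filter")
        if spec.match_null_policy == "inclusive":
            anchor_pairs = [
                (a, b)
                for i, a in enumerate(sorted(s.words))
                for b in sorted(s.words)[i + 1 :]
            ]
        else:
            anchor_pairs = [
                (s.match_null, c) for c in s.words if c != s.match_null
            ]
        for ca, cb in anchor_pairs:
            ra, rb = by_word.loc[s.words[ca]], by_word.loc[s.words[cb]]
            for ctl in spec.controls:
                if isinstance(ctl, Control):
                    va, vb = ra[ctl.variable], rb[ctl.variable]
                    if ctl.tolerance is None:
                        if va != vb:
                            problems.append(
                                f"set {s.set_id}: {ctl.variable} category "
                                f"mismatch {va!r} vs {vb!r}"
                            )
                    else:
                        lo, hi = ctl.tolerance
                        if spec.match_null_policy == "inclusive":
                            # pairwise matching has no anchor to orient an
                            # asymmetric interval
                            m = min(hi, -lo)
                            lo, hi = -m, m
                        # otherwise anchored at the null (first of the pair)
                        if not (va + lo <= vb <= va + hi):
                            problems.append(
                                f"set {s.set_id}: {ctl.variable} "
                                f"|{vb} - {va}| outside [{lo}, {hi}]"
                            )
                elif isinstance(ctl, MapControl):
                    d = ctl.distance(ra, rb)
                    if not (ctl.tolerance[0] <= d <= ctl.tolerance[1]):
                        problems.append(
                            f"set {s.set_id}: map control {ctl.function} "
                            f"distance {d} outside {ctl.tolerance}"
                        )

    dup = pd.Series(all_words).duplicated()
    if dup.any():
        problems.append(
            f"word(s) reused across sets/conditions: "
            f"{sorted(pd.Series(all_words)[dup].unique())}"
        )
    if spec.match_null_policy in ("balanced", "inclusive") and len(slist):
        counts = pd.Series([s.match_null for s in slist.sets]).value_counts()
        full = counts.reindex(slist.conditions, fill_value=0)
        if full.max() - full.min() > 1:
            problems.append(f"match-null counts unbalanced: {full.to_dict()}")
    return problems


# ---------------------------------------------------------------------------
# Optional plotting (thin layer; the tables above are the tested surface)
# ---------------------------------------------------------------------------


def plot_design(
    slist: StimulusList,
    lex: Lexicon,
    variables: list[str],
    path: str | None = None,
):
    """Violin-style distribution plot per condition and variable, with lines
    joining words of the same matched set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = condition_summaries(slist, lex, variables)
    long = slist.to_long().merge(
        lex.data[[lex.word_key] + variables],
        left_on="word",
        right_on=lex.word_key,
    )
    conds = sorted(long["condition"].unique())
    fig, axes = plt.subplots(
        1, len(variables), figsize=(4 * len(variables), 4), squeeze=False
    )
    for ax, v in zip(axes[0], variables):
        data = [long.loc[long["condition"] == c, v].dropna() for c in conds]
        ax.violinplot(data, showmedians=True)
        for _, grp in long.groupby("item"):
            xs = [conds.index(c) + 1 for c in grp["condition"]]
            ax.plot(xs, grp[v], color="gray", alpha=0.3, lw=0.7)
        ax.set_xticks(range(1, len(conds) + 1), conds)
        ax.set_title(v)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
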