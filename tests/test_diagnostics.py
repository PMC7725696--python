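import logging

import numpy as np
import pytest

from stimgen import (
    StimulusList,
    StimulusSet,
    audit_stimulus_list,
    compare_lists,
    condition_summaries,
    generate,
    matched_distance_report,
)
from stimgen.synthetic import example_design, example_lexicon

from conftest import make_lex


def fabricate_list(values: dict[str, list[str]]) -> StimulusList:
    """Build a StimulusList by hand: condition -> ordered words; row i of
    each condition forms matched set i."""
    conditions = list(values)
    n = len(values[conditions[0]])
    sets = [
        StimulusSet(i, {c: values[c][i] for c in conditions}, conditions[0])
        for i in range(n)
    ]
    return StimulusList(sets, None, seed=0)


def grid_lexicon(n_per_cond: int, k: int, rng, sd_noise=1.0):
    words, a, b = [], [], []
    for c in range(k):
        for i in range(n_per_cond):
            words.append(f"w{c}_{i}")
            a.append(rng.normal(0, sd_noise))
            b.append(rng.normal(10, 2 * sd_noise))
    return make_lex({"word": words, "a": a, "b": b})


class TestConditionSummaries:
    def test_hand_computed_stats(self):
        lex = make_lex(
            {"word": ["p", "q", "r", "s"], "zipf": [5.0, 5.2, 4.0, 4.4]}
        )
        slist = fabricate_list({"A1": ["p", "r"], "A2": ["q", "s"]})
        summ = condition_summaries(slist, lex, ["zipf"])
        stats = summ.stats.set_index("condition")
        assert stats.loc["A1", "mean"] == pytest.approx((5.0 + 4.0) / 2)
        assert stats.loc["A2", "mean"] == pytest.approx((5.2 + 4.4) / 2)
        assert stats.loc["A1", "sd"] == pytest.approx(np.std([5.0, 4.0], ddof=1))
        assert stats.loc["A1", "count"] == 2

    def test_pairing_table_covers_every_word(self):
        lex = make_lex({"word": list("pqrs"), "zipf": [1.0, 2.0, 3.0, 4.0]})
        slist = fabricate_list({"A1": ["p", "r"], "A2": ["q", "s"]})
        summ = condition_summaries(slist, lex, ["zipf"])
        assert sorted(summ.pairs["word"]) == ["p", "q", "r", "s"]
        assert set(summ.pairs.columns) == {"item", "condition", "word"}

    def test_exact_length_control_gives_identical_multisets(self):
        lex = example_lexicon(seed=30, n_words=2500, n_planted=14)
        slist = generate(example_design(), lex, 12, seed=8)
        long = slist.to_long(lex)
        by_cond = {
            c: sorted(g["length"]) for c, g in long.groupby("condition")
        }
        first = next(iter(by_cond.values()))
        assert all(v == first for v in by_cond.values())

    def test_empty_list_empty_tables(self):
        lex = make_lex({"word": ["p"], "zipf": [1.0]})
        summ = condition_summaries(StimulusList([], None, 0), lex, ["zipf"])
        assert summ.stats.empty and summ.pairs.empty

    def test_non_numeric_variable_rejected(self, toy_lexicon):
        slist = fabricate_list({"A1": ["cat"], "A2": ["dog"]})
        with pytest.raises(ValueError):
            condition_summaries(slist, toy_lexicon, ["pos"])


class TestMatchedDistanceReport:
    @pytest.mark.parametrize("k,n", [(2, 38), (2, 1), (3, 7), (4, 20), (6, 40)])
    def test_observation_count_identity(self, k, n):
        rng = np.random.default_rng(k * 100 + n)
        lex = grid_lexicon(n, k, rng)
        slist = fabricate_list(
            {f"A{c+1}": [f"w{c}_{i}" for i in range(n)] for c in range(k)}
        )
        rep = matched_distance_report(slist, lex, ["a", "b"])
        assert len(rep.distances) == n * k * (k - 1) // 2
        assert rep.n == n and rep.k == k
        assert (rep.distances["distance"] >= 0).all()

    def test_identical_values_give_zero_distance(self):
        lex = make_lex(
            {"word": list("pqrs"), "a": [1.0, 1.0, 3.0, 4.0], "b": [2.0, 2.0, 9.0, 7.0]}
        )
        slist = fabricate_list({"A1": ["p", "r"], "A2": ["q", "s"]})
        rep = matched_distance_report(slist, lex, ["a", "b"])
        d = rep.distances.set_index("item")["distance"]
        assert d[0] == pytest.approx(0.0)
        assert d[1] > 0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(77)
        lex = grid_lexicon(15, 3, rng)
        slist = fabricate_list(
            {f"A{c+1}": [f"w{c}_{i}" for i in range(15)] for c in range(3)}
        )
        rep1 = matched_distance_report(slist, lex, ["a", "b"])
        scaled = lex.data.copy()
        scaled["a"] = scaled["a"] * 10 + 3.5
        rep2 = matched_distance_report(slist, lex.with_data(scaled), ["a", "b"])
        assert np.allclose(
            rep1.distances["distance"], rep2.distances["distance"], atol=1e-10
        )

    def test_summary_recomputable_from_distances(self):
        rng = np.random.default_rng(5)
        lex = grid_lexicon(20, 2, rng)
        slist = fabricate_list(
            {f"A{c+1}": [f"w{c}_{i}" for i in range(20)] for c in range(2)}
        )
        rep = matched_distance_report(slist, lex, ["a", "b"])
        vals = rep.distances["distance"].to_numpy()
        assert rep.summary["median"] == pytest.approx(np.median(vals))
        assert rep.summary["q1"] == pytest.approx(np.percentile(vals, 25))
        assert rep.summary["whisker_high"] <= vals.max()
        assert rep.summary["whisker_low"] >= vals.min()

    def test_zero_variance_variable_dropped_with_warning(self, caplog):
        lex = make_lex(
            {"word": list("pqrs"), "a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]}
        )
        slist = fabricate_list({"A1": ["p", "r"], "A2": ["q", "s"]})
        with caplog.at_level(logging.WARNING, logger="stimgen"):
            rep = matched_distance_report(slist, lex, ["a", "b"])
        assert rep.control_vars == ("b",)
        assert any("zero variance" in r.message for r in caplog.records)

    def test_missing_control_value_rejected(self):
        lex = make_lex({"word": list("pq"), "a": [1.0, np.nan]})
        slist = fabricate_list({"A1": ["p"], "A2": ["q"]})
        with pytest.raises(ValueError, match="missing"):
            matched_distance_report(slist, lex, ["a"])

    def test_empty_list_rejected(self):
        lex = make_lex({"word": ["p"], "a": [1.0]})
        with pytest.raises(ValueError):
            matched_distance_report(StimulusList([], None, 0), lex, ["a"])


class TestCompareLists:
    def report(self, seed, noise=0.0):
        rng = np.random.default_rng(42)  # same base data each time
        lex = grid_lexicon(15, 2, rng)
        if noise:
            nrng = np.random.default_rng(seed)
            df = lex.data.copy()
            df["a"] = df["a"] + nrng.normal(0, noise, len(df))
            lex = lex.with_data(df)
        slist = fabricate_list(
            {f"A{c+1}": [f"w{c}_{i}" for i in range(15)] for c in range(2)}
        )
        return matched_distance_report(slist, lex, ["a", "b"])

    def test_report_vs_itself_zero_difference(self):
        rep = self.report(0)
        cmp = compare_lists(rep, rep)
        assert cmp.loc["difference", "median"] == pytest.approx(0.0)

    def test_mismatched_variables_error(self):
        rng = np.random.default_rng(1)
        lex = grid_lexicon(5, 2, rng)
        slist = fabricate_list(
            {f"A{c+1}": [f"w{c}_{i}" for i in range(5)] for c in range(2)}
        )
        a = matched_distance_report(slist, lex, ["a", "b"])
        b = matched_distance_report(slist, lex, ["a"])
        with pytest.raises(ValueError):
            compare_lists(a, b)


class TestAuditDetectsViolations:
    def test_corrupted_set_is_flagged(self):
        lex = example_lexicon(seed=31, n_words=2500, n_planted=12)
        slist = generate(example_design(), lex, 8, seed=9)
        assert audit_stimulus_list(slist, lex) == []
        # swap one word for a word from the wrong condition/tolerance
        outsider = lex.data.loc[
            ~lex.words.isin(slist.to_long()["word"]), "word"
        ].iloc[0]
        cond = slist.sets[0].match_null
        other = next(c for c in slist.sets[0].words if c != cond)
        slist.sets[0].words[other] = str(outsider)
        assert audit_stimulus_list(slist, lex) != []

    def test_reused_word_is_flagged(self):
        lex = example_lexicon(seed=32, n_words=2500, n_planted=12)
        slist = generate(example_design(), lex, 6, seed=10)
        w = slist.sets[0].words[slist.sets[0].match_null]
        slist.sets[1].words[slist.sets[1].match_null] = w
        problems = audit_stimulus_list(slist, lex)
        assert any("reused" in p for p in problems)


def test_plot_design_produces_figure(tmp_path):
    lex = example_lexicon(seed=33, n_words=2000, n_planted=8)
    slist = generate(example_design(), lex, 5, seed=3)
    out = tmp_path / "design.png"
    from stimgen import plot_design

    fig = plot_design(slist, lex, ["zipf", "length"], str(out))
    assert out.exists()
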