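import logging
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from stimgen import (
    Control,
    DesignSpec,
    LevelInterval,
    MapControl,
    RandomSplit,
    Split,
    allocate_match_nulls,
    audit_stimulus_list,
    candidate_pool,
    enumerate_conditions,
    generate,
    generate_random_split_assignment,
)
from stimgen.synthetic import (
    example_design,
    example_lexicon,
    make_lexicon,
    SynthSpec,
    NumericVar,
)

from conftest import make_lex


def num_split(var, *bins):
    return Split(var, tuple(LevelInterval(a, b) for a, b in bins))


class TestAllocateMatchNulls:
    def test_divisible_request_is_exactly_equal(self):
        out = allocate_match_nulls(4, ["A1", "A2"], "balanced",
                                   np.random.default_rng(0))
        assert Counter(out) == {"A1": 2, "A2": 2}

    def test_remainder_goes_to_random_condition(self):
        winners = set()
        for seed in range(30):
            out = allocate_match_nulls(5, ["A1", "A2"], "balanced",
                                       np.random.default_rng(seed))
            counts = Counter(out)
            assert sorted(counts.values()) == [2, 3]
            winners.add(max(counts, key=counts.get))
        assert winners == {"A1", "A2"}  # over-represented condition varies

    def test_order_is_random_not_blocked(self):
        orders = {
            tuple(allocate_match_nulls(6, ["A1", "A2"], "balanced",
                                       np.random.default_rng(s)))
            for s in range(20)
        }
        assert len(orders) > 1

    def test_zero_request(self):
        assert allocate_match_nulls(0, ["A1", "A2"], "balanced",
                                    np.random.default_rng(0)) == []

    def test_fixed_policy_constant(self):
        out = allocate_match_nulls(5, ["A1", "A2"], "fixed:A2",
                                   np.random.default_rng(0))
        assert out == ["A2"] * 5

    def test_fixed_policy_unknown_condition(self):
        with pytest.raises(ValueError):
            allocate_match_nulls(2, ["A1", "A2"], "fixed:A9",
                                 np.random.default_rng(0))

    def test_random_per_set_is_iid(self):
        out = allocate_match_nulls(2000, ["A1", "A2", "A3"], "random_per_set",
                                   np.random.default_rng(5))
        counts = Counter(out)
        assert all(500 < c < 840 for c in counts.values())


class TestCandidatePool:
    def make(self):
        lex = make_lex(
            {
                "word": ["aa", "bb", "cc", "dd", "ee"],
                "conc": [1.5, 1.6, 1.7, 4.5, 4.6],
                "zipf": [5.0, 5.1, np.nan, 5.0, 5.2],
            }
        )
        spec = DesignSpec(
            splits=(num_split("conc", (1, 2), (4, 5)),),
            controls=(Control("zipf", (-0.2, 0.2)),),
        )
        return lex, spec

    def test_pool_contents(self):
        lex, spec = self.make()
        pool = candidate_pool("A1", spec, lex)
        # 'cc' missing the control value is excluded
        assert sorted(pool["word"]) == ["aa", "bb"]

    def test_used_words_excluded(self):
        lex, spec = self.make()
        pool = candidate_pool("A1", spec, lex, used={"aa"})
        assert sorted(pool["word"]) == ["bb"]

    def test_all_used_empty(self):
        lex, spec = self.make()
        assert len(candidate_pool("A2", spec, lex, used={"dd", "ee"})) == 0


class TestGenerate:
    def test_deterministic_under_seed(self):
        lex = example_lexicon(seed=3, n_words=2000, n_planted=12)
        d = example_design()
        a = generate(d, lex, 10, seed=99).to_long(lex)
        b = generate(d, lex, 10, seed=99).to_long(lex)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        lex = example_lexicon(seed=3, n_words=2000, n_planted=12)
        d = example_design()
        a = generate(d, lex, 10, seed=1).to_long()
        b = generate(d, lex, 10, seed=2).to_long()
        assert not a["word"].tolist() == b["word"].tolist()

    def test_planted_request_succeeds_and_audits_clean(self):
        lex = example_lexicon(seed=5, n_words=3000, n_planted=20)
        slist = generate(example_design(), lex, 20, seed=11)
        assert len(slist) == 20
        assert not slist.exhausted
        assert audit_stimulus_list(slist, lex) == []

    def test_long_form_row_count(self):
        lex = example_lexicon(seed=5, n_words=3000, n_planted=20)
        slist = generate(example_design(), lex, 15, seed=2)
        long = slist.to_long(lex)
        assert len(long) == 15 * 4
        assert set(long["condition"]) == set(enumerate_conditions(slist.design))
        # one match-null per set
        assert long.groupby("item")["is_match_null"].sum().eq(1).all()

    def test_no_word_reuse(self):
        lex = example_lexicon(seed=6, n_words=3000, n_planted=20)
        long = generate(example_design(), lex, 20, seed=3).to_long()
        assert long["word"].is_unique

    def test_infeasible_tolerance_zero_sets(self):
        rng = np.random.default_rng(0)
        lex = make_lex(
            {
                "word": [f"w{i}" for i in range(40)],
                "conc": np.r_[rng.uniform(1, 2, 20), rng.uniform(4, 5, 20)],
                # all-distinct continuous values: exact matching impossible
                "x": rng.uniform(0, 1, 40),
            }
        )
        spec = DesignSpec(
            splits=(num_split("conc", (1, 2), (4, 5)),),
            controls=(Control("x", (0.0, 0.0)),),
        )
        slist = generate(spec, lex, 5, seed=1)
        assert len(slist) == 0
        assert slist.exhausted

    def test_empty_condition_warns_and_returns_empty(self, caplog):
        lex = make_lex(
            {"word": ["aa", "bb"], "conc": [1.5, 1.6], "zipf": [5.0, 5.0]}
        )
        spec = DesignSpec(
            splits=(num_split("conc", (1, 2), (4, 5)),),
            controls=(Control("zipf", (-0.2, 0.2)),),
        )
        with caplog.at_level(logging.WARNING, logger="stimgen"):
            slist = generate(spec, lex, 3, seed=0)
        assert len(slist) == 0 and slist.exhausted
        assert any("zero eligible" in r.message for r in caplog.records)

    def test_shortfall_warns_never_silently_truncates(self, caplog):
        lex = example_lexicon(seed=7, n_words=600, n_planted=4)
        with caplog.at_level(logging.WARNING, logger="stimgen"):
            slist = generate(example_design(), lex, 500, seed=1)
        assert slist.exhausted
        assert 0 < len(slist) < 500
        assert any("only" in r.message for r in caplog.records)

    def test_all_mode_runs_to_exhaustion(self):
        lex = example_lexicon(seed=8, n_words=1500, n_planted=10)
        slist = generate(example_design(), lex, "all", seed=4)
        assert slist.exhausted
        assert len(slist) >= 10  # at least the planted structure exists
        assert audit_stimulus_list(slist, lex) == []

    def test_match_null_balance(self):
        lex = example_lexicon(seed=9, n_words=3000, n_planted=24)
        slist = generate(example_design(), lex, 22, seed=5)
        counts = Counter(s.match_null for s in slist.sets)
        assert max(counts.values()) - min(counts.values()) <= 1
        for c in enumerate_conditions(slist.design):
            assert abs(counts.get(c, 0) - 22 / 4) < 1

    def test_inclusive_policy_pairwise_audit(self):
        lex = example_lexicon(seed=10, n_words=3000, n_planted=20)
        spec = DesignSpec(
            splits=example_design().splits,
            controls=example_design().controls,
            filters=example_design().filters,
            match_null_policy="inclusive",
        )
        slist = generate(spec, lex, 8, seed=6)
        assert len(slist) == 8
        assert audit_stimulus_list(slist, lex) == []

    def test_map_control_generation_audits_clean(self):
        spec = SynthSpec(
            n_words=400,
            numeric_vars=(NumericVar("conc", "uniform", (1.0, 5.0)),),
            seed=21,
        )
        lex = make_lexicon(spec)
        design = DesignSpec(
            splits=(num_split("conc", (1, 2), (4, 5)),),
            controls=(MapControl("levenshtein", "word", (0.0, 4.0)),),
        )
        slist = generate(design, lex, 5, seed=7)
        assert len(slist) == 5
        assert audit_stimulus_list(slist, lex) == []


class TestRandomSplitAssignment:
    def base_list(self, n_sets, seed=0):
        lex = example_lexicon(seed=12, n_words=2500, n_planted=n_sets + 4)
        return generate(example_design(), lex, n_sets, seed=seed)

    def test_even_sets_balanced_exactly(self):
        slist = self.base_list(10)
        out = generate_random_split_assignment(
            slist, RandomSplit(2), np.random.default_rng(0)
        )
        levels = Counter(out.random_levels.values())
        assert sorted(levels.values()) == [5, 5]

    def test_odd_sets_differ_by_one_and_vary(self):
        slist = self.base_list(11)
        winners = set()
        for seed in range(12):
            out = generate_random_split_assignment(
                slist, RandomSplit(2), np.random.default_rng(seed)
            )
            levels = Counter(out.random_levels.values())
            assert sorted(levels.values()) == [5, 6]
            winners.add(max(levels, key=levels.get))
        assert len(winners) == 2

    def test_label_component_appended_to_condition(self):
        slist = self.base_list(4)
        out = generate_random_split_assignment(
            slist, RandomSplit(2), np.random.default_rng(1)
        )
        long = out.to_long()
        assert long["condition"].str.match(r"A\d_B\d_C\d").all()

    def test_empty_list_rejected(self):
        from stimgen import StimulusList

        empty = StimulusList([], example_design(), 0)
        with pytest.raises(ValueError):
            generate_random_split_assignment(
                empty, RandomSplit(2), np.random.default_rng(0)
            )
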