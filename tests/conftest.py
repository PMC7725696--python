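import numpy as np
import pandas as pd
import pytest

from stimgen import (
    Control,
    DesignSpec,
    LevelInterval,
    Lexicon,
    Split,
    VariableMeta,
)


def make_lex(rows: dict, kinds: dict | None = None, word_key: str = "word") -> Lexicon:
    """Build a Lexicon from a column dict; kinds inferred unless given."""
    df = pd.DataFrame(rows)
    metas = []
    for col in df.columns:
        if col == word_key or col.startswith("_"):
            continue
        if kinds and col in kinds:
            kind = kinds[col]
        else:
            kind = "numeric" if pd.api.types.is_numeric_dtype(df[col]) else "categorical"
        metas.append(VariableMeta(col, kind))
    return Lexicon(df, metas, word_key)


@pytest.fixture
def toy_lexicon() -> Lexicon:
    return make_lex(
        {
            "word": ["cat", "cot", "cap", "dog", "dot", "pig"],
            "zipf": [5.0, 4.9, 4.8, 5.1, 3.0, 4.95],
            "conc": [4.5, 4.4, 4.6, 4.8, 1.5, 4.5],
            "pos": ["noun", "noun", "noun", "noun", "noun", "noun"],
        }
    )


@pytest.fixture
def two_cond_design() -> DesignSpec:
    return DesignSpec(
        splits=(Split("conc", (LevelInterval(1, 2), LevelInterval(4, 5))),),
        controls=(Control("zipf", (-0.2, 0.2)),),
        seed=0,
    )


def random_word_pool(rng: np.random.Generator, size: int, max_len: int = 6) -> list[str]:
    letters = np.array(list("abcdef"))  # small alphabet -> dense neighborhoods
    seen, out = set(), []
    while len(out) < size:
        L = int(rng.integers(2, max_len + 1))
        w = "".join(rng.choice(letters, size=L))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out
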