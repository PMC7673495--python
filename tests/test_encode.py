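"""Design-matrix encoding: vocabularies, count vectors, one-hot, scaling."""

import numpy as np
import pandas as pd
import pytest

from ethniclass.encode import (
    PRESETS,
    CensusFeaturizer,
    FeatureSetSpec,
    fit_vocabulary,
    vectorize,
)


def _frame(names, locations=None, sexes=None):
    n = len(names)
    return pd.DataFrame(
        {
            "name": names,
            "location": locations or ["A, York, Ontario, Canada"] * n,
            "sex": sexes or ["female"] * n,
        }
    )


class TestVocabulary:
    def test_lexicographic_and_deterministic(self):
        vocab = fit_vocabulary(["wi", "lee", "ng", "lee"])
        assert vocab == {"lee": 0, "ng": 1, "wi": 2}
        assert fit_vocabulary(["ng", "wi", "lee"]) == vocab

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_vocabulary([])

    def test_vectorize_counts_and_oov(self):
        vocab = fit_vocabulary(["lee", "ng", "wi"])
        mat = vectorize([["lee", "ng"], [], ["zzz", "lee", "lee"]], vocab)
        assert mat.toarray().tolist() == [[1, 1, 0], [0, 0, 0], [2, 0, 0]]

    def test_row_sum_equals_in_vocab_tokens(self, rng):
        universe = [f"tok{i}" for i in range(20)]
        vocab = fit_vocabulary(universe[:10])
        rows = [list(rng.choice(universe, size=rng.integers(0, 15))) for _ in range(30)]
        mat = vectorize(rows, vocab)
        expected = [sum(t in vocab for t in row) for row in rows]
        assert mat.sum(axis=1).A1.tolist() == expected


class TestFeaturizer:
    def test_presets_cover_selection_rows(self):
        assert set(PRESETS) == {
            "Dummy features only", "Sex only", "Basic name features",
            "Name substring features", "Numeric name features",
            "Phonetic name features", "All name features",
            "All location features", "All name and location features",
        }
        assert PRESETS["All name features"].groups == frozenset(
            {"basic", "substrings", "numeric", "phonetic"}
        )
        with pytest.raises(ValueError):
            FeatureSetSpec("bad", frozenset({"sound"}))

    def test_oov_tokens_contribute_nothing(self):
        train = _frame(["wing sun lee", "anna smith"])
        fz = CensusFeaturizer("All name features").fit(train)
        base = fz.transform(_frame(["anna smith"])).toarray()
        with_novel = fz.transform(_frame(["anna smith zzyzzy"]))
        # novel-token columns don't exist; existing columns may shift via
        # numeric stats only
        assert with_novel.shape[1] == base.shape[1]

    def test_unknown_onehot_is_all_zeros(self):
        train = _frame(
            ["wing sun lee", "anna smith"],
            locations=["A, York, Ontario, Canada", "B, Halifax, Nova Scotia, Canada"],
        )
        fz = CensusFeaturizer("All location features").fit(train)
        row = fz.transform(_frame(["x y"], locations=["Z, Nowhere, Atlantis, Canada"]))
        assert row.nnz == 0

    def test_scaling_closed_form(self):
        # training column (1,2,3) must z-score to (-1.2247, 0, +1.2247)
        # under population variance
        train = _frame(["ab", "ab cd", "ab cd ef"])
        fz = CensusFeaturizer("Numeric name features").fit(train)
        M = fz.transform(train).toarray()
        names = list(fz.get_feature_names_out())
        col = M[:, names.index("numeric:n_entities")]
        assert col == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_constant_numeric_column_maps_to_zero(self):
        train = _frame(["ab cd", "ef gh"])
        fz = CensusFeaturizer("Numeric name features").fit(train)
        M = fz.transform(train).toarray()
        names = list(fz.get_feature_names_out())
        assert M[:, names.index("numeric:n_entities")] == pytest.approx([0.0, 0.0])

    def test_dummy_preset_has_exactly_two_columns(self):
        fz = CensusFeaturizer("Dummy features only", random_state=0).fit(_frame(["a b", "c d"]))
        assert fz.n_features_out_ == 2

    def test_subset_property_and_column_determinism(self):
        train = _frame(
            ["wing sun lee", "anna smith", "jean tremblay"],
            locations=[
                "A, York, Ontario, Canada",
                "B, Halifax, Nova Scotia, Canada",
                "C, Montreal, Quebec, Canada",
            ],
        )
        name_cols = set(CensusFeaturizer("All name features").fit(train).get_feature_names_out())
        both = CensusFeaturizer("All name and location features").fit(train)
        assert name_cols < set(both.get_feature_names_out())
        again = CensusFeaturizer("All name and location features").fit(train)
        assert list(both.get_feature_names_out()) == list(again.get_feature_names_out())

    def test_empty_fit_raises(self):
        with pytest.raises(ValueError):
            CensusFeaturizer().fit(_frame([]))

    def test_no_test_set_leakage(self):
        """Refitting on train+test changes the vocabulary when the test
        partition introduces novel tokens; fitting on train alone (what the
        pipeline does) therefore cannot have seen them."""
        train = _frame(["wing sun lee"])
        test = _frame(["zorro quux"])
        fz_train = CensusFeaturizer("All name features").fit(train)
        fz_leaky = CensusFeaturizer("All name features").fit(pd.concat([train, test]))
        train_vocab = set(fz_train.vocabularies_["substrings"])
        leaky_vocab = set(fz_leaky.vocabularies_["substrings"])
        assert train_vocab < leaky_vocab
        assert not any("zorro" in t for t in train_vocab)
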