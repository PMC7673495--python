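"""Record cleaning, name splitting, label standardization, deduplication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethniclass.ingest import (
    EthnicityLabel,
    RawRecord,
    binarize,
    clean_name,
    drop_incomplete_and_duplicates,
    retention_percent,
    split_name,
    standardize_ethnicity,
)


class TestCleanName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Wing Sun Lee", "wing sun lee"),
            ("", ""),
            ("Mr. J. O'Neil 2nd", "oneil"),
            ("  DR    Marie   Curie ", "marie curie"),
            ("Jean-Baptiste 3", "jeanbaptiste"),  # hyphen fuses, digits drop
            ("A B C", ""),  # single alphabets only
        ],
    )
    def test_examples(self, raw, expected):
        assert clean_name(raw) == expected

    def test_apostrophe_policy_flag(self):
        assert clean_name("Mr. J. O'Neil 2nd", strip_apostrophes=False) == "o'neil"

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, raw):
        once = clean_name(raw)
        assert clean_name(once) == once

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_postconditions(self, raw):
        cleaned = clean_name(raw)
        assert cleaned == cleaned.lower()
        assert not any(ch.isdigit() for ch in cleaned)
        for token in cleaned.split():
            assert len(token) > 1
        assert "  " not in cleaned


class TestSplitName:
    @pytest.mark.parametrize(
        "cleaned,first,middle,last",
        [
            ("wing sun lee", "wing", "sun", "lee"),
            ("wing lee", "wing", "", "lee"),
            ("madonna", "", "", "madonna"),  # single token -> surname slot
            ("anna maria luisa gomez", "anna", "maria luisa", "gomez"),
        ],
    )
    def test_positional_assignment(self, cleaned, first, middle, last):
        parsed = split_name(cleaned)
        assert (parsed.first, parsed.middle, parsed.last) == (first, middle, last)
        assert parsed.entities == cleaned.split()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            split_name("")

    @given(st.lists(st.text(alphabet="abcdefgh", min_size=2, max_size=6), min_size=2, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_split_merge_round_trip(self, tokens):
        cleaned = clean_name(" ".join(tokens))
        parsed = split_name(cleaned)
        rejoined = " ".join(p for p in (parsed.first, parsed.middle, parsed.last) if p)
        assert rejoined == cleaned


class TestStandardizeEthnicity:
    def test_identity_and_alias(self):
        assert standardize_ethnicity("french") == EthnicityLabel("Fr")
        assert standardize_ethnicity(" French  ") == EthnicityLabel("Fr")
        assert standardize_ethnicity("cree") == EthnicityLabel("Ab", "Ab-Fn")

    def test_fallback_and_missing(self):
        assert standardize_ethnicity("klingon") == EthnicityLabel("Others")
        assert standardize_ethnicity("") is None
        assert standardize_ethnicity(None) is None

    def test_subgroup_requires_aboriginal(self):
        with pytest.raises(ValueError):
            EthnicityLabel("Fr", "Ab-Fn")


def _record(name="Wing Sun Lee", loc="H, L'Assomption, Quebec, Canada", sex="male", eth="chinese"):
    return RawRecord(name, loc, sex, eth)


class TestDropIncompleteAndDuplicates:
    def test_duplicates_collapse(self):
        kept, audit = drop_incomplete_and_duplicates([_record(), _record()])
        assert len(kept) == 1
        assert audit["n_duplicate"] == 1

    def test_incomplete_rules(self):
        records = [
            _record(),
            _record(name="Mr. 2nd"),  # name cleans to empty
            _record(loc=""),
            _record(eth=""),
        ]
        kept, audit = drop_incomplete_and_duplicates(records, training_mode=True)
        assert audit["n_incomplete"] == 3 and len(kept) == 1
        # ethnicity only required in training mode
        kept, audit = drop_incomplete_and_duplicates(records, training_mode=False)
        assert audit["n_incomplete"] == 2 and len(kept) == 2

    def test_audit_arithmetic_and_order_invariance(self, rng):
        records = [
            _record(name=f"Name{chr(97+i)} Surname{chr(97+i)}", eth="irish") for i in range(8)
        ] + [_record(), _record(), _record(name="")]
        kept, audit = drop_incomplete_and_duplicates(records)
        assert audit["n_kept"] + audit["n_incomplete"] + audit["n_duplicate"] == audit["n_initial"]
        shuffled = [records[i] for i in rng.permutation(len(records))]
        kept2, audit2 = drop_incomplete_and_duplicates(shuffled)
        key = lambda r: (tuple(r.name.entities), r.location.full_string, r.sex)
        assert sorted(map(key, kept)) == sorted(map(key, kept2))
        for field in ("n_kept", "n_incomplete", "n_duplicate"):
            assert audit[field] == audit2[field]

    def test_retention_percent_reported_figures(self):
        # arithmetic on the published census audit counts
        assert retention_percent(5_079_210, 4_812_958) == 94.8

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            drop_incomplete_and_duplicates([])


class TestBinarize:
    def test_target_semantics(self):
        labels = [
            EthnicityLabel("Ab", "Ab-Fn"),
            EthnicityLabel("Ab", "Ab-Mé"),
            EthnicityLabel("Fr"),
        ]
        assert binarize(labels, "Ab").tolist() == [1, 1, 0]
        assert binarize(labels, "Ab-Fn").tolist() == [1, 0, 0]
        assert binarize(labels, "Ab-Mé").tolist() == [0, 1, 0]
        assert binarize(labels, "Fr").tolist() == [0, 0, 1]

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError):
            binarize([EthnicityLabel("Fr")], "Martian")
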