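"""Name feature extraction.

Four feature groups are derived from a positionally-split personal name:

* basic — the individual name entities (pooled over the full name) plus
  the first and last letter of each occupied slot;
* substrings — all contiguous 1- to 6-letter substrings per slot (the
  1-letter cell is the distinct letters of the slot, plus a pooled
  full-name distinct-letter set);
* phonetic — the union of double-metaphone primary/secondary codes over
  all name entities;
* numeric — entity count, total character length, mean entity length,
  vowel count and vowel-to-length ratio.

Tokens are namespaced ``group:slot[:n]:value`` so that the same literal
substring in different slots stays a distinct vocabulary entry.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ingest import ParsedName
from .metaphone import double_metaphone

VOWELS = frozenset("aeiou")  # "y" is not counted as a vowel
SLOTS = ("first", "middle", "last")
MAX_NGRAM = 6

NUMERIC_STAT_NAMES = (
    "n_entities",
    "total_length",
    "mean_entity_length",
    "n_vowels",
    "vowel_ratio",
)


@dataclass
class NumericNameStats:
    n_entities: int
    total_length: int
    mean_entity_length: float  # full precision; display rounds to 1 d.p.
    n_vowels: int
    vowel_ratio: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            float(self.n_entities),
            float(self.total_length),
            self.mean_entity_length,
            float(self.n_vowels),
            self.vowel_ratio,
        )


@dataclass
class NameFeatureBundle:
    basic_tokens: list[str]
    letter_tokens: list[str]
    substring_tokens: list[str]
    phonetic_tokens: list[str]
    numerics: NumericNameStats

    @property
    def basic_group(self) -> list[str]:
        """The "basic name features" group: entities + first/last letters."""
        return self.basic_tokens + self.letter_tokens


def _dedup(items) -> list[str]:
    """Order-preserving deduplication (first occurrence wins)."""
    return list(dict.fromkeys(items))


def extract_basic(parsed: ParsedName, dedup: bool = True) -> tuple[list[str], list[str]]:
    """Entity tokens (pooled over the full name) and per-slot first/last
    letter tokens."""
    if not parsed.entities:
        raise ValueError("parsed name has no entities")
    entity = [f"entity:full:{word}" for word in parsed.entities]
    letters = []
    for slot in SLOTS:
        value = getattr(parsed, slot)
        if value:
            letters.append(f"first_letter:{slot}:{value[0]}")
            letters.append(f"last_letter:{slot}:{value.replace(' ', '')[-1]}")
    if dedup:
        entity = _dedup(entity)
    return entity, letters


def extract_substrings(parsed: ParsedName, dedup: bool = True) -> list[str]:
    """1- to 6-letter substring tokens per slot plus the pooled full-name
    distinct-letter set.

    For n >= 2 every contiguous length-n window of each word in the slot
    is emitted; the 1-letter cell is the slot's letters. Cells whose words
    are shorter than n contribute nothing. Within-cell duplicates are
    collapsed unless ``dedup=False`` (multiset counting).
    """
    if not parsed.entities:
        raise ValueError("parsed name has no entities")
    tokens: list[str] = []
    for slot in SLOTS:
        value = getattr(parsed, slot)
        if not value:
            continue
        words = value.split()
        for n in range(1, MAX_NGRAM + 1):
            cell = []
            for word in words:
                if n == 1:
                    cell.extend(word)
                else:
                    cell.extend(word[i : i + n] for i in range(len(word) - n + 1))
            if dedup:
                cell = _dedup(cell)
            tokens.extend(f"sub:{slot}:{n}:{s}" for s in cell)
    # Pooled full-name 1-letter cell.
    full_letters = [ch for word in parsed.entities for ch in word]
    if dedup:
        full_letters = _dedup(full_letters)
    tokens.extend(f"sub:full:1:{ch}" for ch in full_letters)
    return tokens


def extract_phonetic(parsed: ParsedName, dedup: bool = True) -> list[str]:
    """Union of double-metaphone primary and secondary codes over all
    entities, empties dropped, first-occurrence order."""
    if not parsed.entities:
        raise ValueError("parsed name has no entities")
    codes: list[str] = []
    for word in parsed.entities:
        primary, secondary = double_metaphone(word)
        if primary:
            codes.append(primary)
        if secondary:
            codes.append(secondary)
    if dedup:
        codes = _dedup(codes)
    return [f"phon:full:{c}" for c in codes]


def extract_numeric(parsed: ParsedName) -> NumericNameStats:
    if not parsed.entities:
        raise ValueError("parsed name has no entities")
    lengths = [len(w) for w in parsed.entities]
    total = sum(lengths)
    n_vowels = sum(ch in VOWELS for w in parsed.entities for ch in w)
    return NumericNameStats(
        n_entities=len(parsed.entities),
        total_length=total,
        mean_entity_length=total / len(parsed.entities),
        n_vowels=n_vowels,
        vowel_ratio=n_vowels / total if total else 0.0,
    )


def extract_all(parsed: ParsedName, dedup: bool = True) -> NameFeatureBundle:
    entity, letters = extract_basic(parsed, dedup=dedup)
    return NameFeatureBundle(
        basic_tokens=entity,
        letter_tokens=letters,
        substring_tokens=extract_substrings(parsed, dedup=dedup),
        phonetic_tokens=extract_phonetic(parsed, dedup=dedup),
        numerics=extract_numeric(parsed),
    )


def feature_table(parsed: ParsedName) -> dict:
    """Human-readable view of every feature cell, organised the way the
    extraction scheme is usually presented: rows are feature kinds,
    columns are the full name and the three slots. Empty cells are absent.
    Intended for golden tests and inspection, not for model input.
    """
    bundle = extract_all(parsed, dedup=True)
    table: dict = {
        "entities": [t.rsplit(":", 1)[1] for t in bundle.basic_tokens],
        "first_letter": {},
        "last_letter": {},
        "substrings": {slot: {} for slot in SLOTS},
        "full_name_letters": [],
        "phonemes": [t.rsplit(":", 1)[1] for t in bundle.phonetic_tokens],
        "numeric": {
            "n_entities": bundle.numerics.n_entities,
            "total_length": bundle.numerics.total_length,
            "mean_entity_length": round(bundle.numerics.mean_entity_length, 1),
            "n_vowels": bundle.numerics.n_vowels,
            "vowel_ratio": bundle.numerics.vowel_ratio,
        },
    }
    for tok in bundle.letter_tokens:
        kind, slot, value = tok.split(":")
        table[kind][slot] = value
    for tok in bundle.substring_tokens:
        _, slot, n, value = tok.split(":")
        if slot == "full":
            table["full_name_letters"].append(value)
        else:
            table["substrings"][slot].setdefault(int(n), []).append(value)
    return table
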