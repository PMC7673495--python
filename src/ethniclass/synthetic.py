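"""Synthetic census-style data with controllable planted signal.

The generator emulates the structure of early-1900s Canadian census
microdata without containing any real personal data: ten ethnic
categories with heavy class imbalance, ethnicity-informative name
tokens, ethnicity-skewed districts, and sex independent of ethnicity.

Names are drawn from per-category lexicons produced by Dirichlet-skewed
first-order character chains, so substring and phonetic features carry
genuine category signal. Two knobs control how much signal is planted:

* ``lexicon_overlap`` — probability that a name token is drawn from a
  shared (category-independent) lexicon instead of the category's own;
  at 1.0 names carry no signal.
* ``segregation`` — probability that a record's district is drawn from
  its category's home districts instead of uniformly; at 0.0 location
  carries no signal.

Output matches the ingest input schema exactly (columns name, location,
sex, ethnicity with free-text labels), so every pipeline stage runs on
it unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ingest import AB_SUBGROUPS, PRIMARY_LABELS

#: Class-imbalance preset shaped like turn-of-the-century Canada:
#: dominant French/English/Irish/Scottish, rare Japanese/Russian/Italian.
CENSUS1901_PRIORS: dict[str, float] = {
    "Fr": 0.31,
    "En": 0.24,
    "Ir": 0.18,
    "Sc": 0.15,
    "Others": 0.085,
    "Ab": 0.025,
    "Ru": 0.004,
    "Ch": 0.003,
    "It": 0.002,
    "Jp": 0.001,
}

DEFAULT_AB_SUBGROUP_PROPS: dict[str, float] = {
    "Ab-Fn": 0.70,
    "Ab-Mé": 0.20,
    "Ab-In": 0.05,
    "Ab-other": 0.05,
}

#: Free-text responses written to the ethnicity column, exercising the
#: alias-map standardization downstream.
RAW_LABEL_STRINGS: dict[str, str] = {
    "Ch": "chinese",
    "En": "english",
    "Fr": "french",
    "Ir": "irish",
    "It": "italian",
    "Jp": "japanese",
    "Ru": "russian",
    "Sc": "scottish",
    "Others": "other",
    "Ab-Fn": "cree",
    "Ab-Mé": "metis",
    "Ab-In": "inuit",
    "Ab-other": "aboriginal",
}

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def load_gazetteer() -> list[tuple[str, str]]:
    """(province, district) pairs shipped for synthetic generation only."""
    text = resources.files("ethniclass.data").joinpath("gazetteer.csv").read_text("utf-8")
    return [(row["province"], row["district"]) for row in csv.DictReader(text.splitlines())]


@dataclass
class SyntheticConfig:
    """Generative parameters for the synthetic census."""

    n_records: int = 20_000
    priors: dict[str, float] = field(default_factory=lambda: dict(CENSUS1901_PRIORS))
    ab_subgroup_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AB_SUBGROUP_PROPS)
    )
    surname_lexicon_size: int = 120
    firstname_lexicon_size: int = 80
    char_skew: float = 0.25  # Dirichlet concentration; smaller = more distinctive
    lexicon_overlap: float = 0.2
    segregation: float = 0.7
    #: Probability that a word's length is drawn around a category-specific
    #: centre instead of the global range, making the numeric name
    #: statistics informative. 0 leaves them label-independent.
    numeric_signal: float = 0.5
    n_districts: int = 0  # 0 = use the whole gazetteer
    label_noise: float = 0.01
    middle_name_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"category priors must sum to 1 (got {total})")
        if any(p < 0 for p in self.priors.values()):
            raise ValueError("category priors must be non-negative")
        unknown = set(self.priors) - set(PRIMARY_LABELS)
        if unknown:
            raise ValueError(f"priors name unknown categories: {sorted(unknown)}")
        if abs(sum(self.ab_subgroup_props.values()) - 1.0) > 1e-8:
            raise ValueError("Aboriginal subgroup proportions must sum to 1")
        for name in (
            "lexicon_overlap",
            "segregation",
            "label_noise",
            "middle_name_prob",
            "numeric_signal",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")


class _CharChain:
    """First-order character chain with Dirichlet-sampled rows."""

    def __init__(self, rng: np.random.Generator, concentration: float):
        k = len(_LETTERS)
        alpha = np.full(k, concentration)
        self.start = rng.dirichlet(alpha)
        self.trans = rng.dirichlet(alpha, size=k)

    def word(self, rng: np.random.Generator, length: int | None = None) -> str:
        if length is None:
            length = int(rng.integers(3, 10))
        idx = int(rng.choice(len(_LETTERS), p=self.start))
        chars = [_LETTERS[idx]]
        for _ in range(length - 1):
            idx = int(rng.choice(len(_LETTERS), p=self.trans[idx]))
            chars.append(_LETTERS[idx])
        return "".join(chars)


def _build_lexicon(
    chain: _CharChain,
    rng: np.random.Generator,
    size: int,
    taken: set[str],
    length_sampler=None,
) -> list[str]:
    """Draw *size* distinct words not used by any other lexicon."""
    words: list[str] = []
    attempts = 0
    while len(words) < size and attempts < size * 200:
        w = chain.word(rng, length_sampler() if length_sampler else None)
        attempts += 1
        if w not in taken:
            taken.add(w)
            words.append(w)
    if len(words) < size:
        raise RuntimeError("could not draw enough distinct lexicon words")
    return words


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a raw record table with gold free-text ethnicity labels.

    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    categories = [c for c in PRIMARY_LABELS if config.priors.get(c, 0.0) > 0]
    priors = np.array([config.priors[c] for c in categories])
    priors = priors / priors.sum()

    # Lexicons: one chain per category plus a shared, signal-free chain.
    # Category-specific word-length centres (spread over 3..9) plant signal
    # in the numeric name statistics with probability `numeric_signal`.
    centres = 3 + (np.arange(len(categories)) * 6) // max(len(categories) - 1, 1)
    taken: set[str] = set()
    lex_first: dict[str, list[str]] = {}
    lex_last: dict[str, list[str]] = {}
    for ci, cat in enumerate(categories):
        chain = _CharChain(rng, config.char_skew)

        def length_sampler(centre=int(centres[ci])):
            if rng.random() < config.numeric_signal:
                return int(np.clip(centre + rng.integers(-1, 2), 3, 9))
            return int(rng.integers(3, 10))

        lex_first[cat] = _build_lexicon(
            chain, rng, config.firstname_lexicon_size, taken, length_sampler
        )
        lex_last[cat] = _build_lexicon(
            chain, rng, config.surname_lexicon_size, taken, length_sampler
        )
    shared_chain = _CharChain(rng, config.char_skew)
    shared_first = _build_lexicon(shared_chain, rng, config.firstname_lexicon_size, taken)
    shared_last = _build_lexicon(shared_chain, rng, config.surname_lexicon_size, taken)

    # Geography: disjoint home-district sets per category (round-robin over
    # a permuted gazetteer), so segregation=1 makes location identifying.
    gazetteer = load_gazetteer()
    if config.n_districts:
        gazetteer = gazetteer[: config.n_districts]
    order = rng.permutation(len(gazetteer))
    home: dict[str, list[int]] = {cat: [] for cat in categories}
    for pos, gi in enumerate(order):
        home[categories[pos % len(categories)]].append(int(gi))
    for cat in categories:  # more categories than districts: no segregation
        if not home[cat]:
            home[cat] = list(range(len(gazetteer)))

    subgroups = list(config.ab_subgroup_props)
    subgroup_p = np.array([config.ab_subgroup_props[s] for s in subgroups])
    subgroup_p = subgroup_p / subgroup_p.sum()

    cat_idx = rng.choice(len(categories), size=config.n_records, p=priors)
    rows = []
    for i in range(config.n_records):
        cat = categories[int(cat_idx[i])]

        def token(lexicons: dict[str, list[str]], shared: list[str]) -> str:
            if rng.random() < config.lexicon_overlap:
                pool = shared
            else:
                pool = lexicons[cat]
            return pool[int(rng.integers(0, len(pool)))]

        parts = [token(lex_first, shared_first)]
        if rng.random() < config.middle_name_prob:
            parts.append(token(lex_first, shared_first))
        parts.append(token(lex_last, shared_last))
        name = " ".join(p.capitalize() for p in parts)

        if rng.random() < config.segregation:
            gi = home[cat][int(rng.integers(0, len(home[cat])))]
        else:
            gi = int(rng.integers(0, len(gazetteer)))
        province, district = gazetteer[gi]
        subdistrict = _LETTERS[int(rng.integers(0, 26))].upper()
        location = f"{subdistrict}, {district}, {province}, Canada"

        sex = "female" if rng.random() < 0.5 else "male"

        gold = cat
        if config.label_noise and rng.random() < config.label_noise:
            gold = categories[int(rng.choice(len(categories), p=priors))]
        if gold == "Ab":
            key = subgroups[int(rng.choice(len(subgroups), p=subgroup_p))]
        else:
            key = gold
        rows.append((name, location, sex, RAW_LABEL_STRINGS[key]))

    return pd.DataFrame(rows, columns=["name", "location", "sex", "ethnicity"])


def make_fixture_small() -> pd.DataFrame:
    """Tiny hand-built table of worked examples and edge cases.

    Contains the "Wing Sun Lee" record with its census location, a
    title-prefixed name, a single-token name, a byte-identical duplicate
    pair, and an incomplete record that ingest must drop.
    """
    rows = [
        ("Wing Sun Lee", "H, L'Assomption, Quebec, Canada", "male", "chinese"),
        ("Mr. J. O'Neil 2nd", "12, Halifax, Nova Scotia, Canada", "male", "irish"),
        ("Madonna", "A, York, Ontario, Canada", "female", "italian"),
        ("Jean Baptiste Tremblay", "3, Montreal, Quebec, Canada", "male", "french"),
        ("Jean Baptiste Tremblay", "3, Montreal, Quebec, Canada", "male", "french"),
        ("", "B, Winnipeg, Manitoba, Canada", "female", "english"),  # incomplete
        ("Mary Smith", "", "female", "scottish"),  # incomplete
    ]
    return pd.DataFrame(rows, columns=["name", "location", "sex", "ethnicity"])
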