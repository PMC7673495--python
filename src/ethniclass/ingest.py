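"""Reading, cleaning and labelling of census-style records.

Raw records carry an unstructured full name, a comma-delimited census
location string, a sex field, and (for training data) a free-text
ethnicity response. Cleaning strips personal titles, digits, isolated
single letters and punctuation from names; free-text ethnicity responses
are standardized into ten primary categories (Ab, Ch, En, Fr, Ir, It,
Jp, Ru, Sc, Others) with optional Aboriginal subgroup labels (Ab-Fn,
Ab-Mé, Ab-In, Ab-other); incomplete and duplicate records are removed
with an audit trail.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .location_features import LocationFeatures, parse_location

logger = logging.getLogger(__name__)

PRIMARY_LABELS: tuple[str, ...] = (
    "Ab", "Ch", "En", "Fr", "Ir", "It", "Jp", "Others", "Ru", "Sc",
)
AB_SUBGROUPS: tuple[str, ...] = ("Ab-Fn", "Ab-Mé", "Ab-In", "Ab-other")
#: Valid targets for binary classification: the ten primary categories
#: plus the three named Aboriginal subgroups.
BINARY_TARGETS: tuple[str, ...] = (
    "Ab", "Ab-Fn", "Ab-Mé", "Ab-In", "Ch", "En", "Fr", "Ir", "It", "Jp",
    "Others", "Ru", "Sc",
)

_APOSTROPHES = "'’ʼ`"


@dataclass
class RawRecord:
    """One row as read from disk, verbatim."""

    name_raw: str
    location_raw: str
    sex: str = "unknown"
    ethnicity_raw: Optional[str] = None


@dataclass
class ParsedName:
    """Positional split of a cleaned name into first/middle/last slots."""

    first: str
    middle: str
    last: str
    entities: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class EthnicityLabel:
    primary: str
    ab_subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.primary not in PRIMARY_LABELS:
            raise ValueError(f"unknown primary label {self.primary!r}")
        if self.ab_subgroup is not None:
            if self.primary != "Ab":
                raise ValueError("ab_subgroup requires primary='Ab'")
            if self.ab_subgroup not in AB_SUBGROUPS:
                raise ValueError(f"unknown Aboriginal subgroup {self.ab_subgroup!r}")


@dataclass
class PersonRecord:
    """A cleaned, analysis-ready record."""

    record_id: int
    name: ParsedName
    location: LocationFeatures
    sex: str
    ethnicity: Optional[EthnicityLabel] = None


def load_title_lexicon() -> frozenset[str]:
    """Personal-title tokens shipped as an editable text fixture."""
    text = resources.files("ethniclass.data").joinpath("titles.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_alias_map() -> dict[str, EthnicityLabel]:
    """Default free-text -> category alias map (editable CSV fixture)."""
    text = resources.files("ethniclass.data").joinpath("ethnicity_aliases.csv").read_text("utf-8")
    out: dict[str, EthnicityLabel] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["raw"].strip().lower()] = EthnicityLabel(
            row["primary"].strip(), row["subgroup"].strip() or None
        )
    return out


def clean_name(
    name_raw: str,
    title_lexicon: Optional[frozenset[str]] = None,
    strip_apostrophes: bool = True,
) -> str:
    """Lowercase a raw name and strip titles, numbers, single letters and
    punctuation.

    Tokens containing any digit are dropped whole ("2nd"); apostrophes and
    hyphens are removed fusing the token ("o'neil" -> "oneil") unless
    ``strip_apostrophes=False``, which keeps them for sensitivity analyses.
    Idempotent; may return the empty string (caller decides how to treat
    an unusable name).
    """
    if title_lexicon is None:
        title_lexicon = _DEFAULT_TITLES
    kept: list[str] = []
    for token in name_raw.lower().split():
        if any(ch.isdigit() for ch in token):
            continue
        for apo in _APOSTROPHES:
            token = token.replace(apo, "" if strip_apostrophes else "'")
        chars = []
        for ch in token:
            if ch.isalpha() or (not strip_apostrophes and ch in "'-"):
                chars.append(ch)
            elif ch == "-" and strip_apostrophes:
                continue  # fuse hyphenated parts
        token = "".join(chars).strip("'-")
        if not token or len(token) == 1:
            continue
        if token.strip("'-") in title_lexicon:
            continue
        kept.append(token)
    return " ".join(kept)


def split_name(cleaned: str) -> ParsedName:
    """Assign name entities positionally: first token -> first name, last
    token -> last name, interior tokens -> middle name.

    A single-token name goes to the last-name slot (surnames carry the
    dominant signal and the positional rule is undefined at one entity).
    """
    entities = cleaned.split()
    if not entities:
        raise ValueError("cannot split an empty name")
    if len(entities) == 1:
        return ParsedName(first="", middle="", last=entities[0], entities=entities)
    return ParsedName(
        first=entities[0],
        middle=" ".join(entities[1:-1]),
        last=entities[-1],
        entities=entities,
    )


def standardize_ethnicity(
    ethnicity_raw: Optional[str],
    alias_map: Optional[Mapping[str, EthnicityLabel]] = None,
    unmapped_counter: Optional[Counter] = None,
) -> Optional[EthnicityLabel]:
    """Map a free-text ethnicity response onto the study categories.

    Returns ``None`` for an empty response (incomplete record). Unmapped
    non-empty responses fall back to Others and are counted/logged.
    """
    if alias_map is None:
        alias_map = _DEFAULT_ALIASES
    if ethnicity_raw is None:
        return None
    key = unicodedata.normalize("NFC", ethnicity_raw).strip().lower()
    if not key:
        return None
    label = alias_map.get(key)
    if label is None:
        if unmapped_counter is not None:
            unmapped_counter[key] += 1
        logger.debug("unmapped ethnicity %r -> Others", key)
        return EthnicityLabel("Others")
    return label


def drop_incomplete_and_duplicates(
    records: Sequence[RawRecord],
    training_mode: bool = True,
    title_lexicon: Optional[frozenset[str]] = None,
    alias_map: Optional[Mapping[str, EthnicityLabel]] = None,
    strip_apostrophes: bool = True,
) -> tuple[list[PersonRecord], dict]:
    """Clean every record, dropping incomplete ones and collapsing
    duplicates, with an audit of the counts.

    A record is incomplete when its cleaned name or location is empty or,
    in training mode, its ethnicity is missing. A duplicate is an exact
    match on the (cleaned name, cleaned location, sex, ethnicity) tuple;
    the first occurrence in input order is kept.
    """
    if not records:
        raise ValueError("no records to process")
    kept: list[PersonRecord] = []
    seen: set[tuple] = set()
    n_incomplete = n_duplicate = 0
    unmapped: Counter = Counter()
    for raw in records:
        cleaned = clean_name(raw.name_raw, title_lexicon, strip_apostrophes)
        loc = parse_location(raw.location_raw)
        label = standardize_ethnicity(raw.ethnicity_raw, alias_map, unmapped)
        if not cleaned or not loc.full_string or (training_mode and label is None):
            n_incomplete += 1
            continue
        key = (cleaned, loc.full_string, raw.sex, label)
        if key in seen:
            n_duplicate += 1
            continue
        seen.add(key)
        kept.append(
            PersonRecord(
                record_id=len(kept),
                name=split_name(cleaned),
                location=loc,
                sex=raw.sex,
                ethnicity=label,
            )
        )
    n_initial = len(records)
    audit = {
        "n_initial": n_initial,
        "n_incomplete": n_incomplete,
        "n_duplicate": n_duplicate,
        "n_kept": len(kept),
        "retention_pct": retention_percent(n_initial, len(kept)),
        "n_unmapped_ethnicity": sum(unmapped.values()),
    }
    return kept, audit


def retention_percent(n_initial: int, n_kept: int) -> float:
    """Percent of initial records retained, rounded to 1 decimal."""
    return round(100.0 * n_kept / n_initial, 1)


def binarize(labels: Iterable[EthnicityLabel], target: str) -> np.ndarray:
    """Collapse multiclass labels to 0/1 for one binary target.

    ``Ab`` matches any Aboriginal record; a subgroup target (``Ab-Fn``,
    ``Ab-Mé``, ``Ab-In``) matches only that subgroup; every other target
    matches on the primary category.
    """
    if target not in BINARY_TARGETS:
        raise ValueError(f"unknown binary target {target!r}")
    out = []
    for lab in labels:
        if target == "Ab":
            out.append(lab.primary == "Ab")
        elif target.startswith("Ab-"):
            out.append(lab.ab_subgroup == target)
        else:
            out.append(lab.primary == target)
    return np.asarray(out, dtype=int)


def read_records(
    path,
    name_col: str = "name",
    location_col: str = "location",
    sex_col: str = "sex",
    ethnicity_col: str = "ethnicity",
    sep: str = ",",
) -> list[RawRecord]:
    """Read raw records from a delimited UTF-8 file."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return records_from_frame(df, name_col, location_col, sex_col, ethnicity_col)


def records_from_frame(
    df: pd.DataFrame,
    name_col: str = "name",
    location_col: str = "location",
    sex_col: str = "sex",
    ethnicity_col: str = "ethnicity",
) -> list[RawRecord]:
    has_eth = ethnicity_col in df.columns
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        out.append(
            RawRecord(
                name_raw=str(d.get(name_col, "") or ""),
                location_raw=str(d.get(location_col, "") or ""),
                sex=str(d.get(sex_col, "unknown") or "unknown"),
                ethnicity_raw=str(d[ethnicity_col]) if has_eth and str(d.get(ethnicity_col, "")) != "" else None,
            )
        )
    return out


_DEFAULT_TITLES = load_title_lexicon()
_DEFAULT_ALIASES = load_alias_map()
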