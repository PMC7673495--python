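"""Parsing of the census location string.

A census location is recorded as "subdistrict, district,
province/territory, country". The country token is non-informative and is
removed; the remainder is lowercased and split right-to-left into the
province, district and subdistrict features, with the cleaned whole kept
as a fourth feature (the full location string).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

DEFAULT_COUNTRY_STOPWORDS = frozenset({"canada"})

#: Unicode apostrophe variants normalized to ASCII before comparison.
_APOSTROPHE_VARIANTS = {"’": "'", "ʼ": "'", "`": "'"}


@dataclass
class LocationFeatures:
    full_string: str
    province: str
    district: str
    subdistrict: str


def parse_location(
    location_raw: str,
    country_stopwords: frozenset[str] = DEFAULT_COUNTRY_STOPWORDS,
) -> LocationFeatures:
    """Parse a raw comma-delimited location string.

    The trailing country component is dropped when it matches
    ``country_stopwords``; the remaining components are lowercased,
    whitespace-trimmed and assigned right-to-left as province, district
    and subdistrict (any surplus leading components are joined into the
    subdistrict). An empty input yields all-empty fields, which callers
    treat as an incomplete record. Apostrophes are preserved (unlike name
    cleaning) but Unicode variants are normalized to ASCII.
    """
    text = unicodedata.normalize("NFC", location_raw or "")
    for variant, ascii_apo in _APOSTROPHE_VARIANTS.items():
        text = text.replace(variant, ascii_apo)
    parts = [p.strip().lower() for p in text.split(",")]
    parts = [p for p in parts if p]
    if parts and parts[-1] in country_stopwords:
        parts = parts[:-1]
    if not parts:
        return LocationFeatures("", "", "", "")
    province = parts[-1]
    district = parts[-2] if len(parts) >= 2 else ""
    subdistrict = ", ".join(parts[:-2]) if len(parts) >= 3 else ""
    return LocationFeatures(
        full_string=", ".join(parts),
        province=province,
        district=district,
        subdistrict=subdistrict,
    )
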