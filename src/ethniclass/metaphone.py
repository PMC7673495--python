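"""Double-metaphone phonetic encoding.

Implements Lawrence Philips' double-metaphone algorithm (C/C++ User's
Journal, 2000): a rule-based phonetic key that maps a word to a primary
and an optional secondary consonant-skeleton code, grouping names that
sound alike across Anglo, Germanic, Slavic and Romance spelling
conventions ("wing" -> ANK with alternate FNK, "sun" -> SN, "lee" -> L).

Codes are returned untruncated (no 4-character cap), which is the
convention of most modern ports. The secondary code is the empty string
when it does not differ from the primary.
"""

from __future__ import annotations

VOWELS = frozenset("AEIOUY")

__all__ = ["double_metaphone"]


class _Word:
    """Uppercased word with padded, bounds-safe indexing."""

    def __init__(self, word: str) -> None:
        self.raw = "".join(ch for ch in word.upper() if ch.isalpha())
        self.length = len(self.raw)
        self.last = self.length - 1
        # Trailing pad so that lookahead rules (e.g. "IER ") can read
        # past the end of the word, as in the reference implementation.
        self._padded = self.raw + "     "

    def char(self, i: int) -> str:
        if i < 0 or i >= self.length:
            return self._padded[i] if 0 <= i < len(self._padded) else ""
        return self._padded[i]

    def at(self, start: int, length: int, *matches: str) -> bool:
        if start < 0:
            return False
        return self._padded[start : start + length] in matches

    def is_vowel(self, i: int) -> bool:
        return 0 <= i < self.length and self.raw[i] in VOWELS

    @property
    def slavo_germanic(self) -> bool:
        return any(s in self.raw for s in ("W", "K", "CZ", "WITZ"))


def double_metaphone(word: str) -> tuple[str, str]:
    """Return (primary, secondary) double-metaphone codes for *word*.

    The secondary code is ``""`` when identical to the primary.
    Raises ``ValueError`` on input with no alphabetic characters.
    """
    w = _Word(word)
    if w.length == 0:
        raise ValueError("cannot encode an empty word")

    primary: list[str] = []
    secondary: list[str] = []

    def add(p: str, s: str | None = None) -> None:
        if s is None:
            s = p
        if p:
            primary.append(p)
        if s:
            secondary.append(s)

    current = 0
    # Silent initial consonant clusters.
    if w.at(0, 2, "GN", "KN", "PN", "WR", "PS"):
        current = 1
    # Initial X is pronounced Z, encoded S ("Xavier").
    if w.char(0) == "X":
        add("S")
        current = 1

    while current < w.length:
        ch = w.char(current)

        if ch in VOWELS:
            if current == 0:
                add("A")
            current += 1

        elif ch == "B":
            add("P")
            current += 2 if w.char(current + 1) == "B" else 1

        elif ch == "Ç":  # C-cedilla
            add("S")
            current += 1

        elif ch == "C":
            current = _handle_c(w, current, add)

        elif ch == "D":
            if w.at(current, 2, "DG"):
                if w.at(current + 2, 1, "I", "E", "Y"):
                    add("J")  # "edge"
                    current += 3
                else:
                    add("TK")  # "edgar"
                    current += 2
            elif w.at(current, 2, "DT", "DD"):
                add("T")
                current += 2
            else:
                add("T")
                current += 1

        elif ch == "F":
            add("F")
            current += 2 if w.char(current + 1) == "F" else 1

        elif ch == "G":
            current = _handle_g(w, current, add)

        elif ch == "H":
            # Only pronounced between vowels or word-initially before a vowel.
            if (current == 0 or w.is_vowel(current - 1)) and w.is_vowel(current + 1):
                add("H")
                current += 2
            else:
                current += 1

        elif ch == "J":
            current = _handle_j(w, current, add)

        elif ch == "K":
            add("K")
            current += 2 if w.char(current + 1) == "K" else 1

        elif ch == "L":
            if w.char(current + 1) == "L":
                # Spanish "-illo"/"-illa"/"-alle": alternate drops the L.
                if (
                    current == w.length - 3
                    and w.at(current - 1, 4, "ILLO", "ILLA", "ALLE")
                ) or (
                    (w.at(w.last - 1, 2, "AS", "OS") or w.at(w.last, 1, "A", "O"))
                    and w.at(current - 1, 4, "ALLE")
                ):
                    add("L", "")
                else:
                    add("L")
                current += 2
            else:
                add("L")
                current += 1

        elif ch == "M":
            add("M")
            if (
                w.at(current - 1, 3, "UMB")
                and (current + 1 == w.last or w.at(current + 2, 2, "ER"))
            ) or w.char(current + 1) == "M":
                current += 2
            else:
                current += 1

        elif ch == "N":
            add("N")
            current += 2 if w.char(current + 1) == "N" else 1

        elif ch == "Ñ":  # N-tilde
            add("N")
            current += 1

        elif ch == "P":
            if w.char(current + 1) == "H":
                add("F")
                current += 2
            else:
                add("P")
                current += 2 if w.at(current + 1, 1, "P", "B") else 1

        elif ch == "Q":
            add("K")
            current += 2 if w.char(current + 1) == "Q" else 1

        elif ch == "R":
            # French terminal -IER: primary drops the R.
            if (
                current == w.last
                and not w.slavo_germanic
                and w.at(current - 2, 2, "IE")
                and not w.at(current - 4, 2, "ME", "MA")
            ):
                add("", "R")
            else:
                add("R")
            current += 2 if w.char(current + 1) == "R" else 1

        elif ch == "S":
            current = _handle_s(w, current, add)

        elif ch == "T":
            if w.at(current, 4, "TION"):
                add("X")
                current += 3
            elif w.at(current, 3, "TIA", "TCH"):
                add("X")
                current += 3
            elif w.at(current, 2, "TH") or w.at(current, 3, "TTH"):
                if w.at(current + 2, 2, "OM", "AM") or w.at(0, 4, "VAN ", "VON ") or w.at(0, 3, "SCH"):
                    add("T")  # "thomas", Germanic
                else:
                    add("0", "T")  # theta
                current += 2
            else:
                add("T")
                current += 2 if w.at(current + 1, 1, "T", "D") else 1

        elif ch == "V":
            add("F")
            current += 2 if w.char(current + 1) == "V" else 1

        elif ch == "W":
            current = _handle_w(w, current, add)

        elif ch == "X":
            # French terminal -AUX/-EAUX is silent.
            if not (
                current == w.last
                and (w.at(current - 3, 3, "IAU", "EAU") or w.at(current - 2, 2, "AU", "OU"))
            ):
                add("KS")
            current += 2 if w.at(current + 1, 1, "C", "X") else 1

        elif ch == "Z":
            if w.char(current + 1) == "H":
                add("J")  # Chinese pinyin "zh"
                current += 2
            else:
                if w.at(current + 1, 2, "ZO", "ZI", "ZA") or (
                    w.slavo_germanic and current > 0 and w.char(current - 1) != "T"
                ):
                    add("S", "TS")
                else:
                    add("S")
                current += 2 if w.char(current + 1) == "Z" else 1

        else:
            current += 1

    pri = "".join(primary)
    sec = "".join(secondary)
    return pri, sec if sec != pri else ""


def _handle_c(w: _Word, current: int, add) -> int:
    # Germanic "-ACH-" ("michael" handled below via CH).
    if (
        current > 1
        and not w.is_vowel(current - 2)
        and w.at(current - 1, 3, "ACH")
        and w.char(current + 2) != "I"
        and (w.char(current + 2) != "E" or w.at(current - 2, 6, "BACHER", "MACHER"))
    ):
        add("K")
        return current + 2
    if current == 0 and w.at(current, 6, "CAESAR"):
        add("S")
        return current + 2
    if w.at(current, 4, "CHIA"):  # Italian
        add("K")
        return current + 2
    if w.at(current, 2, "CH"):
        if current > 0 and w.at(current, 4, "CHAE"):  # "michael"
            add("K", "X")
            return current + 2
        if (
            current == 0
            and (w.at(current + 1, 5, "HARAC", "HARIS") or w.at(current + 1, 3, "HOR", "HYM", "HIA", "HEM"))
            and not w.at(0, 5, "CHORE")
        ):
            add("K")  # Greek roots: "chorus", "chymera"
            return current + 2
        if (
            w.at(0, 4, "VAN ", "VON ")
            or w.at(0, 3, "SCH")
            or w.at(current - 2, 6, "ORCHES", "ARCHIT", "ORCHID")
            or w.at(current + 2, 1, "T", "S")
            or (
                (w.at(current - 1, 1, "A", "O", "U", "E") or current == 0)
                and w.at(current + 2, 1, "L", "R", "N", "M", "B", "H", "F", "V", "W", " ")
            )
        ):
            add("K")
        else:
            if current > 0:
                if w.at(0, 2, "MC"):
                    add("K")
                else:
                    add("X", "K")
            else:
                add("X")
        return current + 2
    if w.at(current, 2, "CZ") and not w.at(current - 2, 4, "WICZ"):
        add("S", "X")  # "czerny"
        return current + 2
    if w.at(current + 1, 3, "CIA"):  # "focaccia"
        add("X")
        return current + 3
    if w.at(current, 2, "CC") and not (current == 1 and w.char(0) == "M"):
        if w.at(current + 2, 1, "I", "E", "H") and not w.at(current + 2, 2, "HU"):
            if (current == 1 and w.char(current - 1) == "A") or w.at(current - 1, 5, "UCCEE", "UCCES"):
                add("KS")  # "accident", "succeed"
            else:
                add("X")  # "bacci", "bertucci"
            return current + 3
        add("K")  # Pierce's rule
        return current + 2
    if w.at(current, 2, "CK", "CG", "CQ"):
        add("K")
        return current + 2
    if w.at(current, 2, "CI", "CE", "CY"):
        if w.at(current, 3, "CIO", "CIE", "CIA"):
            add("S", "X")  # Italian vs. English
        else:
            add("S")
        return current + 2
    add("K")
    if w.at(current + 1, 2, " C", " Q", " G"):  # "mac caffrey"
        return current + 3
    if w.at(current + 1, 1, "C", "K", "Q") and not w.at(current + 1, 2, "CE", "CI"):
        return current + 2
    return current + 1


def _handle_g(w: _Word, current: int, add) -> int:
    nxt = w.char(current + 1)
    if nxt == "H":
        if current > 0 and not w.is_vowel(current - 1):
            add("K")
            return current + 2
        if current == 0:
            if w.char(current + 2) == "I":  # "ghislane"
                add("J")
            else:
                add("K")  # "ghiradelli"
            return current + 2
        if (
            (current > 1 and w.at(current - 2, 1, "B", "H", "D"))
            or (current > 2 and w.at(current - 3, 1, "B", "H", "D"))
            or (current > 3 and w.at(current - 4, 1, "B", "H"))
        ):
            return current + 2  # silent: "hugh", "bough", "broughton"
        if current > 2 and w.char(current - 1) == "U" and w.at(current - 3, 1, "C", "G", "L", "R", "T"):
            add("F")  # "laugh", "cough"
        elif current > 0 and w.char(current - 1) != "I":
            add("K")
        return current + 2
    if nxt == "N":
        if current == 1 and w.is_vowel(0) and not w.slavo_germanic:
            add("KN", "N")
        elif not w.at(current + 2, 2, "EY") and nxt != "Y" and not w.slavo_germanic:
            add("N", "KN")
        else:
            add("KN")
        return current + 2
    if w.at(current + 1, 2, "LI") and not w.slavo_germanic:  # "tagliaro"
        add("KL", "L")
        return current + 2
    if current == 0 and (
        nxt == "Y"
        or w.at(current + 1, 2, "ES", "EP", "EB", "EL", "EY", "IB", "IL", "IN", "IE", "EI", "ER")
    ):
        add("K", "J")  # -ges-, -gep- etc. at word start
        return current + 2
    if (
        (w.at(current + 1, 2, "ER") or nxt == "Y")
        and not w.at(0, 6, "DANGER", "RANGER", "MANGER")
        and not w.at(current - 1, 1, "E", "I")
        and not w.at(current - 1, 3, "RGY", "OGY")
    ):
        add("K", "J")
        return current + 2
    if w.at(current + 1, 1, "E", "I", "Y") or w.at(current - 1, 4, "AGGI", "OGGI"):
        if w.at(0, 4, "VAN ", "VON ") or w.at(0, 3, "SCH") or w.at(current + 1, 2, "ET"):
            add("K")  # Germanic
        elif w.at(current + 1, 4, "IER "):
            add("J")  # always soft in French -gier
        else:
            add("J", "K")
        return current + 2
    add("K")
    return current + 2 if nxt == "G" else current + 1


def _handle_j(w: _Word, current: int, add) -> int:
    if w.at(current, 4, "JOSE") or w.at(0, 4, "SAN "):
        if (current == 0 and w.char(current + 4) == " ") or w.at(0, 4, "SAN "):
            add("H")  # Spanish: "jose", "san jacinto"
        else:
            add("J", "H")
        return current + 2 if w.char(current + 1) == "J" else current + 1
    if current == 0:
        add("J", "A")  # "yankelovich" / "jahn"
    elif (
        w.is_vowel(current - 1)
        and not w.slavo_germanic
        and w.char(current + 1) in ("A", "O")
    ):
        add("J", "H")
    elif current == w.last:
        add("J", "")
    elif not w.at(current + 1, 1, "L", "T", "K", "S", "N", "M", "B", "Z") and not w.at(
        current - 1, 1, "S", "K", "L"
    ):
        add("J")
    # else silent
    return current + 2 if w.char(current + 1) == "J" else current + 1


def _handle_s(w: _Word, current: int, add) -> int:
    if w.at(current - 1, 3, "ISL", "YSL"):  # "island", "carlysle"
        return current + 1
    if current == 0 and w.at(current, 5, "SUGAR"):
        add("X", "S")
        return current + 1
    if w.at(current, 2, "SH"):
        if w.at(current + 1, 4, "HEIM", "HOEK", "HOLM", "HOLZ"):
            add("S")  # Germanic
        else:
            add("X")
        return current + 2
    if w.at(current, 3, "SIO", "SIA") or w.at(current, 4, "SIAN"):
        if w.slavo_germanic:
            add("S")
        else:
            add("S", "X")  # "-sio-", "-sia-"
        return current + 3
    if (current == 0 and w.at(current + 1, 1, "M", "N", "L", "W")) or w.at(current + 1, 1, "Z"):
        # German/Anglicization, e.g. "smith" -> SM(X); "-sz-"
        add("S", "X")
        return current + 2 if w.at(current + 1, 1, "Z") else current + 1
    if w.at(current, 2, "SC"):
        if w.char(current + 2) == "H":
            if w.at(current + 3, 2, "OO", "ER", "EN", "UY", "ED", "EM"):
                if w.at(current + 3, 2, "ER", "EN"):
                    add("X", "SK")  # "schermerhorn"
                else:
                    add("SK")  # "school", "schooner"
            else:
                if current == 0 and not w.is_vowel(3) and w.char(3) != "W":
                    add("X", "S")
                else:
                    add("X")
            return current + 3
        if w.at(current + 2, 1, "I", "E", "Y"):
            add("S")
            return current + 3
        add("SK")
        return current + 3
    if current == w.last and w.at(current - 2, 2, "AI", "OI"):
        add("", "S")  # French: "resnais", "artois"
    else:
        add("S")
    return current + 2 if w.at(current + 1, 1, "S", "Z") else current + 1


def _handle_w(w: _Word, current: int, add) -> int:
    if w.at(current, 2, "WR"):
        add("R")
        return current + 2
    if current == 0 and (w.is_vowel(current + 1) or w.at(current, 2, "WH")):
        if w.is_vowel(current + 1):
            add("A", "F")  # Wasserman / Vasserman
        else:
            add("A")  # Uomo
    if (
        (current == w.last and w.is_vowel(current - 1))
        or w.at(current - 1, 5, "EWSKI", "EWSKY", "OWSKI", "OWSKY")
        or w.at(0, 3, "SCH")
    ):
        add("", "F")  # Polish -owski etc.: alternate F
        return current + 1
    if w.at(current, 4, "WICZ", "WITZ"):
        add("TS", "FX")
        return current + 4
    return current + 1
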