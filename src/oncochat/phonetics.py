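"""Phonetic keys for fuzzy matching of spoken terms.

Implements the classic Metaphone rule set (consonant-class reduction of
English spelling), applied per whitespace token.  Sound-alike
transcriptions of the same term — e.g. ``"kay rass"`` for an utterance of
*KRAS* — collapse onto similar keys, which the out-of-vocabulary matcher
uses as one feature family alongside character n-grams.

Only alphabetic characters are encoded; digits inside a token (``tp53``)
are ignored here and captured separately by length/syllable features.
"""

from __future__ import annotations

__all__ = ["metaphone", "phonetic_code"]

_VOWELS = "AEIOU"


def _in(c: str, group: str) -> bool:
    """Membership that treats the empty string (past end of word) as False."""
    return bool(c) and c in group


def _encode_word(w: str) -> str:
    # Initial-letter exceptions.
    if w[:2] in ("AE", "GN", "KN", "PN", "WR"):
        w = w[1:]
    elif w[:2] == "WH":
        w = "W" + w[2:]
    elif w[:1] == "X":
        w = "S" + w[1:]

    out: list[str] = []
    n = len(w)
    i = 0
    while i < n:
        c = w[i]
        if i > 0 and c == w[i - 1] and c != "C":
            i += 1
            continue
        prev = w[i - 1] if i > 0 else ""
        nxt = w[i + 1] if i + 1 < n else ""
        nxt2 = w[i + 2] if i + 2 < n else ""

        if c in _VOWELS:
            if i == 0:
                out.append(c)
        elif c == "B":
            # silent terminal B after M (lamb, comb)
            if not (i == n - 1 and prev == "M"):
                out.append("B")
        elif c == "C":
            if nxt == "I" and nxt2 == "A":
                out.append("X")
            elif nxt == "H":
                out.append("K" if prev == "S" else "X")
            elif _in(nxt, "IEY"):
                if prev != "S":  # SCI/SCE/SCY: C silent
                    out.append("S")
            else:
                out.append("K")
        elif c == "D":
            if nxt == "G" and _in(nxt2, "EIY"):
                out.append("J")
                i += 1  # the G is consumed
            else:
                out.append("T")
        elif c == "F":
            out.append("F")
        elif c == "G":
            if nxt == "H" and not _in(nxt2, _VOWELS):
                pass  # -GH not before a vowel: silent
            elif nxt == "N":
                pass  # GN, GNED
            elif _in(nxt, "IEY"):
                out.append("J")
            else:
                out.append("K")
        elif c == "H":
            if _in(prev, _VOWELS) and not _in(nxt, _VOWELS):
                pass
            elif _in(prev, "CSPTG"):
                pass  # digraph already encoded
            else:
                out.append("H")
        elif c == "J":
            out.append("J")
        elif c == "K":
            if prev != "C":
                out.append("K")
        elif c in "LMNR":
            out.append(c)
        elif c == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif c == "Q":
            out.append("K")
        elif c == "S":
            if nxt == "H":
                out.append("X")
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            else:
                out.append("S")
        elif c == "T":
            if nxt == "H":
                out.append("0")  # theta
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            elif nxt == "C" and nxt2 == "H":
                pass  # -TCH-: T silent
            else:
                out.append("T")
        elif c == "V":
            out.append("F")
        elif c == "W":
            if _in(nxt, _VOWELS):
                out.append("W")
        elif c == "Y":
            if _in(nxt, _VOWELS):
                out.append("Y")
        elif c == "Z":
            out.append("S")
        i += 1
    return "".join(out)


def metaphone(word: str) -> str:
    """Metaphone key of a single word; empty string if no letters."""
    letters = "".join(c for c in word.upper() if c.isalpha())
    if not letters:
        return ""
    return _encode_word(letters)


def phonetic_code(text: str) -> str:
    """Space-joined Metaphone keys of each whitespace token of `text`."""
    codes = [metaphone(tok) for tok in text.split()]
    return " ".join(c for c in codes if c)
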