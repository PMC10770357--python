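"""Normalization of speech-to-text transcriptions.

Query utterances and lexicon terms are compared after an identical
normalization: lowercasing, punctuation stripping, whitespace collapsing
and token-wise lemmatization.  Using one function for both sides keeps the
lookup key symmetric, so every supported term trivially maps to itself.

The lemmatizer is a small rule-based English suffix stripper.  Tokens that
look like gene symbols (they contain a digit, e.g. ``tp53``) are exempt so
that symbols are never mangled; short tokens are left alone so that
symbols spoken as words (``ras``, ``myc``) survive unchanged.
"""

from __future__ import annotations

import re

__all__ = ["normalize_text", "lemmatize_token", "syllable_count", "EMPTY"]

#: Sentinel returned when an input is empty after cleaning.  Falsy, prints
#: as the empty string, and is distinguishable from a crash.
EMPTY = ""

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")
_HAS_DIGIT_RE = re.compile(r"\d")

# Irregular plurals that show up in conversational genomics queries.
_IRREGULAR = {
    "copies": "copy",
    "analyses": "analysis",
    "indices": "index",
    "matrices": "matrix",
}


def lemmatize_token(token: str) -> str:
    """Reduce one lowercase token to a base form.

    Plural and common inflectional suffixes are stripped with conservative
    length guards: a token is never reduced below four characters, and
    tokens containing digits are returned verbatim.
    """
    if _HAS_DIGIT_RE.search(token):
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "ches", "shes", "xes", "zes")) and len(token) > 4:
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")) and len(token) >= 5:
        return token[:-1]
    return token


def normalize_text(raw: str) -> str:
    """Clean, case-transform and lemmatize a transcription.

    Returns the normalized text, or :data:`EMPTY` when nothing survives
    cleaning.  Idempotent: ``normalize_text(normalize_text(x)) ==
    normalize_text(x)``.
    """
    if raw is None:
        return EMPTY
    text = _PUNCT_RE.sub(" ", raw.lower())
    tokens = [lemmatize_token(t) for t in _WS_RE.split(text.strip()) if t]
    if not tokens:
        return EMPTY
    return " ".join(tokens)


_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def syllable_count(text: str) -> int:
    """Heuristic syllable count of a normalized string.

    Counts vowel groups per alphabetic token (with a silent-``e`` rule);
    each digit counts as one syllable, since digits in symbols are spoken
    individually.  Non-empty input yields at least 1.
    """
    total = 0
    for token in text.split():
        letters = "".join(c for c in token if c.isalpha())
        digits = sum(c.isdigit() for c in token)
        n = len(_VOWEL_GROUP_RE.findall(letters))
        if n > 1 and letters.endswith("e") and not letters.endswith(("le", "ee")):
            n -= 1
        if letters and n == 0:
            n = 1
        total += n + digits
    if text.strip() and total == 0:
        total = 1
    return total
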