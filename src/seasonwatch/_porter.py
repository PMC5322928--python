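"""Porter stemmer for English (the classic 1980 suffix-stripping algorithm).

Used only on the term-mining path (building symptomatic vocabularies from a
seed corpus); query matching never stems unless explicitly asked to.  The
implementation follows the published rule tables: words are viewed as
``[C](VC){m}[V]`` and suffix rules fire conditionally on the measure ``m``
of the remaining stem.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem_: str) -> int:
    """Number of VC sequences in the [C](VC){m}[V] form of the stem."""
    m = 0
    i = 0
    n = len(stem_)
    while i < n and _is_consonant(stem_, i):
        i += 1
    while i < n:
        while i < n and not _is_consonant(stem_, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(stem_, i):
            i += 1
    return m


def _contains_vowel(stem_: str) -> bool:
    return any(not _is_consonant(stem_, i) for i in range(len(stem_)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """*o condition: stem ends cvc where the final c is not w, x or y."""
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """Apply rule (m > min_measure-1) suffix -> repl; None when not applied."""
    if not word.endswith(suffix):
        return None
    stem_ = word[: len(word) - len(suffix)]
    if _measure(stem_) >= min_measure:
        return stem_ + repl
    return word  # suffix matched but condition failed: rule consumed


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem_ = word[:-3]
        return word[:-1] if _measure(stem_) > 0 else word
    flag = False
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        word = word[:-2]
        flag = True
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        word = word[:-3]
        flag = True
    if flag:
        if word.endswith(("at", "bl", "iz")):
            return word + "e"
        if _ends_double_consonant(word) and word[-1] not in "lsz":
            return word[:-1]
        if _measure(word) == 1 and _ends_cvc(word):
            return word + "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _step2(word: str) -> str:
    for suffix, repl in _STEP2:
        out = _replace(word, suffix, repl, 1)
        if out is not None:
            return out
    return word


def _step3(word: str) -> str:
    for suffix, repl in _STEP3:
        out = _replace(word, suffix, repl, 1)
        if out is not None:
            return out
    return word


def _step4(word: str) -> str:
    for suffix in _STEP4:
        if word.endswith(suffix):
            stem_ = word[: len(word) - len(suffix)]
            if suffix == "ion" and (not stem_ or stem_[-1] not in "st"):
                return word
            return stem_ if _measure(stem_) > 1 else word
    return word


def _step5(word: str) -> str:
    if word.endswith("e"):
        stem_ = word[:-1]
        m = _measure(stem_)
        if m > 1 or (m == 1 and not _ends_cvc(stem_)):
            word = stem_
    if _ends_double_consonant(word) and word[-1] == "l" and _measure(word) > 1:
        word = word[:-1]
    return word


def stem(word: str) -> str:
    """Stem one lowercase word.  Words of length <= 2 are returned as-is."""
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _step2(word)
    word = _step3(word)
    word = _step4(word)
    word = _step5(word)
    return word
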