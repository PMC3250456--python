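"""Porter stemmer (classic 1980 algorithm).

Suffix-stripping stemmer for English used by the document model. The
implementation follows the original five-step rule tables; no revised
("Porter2") extensions are applied, so stems match the widely published
reference behaviour (e.g. "studies" -> "studi", "relational" -> "relat").
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions ([C](VC)^m[V])."""
    m = 0
    prev_cons = True
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and not prev_cons:
            m += 1
        prev_cons = cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, repl: str, min_m: int) -> str | None:
    """If word ends with suffix and the remaining stem has measure > min_m,
    return stem+repl, else None."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_m:
        return stem + repl
    return word  # suffix matched but condition failed: rule consumed, no change


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def stem(word: str) -> str:
    """Stem a single lowercase word."""
    w = word
    if len(w) <= 2:
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    fired = False
    if w.endswith("eed"):
        stem_ = w[:-3]
        if _measure(stem_) > 0:
            w = w[:-1]
    elif w.endswith("ed"):
        stem_ = w[:-2]
        if _contains_vowel(stem_):
            w = stem_
            fired = True
    elif w.endswith("ing"):
        stem_ = w[:-3]
        if _contains_vowel(stem_):
            w = stem_
            fired = True
    if fired:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            out = _replace(w, suffix, repl, 0)
            if out is not None:
                w = out
            break

    # Step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            out = _replace(w, suffix, repl, 0)
            if out is not None:
                w = out
            break

    # Step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem_ = w[: len(w) - len(suffix)]
            if _measure(stem_) > 1:
                if suffix == "ion" and not stem_.endswith(("s", "t")):
                    break
                w = stem_
            break

    # Step 5a
    if w.endswith("e"):
        stem_ = w[:-1]
        m = _measure(stem_)
        if m > 1 or (m == 1 and not _ends_cvc(stem_)):
            w = stem_

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w
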