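"""English Snowball (Porter2) stemming algorithm.

A direct implementation of Martin Porter's revised English stemmer, the
algorithm commonly exposed as the "English Snowball stemmer" in NLP
toolkits.  Tokens are reduced to lexical roots so that inflectional
variants ("viewing", "viewed", "views") collapse onto one feature
("view").  Stems need not be dictionary words ("memory" -> "memori").

Only lowercase input is meaningful; callers lowercase upstream.
"""

from __future__ import annotations

__all__ = ["stem", "stem_tokens"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_VALID = frozenset("cdeghkmnrt")

_EXCEPTIONS = {
    "skis": "ski",
    "skies": "sky",
    "dying": "die",
    "lying": "lie",
    "tying": "tie",
    "idly": "idl",
    "gently": "gentl",
    "ugly": "ugli",
    "early": "earli",
    "only": "onli",
    "singly": "singl",
    "sky": "sky",
    "news": "news",
    "howe": "howe",
    "atlas": "atlas",
    "cosmos": "cosmos",
    "bias": "bias",
    "andes": "andes",
}

# left invariant if matched immediately after step 1a
_EXCEPTIONS2 = frozenset(
    {"inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"}
)

_STEP2 = [
    ("ization", "ize"),
    ("ational", "ate"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("iveness", "ive"),
    ("tional", "tion"),
    ("biliti", "ble"),
    ("lessli", "less"),
    ("entli", "ent"),
    ("ation", "ate"),
    ("alism", "al"),
    ("aliti", "al"),
    ("ousli", "ous"),
    ("iviti", "ive"),
    ("fulli", "ful"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("abli", "able"),
    ("izer", "ize"),
    ("ator", "ate"),
    ("alli", "al"),
    ("bli", "ble"),
    ("ogi", "og"),   # only when preceded by l
    ("li", ""),      # only when preceded by a valid li-ending
]

_STEP3 = [
    ("ational", "ate"),
    ("tional", "tion"),
    ("alize", "al"),
    ("icate", "ic"),
    ("iciti", "ic"),
    ("ative", ""),   # only when in R2
    ("ical", "ic"),
    ("ness", ""),
    ("ful", ""),
]

_STEP4 = [
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "ion", "al", "er", "ic",
]


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _regions(word: str) -> tuple[int, int]:
    """Start indices of R1 and R2 (len(word) when the region is empty)."""
    n = len(word)
    if word.startswith(("gener", "commun", "arsen")):
        # these prefixes fix R1 just past the prefix
        r1 = 6 if word.startswith("commun") else 5
    else:
        r1 = n
        for i in range(1, n):
            if not _is_vowel(word[i]) and _is_vowel(word[i - 1]):
                r1 = i + 1
                break
    r2 = n
    for i in range(r1 + 1, n):
        if not _is_vowel(word[i]) and _is_vowel(word[i - 1]):
            r2 = i + 1
            break
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return _is_vowel(word[0]) and not _is_vowel(word[1])
    if n >= 3:
        return (
            not _is_vowel(word[-3])
            and _is_vowel(word[-2])
            and not _is_vowel(word[-1])
            and word[-1] not in "wxY"
        )
    return False


def stem(word: str) -> str:
    word = word.lower()
    if len(word) <= 2:
        return word
    if word[0] == "'":
        word = word[1:]
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]

    # mark y functioning as a consonant
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and _is_vowel(chars[i - 1]):
            chars[i] = "Y"
    word = "".join(chars)

    r1, r2 = _regions(word)

    # step 0: possessives
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-2] if len(word) > 4 else word[:-1]
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if any(_is_vowel(c) for c in word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS2:
        return word

    # step 1b
    if word.endswith(("eed", "eedly")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= r1:
            word = word[: -len(suf)] + "ee"
    else:
        for suf in ("ingly", "edly", "ing", "ed"):
            if word.endswith(suf):
                stem_part = word[: -len(suf)]
                if any(_is_vowel(c) for c in stem_part):
                    word = stem_part
                    if word.endswith(("at", "bl", "iz")):
                        word += "e"
                    elif word.endswith(_DOUBLES):
                        word = word[:-1]
                    elif r1 >= len(word) and _ends_short_syllable(word):
                        word += "e"
                break

    # step 1c
    if (
        len(word) > 2
        and word[-1] in "yY"
        and not _is_vowel(word[-2])
    ):
        word = word[:-1] + "i"

    # step 2
    for suf, repl in _STEP2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ogi":
                    if word.endswith("logi"):
                        word = word[:-1]
                elif suf == "li":
                    if len(word) >= 3 and word[-3] in _LI_VALID:
                        word = word[:-2]
                else:
                    word = word[: -len(suf)] + repl
            break

    # step 3
    for suf, repl in _STEP3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - 5 >= r2:
                        word = word[:-5]
                else:
                    word = word[: -len(suf)] + repl
            break

    # step 4
    for suf in _STEP4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # step 5
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")


def stem_tokens(tokens):
    """Stem a sequence of tokens, preserving order and length."""
    return [stem(t) for t in tokens]
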