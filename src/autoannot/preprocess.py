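"""Deterministic text normalization shared by both feature spaces.

The pipeline order is part of the contract::

    expand_abbreviations -> normalize_text -> tokenize
        -> remove_stopwords -> stem_tokens -> extract_ngrams

Stop-word removal happens before stemming (stems like "veri" would no
longer match a raw stop list), and the minimum word length applies to
raw tokens, not stems.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from ._stem import stem, stem_tokens

__all__ = [
    "PreprocessConfig",
    "load_default_stopwords",
    "load_default_spelling_map",
    "expand_abbreviations",
    "normalize_text",
    "tokenize",
    "remove_stopwords",
    "stem_tokens",
    "extract_ngrams",
    "preprocess_tokens",
    "preprocess_text",
]


def load_default_stopwords() -> frozenset[str]:
    """Standard English stop-word list shipped with the package."""
    text = resources.files("autoannot.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_default_spelling_map() -> dict[str, str]:
    """British->American spelling dictionary shipped with the package."""
    text = resources.files("autoannot.data").joinpath("spelling_gb_us.csv").read_text("utf-8")
    reader = csv.DictReader(text.splitlines())
    return {row["british"]: row["american"] for row in reader}


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the normalization pipeline.

    ``min_word_len`` defaults to 3: only words with at least three
    letters become features.  ``ngram_orders`` defaults to {1, 2, 3}
    (unigrams, bigrams, trigrams).
    """

    stopword_list: frozenset[str] = field(default_factory=load_default_stopwords)
    spelling_map: Mapping[str, str] = field(default_factory=load_default_spelling_map)
    min_word_len: int = 3
    ngram_orders: frozenset[int] = frozenset({1, 2, 3})
    keep_hyphens: bool = True

    def __post_init__(self) -> None:
        if not self.ngram_orders:
            raise ValueError("ngram_orders must be nonempty")
        if self.min_word_len < 1:
            raise ValueError("min_word_len must be >= 1")
        bad = [k for k, v in self.spelling_map.items() if k == v]
        if bad:
            raise ValueError(f"spelling_map maps words to themselves: {bad[:5]}")
        notlower = [w for w in self.stopword_list if w != w.lower()]
        if notlower:
            raise ValueError(f"stopword entries must be lowercase: {notlower[:5]}")


_PAREN_RE = re.compile(r"\(([^()\s]{2,10})\)")


def _abbrev_matches(abbrev: str, preceding_words: Sequence[str]) -> bool:
    letters = [c for c in abbrev if c.isalpha()]
    k = len(letters)
    if k == 0 or len(preceding_words) < k:
        return False
    candidate = preceding_words[-k:]
    return all(w and w[0].lower() == c.lower() for c, w in zip(letters, candidate))


def expand_abbreviations(text: str) -> str:
    """Expand parenthetically defined abbreviations in place.

    A parenthesized token of 2-10 characters containing at least one
    letter is accepted as an abbreviation when the i-th of its letters
    begins (case-insensitively) the i-th of the words immediately
    preceding the parentheses, taking as many words as the abbreviation
    has letters.  The parenthesized definition is removed and every
    later standalone occurrence of the abbreviation is replaced by the
    full term.
    """
    pos = 0
    while True:
        m = _PAREN_RE.search(text, pos)
        if m is None:
            return text
        abbrev = m.group(1)
        before = text[: m.start()]
        words = before.split()
        letters = [c for c in abbrev if c.isalpha()]
        if not letters or not _abbrev_matches(abbrev, words):
            pos = m.end()
            continue
        full_term = " ".join(words[-len(letters):])
        head = before.rstrip()
        tail = text[m.end():]
        token_re = re.compile(
            r"(?<![\w-])" + re.escape(abbrev) + r"(?![\w-])"
        )
        tail = token_re.sub(full_term, tail)
        pos = len(head)
        text = head + tail


_KEEP_RE = re.compile(r"[^0-9a-z\-\s]+")
_WORD_RE = re.compile(r"[0-9a-z]+")


def normalize_text(text: str, config: PreprocessConfig) -> str:
    """Lowercase, strip punctuation (hyphens survive), Americanize spelling."""
    text = text.lower()
    if config.keep_hyphens:
        text = _KEEP_RE.sub("", text)
    else:
        text = _KEEP_RE.sub("", text).replace("-", "")
    spelling = config.spelling_map
    if spelling:
        text = _WORD_RE.sub(lambda m: spelling.get(m.group(0), m.group(0)), text)
    return text


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization; empty tokens dropped."""
    return text.split()


def remove_stopwords(tokens: Iterable[str], config: PreprocessConfig) -> list[str]:
    """Drop stop words and tokens shorter than ``min_word_len``."""
    stop = config.stopword_list
    n = config.min_word_len
    return [t for t in tokens if len(t) >= n and t not in stop]


def extract_ngrams(tokens: Sequence[str], config: PreprocessConfig) -> Counter[str]:
    """Contiguous n-grams (space-joined) for each configured order."""
    counts: Counter[str] = Counter()
    L = len(tokens)
    for n in sorted(config.ngram_orders):
        for i in range(L - n + 1):
            counts[" ".join(tokens[i : i + n])] += 1
    return counts


def preprocess_tokens(text: str, config: PreprocessConfig | None = None) -> list[str]:
    """Full pipeline up to (and including) stemming; returns stem stream."""
    if config is None:
        config = PreprocessConfig()
    text = expand_abbreviations(text)
    text = normalize_text(text, config)
    tokens = tokenize(text)
    tokens = remove_stopwords(tokens, config)
    return stem_tokens(tokens)


def preprocess_text(text: str, config: PreprocessConfig | None = None) -> Counter[str]:
    """Full pipeline; returns the n-gram feature-count map for one document."""
    if config is None:
        config = PreprocessConfig()
    return extract_ngrams(preprocess_tokens(text, config), config)
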