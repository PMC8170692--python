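"""Free-text functional description similarity.

When two hits share no database identifier, their free-text descriptions are
compared instead.  The pipeline is deliberately small and deterministic:
lowercase, strip punctuation and embedded database identifiers, drop
stop-words (a standard English list plus domain fillers such as "protein"
and "putative"), apply a light suffix stemmer, optionally map synonyms, then
compare token weight vectors by cosine similarity.  Token weights are raw
counts, optionally multiplied by inverse document frequency computed over the
loaded metadata corpus.

Two descriptions count as functionally similar when their cosine similarity
reaches the configured threshold (default 0.8); a pair exactly at the
threshold passes.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .metadata import _ID_PATTERNS

__all__ = [
    "DEFAULT_SIMILARITY_THRESHOLD",
    "TokenProfile",
    "CorpusStats",
    "preprocess",
    "description_similarity",
    "is_similar",
    "light_stem",
]

DEFAULT_SIMILARITY_THRESHOLD = 0.8

# standard English stop-words (small closed-class list) plus domain fillers
# that carry no functional signal in annotation descriptions
_ENGLISH_STOPWORDS = frozenset(
    """a an and are as at be been by for from has have in into is it its of on
    or that the this to was were which will with within without""".split()
)
_DOMAIN_FILLERS = frozenset(
    """protein proteins putative predicted probable possible uncharacterized
    hypothetical family domain containing conserved related like associated
    responsible involved function functional activity enzyme""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# ordered suffix-stripping rules; longest first, applied once, stem >= 3 chars
_SUFFIXES = (
    "ization", "ational", "ibility", "ation", "ition", "ility", "ical",
    "ible", "able", "ious", "ment", "ness", "ases", "ing", "ive", "ize",
    "ise", "ful", "est", "ase", "ed", "es", "al", "ic", "s", "e", "y",
)


def light_stem(token: str) -> str:
    """Strip the longest matching suffix once, keeping a stem of >= 3 chars.

    E.g. ``degradation -> degrad``, ``glucose -> glucos``, ``kinases -> kin...``
    This is a deliberately light normalization, not a full stemmer.
    """
    for suffix in _SUFFIXES:
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    return token


@dataclass
class TokenProfile:
    """Normalized keyword multiset for one description."""

    text: str
    tokens: Counter = field(default_factory=Counter)

    def __bool__(self) -> bool:
        return bool(self.tokens)


@dataclass
class CorpusStats:
    """Document frequencies over the loaded descriptions, for IDF weighting."""

    doc_freq: Counter = field(default_factory=Counter)
    n_docs: int = 0

    def add(self, profile: TokenProfile) -> None:
        self.n_docs += 1
        for token in profile.tokens:
            self.doc_freq[token] += 1

    def idf(self, token: str) -> float:
        # smoothed IDF; strictly positive so seen tokens are never erased
        return math.log((1 + self.n_docs) / (1 + self.doc_freq.get(token, 0))) + 1.0

    @classmethod
    def from_texts(cls, texts: Iterable[str], **kwargs) -> "CorpusStats":
        stats = cls()
        for t in texts:
            stats.add(preprocess(t, **kwargs))
        return stats


def preprocess(
    text: str,
    extra_stopwords: Iterable[str] = (),
    synonyms: Mapping[str, str] | None = None,
) -> TokenProfile:
    """Turn a description into a normalized keyword multiset.

    Embedded database identifiers are removed first (they are handled by the
    identifier-intersection path, not by text similarity).
    """
    cleaned = text
    for _, pattern in _ID_PATTERNS:
        cleaned = pattern.sub(" ", cleaned)
    cleaned = cleaned.lower()
    stop = _ENGLISH_STOPWORDS | _DOMAIN_FILLERS | set(extra_stopwords)
    tokens: Counter = Counter()
    for raw in _TOKEN_RE.findall(cleaned):
        if raw in stop or raw.isdigit():
            continue
        token = light_stem(raw)
        if synonyms:
            token = synonyms.get(token, token)
        tokens[token] += 1
    return TokenProfile(text=text, tokens=tokens)


def description_similarity(
    a: TokenProfile,
    b: TokenProfile,
    corpus_stats: CorpusStats | None = None,
) -> float:
    """Cosine similarity of the two token weight vectors, in [0, 1].

    Weights are term counts, multiplied by IDF when corpus statistics are
    available.  Two empty profiles are *not* similar (0.0).
    """
    if not a.tokens or not b.tokens:
        return 0.0
    if a.tokens == b.tokens:
        # identical profiles are exactly similar regardless of weighting
        return 1.0

    def weight(token: str, count: int) -> float:
        w = float(count)
        if corpus_stats is not None and corpus_stats.n_docs > 0:
            w *= corpus_stats.idf(token)
        return w

    wa = {t: weight(t, c) for t, c in a.tokens.items()}
    wb = {t: weight(t, c) for t, c in b.tokens.items()}
    dot = sum(w * wb[t] for t, w in wa.items() if t in wb)
    norm = math.sqrt(sum(w * w for w in wa.values())) * math.sqrt(
        sum(w * w for w in wb.values())
    )
    if norm == 0.0:
        return 0.0
    return min(1.0, dot / norm)


def is_similar(
    a: TokenProfile,
    b: TokenProfile,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    corpus_stats: CorpusStats | None = None,
) -> bool:
    """Thresholded similarity decision; a pair exactly at the threshold passes."""
    return description_similarity(a, b, corpus_stats) >= threshold
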