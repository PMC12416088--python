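"""Text feature extraction with caching.

Two vectorizers are supported: presence/absence one-hot and TF-IDF.
TF-IDF uses raw term counts, smoothed idf ``ln((1+N)/(1+df)) + 1`` and
L2 row normalization; the default n-gram range is (1, 2) so both single
tokens and pairs of consecutive tokens enter the vocabulary.

Tokenization splits on non-alphanumeric characters, lowercases and drops
empty tokens.  The vocabulary is sorted lexicographically so matrices —
and every downstream score and ranking — are reproducible across runs.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Optional

import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

from .errors import ValidationError, VectorizationError

_TOKEN_SPLIT = re.compile(r"[^0-9a-zA-Z]+")


@dataclass(frozen=True)
class VectorizerSpec:
    """Configuration of one feature extractor."""

    kind: str = "tfidf"                      # {"onehot", "tfidf"}
    ngram_range: tuple[int, int] = (1, 2)
    lowercase: bool = True
    min_token_length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("onehot", "tfidf"):
            raise ValidationError(f"unknown vectorizer kind {self.kind!r}")
        low, high = self.ngram_range
        if not (1 <= low <= high):
            raise ValidationError(
                f"ngram_range must satisfy 1 <= low <= high, got {self.ngram_range}"
            )

    def cache_key(self) -> tuple:
        return (self.kind, self.ngram_range, self.lowercase,
                self.min_token_length)


@dataclass
class FeatureMatrix:
    """Sparse document-term matrix aligned to corpus order."""

    matrix: sp.csr_matrix
    vocabulary: dict[str, int]
    spec: VectorizerSpec
    fingerprint: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def tokenize(text: str, spec: VectorizerSpec) -> list[str]:
    """Split on non-alphanumeric characters; lowercase; drop shorties."""
    if spec.lowercase:
        text = text.lower()
    return [t for t in _TOKEN_SPLIT.split(text)
            if len(t) >= spec.min_token_length]


def corpus_fingerprint(corpus) -> str:
    """Content hash of (id, title, body) triples; detects corpus edits."""
    h = hashlib.sha256()
    for rec in corpus:
        h.update(rec.record_id.encode("utf-8"))
        h.update(b"\x1f")
        h.update(rec.title.encode("utf-8"))
        h.update(b"\x1f")
        h.update(rec.body.encode("utf-8"))
        h.update(b"\x1e")
    return h.hexdigest()


def fit_transform(corpus, spec: VectorizerSpec) -> FeatureMatrix:
    """Vectorize a corpus deterministically.

    Row *i* of the result corresponds to corpus record *i*.  Raises
    :class:`VectorizationError` when every record tokenizes to nothing.
    """
    if len(corpus) == 0:
        raise VectorizationError("cannot vectorize an empty corpus")
    texts = corpus.texts

    def _tok(doc: str) -> list[str]:
        return tokenize(doc, spec)

    common = dict(
        tokenizer=_tok,
        preprocessor=lambda d: d,     # lowercasing handled in tokenize
        lowercase=False,
        token_pattern=None,
        ngram_range=spec.ngram_range,
    )
    if spec.kind == "onehot":
        vec = CountVectorizer(binary=True, **common)
    else:
        # matches the documented dialect: raw counts, smooth idf, l2 norm
        vec = TfidfVectorizer(norm="l2", smooth_idf=True, sublinear_tf=False,
                              **common)
    try:
        matrix = vec.fit_transform(texts).tocsr()
    except ValueError as exc:
        raise VectorizationError(str(exc)) from exc
    # sklearn sorts its vocabulary lexicographically already; rely on it
    vocab = {term: int(idx) for term, idx in vec.vocabulary_.items()}
    return FeatureMatrix(
        matrix=matrix,
        vocabulary=vocab,
        spec=spec,
        fingerprint=corpus_fingerprint(corpus),
    )


@dataclass
class FeatureCache:
    """Keyed store of feature matrices shared across agents.

    Keys combine the corpus fingerprint with the vectorizer spec, so a
    corpus edit invalidates stale entries while differently-configured
    extractors coexist.
    """

    _entries: dict[tuple, FeatureMatrix] = field(default_factory=dict)
    n_builds: int = 0

    def get_or_build(self, corpus, spec: VectorizerSpec) -> FeatureMatrix:
        fp = corpus_fingerprint(corpus)
        key = (fp, spec.cache_key())
        hit = self._entries.get(key)
        if hit is not None:
            return hit
        built = fit_transform(corpus, spec)
        self._entries[key] = built
        self.n_builds += 1
        return built

    def __len__(self) -> int:
        return len(self._entries)


def feature_cache_get_or_build(cache: Optional[FeatureCache], corpus,
                               spec: VectorizerSpec) -> FeatureMatrix:
    """Fetch from the cache (building on miss); bypasses if cache is None."""
    if cache is None:
        return fit_transform(corpus, spec)
    return cache.get_or_build(corpus, spec)
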