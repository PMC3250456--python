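"""Sparse term-vector document model and the Soergel distance.

Documents (title + abstract) are lowercased, tokenized, stopword-filtered,
stripped of pure numerals and of DNA-like tokens (>=6 characters drawn only
from A/C/G/T), and Porter-stemmed. Each document becomes a sparse
tf-idf vector with cosine (L2) normalization:

    r_{t,d} = f_{t,d} * ln(N / n_t)
    w_{t,d} = r_{t,d} / sqrt(sum_t' r_{t',d}^2)

where f_{t,d} is the term frequency, n_t the document frequency and N the
corpus size. Terms occurring in every document get idf 0 and drop out.

Distances between documents use the Soergel distance

    D(u, v) = sum_t |u_t - v_t| / sum_t max(u_t, v_t)

over the union of stored terms: a true metric on nonnegative vectors,
0 for identical vectors and exactly 1 when the supports are disjoint.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import porter

try:  # default stopword list; a user file overrides it
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS
    DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)
except ImportError:  # pragma: no cover
    DEFAULT_STOPWORDS = frozenset()


class UndefinedDistanceError(ValueError):
    """Soergel distance is undefined when both vectors are empty."""


_TOKEN = re.compile(r"[a-z0-9]+")
_NUMERAL = re.compile(r"[0-9]+$")
_DNA = re.compile(r"[acgt]{6,}$")


def tokenize_and_stem(
    text: str, stopwords: Iterable[str] | None = None
) -> list[str]:
    """Lowercase, tokenize, filter, and Porter-stem a text.

    Removes stopwords, pure-numeral tokens (unit-less measurements such as
    "12" or the pieces of "12.5"), and DNA-sequence-like tokens composed
    solely of >=6 A/C/G/T characters.
    """
    stop = DEFAULT_STOPWORDS if stopwords is None else set(stopwords)
    out: list[str] = []
    for tok in _TOKEN.findall(text.lower()):
        if tok in stop:
            continue
        if _NUMERAL.fullmatch(tok):
            continue
        if _DNA.fullmatch(tok):
            continue
        out.append(porter.stem(tok))
    return out


@dataclass(frozen=True)
class TermVector:
    """Sparse nonnegative term->weight map for one document.

    Stored weights are strictly positive; any nonzero vector has unit
    Euclidean norm.
    """

    doc_id: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.weights)


@dataclass
class Vocabulary:
    """Stemmed term universe with document frequencies."""

    doc_frequency: dict[str, int]
    N: int

    @property
    def terms(self) -> set[str]:
        return set(self.doc_frequency)


def build_vectors(
    corpus, stopwords: Iterable[str] | None = None
) -> tuple[Vocabulary, dict[str, TermVector]]:
    """Model every corpus document as a cosine-normalized tf-idf vector.

    Deterministic and invariant to corpus ordering. Documents whose raw
    weights are all zero (every term appears in all N documents) yield the
    empty vector.
    """
    docs = list(corpus)
    counts: dict[str, dict[str, int]] = {}
    for doc in docs:
        tf: dict[str, int] = {}
        for term in tokenize_and_stem(doc.title + " " + doc.abstract, stopwords):
            tf[term] = tf.get(term, 0) + 1
        counts[doc.doc_id] = tf

    df: dict[str, int] = {}
    for tf in counts.values():
        for term in tf:
            df[term] = df.get(term, 0) + 1
    N = len(docs)
    vocab = Vocabulary(doc_frequency=df, N=N)

    idf = {t: math.log(N / n) for t, n in df.items()}
    vectors: dict[str, TermVector] = {}
    for doc in docs:
        raw = {
            t: f * idf[t]
            for t, f in counts[doc.doc_id].items()
            if idf[t] > 0.0
        }
        norm = math.sqrt(sum(w * w for w in raw.values()))
        if norm > 0.0:
            weights = {t: w / norm for t, w in sorted(raw.items())}
        else:
            weights = {}
        vectors[doc.doc_id] = TermVector(doc_id=doc.doc_id, weights=weights)
    return vocab, vectors


def soergel_distance(u: TermVector | Mapping[str, float],
                     v: TermVector | Mapping[str, float]) -> float:
    """Soergel distance in [0, 1] between two sparse nonnegative vectors."""
    uw = u.weights if isinstance(u, TermVector) else u
    vw = v.weights if isinstance(v, TermVector) else v
    if not uw and not vw:
        raise UndefinedDistanceError(
            "Soergel distance undefined for two empty vectors"
        )
    num = 0.0
    den = 0.0
    # sorted union keeps summation order (hence rounding) symmetric in u, v
    for t in sorted(uw.keys() | vw.keys()):
        a = uw.get(t, 0.0)
        b = vw.get(t, 0.0)
        num += abs(a - b)
        den += a if a >= b else b
    if den == 0.0:  # only possible with all-zero stored weights
        raise UndefinedDistanceError("Soergel distance undefined: zero union")
    d = num / den
    # guard tiny float overshoot so the contract range holds exactly
    return 0.0 if d < 0.0 else (1.0 if d > 1.0 else d)


def save_vectors(path: str, vocab: Vocabulary,
                 vectors: Mapping[str, TermVector]) -> None:
    """Persist vectors as a sparse coordinate text file plus a term index.

    ``path`` gets the (doc, term, weight) triples; ``path + '.terms.tsv'``
    gets the term index with document frequencies.
    """
    terms = sorted(vocab.doc_frequency)
    t_index = {t: i for i, t in enumerate(terms)}
    with open(path + ".terms.tsv", "w", encoding="utf-8") as fh:
        for t in terms:
            fh.write(f"{t}\t{vocab.doc_frequency[t]}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"%%storyline sparse vectors N={vocab.N}\n")
        for doc_id in sorted(vectors):
            for t, w in vectors[doc_id].weights.items():
                fh.write(f"{doc_id}\t{t_index[t]}\t{w:.12g}\n")


def load_vectors(path: str) -> tuple[Vocabulary, dict[str, TermVector]]:
    """Inverse of :func:`save_vectors`."""
    terms: list[str] = []
    df: dict[str, int] = {}
    with open(path + ".terms.tsv", encoding="utf-8") as fh:
        for line in fh:
            t, n = line.rstrip("\n").split("\t")
            terms.append(t)
            df[t] = int(n)
    weights: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        N = int(header.strip().rsplit("N=", 1)[1])
        for line in fh:
            doc_id, ti, w = line.rstrip("\n").split("\t")
            weights.setdefault(doc_id, {})[terms[int(ti)]] = float(w)
    vectors = {
        d: TermVector(doc_id=d, weights=dict(sorted(w.items())))
        for d, w in weights.items()
    }
    return Vocabulary(doc_frequency=df, N=N), vectors


def load_stopwords(path: str) -> frozenset[str]:
    """Read a one-term-per-line stopword file."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower() for line in fh if line.strip()
        )
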