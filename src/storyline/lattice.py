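"""Concept-lattice index over the binarized term-document matrix.

Closed itemsets ("concepts") are maximal (document set, term set) pairs:
the documents are exactly those containing every term of the term set, and
the terms exactly those shared by every document of the document set. The
per-document concept lists, ordered by descending term-set size, serve as an
approximate nearest-neighbor index: documents co-occurring in a concept with
a long term set share many terms and hence tend to be close in Soergel
distance. The index replaces any materialized all-pairs similarity graph.

The miner is a prefix-preserving closure-extension DFS (LCM/Close-by-One
style); any correct closed-set enumerator is contractually equivalent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class Concept:
    """A closed (document set, term set) pair."""

    doc_set: frozenset[str]
    term_set: frozenset[str]

    def sort_key(self) -> tuple:
        # larger term sets first; ties by lexicographically smallest term set
        return (-len(self.term_set), tuple(sorted(self.term_set)))


@dataclass
class ConceptIndex:
    """All concepts meeting min_support plus per-document ordered lists."""

    concepts: list[Concept]
    per_doc: dict[str, list[Concept]] = field(default_factory=dict)
    min_support: float = 0.0

    def __len__(self) -> int:
        return len(self.concepts)


def binarize(vectors: Mapping[str, "TermVector"]) -> dict[str, set[str]]:  # noqa: F821
    """Document -> set of terms with positive modeled weight."""
    return {d: set(v.weights) for d, v in vectors.items()}


def mine_concepts(
    doc_terms: Mapping[str, set[str]] | Mapping[str, Sequence[str]],
    min_support: float,
) -> ConceptIndex:
    """Mine exactly the closed itemsets with support >= ``min_support``.

    ``doc_terms`` maps each document id to its term set (the boolean
    doc x term matrix in sparse form). ``min_support`` is a fraction of the
    corpus; a concept's support is |doc_set| / N. Concepts with empty term
    sets are not itemsets and are not reported.
    """
    if not doc_terms:
        raise ValueError("empty matrix")
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must be in (0, 1]")

    docs = sorted(doc_terms)
    n = len(docs)
    min_count = max(1, math.ceil(min_support * n - 1e-12))

    tids: dict[str, frozenset[str]] = {}
    for d in docs:
        for t in doc_terms[d]:
            tids.setdefault(t, frozenset())
    for t in tids:
        tids[t] = frozenset(d for d in docs if t in doc_terms[d])
    terms = sorted(tids)

    def closure(tidset: frozenset[str]) -> frozenset[str]:
        return frozenset(t for t in terms if tids[t] >= tidset)

    concepts: list[Concept] = []

    def emit(tidset: frozenset[str], itemset: frozenset[str]) -> None:
        if itemset:
            concepts.append(Concept(doc_set=tidset, term_set=itemset))

    def extend(itemset: frozenset[str], tidset: frozenset[str],
               core: int) -> None:
        for i in range(core + 1, len(terms)):
            t = terms[i]
            if t in itemset:
                continue
            new_tid = tidset & tids[t]
            if len(new_tid) < min_count:
                continue
            new_close = closure(new_tid)
            # prefix-preservation: reject extensions whose closure pulls in
            # an earlier term not already present (they are reached elsewhere)
            if any(terms[j] in new_close and terms[j] not in itemset
                   for j in range(i)):
                continue
            emit(new_tid, new_close)
            extend(new_close, new_tid, i)

    all_docs = frozenset(docs)
    root = closure(all_docs)
    emit(all_docs, root)
    extend(root, all_docs, -1)

    if not concepts:
        warnings.warn(
            f"min_support={min_support} leaves no concept; index is empty",
            stacklevel=2,
        )

    concepts.sort(key=Concept.sort_key)
    per_doc: dict[str, list[Concept]] = {d: [] for d in docs}
    for c in concepts:
        for d in c.doc_set:
            per_doc[d].append(c)
    return ConceptIndex(concepts=concepts, per_doc=per_doc,
                        min_support=min_support)


def default_min_support(n_docs: int) -> float:
    """Support fraction giving an expected support count of ~2 documents."""
    return min(1.0, 2.0 / max(n_docs, 1))


def candidate_neighbors(index: ConceptIndex, doc: str, m: int) -> list[str]:
    """Up to ``m`` approximate nearest neighbors of ``doc``.

    Walks the document's concepts in decreasing term-set-size order and
    emits co-member documents (deduplicated, excluding the query) until m
    candidates are collected or the concepts are exhausted. Every candidate
    shares at least one term with the query by construction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    out: list[str] = []
    seen = {doc}
    for concept in index.per_doc.get(doc, ()):
        for member in sorted(concept.doc_set):
            if member in seen:
                continue
            seen.add(member)
            out.append(member)
            if len(out) == m:
                return out
    return out
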