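"""Story evaluation and presentation.

The dispersion plot realizes Swanson's complementary-but-disjoint ideal: a
good story's non-adjacent documents should NOT satisfy the distance
threshold. For junctions d_0..d_{n-1}, cells (i, j) with j >= i+2 fill when
soergel(d_i, d_j) <= theta, and the dispersion coefficient is

    eta = 1 - sum_{filled} (j - i - 1) / sum_{all j>=i+2} (j - i - 1)

so a filled cell deep in the lower-left corner (a long-range shortcut)
penalizes more than one near the diagonal. eta is 1 for an ideal story
(no non-adjacent pair within threshold) and 0 in the worst case (all
filled). The linear corner-heavy weight is the package's reconstruction of
that behaviour and is pluggable.

Also here: MeSH labeling of chain documents (the MeSH term occurring most
often in the abstract) and Table-style story summaries from the cohesion
sentence path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .corpus import Document
from .vectors import TermVector, soergel_distance


class LabelingError(ValueError):
    """Raised when a document has no MeSH terms to label with."""


@dataclass
class DispersionPlot:
    """Threshold-satisfaction matrix over non-adjacent junction pairs."""

    n: int
    theta: float
    filled: set[tuple[int, int]]
    coefficient: float

    def to_tsv(self) -> str:
        """0/1 matrix, rows/cols = junction indices (adjacent cells blank)."""
        lines = ["\t" + "\t".join(str(j) for j in range(self.n))]
        for i in range(self.n):
            row = [str(i)]
            for j in range(self.n):
                if j >= i + 2:
                    row.append("1" if (i, j) in self.filled else "0")
                else:
                    row.append(".")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def linear_weight(i: int, j: int) -> float:
    """Corner-heavy cell weight; grows with the pair's junction separation."""
    return float(j - i - 1)


def dispersion(
    junctions: Sequence[str],
    vectors: Mapping[str, TermVector],
    theta: float,
    weight: Callable[[int, int], float] = linear_weight,
) -> DispersionPlot:
    """Dispersion plot and coefficient of a story's junction sequence.

    Evaluates the story's junctions only, never the evidence cliques. For
    n < 3 there are no non-adjacent pairs and eta = 1.
    """
    n = len(junctions)
    if n < 2:
        raise ValueError("a story has at least 2 documents")
    filled: set[tuple[int, int]] = set()
    total_w = 0.0
    filled_w = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            w = weight(i, j)
            total_w += w
            if soergel_distance(vectors[junctions[i]], vectors[junctions[j]]) <= theta:
                filled.add((i, j))
                filled_w += w
    eta = 1.0 if total_w == 0.0 else 1.0 - filled_w / total_w
    return DispersionPlot(n=n, theta=theta, filled=filled, coefficient=eta)


def mesh_label(doc: Document) -> str:
    """The document's most-frequent-in-abstract MeSH term.

    Occurrences are counted case-insensitively in the abstract text; ties
    break to the lexicographically first term, and if no term occurs at all
    the first listed MeSH term is returned.
    """
    if not doc.mesh_terms:
        raise LabelingError(f"document {doc.doc_id!r} has no MeSH terms")
    abstract = doc.abstract.lower()
    best_term = None
    best_count = 0
    for term in sorted(set(doc.mesh_terms), key=str.lower):
        count = len(
            re.findall(re.escape(term.lower()), abstract)
        )
        if count > best_count:
            best_term, best_count = term, count
    if best_term is None:
        return doc.mesh_terms[0]
    return best_term


@dataclass(frozen=True)
class SummaryRow:
    doc_id: str
    mesh_label: str
    title: str
    chosen_sentence: str


def summarize(
    story_docs: Sequence[Document],
    sentence_path: Sequence[tuple[str, int]],
) -> list[SummaryRow]:
    """One row per junction: id, MeSH label, title, cohesion-path sentence.

    ``sentence_path`` is the entity-linked path from the cohesion filter;
    stories must pass that filter before summarization.
    """
    if sentence_path is None or len(sentence_path) != len(story_docs):
        raise ValueError(
            "summarize requires a cohesion sentence path covering the story"
        )
    rows = []
    for doc, (doc_id, pos) in zip(story_docs, sentence_path):
        if doc.doc_id != doc_id:
            raise ValueError("sentence path misaligned with story documents")
        rows.append(
            SummaryRow(
                doc_id=doc.doc_id,
                mesh_label=mesh_label(doc),
                title=doc.title,
                chosen_sentence=doc.sentences[pos],
            )
        )
    return rows


def summary_tsv(rows: Sequence[SummaryRow]) -> str:
    lines = ["doc_id\tmesh\ttitle\tchosen_sentence"]
    for r in rows:
        lines.append(
            f"{r.doc_id}\t{r.mesh_label}\t{r.title}\t{r.chosen_sentence}"
        )
    return "\n".join(lines) + "\n"
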