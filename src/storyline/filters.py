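"""Post-search story filters: context overlap and sentence cohesion.

Abstracts broadly open with background/context sentences and close with
result/conclusion sentences. A Naive Bayes classifier separates the two
classes from (i) the sentence's distance-from-title (DFT = #preceding/N_s,
discretized into 10 equal bins) and (ii) presence of indicator phrases
("investigated", "observed", ...). The context overlap filter then requires
a minimum Jaccard coefficient between the context-token sets of every
consecutive document pair, and the sentence cohesion filter requires an
entity-linked path of sentences (one per document) across the story, which
also yields the story's summary sentences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Document
from .vectors import tokenize_and_stem

# Indicator phrases named as class markers; user lexicons replace this list.
DEFAULT_PHRASES: tuple[str, ...] = (
    "investigated",
    "known to",
    "study",
    "evident",
    "identified",
    "significant change",
    "observed",
    "showed",
)

CONTEXT = "context"
RESULT = "result"
N_BINS = 10


class TrainingError(ValueError):
    """Raised when classifier training data is unusable."""


@dataclass(frozen=True)
class SentenceRecord:
    """One abstract sentence with its position-derived DFT feature."""

    doc_id: str
    position: int
    n_sentences: int
    text: str
    label: str | None = None

    @property
    def dft(self) -> float:
        return self.position / self.n_sentences

    @property
    def bin(self) -> int:
        # bins [0,0.1), ..., [0.9,1.0]; DFT < 1 by construction but the
        # final bin is closed for robustness to externally supplied values
        return min(int(self.dft * N_BINS), N_BINS - 1)


def sentence_records(doc: Document) -> list[SentenceRecord]:
    n = len(doc.sentences)
    return [
        SentenceRecord(doc_id=doc.doc_id, position=i, n_sentences=n, text=s)
        for i, s in enumerate(doc.sentences)
    ]


def _phrases_in(text: str, lexicon: Sequence[str]) -> list[str]:
    low = text.lower()
    return [p for p in lexicon if p in low]


@dataclass
class SentenceClassifierModel:
    """Naive Bayes over DFT bins and indicator-phrase presence.

    ``bin_likelihood[i][c]`` is the smoothed share of bin-i training
    sentences of class c; ``phrase_likelihood[p][c]`` likewise over the
    sentences containing phrase p. Phrase features contribute only when
    present in a sentence.
    """

    prior: dict[str, float]
    bin_likelihood: list[dict[str, float]]
    phrase_likelihood: dict[str, dict[str, float]]
    phrase_lexicon: tuple[str, ...] = DEFAULT_PHRASES
    alpha: float = 1.0


def train_classifier(
    labeled: Sequence[SentenceRecord],
    phrase_lexicon: Sequence[str] = DEFAULT_PHRASES,
    alpha: float = 1.0,
) -> SentenceClassifierModel:
    """Estimate priors and per-feature class shares from tagged sentences.

    prior(c) = class count / total. Each likelihood is
    (class-c count + alpha) / (feature count + 2 alpha), Laplace-smoothed so
    unseen features stay uninformative (0.5/0.5) instead of vetoing a class.
    """
    labels = {s.label for s in labeled}
    if labels != {CONTEXT, RESULT}:
        raise TrainingError(
            f"training data must contain both classes, got {sorted(labels - {None})}"
        )
    total = len(labeled)
    n_ctx = sum(1 for s in labeled if s.label == CONTEXT)
    prior = {CONTEXT: n_ctx / total, RESULT: (total - n_ctx) / total}

    bin_counts = [{CONTEXT: 0, RESULT: 0} for _ in range(N_BINS)]
    for s in labeled:
        bin_counts[s.bin][s.label] += 1
    bin_likelihood = [
        {
            c: (bc[c] + alpha) / (bc[CONTEXT] + bc[RESULT] + 2 * alpha)
            for c in (CONTEXT, RESULT)
        }
        for bc in bin_counts
    ]

    phrase_counts = {p: {CONTEXT: 0, RESULT: 0} for p in phrase_lexicon}
    for s in labeled:
        for p in _phrases_in(s.text, phrase_lexicon):
            phrase_counts[p][s.label] += 1
    phrase_likelihood = {
        p: {
            c: (pc[c] + alpha) / (pc[CONTEXT] + pc[RESULT] + 2 * alpha)
            for c in (CONTEXT, RESULT)
        }
        for p, pc in phrase_counts.items()
    }
    return SentenceClassifierModel(
        prior=prior,
        bin_likelihood=bin_likelihood,
        phrase_likelihood=phrase_likelihood,
        phrase_lexicon=tuple(phrase_lexicon),
        alpha=alpha,
    )


def classify_sentence(
    model: SentenceClassifierModel, sentence: SentenceRecord
) -> str:
    """Most probable class; exact posterior ties resolve to context."""
    phrases = _phrases_in(sentence.text, model.phrase_lexicon)
    scores = {}
    for c in (CONTEXT, RESULT):
        s = model.prior[c] * model.bin_likelihood[sentence.bin][c]
        for p in phrases:
            s *= model.phrase_likelihood[p][c]
        scores[c] = s
    return CONTEXT if scores[CONTEXT] >= scores[RESULT] else RESULT


def classify_document(
    model: SentenceClassifierModel, doc: Document
) -> list[str]:
    return [classify_sentence(model, s) for s in sentence_records(doc)]


def _context_tokens(
    doc: Document, labels: Sequence[str], stopwords: Iterable[str] | None
) -> set[str]:
    ctx = " ".join(
        s for s, lab in zip(doc.sentences, labels) if lab == CONTEXT
    )
    return set(tokenize_and_stem(ctx, stopwords))


def context_overlap_filter(
    story_docs: Sequence[Document],
    sentence_labels: Mapping[str, Sequence[str]],
    j_min: float = 0.05,
    stopwords: Iterable[str] | None = None,
) -> tuple[bool, list[float]]:
    """Minimum context Jaccard across every consecutive document pair.

    The per-link score is |A n B| / |A u B| over the stemmed, stopword-free
    token sets of each document's concatenated context sentences; a document
    with no context sentences scores 0 on its links. Returns
    (pass, per-link scores); pass requires every link >= j_min.
    """
    token_sets = [
        _context_tokens(d, sentence_labels[d.doc_id], stopwords)
        for d in story_docs
    ]
    scores: list[float] = []
    for a, b in zip(token_sets, token_sets[1:]):
        union = a | b
        scores.append(len(a & b) / len(union) if union else 0.0)
    return all(s >= j_min for s in scores), scores


# --- named entities ---------------------------------------------------------


@dataclass
class EntityAnnotation:
    """(doc_id, sentence position) -> set of recognized entity surface forms."""

    by_sentence: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    def entities(self, doc_id: str, position: int) -> set[str]:
        return self.by_sentence.get((doc_id, position), set())


class GazetteerRecognizer:
    """Longest-match, case-insensitive dictionary entity recognizer.

    Overlapping candidate mentions resolve to the longest match only
    ("pyruvate kinase" beats "kinase"). The recognizer interface is a
    callable text -> set of canonical entity names, so externally produced
    annotations can be plugged in instead.
    """

    def __init__(self, gazetteer: Iterable[str]):
        entries = sorted(
            {e.strip() for e in gazetteer if e.strip()},
            key=lambda e: (-len(e), e.lower()),
        )
        if not entries:
            raise ValueError("gazetteer is empty")
        self.entries = entries
        self._patterns = [
            (e, re.compile(r"(?<![A-Za-z0-9])" + re.escape(e) + r"(?![A-Za-z0-9])",
                           re.IGNORECASE))
            for e in entries
        ]

    def __call__(self, text: str) -> set[str]:
        found: set[str] = set()
        claimed: list[tuple[int, int]] = []
        for entity, pat in self._patterns:  # longest entries first
            for mt in pat.finditer(text):
                span = mt.span()
                if any(s < span[1] and span[0] < e for s, e in claimed):
                    continue  # inside a longer match
                claimed.append(span)
                found.add(entity)
        return found


def annotate_entities(
    docs: Iterable[Document], recognizer
) -> EntityAnnotation:
    """Map every sentence of every document to its (possibly empty) entities."""
    ann = EntityAnnotation()
    for doc in docs:
        for i, sent in enumerate(doc.sentences):
            ann.by_sentence[(doc.doc_id, i)] = set(recognizer(sent))
    return ann


def cohesion_filter(
    story_docs: Sequence[Document],
    annotations: EntityAnnotation,
) -> tuple[bool, list[tuple[str, int]] | None, float]:
    """Entity-linked sentence path across the story's documents.

    Builds a layered graph (layer i = sentences of document i, edges between
    consecutive layers where entity sets intersect). The story passes when a
    start-to-end path exists; the returned path maximizes the summed
    per-edge Jaccard coefficient between neighboring entity sets, ties
    resolving to the earliest sentence positions. Returns
    (pass, path or None, best path score).
    """
    layers: list[list[tuple[int, set[str]]]] = [
        [
            (i, annotations.entities(doc.doc_id, i))
            for i in range(len(doc.sentences))
        ]
        for doc in story_docs
    ]
    # DP over layers: best cumulative Jaccard ending at each sentence
    NEG = float("-inf")
    score: list[dict[int, float]] = [{i: 0.0 for i, _ in layers[0]}]
    back: list[dict[int, int]] = [{}]
    for li in range(1, len(layers)):
        cur: dict[int, float] = {}
        bk: dict[int, int] = {}
        for i, ents in layers[li]:
            best_s, best_prev = NEG, -1
            if ents:
                for j, prev_ents in layers[li - 1]:
                    prev_s = score[li - 1].get(j, NEG)
                    if prev_s == NEG:
                        continue
                    inter = ents & prev_ents
                    if not inter:
                        continue
                    jac = len(inter) / len(ents | prev_ents)
                    s = prev_s + jac
                    # strictly-better wins; ties keep the earliest previous
                    # sentence (j ascending ensures that)
                    if s > best_s:
                        best_s, best_prev = s, j
            if best_prev >= 0:
                cur[i] = best_s
                bk[i] = best_prev
        score.append(cur)
        back.append(bk)
    final = score[-1]
    if not final:
        return False, None, 0.0
    best_score = max(final.values())
    last = min(i for i, s in final.items() if s == best_score)
    path_positions = [last]
    for li in range(len(layers) - 1, 0, -1):
        path_positions.append(back[li][path_positions[-1]])
    path_positions.reverse()
    path = [
        (doc.doc_id, pos) for doc, pos in zip(story_docs, path_positions)
    ]
    return True, path, best_score


def load_gazetteer(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def load_phrase_lexicon(path: str) -> tuple[str, ...]:
    with open(path, encoding="utf-8") as fh:
        return tuple(line.strip().lower() for line in fh if line.strip())


def load_labeled_sentences(path: str) -> list[SentenceRecord]:
    """Read a training TSV of (doc_id, position, text, label).

    Rows must cover whole abstracts: each document's sentence count is
    inferred as its largest position + 1.
    """
    rows: list[tuple[str, int, str, str]] = []
    n_by_doc: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            doc_id, pos, text, label = line.rstrip("\n").split("\t")
            rows.append((doc_id, int(pos), text, label))
            n_by_doc[doc_id] = max(n_by_doc.get(doc_id, 0), int(pos) + 1)
    return [
        SentenceRecord(
            doc_id=d, position=p, n_sentences=n_by_doc[d], text=t, label=lab
        )
        for d, p, t, lab in rows
    ]


def save_labeled_sentences(path: str, records: Sequence[SentenceRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.doc_id}\t{r.position}\t{r.text}\t{r.label}\n")
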