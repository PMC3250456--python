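"""Deterministic synthetic corpora with planted story structure.

The generator emits an abstracts corpus shaped like the pipeline's real
inputs: topic clusters of mutually similar documents, a planted bridge
chain whose adjacent documents share a controlled fraction of vocabulary
(and whose non-adjacent documents share none — Swanson's complementary-
but-disjoint shape), context-then-result sentence structure with indicator
phrases, gazetteer entities threaded along the bridge so exactly the
planted sentence path is cohesive, review-flagged distractors, and MeSH
terms drawn from each document's own vocabulary.

Vocabulary is drawn from disjoint synthetic token pools per cluster and per
bridge link, which makes Soergel distances analytically controllable; the
boilerplate template words appear in every document and therefore carry
idf 0, vanishing from the modeled vectors. Generation is a pure function of
the parameter set, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Corpus, corpus_from_records
from .filters import CONTEXT, RESULT, SentenceRecord
from .vectors import build_vectors, soergel_distance


class GenerationError(ValueError):
    """Raised for contradictory synthesis parameters."""


@dataclass(frozen=True)
class SynthesisParams:
    """Study conditions for one synthetic corpus.

    chain_overlap is the fraction of a bridge document's planted terms
    shared with each adjacent bridge document; it must not exceed 0.5
    (a middle document shares with two neighbors from disjoint pools).
    chain_overlap = 0 plants a broken bridge: no two documents satisfy any
    usable distance threshold, so no story exists.
    """

    n_clusters: int = 2
    docs_per_cluster: int = 15
    vocab_per_cluster: int = 40
    shared_vocab: int = 6
    chain_length: int = 5
    chain_overlap: float = 0.5
    terms_per_doc: int = 12
    sentences_per_doc: int = 6
    context_fraction: float = 0.5
    gazetteer_size: int = 8
    review_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.chain_overlap <= 0.5):
            raise GenerationError(
                "chain_overlap must be in [0, 0.5]: a middle bridge document "
                "shares disjoint pools with two neighbors"
            )
        if self.chain_length < 2:
            raise GenerationError("chain_length must be >= 2")
        if self.n_clusters < 1 or self.docs_per_cluster < 1:
            raise GenerationError("cluster counts must be >= 1")
        if not (0.0 < self.context_fraction <= 1.0):
            raise GenerationError("context_fraction must be in (0, 1]")
        if self.terms_per_doc > self.vocab_per_cluster:
            raise GenerationError("terms_per_doc exceeds cluster vocabulary")
        if self.sentences_per_doc < 2:
            raise GenerationError("sentences_per_doc must be >= 2")


# Template words recur in every document, so they get idf 0 and drop out of
# the vector model; planted tokens end in 'x'/'q' so Porter leaves them be.
_CONTEXT_TEMPLATE = "In this study we investigated {terms}."
_RESULT_TEMPLATE = "We observed that {terms} showed significant change."

START_LABEL = "startmol"
END_LABEL = "endmol"
_START_KEYWORD = "alphastartx"
_END_KEYWORD = "betaendx"


def _cluster_term(c: int, i: int) -> str:
    return f"clu{c}t{i:03d}x"


def _bridge_overlap_term(link: int, i: int) -> str:
    return f"brg{link}o{i:03d}x"


def _bridge_private_term(doc: int, i: int) -> str:
    return f"brg{doc}p{i:03d}x"


def _entity(i: int) -> str:
    return f"entq{i:02d}x"


def _distractor_entity(i: int) -> str:
    return f"distq{i:02d}x"


def _shared_term(i: int) -> str:
    return f"sharedt{i:02d}x"


def _sentences(
    context_terms: Sequence[Sequence[str]],
    result_terms: Sequence[Sequence[str]],
) -> list[str]:
    out = [
        _CONTEXT_TEMPLATE.format(terms=" ".join(ts)) for ts in context_terms
    ]
    out += [
        _RESULT_TEMPLATE.format(terms=" ".join(ts)) for ts in result_terms
    ]
    return out


def _chunk(terms: Sequence[str], n_chunks: int) -> list[list[str]]:
    """Deal terms into n_chunks round-robin; every chunk non-empty."""
    if n_chunks == 0:
        return []
    chunks: list[list[str]] = [[] for _ in range(n_chunks)]
    for i, t in enumerate(terms):
        chunks[i % n_chunks].append(t)
    for c in chunks:
        if not c:
            c.append(terms[0] if terms else "fillerq")
    return chunks


def _make_doc_record(
    doc_id: str,
    title_terms: Sequence[str],
    context_terms: Sequence[str],
    result_terms: Sequence[str],
    n_context: int,
    n_result: int,
    mesh_terms: Sequence[str],
    publication_types: Sequence[str],
    entity_terms: Sequence[str] = (),
    entity_sentence: int = 0,
) -> dict:
    context_terms = list(context_terms)
    result_terms = list(result_terms)
    if n_result and not result_terms:
        result_terms = context_terms[-1:]
    ctx_chunks = _chunk(context_terms, n_context)
    res_chunks = _chunk(result_terms, n_result)
    if entity_terms:
        ctx_chunks[entity_sentence] = (
            ctx_chunks[entity_sentence] + list(entity_terms)
        )
    return {
        "doc_id": doc_id,
        "title": "Study of " + " ".join(title_terms),
        "abstract": " ".join(_sentences(ctx_chunks, res_chunks)),
        "mesh_terms": list(mesh_terms),
        "publication_types": list(publication_types),
    }


def generate_records(
    params: SynthesisParams,
) -> tuple[list[dict], dict]:
    """Raw corpus records (JSONL dialect) plus the planted ground truth."""
    rng = np.random.default_rng(params.rng_seed)
    L = params.chain_length
    T = params.terms_per_doc
    s = int(round(params.chain_overlap * T))
    n_context = math.ceil(params.context_fraction * params.sentences_per_doc)
    n_result = params.sentences_per_doc - n_context

    # --- bridge documents ------------------------------------------------
    overlap_sets = [
        [_bridge_overlap_term(link, i) for i in range(s)] for link in range(L - 1)
    ]
    entities = [_entity(i) for i in range(L - 1)]
    bridge_ids = [f"B{i:02d}" for i in range(L)]
    records: list[dict] = []
    sentence_classes: dict[str, list[str]] = {}

    for i in range(L):
        prev_overlap = overlap_sets[i - 1] if i > 0 else []
        next_overlap = overlap_sets[i] if i < L - 1 else []
        n_private = max(T - len(prev_overlap) - len(next_overlap), 0)
        private = [_bridge_private_term(i, j) for j in range(n_private)]
        # context sentences carry the link-shared vocabulary (plus threaded
        # entities when the chain is connected); results carry private terms
        ctx_terms = list(prev_overlap) + list(next_overlap)
        ents: list[str] = []
        if params.chain_overlap > 0:
            if i > 0:
                ents.append(entities[i - 1])
            if i < L - 1:
                ents.append(entities[i])
        else:
            # broken bridge: entities stay in their home document only
            if i < L - 1:
                ents.append(entities[i])
        res_terms = list(private)
        if not ctx_terms:
            ctx_terms = res_terms[: max(1, len(res_terms) // 2)]
            res_terms = res_terms[len(ctx_terms):] or list(ctx_terms)
        title_terms: list[str] = []
        cluster_ties: list[str] = []
        if i == 0:
            title_terms.append(_START_KEYWORD)
            cluster_ties = [_cluster_term(0, j) for j in range(2)]
        elif i == L - 1:
            title_terms.append(_END_KEYWORD)
            cluster_ties = [
                _cluster_term(params.n_clusters - 1, j) for j in range(2)
            ]
        res_terms = res_terms + cluster_ties
        mesh_source = private or ctx_terms
        mesh = [mesh_source[0].capitalize(), (ctx_terms or res_terms)[0].capitalize()]
        records.append(
            _make_doc_record(
                bridge_ids[i],
                title_terms + (private[:2] if private else ctx_terms[:2]),
                ctx_terms,
                res_terms,
                n_context,
                n_result,
                mesh,
                ["Journal Article"],
                entity_terms=ents,
                entity_sentence=min(1, n_context - 1),
            )
        )
        sentence_classes[bridge_ids[i]] = (
            [CONTEXT] * n_context + [RESULT] * n_result
        )

    # --- cluster documents -----------------------------------------------
    shared_pool = [_shared_term(i) for i in range(params.shared_vocab)]
    distractors = [
        _distractor_entity(i)
        for i in range(max(params.gazetteer_size - len(entities), 0))
    ]
    review_ids: list[str] = []
    n_reviews_per_cluster = int(round(params.review_fraction * params.docs_per_cluster))
    d_i = 0
    for c in range(params.n_clusters):
        pool = [_cluster_term(c, i) for i in range(params.vocab_per_cluster)]
        for j in range(params.docs_per_cluster):
            doc_id = f"C{c}d{j:02d}"
            terms = [
                pool[i]
                for i in rng.choice(len(pool), size=T, replace=False)
            ]
            if shared_pool:
                terms.append(
                    shared_pool[int(rng.integers(len(shared_pool)))]
                )
            extra: list[str] = []
            if d_i < len(distractors):
                extra = [distractors[d_i]]
                d_i += 1
            half = len(terms) // 2
            ctx_terms = terms[:half] + extra
            res_terms = terms[half:]
            is_review = j < n_reviews_per_cluster
            if is_review:
                review_ids.append(doc_id)
            records.append(
                _make_doc_record(
                    doc_id,
                    terms[:2],
                    ctx_terms,
                    res_terms,
                    n_context,
                    n_result,
                    [terms[0].capitalize(), terms[1].capitalize()],
                    ["Journal Article", "Review"] if is_review else ["Journal Article"],
                )
            )
            sentence_classes[doc_id] = (
                [CONTEXT] * n_context + [RESULT] * n_result
            )

    # --- ground truth ----------------------------------------------------
    corpus = corpus_from_records(records)
    _, vectors = build_vectors(corpus)
    adjacent = [
        soergel_distance(vectors[a], vectors[b])
        for a, b in zip(bridge_ids, bridge_ids[1:])
    ]
    non_adjacent = [
        soergel_distance(vectors[bridge_ids[i]], vectors[bridge_ids[j]])
        for i in range(L)
        for j in range(i + 2, L)
    ]
    d_adj_max = max(adjacent)
    d_other_min = min(non_adjacent) if non_adjacent else 1.0
    if params.chain_overlap > 0:
        theta_star = min(d_adj_max + 0.05, (d_adj_max + d_other_min) / 2.0)
    else:
        theta_star = 0.95  # nothing satisfies it: the bridge is broken

    gazetteer = entities + distractors
    ground_truth = {
        "junctions": bridge_ids,
        "theta_star": theta_star,
        "adjacent_distances": adjacent,
        "min_non_adjacent_distance": d_other_min,
        "keyword_sets": {
            START_LABEL: [_START_KEYWORD],
            END_LABEL: [_END_KEYWORD],
        },
        "start_label": START_LABEL,
        "end_label": END_LABEL,
        "entity_path": [
            [doc_id, min(1, n_context - 1)] for doc_id in bridge_ids
        ],
        "entities": entities,
        "gazetteer": gazetteer,
        "review_ids": review_ids,
        "sentence_classes": sentence_classes,
    }
    return records, ground_truth


def generate_corpus(params: SynthesisParams) -> tuple[Corpus, dict]:
    """Review-pruned corpus plus ground truth (see generate_records)."""
    records, ground_truth = generate_records(params)
    return corpus_from_records(records), ground_truth


# --- classifier training data ------------------------------------------------

_CONTEXT_PHRASES = ("investigated", "known to", "study")
_RESULT_PHRASES = ("observed", "showed", "significant change", "evident",
                   "identified")
_FILLERS = ("cellq", "proteinq", "pathwayq", "responseq", "tissueq",
            "assayq", "sampleq", "signalq")


def generate_labeled_sentences(
    params: SynthesisParams, n_docs: int = 100
) -> list[SentenceRecord]:
    """Labeled sentences drawn from the sentence classifier's assumptions.

    Each synthetic abstract has 4-9 sentences; a sentence is a context
    sentence when its distance-from-title is below ``context_fraction``
    (with a 5% label flip for realism), and carries an indicator phrase of
    its class with probability 0.75 (of the opposite class with
    probability 0.05). Context is therefore concentrated near the title and
    phrases are class-skewed, mirroring real structured abstracts.
    """
    rng = np.random.default_rng(params.rng_seed + 101)
    out: list[SentenceRecord] = []
    for d in range(n_docs):
        n_s = int(rng.integers(4, 10))
        for pos in range(n_s):
            dft = pos / n_s
            label = CONTEXT if dft < params.context_fraction else RESULT
            if rng.random() < 0.05:
                label = RESULT if label == CONTEXT else CONTEXT
            words = list(rng.choice(_FILLERS, size=3, replace=True))
            u = rng.random()
            own = _CONTEXT_PHRASES if label == CONTEXT else _RESULT_PHRASES
            other = _RESULT_PHRASES if label == CONTEXT else _CONTEXT_PHRASES
            if u < 0.75:
                words.insert(1, own[int(rng.integers(len(own)))])
            elif u < 0.80:
                words.insert(1, other[int(rng.integers(len(other)))])
            text = "The " + " ".join(str(w) for w in words) + " here."
            out.append(
                SentenceRecord(
                    doc_id=f"T{d:03d}",
                    position=pos,
                    n_sentences=n_s,
                    text=text,
                    label=label,
                )
            )
    return out
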