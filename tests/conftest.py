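"""Shared fixtures: tiny hand-built corpora and the default synthetic corpus."""

from __future__ import annotations

import json

import pytest

from storyline.corpus import corpus_from_records
from storyline.synthetic import SynthesisParams, generate_corpus
from storyline.vectors import TermVector, build_vectors


def make_records(n: int = 4) -> list[dict]:
    """Small well-formed JSONL-dialect records."""
    base = [
        {
            "doc_id": "d1",
            "title": "Pyruvate kinase in tumor metabolism",
            "abstract": (
                "We investigated pyruvate kinase isoforms. "
                "Glutamine metabolism supports growth. "
                "We observed increased lactate production."
            ),
            "mesh_terms": ["Pyruvate Kinase", "Glutamine"],
            "publication_types": ["Journal Article"],
        },
        {
            "doc_id": "d2",
            "title": "Glutamine fuels the TCA cycle",
            "abstract": (
                "Glutamine is converted to glutamate. "
                "Malate can be converted to pyruvate."
            ),
            "mesh_terms": ["Glutamine"],
            "publication_types": ["Journal Article"],
        },
        {
            "doc_id": "d3",
            "title": "Lactate transport in muscle",
            "abstract": (
                "Lactate shuttles between tissues. "
                "We measured transport kinetics."
            ),
            "mesh_terms": ["Lactates"],
            "publication_types": ["Journal Article"],
        },
        {
            "doc_id": "d4",
            "title": "Hydrogen sulfide signaling",
            "abstract": (
                "Hydrogen sulfide is produced from cysteine. "
                "It relaxes smooth muscle."
            ),
            "mesh_terms": ["Hydrogen Sulfide"],
            "publication_types": ["Journal Article"],
        },
    ]
    return base[:n]


@pytest.fixture
def small_corpus():
    return corpus_from_records(make_records())


@pytest.fixture
def jsonl_file(tmp_path):
    def write(records):
        path = tmp_path / "corpus.jsonl"
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
        return str(path)

    return write


@pytest.fixture(scope="session")
def synthetic_default():
    """Default planted-story corpus, its ground truth, and its vectors."""
    params = SynthesisParams()
    corpus, gt = generate_corpus(params)
    vocab, vectors = build_vectors(corpus)
    return params, corpus, gt, vectors


def uniform_vector(doc_id: str, terms) -> TermVector:
    """Unit-weight sparse vector; Soergel needs only nonnegative weights."""
    return TermVector(doc_id=doc_id, weights={t: 1.0 for t in terms})
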