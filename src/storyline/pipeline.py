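"""End-to-end pipeline: ingest -> vectors -> index -> search -> filters -> report.

One declarative configuration drives the whole run; identical configuration
and inputs give identical outputs (all randomness flows from the seed). The
run report carries the surviving-story count after each stage, in pipeline
order: after A* search, after p/q-value filtering, after context filtering,
after sentence cohesion filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import corpus as corpus_io
from . import filters as story_filters
from . import lattice, report, search, significance
from .vectors import build_vectors, load_stopwords

log = logging.getLogger("storyline")

STAGES = (
    "after_astar_search",
    "after_pq_filtering",
    "after_context_filtering",
    "after_sentence_cohesion_filtering",
)


@dataclass
class PipelineConfig:
    """All pipeline parameters in one declarative document.

    File-based fields (corpus_path, gazetteer_path, ...) serve the CLI;
    the in-memory fields (corpus, gazetteer, labeled_sentences) let library
    callers skip serialization. In-memory fields win when both are set.
    """

    # inputs
    corpus_path: str | None = None
    corpus_format: str = "jsonl"
    corpus: corpus_io.Corpus | None = None
    stopwords_path: str | None = None
    # seed labeling
    keyword_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    start_labels: Sequence[str] = ()
    end_labels: Sequence[str] = ()
    seed_cap: int = 700
    max_seed_pairs: int | None = None
    # index + search
    min_support: float | None = None  # default: ~2 docs expected support
    theta: float = 0.90
    k: int = 3
    b: int = 5
    max_expansions: int = 100_000
    # significance
    iterations: int = 50_000
    rng_seed: int = 0
    p_max: float = 0.001
    q_max: float = 0.05
    q_method: str = "bh"
    pool: str = "candidates"  # or "corpus"
    # context filter
    labeled_sentences_path: str | None = None
    labeled_sentences: Sequence[story_filters.SentenceRecord] | None = None
    phrase_lexicon_path: str | None = None
    j_min: float = 0.05
    # cohesion filter
    gazetteer_path: str | None = None
    gazetteer: Sequence[str] | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        """The exact scalar configuration of a run, for logging."""
        out = {}
        for key, value in vars(self).items():
            if key in ("corpus", "labeled_sentences"):
                out[key] = None if value is None else f"<in-memory:{len(value)}>"
            elif key == "gazetteer":
                out[key] = list(value) if value is not None else None
            elif isinstance(value, Mapping):
                out[key] = {k: list(v) for k, v in value.items()}
            elif isinstance(value, (list, tuple)):
                out[key] = list(value)
            else:
                out[key] = value
        return out


@dataclass
class Story:
    """One surviving story with everything computed about it."""

    chain: search.CliqueChain
    significance: significance.SignificanceResult
    context_scores: list[float] | None = None
    sentence_path: list[tuple[str, int]] | None = None
    cohesion_score: float | None = None
    dispersion: report.DispersionPlot | None = None
    summary: list[report.SummaryRow] | None = None

    def to_dict(self) -> dict:
        return {
            "chain": self.chain.to_dict(),
            "junction_p": self.significance.junction_p,
            "chain_p": self.significance.chain_p,
            "q_value": self.significance.q_value,
            "context_scores": self.context_scores,
            "sentence_path": self.sentence_path,
            "cohesion_score": self.cohesion_score,
            "dispersion_coefficient": (
                None if self.dispersion is None else self.dispersion.coefficient
            ),
            "summary": (
                None
                if self.summary is None
                else [vars(r) for r in self.summary]
            ),
        }


@dataclass
class PipelineResult:
    stories: list[Story]
    stage_counts: dict[str, int]
    config: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "config": self.config,
            "provenance": self.provenance,
            "stories": [s.to_dict() for s in self.stories],
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full storytelling pipeline under one configuration."""
    log.info("resolved config: %s", config.resolved())

    # --- ingest ----------------------------------------------------------
    @_stage("ingest")
    def _ingest():
        if config.corpus is not None:
            return config.corpus
        if not config.corpus_path:
            raise ValueError("no corpus configured")
        return corpus_io.read_corpus(config.corpus_path, config.corpus_format)

    corpus = _ingest()
    stopwords = (
        load_stopwords(config.stopwords_path) if config.stopwords_path else None
    )

    # --- vectors + seeds -------------------------------------------------
    @_stage("vectors")
    def _vectors():
        return build_vectors(corpus, stopwords)

    vocab, vectors = _vectors()

    @_stage("seeds")
    def _seeds():
        corpus_io.label_seeds(corpus, config.keyword_sets, config.seed_cap)
        pairs = corpus_io.make_seed_pairs(
            corpus, config.start_labels, config.end_labels, vectors
        )
        if not pairs:
            log.warning("no labeled seed pairs; pipeline will yield no story")
        if config.max_seed_pairs is not None:
            pairs = pairs[: config.max_seed_pairs]
        return pairs

    pairs = _seeds()

    # --- index -----------------------------------------------------------
    @_stage("index")
    def _index():
        support = (
            config.min_support
            if config.min_support is not None
            else lattice.default_min_support(len(corpus))
        )
        return lattice.mine_concepts(lattice.binarize(vectors), support)

    index = _index()
    params = search.SearchParams(
        theta=config.theta,
        k=config.k,
        b=config.b,
        max_expansions=config.max_expansions,
    )

    # --- A* search ---------------------------------------------------------
    @_stage("search")
    def _search():
        chains = []
        for pair in pairs:
            chain = search.astar_story(
                pair.start_id, pair.end_id, params, index, vectors
            )
            if chain is not None:
                chains.append(chain)
        return chains

    chains = _search()
    stage_counts = {STAGES[0]: len(chains)}

    # --- significance ------------------------------------------------------
    @_stage("significance")
    def _significance():
        m = search.min_candidate_count(config.k, config.b)
        scored = []
        all_ids = sorted(vectors)
        for ci, chain in enumerate(chains):
            pools = []
            for clique in chain.cliques:
                if config.pool == "corpus":
                    pool = [d for d in all_ids if d != clique.junction]
                else:
                    pool = lattice.candidate_neighbors(index, clique.junction, m)
                    # lattice exhaustion near isolated documents: widen to
                    # the corpus pool so the test stays defined
                    if len(pool) < config.k - 1:
                        pool = [d for d in all_ids if d != clique.junction]
                pools.append(pool)
            res = significance.score_chain(
                chain,
                pools,
                config.theta,
                vectors,
                R=config.iterations,
                rng_seed=config.rng_seed * 7919 + ci,
            )
            scored.append((chain, res))
        return significance.significance_filter(
            scored, config.p_max, config.q_max
        )

    surviving = _significance()
    stage_counts[STAGES[1]] = len(surviving)

    # --- context overlap ---------------------------------------------------
    @_stage("context_filter")
    def _context():
        if config.labeled_sentences is not None:
            labeled = list(config.labeled_sentences)
        elif config.labeled_sentences_path:
            labeled = story_filters.load_labeled_sentences(
                config.labeled_sentences_path
            )
        else:
            raise ValueError("no labeled sentences for the context filter")
        lexicon = (
            story_filters.load_phrase_lexicon(config.phrase_lexicon_path)
            if config.phrase_lexicon_path
            else story_filters.DEFAULT_PHRASES
        )
        model = story_filters.train_classifier(labeled, lexicon)
        out = []
        for chain, res in surviving:
            docs = [corpus.get(j) for j in chain.junctions]
            labels = {
                d.doc_id: story_filters.classify_document(model, d)
                for d in docs
            }
            ok, scores = story_filters.context_overlap_filter(
                docs, labels, config.j_min, stopwords
            )
            if ok:
                out.append(Story(chain=chain, significance=res,
                                 context_scores=scores))
        return out

    stories = _context()
    stage_counts[STAGES[2]] = len(stories)

    # --- sentence cohesion -------------------------------------------------
    @_stage("cohesion_filter")
    def _cohesion():
        gaz = (
            list(config.gazetteer)
            if config.gazetteer is not None
            else story_filters.load_gazetteer(config.gazetteer_path)
            if config.gazetteer_path
            else None
        )
        if gaz is None:
            raise ValueError("no gazetteer for the cohesion filter")
        recognizer = story_filters.GazetteerRecognizer(gaz)
        out = []
        for story in stories:
            docs = [corpus.get(j) for j in story.chain.junctions]
            ann = story_filters.annotate_entities(docs, recognizer)
            ok, path, score = story_filters.cohesion_filter(docs, ann)
            if ok:
                story.sentence_path = path
                story.cohesion_score = score
                out.append(story)
        return out

    stories = _cohesion()
    stage_counts[STAGES[3]] = len(stories)

    # --- report ------------------------------------------------------------
    @_stage("report")
    def _report():
        for story in stories:
            story.dispersion = report.dispersion(
                story.chain.junctions, vectors, config.theta
            )
            docs = [corpus.get(j) for j in story.chain.junctions]
            story.summary = report.summarize(docs, story.sentence_path)
        return stories

    stories = _report()
    log.info("stage counts: %s", stage_counts)
    return PipelineResult(
        stories=stories,
        stage_counts=stage_counts,
        config=config.resolved(),
        provenance=dict(corpus.provenance),
    )
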