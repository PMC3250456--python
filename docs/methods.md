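# Methods

This note records the model, the parameter choices, and the design
decisions behind `storyline`, including what the synthetic corpus does and
does not emulate.

## Document model

Documents are bags of stemmed words over title + abstract. Tokenization
lowercases, splits on alphanumeric runs, removes stopwords (default: the
scikit-learn English list, overridable by a one-term-per-line file), drops
pure-numeral tokens and DNA-like tokens (≥6 characters drawn only from
A/C/G/T), then applies the classic Porter suffix-stripping algorithm
(implemented in `storyline.porter`, validated against published reference
stems).

Weights are tf-idf with cosine normalization: `r_{t,d} = f_{t,d} ln(N/n_t)`
and `w_{t,d} = r_{t,d} / ‖r_d‖₂`. Natural log is used; terms present in
every document get idf 0 and drop out of the sparse vectors, and a
document whose raw weights are all zero is modeled as the empty vector
(it can never anchor a story). Per-document length normalization beyond
the cosine norm is deliberately not applied: the cosine normalization
already absorbs abstract-length effects, which is its stated purpose.

The Soergel distance `D(u,v) = Σ|u_t − v_t| / Σ max(u_t, v_t)` is computed
over the sorted union of stored terms; sorting fixes the floating-point
summation order so that `D(u,v) == D(v,u)` exactly. The result is clamped
to [0,1] against ~1e-16 overshoot. Both-empty input raises an error rather
than returning a conventional value.

## Concept-lattice index

Nearest-neighbor candidates come from the closed itemsets ("concepts") of
the boolean term-document matrix (term present ⇔ modeled weight > 0).
The miner is a prefix-preserving closure-extension DFS (LCM/Close-by-One
family). The contract is the *output set* — exactly the closed itemsets
meeting minimum support — and the test suite enforces equality with
brute-force enumeration on random matrices, so any correct miner is
substitutable. Concepts with empty term sets are not reported.

Per document, concepts are ordered by descending term-set size (ties:
lexicographically smallest term set), and candidate neighbors are emitted
by walking that list — documents co-occurring in a concept with a long
shared term set are likely near in Soergel distance. The default minimum
support targets an expected support count of about two documents
(`2/N`), the smallest support at which a concept still links documents.
The per-document concept list is the ordering the neighbor lookup
consumes; the lattice's sub/superset edge structure is not materialized.

## Story search

Search parameters: distance threshold θ ∈ (0,1) (default 0.90), clique
size k ≥ 2 (default 3), branching factor b ≥ 1 (default 5), expansion
budget 100,000. The defaults sit inside the empirically useful band of
θ between 0.86 and 0.92 and clique sizes 2–8.

Successor generation takes the top `m` lattice candidates where m is the
smallest count with `C(m, k−1) ≥ b` — each clique is the junction plus a
(k−1)-subset, so m candidates yield at least b candidate cliques — then
validates every pairwise edge against θ (lattice candidates are
approximate, so validation is mandatory), scores each valid clique by the
mean distance from the junction to its other members, and keeps the b
best. Every non-junction member of a kept clique becomes a frontier node.

Path cost g accumulates junction-to-junction Soergel distance; clique
average distance only orders the successor queue. The heuristic
h(d) = D(d, end) is admissible and consistent because Soergel distance
obeys the triangle inequality, so the first time the end document is
popped the chain is optimal *for the explored successor graph* (which is
b-truncated; optimality is always relative to the branching constraint).
The goal test admits the end document into a clique with the current
junction even when the lattice candidate list misses it, provided every
clique edge satisfies θ. Junctions are simple (a document appears at most
once per chain); ties on f break toward smaller h, then document id.
Nothing quadratic in corpus size is ever allocated: memory follows the
frontier and the per-expansion distance cache.

## Significance

Null model per junction: a uniformly random (k−1)-subset of the junction's
candidate pool forms a valid clique. R samples (default 50,000) give
p = max(successes, 1)/R — the floor 1/R is the smallest resolvable
p-value at that iteration count. Chain p-values multiply junction
p-values; q-values over a story batch use Benjamini–Hochberg
(deterministic and parameter-free; a Storey-style π₀ rescaling with
λ = 0.5 sits behind `q_method="storey"`). Default cutoffs are explicit
configuration: p ≤ 0.001 and q ≤ 0.05.

The pool defaults to the m lattice candidates the observed clique was
drawn from; `pool="corpus"` switches to the whole corpus for sensitivity
analysis. At desk scale (tens of documents) the candidate pool is tiny
and nearly saturated with valid neighbors, so the corpus-wide pool is the
discriminating null and is what the end-to-end tests use. When a
junction's candidate list is smaller than k−1 the pipeline widens to the
corpus pool instead of failing; the bare `junction_p_value` keeps its
argument-error contract.

## Sentence classification and filters

Sentences carry a distance-from-title feature, DFT = position / sentence
count, discretized into ten equal bins ([0,0.1), …, [0.9,1.0], last bin
closed). The Naive Bayes model combines the class prior, the bin's class
share, and — for each indicator phrase present in the sentence — the
phrase's class share. Phrase features are presence-only; absence
contributes no factor. All shares are Laplace-smoothed with α = 1
(`(count + α)/(total + 2α)`), so features unseen in training stay
uninformative at 0.5 rather than vetoing a class. Exact posterior ties
resolve to *context*. The default eight-phrase lexicon ("investigated",
"known to", "study", "evident", "identified", "significant change",
"observed", "showed") is user-replaceable by file.

The context overlap filter concatenates each document's context
sentences, tokenizes and stems them, and requires Jaccard ≥ j_min
(default 0.05) on every consecutive pair; a document with no context
sentences scores 0 on its links. The Jaccard is over token sets, not
whole sentences.

Entity recognition is gazetteer-based by default for offline determinism:
case-insensitive longest match with word boundaries, overlapping mentions
resolved to the longest. Any callable text → entity set can be plugged
in. The cohesion filter builds the layered sentence graph (edges between
consecutive documents' sentences with intersecting entity sets), passes
a story iff a start-to-end path exists, and returns the path maximizing
the summed per-edge entity Jaccard, ties resolving to the earliest
sentence positions.

## Dispersion

For junctions d_0 … d_{n−1}, cells (i, j) with j ≥ i+2 fill when
D(d_i, d_j) ≤ θ, and `η = 1 − Σ_filled (j−i−1) / Σ_all (j−i−1)`. The
linear weight (j−i−1) is the simplest function realizing the required
behaviour — η = 1 when no cell fills, η = 0 when all fill, and deeper
(longer-range) cells penalized more — and is pluggable
(`dispersion(..., weight=...)`). Stories of fewer than three documents
have no non-adjacent pairs and score η = 1. Dispersion evaluates the
junction sequence only, never the evidence cliques, and defaults to the
θ the search used.

## Synthetic corpus

The generator plants: (a) `n_clusters` topic clusters whose documents
sample `terms_per_doc` of a disjoint per-cluster pool plus a small shared
pool; (b) a bridge chain of `chain_length` documents where adjacent
documents share `round(chain_overlap · terms_per_doc)` terms from
per-link pools and non-adjacent documents share nothing (the CBD shape);
(c) abstracts whose early sentences use context templates and late
sentences result templates, with the link-shared vocabulary placed in
context sentences; (d) gazetteer entities threaded along the bridge in a
fixed context sentence so exactly one planted cohesive path exists;
(e) a `review_fraction` of cluster documents flagged as reviews; and
(f) MeSH terms drawn from each document's own vocabulary. Endpoint
documents carry unique keyword tokens in their titles for seed labeling
and tie weakly into their flanking clusters.

Two deliberate constructions keep the Soergel geometry analytic. Token
pools are disjoint synthetic strings that Porter stemming leaves intact,
and the sentence boilerplate ("investigated", "observed", …) recurs in
*every* document, so those terms carry idf 0 and vanish from the vectors
— the planted pools alone determine all distances, while the indicator
phrases remain in the text for the sentence classifier. The ground truth
reports θ*, placed between the largest adjacent-bridge distance and the
smallest competing distance (capped at +0.05 above the former), at which
the bridge is exactly recoverable. `chain_overlap` is capped at 0.5
because a middle bridge document shares two disjoint pools with its two
neighbors; `chain_overlap = 0` plants a broken bridge (adjacent documents
disjoint, entities unthreaded) that must yield no story.

The classifier training generator is separate: 100 abstracts of 4–9
sentences, class = context iff DFT < `context_fraction` with a 5% label
flip, own-class indicator phrase with probability 0.75 and cross-class
with 0.05 — i.e., data drawn from the classifier's own assumptions.

What the synthetic corpus does *not* emulate: PubMed's Zipfian term
frequencies, synonymy and polysemy of gene names, abstracts whose
context/result structure deviates from the front-context pattern, and
NER ambiguity. Passing tests therefore demonstrate correctness of the
machinery (search optimality, calibration, filter behaviour) under
controlled geometry, not retrieval quality on real literature.

## Problem sizes and numerics

The default study conditions are desk-scale: 2 clusters × 15 documents
plus a 5-document bridge (~31 documents after review pruning), Monte-Carlo
calibration at R = 10,000, optimality checks on 50 random corpora of up to
30 documents, and miner equivalence on 100 random 8×10 matrices. These
sizes make every property exactly checkable against brute-force or
independent-algorithm oracles (closed-set enumeration; Dijkstra over the
materialized successor graph). Distance computations clamp to [0,1];
comparisons against θ use exact ≤; test tolerances on float equality are
`pytest.approx` defaults (relative 1e-6).

## Known limitations

- Optimality is conditional on the branching factor b: the search is
  optimal over the b-truncated successor graph, as designed.
- Keyword seed labeling takes explicit lists; no synonym expansion.
- The gazetteer recognizer does not resolve entity synonymy.
- Story counts are monotone in θ by construction for k = 2 (no successor
  truncation occurs); for k > 2 truncation can in principle perturb
  monotonicity, though it does not at the tested settings.
- MEDLINE XML ingestion covers the PubmedArticleSet/MedlineCitation
  layout with plain or structured AbstractText; exotic exports may need
  conversion to the JSONL dialect.
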