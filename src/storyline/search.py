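"""A* clique-chain search between a start and an end document.

A story is an ordered sequence of junction documents in which every
consecutive pair lies within the Soergel distance threshold theta; each link
additionally carries a k-clique of evidence documents (junction plus k-1
neighbors, all pairwise within theta). Successors of a junction are drawn
from the concept-lattice candidate list: the top m candidates (m the
smallest count whose (k-1)-subsets number at least the branching factor b)
are combined into candidate cliques, validated pairwise, scored by average
distance from the junction, and the best b kept.

Path cost g accumulates junction-to-junction Soergel distance; the
heuristic h(d) is the straight-line Soergel distance to the end document.
Because Soergel distance is a metric, h never overestimates the remaining
cost (and is consistent), so the search returns the minimum-cost chain
reachable under the theta/k/b constraints. The pairwise-similarity graph is
never materialized: memory follows the search frontier, not corpus pairs.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Mapping

from .lattice import ConceptIndex, candidate_neighbors
from .vectors import TermVector, soergel_distance


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the story search.

    theta: maximum acceptable Soergel distance on any clique edge, in (0,1).
        Stricter (smaller) thresholds give longer but stronger stories.
    k: clique size (>= 2); the evidence neighborhood each link must carry.
    b: branching factor (>= 1); cliques kept per expansion.
    max_expansions: node budget before the search gives up.

    The defaults sit inside the empirically useful region of distance
    thresholds 0.92-0.86 and clique sizes 2-8.
    """

    theta: float = 0.90
    k: int = 3
    b: int = 5
    max_expansions: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must be in (0, 1)")
        if self.k < 2:
            raise ValueError("clique size k must be >= 2")
        if self.b < 1:
            raise ValueError("branching factor b must be >= 1")


@dataclass(frozen=True)
class EvidenceClique:
    """A k-clique supporting one link; all pairwise distances <= theta."""

    members: frozenset[str]
    junction: str
    avg_distance: float

    def others(self) -> list[str]:
        return sorted(self.members - {self.junction})


@dataclass
class CliqueChain:
    """A found story: junctions plus per-link evidence cliques."""

    junctions: list[str]
    cliques: list[EvidenceClique]
    link_distances: list[float]
    total_cost: float

    def __len__(self) -> int:
        return len(self.junctions)

    def to_dict(self) -> dict:
        return {
            "junctions": list(self.junctions),
            "cliques": [
                {
                    "members": sorted(c.members),
                    "junction": c.junction,
                    "avg_distance": c.avg_distance,
                }
                for c in self.cliques
            ],
            "link_distances": list(self.link_distances),
            "total_cost": self.total_cost,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CliqueChain":
        return cls(
            junctions=list(d["junctions"]),
            cliques=[
                EvidenceClique(
                    members=frozenset(c["members"]),
                    junction=c["junction"],
                    avg_distance=float(c["avg_distance"]),
                )
                for c in d["cliques"]
            ],
            link_distances=[float(x) for x in d["link_distances"]],
            total_cost=float(d["total_cost"]),
        )


def min_candidate_count(k: int, b: int) -> int:
    """Smallest m with C(m, k-1) >= b.

    Each clique is the junction plus a (k-1)-subset of the m candidates, so
    m candidates yield C(m, k-1) cliques: at least b, never fewer.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if b < 1:
        raise ValueError("b must be >= 1")
    m = k - 1
    while comb(m, k - 1) < b:
        m += 1
    return m


def _valid_clique(
    junction: str,
    subset: tuple[str, ...],
    vectors: Mapping[str, TermVector],
    theta: float,
    cache: dict[tuple[str, str], float],
) -> float | None:
    """Average junction distance if junction+subset is a valid clique."""

    def dist(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        d = cache.get(key)
        if d is None:
            d = soergel_distance(vectors[a], vectors[b])
            cache[key] = d
        return d

    total = 0.0
    for doc in subset:
        d = dist(junction, doc)
        if d > theta:
            return None
        total += d
    for a, b in itertools.combinations(subset, 2):
        if dist(a, b) > theta:
            return None
    return total / len(subset)


def generate_successors(
    junction: str,
    params: SearchParams,
    index: ConceptIndex,
    vectors: Mapping[str, TermVector],
    _cache: dict | None = None,
) -> list[EvidenceClique]:
    """Priority queue (best first) of at most b valid k-cliques at a junction.

    Takes the top m = min_candidate_count(k, b) lattice candidates, forms
    every (k-1)-subset, keeps the subsets whose union with the junction is
    pairwise within theta, scores each clique by the mean distance from the
    junction to its other members, and returns the b best. An empty list is
    a dead end.
    """
    if not vectors[junction]:
        raise ValueError(f"junction {junction!r} has an empty vector")
    cache = _cache if _cache is not None else {}
    m = min_candidate_count(params.k, params.b)
    candidates = candidate_neighbors(index, junction, m)
    cliques: list[EvidenceClique] = []
    for subset in itertools.combinations(candidates, params.k - 1):
        avg = _valid_clique(junction, subset, vectors, params.theta, cache)
        if avg is not None:
            cliques.append(
                EvidenceClique(
                    members=frozenset(subset) | {junction},
                    junction=junction,
                    avg_distance=avg,
                )
            )
    cliques.sort(key=lambda c: (c.avg_distance, tuple(sorted(c.members))))
    return cliques[: params.b]


def _goal_clique(
    junction: str,
    end: str,
    params: SearchParams,
    index: ConceptIndex,
    vectors: Mapping[str, TermVector],
    cache: dict,
) -> EvidenceClique | None:
    """Best valid clique containing both the junction and the end document.

    Completing a story requires the end document to enter a clique with the
    current junction; the end is admitted as a member even when the lattice
    candidate list misses it, provided every clique edge satisfies theta.
    """
    d_end = soergel_distance(vectors[junction], vectors[end])
    if d_end > params.theta:
        return None
    if params.k == 2:
        return EvidenceClique(
            members=frozenset((junction, end)),
            junction=junction,
            avg_distance=d_end,
        )
    m = min_candidate_count(params.k, params.b)
    candidates = [
        c for c in candidate_neighbors(index, junction, m) if c != end
    ]
    best: EvidenceClique | None = None
    for subset in itertools.combinations(candidates, params.k - 2):
        full = subset + (end,)
        avg = _valid_clique(junction, full, vectors, params.theta, cache)
        if avg is not None:
            cand = EvidenceClique(
                members=frozenset(full) | {junction},
                junction=junction,
                avg_distance=avg,
            )
            if best is None or (cand.avg_distance, tuple(sorted(cand.members))) < (
                best.avg_distance, tuple(sorted(best.members))
            ):
                best = cand
    return best


def iter_successor_edges(
    junction: str,
    end: str,
    params: SearchParams,
    index: ConceptIndex,
    vectors: Mapping[str, TermVector],
    _cache: dict | None = None,
) -> Iterator[tuple[str, float, EvidenceClique]]:
    """(next_junction, link_distance, clique) edges out of a junction.

    Every non-junction member of each of the b successor cliques is a
    candidate next junction; reaching the end document additionally uses the
    best goal clique when one exists. This is the exact edge relation the
    A* search explores, exposed so exhaustive oracles can walk it too.
    """
    cache = _cache if _cache is not None else {}
    seen: set[str] = set()
    for clique in generate_successors(junction, params, index, vectors, cache):
        for member in clique.others():
            if member in seen:
                continue
            seen.add(member)
            key = (junction, member) if junction <= member else (member, junction)
            yield member, cache[key], clique
    if end not in seen:
        goal = _goal_clique(junction, end, params, index, vectors, cache)
        if goal is not None:
            key = (junction, end) if junction <= end else (end, junction)
            d = cache.get(key)
            if d is None:
                d = soergel_distance(vectors[junction], vectors[end])
            yield end, d, goal


def astar_story(
    start: str,
    end: str,
    params: SearchParams,
    index: ConceptIndex,
    vectors: Mapping[str, TermVector],
) -> CliqueChain | None:
    """Minimum-cumulative-distance clique chain from start to end, or None.

    Best-first search on f = g + h with g the cumulative link Soergel
    distance and h the straight-line Soergel distance to the end. Junctions
    are simple (each document appears at most once per chain). Ties on f
    break toward smaller h, then document id. Returns None when the frontier
    empties or the expansion budget is exhausted.
    """
    if start == end:
        raise ValueError("start and end documents must differ")
    if not vectors[start]:
        raise ValueError(f"start document {start!r} has an empty vector")
    if not vectors[end]:
        raise ValueError(f"end document {end!r} has an empty vector")

    cache: dict[tuple[str, str], float] = {}

    def h(doc: str) -> float:
        return soergel_distance(vectors[doc], vectors[end])

    # doc -> (g, parent, clique, link_distance)
    best: dict[str, tuple[float, str | None, EvidenceClique | None, float]] = {
        start: (0.0, None, None, 0.0)
    }
    counter = itertools.count()
    frontier: list[tuple[float, float, str, int]] = [
        (h(start), h(start), start, next(counter))
    ]
    closed: set[str] = set()
    expansions = 0

    while frontier:
        f, _, doc, _ = heapq.heappop(frontier)
        if doc in closed:
            continue
        closed.add(doc)
        if doc == end:
            return _reconstruct(best, end)
        expansions += 1
        if expansions > params.max_expansions:
            return None
        g = best[doc][0]
        for member, link_d, clique in iter_successor_edges(
            doc, end, params, index, vectors, cache
        ):
            if member in closed:
                continue
            ng = g + link_d
            if member not in best or ng < best[member][0]:
                best[member] = (ng, doc, clique, link_d)
                hm = h(member)
                heapq.heappush(frontier, (ng + hm, hm, member, next(counter)))
    return None


def _reconstruct(best, end: str) -> CliqueChain:
    junctions: list[str] = []
    cliques: list[EvidenceClique] = []
    link_distances: list[float] = []
    doc: str | None = end
    total = best[end][0]
    while doc is not None:
        g, parent, clique, link_d = best[doc]
        junctions.append(doc)
        if parent is not None:
            cliques.append(clique)
            link_distances.append(link_d)
        doc = parent
    junctions.reverse()
    cliques.reverse()
    link_distances.reverse()
    return CliqueChain(
        junctions=junctions,
        cliques=cliques,
        link_distances=link_distances,
        total_cost=total,
    )
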