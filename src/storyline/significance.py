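"""Monte-Carlo clique significance and FDR control for clique chains.

Each junction of a discovered chain is tested against the null that a
random (k-1)-subset of its candidate pool forms a valid clique with it:
subsets are sampled uniformly without replacement, validity is every
pairwise distance within theta, and the p-value is the success fraction
floored at 1/R (R sampling iterations bound the smallest resolvable
p-value). A chain's p-value is the product of its junction p-values, and
q-values over a batch of chains control the false discovery rate
(Benjamini-Hochberg by default; a Storey-style pi0 estimate optionally).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .search import CliqueChain
from .vectors import TermVector, soergel_distance


@dataclass
class SignificanceResult:
    """Per-junction and chain-level significance of one clique chain."""

    junction_p: list[float]
    chain_p: float
    iterations: int
    q_value: float | None = None


def _clique_ok(
    junction: str,
    subset: Sequence[str],
    vectors: Mapping[str, TermVector],
    theta: float,
) -> bool:
    members = (junction, *subset)
    for a, b in itertools.combinations(members, 2):
        if soergel_distance(vectors[a], vectors[b]) > theta:
            return False
    return True


def junction_p_value(
    junction: str,
    pool: Sequence[str],
    k: int,
    theta: float,
    vectors: Mapping[str, TermVector],
    R: int = 50_000,
    rng_seed: int = 0,
) -> float:
    """Monte-Carlo p-value for one junction clique.

    Samples R uniform (k-1)-subsets of ``pool`` and counts how often the
    sampled subset forms a valid clique with the junction under theta.
    Returns max(successes, 1) / R, deterministic for a given seed.
    """
    pool = [d for d in pool if d != junction]
    if len(pool) < k - 1:
        raise ValueError(
            f"candidate pool of size {len(pool)} cannot form {k}-cliques"
        )
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pool_arr = np.asarray(pool, dtype=object)
    # distance memoization dominates the cost for repeated subsets
    cache: dict[tuple[str, str], float] = {}

    def dist(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        d = cache.get(key)
        if d is None:
            d = soergel_distance(vectors[a], vectors[b])
            cache[key] = d
        return d

    successes = 0
    for _ in range(R):
        idx = rng.choice(len(pool_arr), size=k - 1, replace=False)
        members = [str(pool_arr[i]) for i in idx]
        ok = all(dist(junction, m) <= theta for m in members)
        if ok and k > 2:
            ok = all(
                dist(a, b) <= theta
                for a, b in itertools.combinations(members, 2)
            )
        if ok:
            successes += 1
    return max(successes, 1) / R


def chain_p_value(junction_ps: Sequence[float]) -> float:
    """Product of the per-junction p-values of a chain."""
    if not junction_ps:
        raise ValueError("a chain needs at least one junction p-value")
    out = 1.0
    for p in junction_ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
        out *= p
    return out


def q_values(
    chain_ps: Sequence[float], method: str = "bh", pi0_lambda: float = 0.5
) -> list[float]:
    """FDR-adjusted q-values, order-aligned with the input p-values.

    ``method="bh"`` is plain Benjamini-Hochberg (deterministic,
    parameter-free); ``method="storey"`` rescales by the Storey pi0
    estimate #{p > lambda} / ((1 - lambda) m), clipped to (0, 1].
    """
    ps = list(chain_ps)
    if not ps:
        raise ValueError("empty p-value list")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    qs = multipletests(ps, method="fdr_bh")[1]
    if method == "storey":
        m = len(ps)
        pi0 = sum(p > pi0_lambda for p in ps) / ((1.0 - pi0_lambda) * m)
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        qs = np.minimum(qs * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return [float(q) for q in qs]


def score_chain(
    chain: CliqueChain,
    pools: Sequence[Sequence[str]],
    theta: float,
    vectors: Mapping[str, TermVector],
    R: int = 50_000,
    rng_seed: int = 0,
) -> SignificanceResult:
    """Significance of every junction clique of a chain.

    ``pools[i]`` is the candidate pool for the i-th link's junction (the
    documents the observed clique was drawn from). Per-junction seeds are
    derived from ``rng_seed`` so results are reproducible yet independent.
    """
    if len(pools) != len(chain.cliques):
        raise ValueError("one candidate pool per link is required")
    ps = []
    k = len(chain.cliques[0].members) if chain.cliques else 2
    for i, (clique, pool) in enumerate(zip(chain.cliques, pools)):
        ps.append(
            junction_p_value(
                clique.junction,
                pool,
                len(clique.members),
                theta,
                vectors,
                R=R,
                rng_seed=(rng_seed * 1_000_003 + i) % (2**31 - 1),
            )
        )
    del k
    return SignificanceResult(
        junction_p=ps, chain_p=chain_p_value(ps), iterations=R
    )


def significance_filter(
    chains: Sequence[tuple[CliqueChain, SignificanceResult]],
    p_max: float = 0.001,
    q_max: float = 0.05,
) -> list[tuple[CliqueChain, SignificanceResult]]:
    """Keep chains with chain_p <= p_max and q <= q_max, preserving order.

    q-values are (re)computed across the given batch with the default BH
    procedure and stored on each result.
    """
    if not (0.0 < p_max <= 1.0) or not (0.0 < q_max <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    if not chains:
        return []
    qs = q_values([res.chain_p for _, res in chains])
    out = []
    for (chain, res), q in zip(chains, qs):
        res.q_value = q
        if res.chain_p <= p_max and q <= q_max:
            out.append((chain, res))
    return out
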