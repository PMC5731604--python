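"""Module separation S_AB between two disease gene sets on the interactome.

For diseases A and B with gene sets G_A and G_B mapped onto the interactome,

    S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2

where, in the default ``nearest`` method, <d_AA> averages for every gene of A
the shortest-path distance to its nearest *other* member of A (likewise
<d_BB>), and <d_AB> averages for every gene of A the distance to its nearest
member of B and vice versa — a gene shared by both sets contributes 0 from
each side. Negative S_AB means the two modules topologically overlap.

The ``all_pair_average`` variant S_<AB> replaces every nearest distance with
the plain average over all distinct pairs (within-set: all unordered pairs;
between: all pairs (a, b) with a != b). It is deliberately retained as the
weaker comparator: it is far less sensitive to re-classifying a single gene.

All distances are unweighted hop counts (breadth-first search). Genes that
cannot reach any relevant counterpart (the interactome may be disconnected)
are excluded from the average and recorded on the result; an error is raised
only when an average would be taken over nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import networkx as nx

from .exceptions import DataError

log = logging.getLogger(__name__)

NEAREST = "nearest"
ALL_PAIR = "all_pair_average"
_METHODS = (NEAREST, ALL_PAIR)

__all__ = [
    "NEAREST", "ALL_PAIR", "DistanceCache", "SeparationResult",
    "within_distances", "between_distances", "separation", "jaccard",
]


def _check_method(method: str) -> None:
    if method not in _METHODS:
        raise DataError(f"unknown method {method!r}; expected one of {_METHODS}")


class DistanceCache:
    """Memoised single-source BFS distance maps.

    One BFS per queried source, reused across every separation evaluated on
    the same graph — the workhorse behind exhaustive candidate scoring, where
    the same |G_A ∪ G_B| sources are queried hundreds of times. Results are
    identical to uncached evaluation by construction (each entry *is* a plain
    BFS), which the test suite asserts bit-for-bit.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._maps: dict = {}

    def from_source(self, u) -> dict:
        m = self._maps.get(u)
        if m is None:
            m = nx.single_source_shortest_path_length(self.graph, u)
            self._maps[u] = m
        return m

    def distance(self, u, v):
        """Hop distance u→v, or None when unreachable."""
        return self.from_source(u).get(v)


@dataclass(frozen=True)
class SeparationResult:
    """The four separation quantities plus exclusion bookkeeping.

    ``s_ab == d_ab - (d_aa + d_bb) / 2`` holds exactly; ``excluded_a`` /
    ``excluded_b`` list genes omitted from some average for unreachability.
    """

    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    method: str
    excluded_a: frozenset = frozenset()
    excluded_b: frozenset = frozenset()


def _mean(values, what: str) -> float:
    if not values:
        raise DataError(f"no finite distances for {what}; gene sets unreachable")
    return sum(values) / len(values)


def within_distances(g: nx.Graph, S, method: str = NEAREST, cache: DistanceCache | None = None):
    """Within-set distance list for <d_AA>.

    Returns ``(distances, excluded)``. ``nearest``: one distance per gene, the
    minimum to any other member (self never counts); genes reaching no other
    member are excluded. ``all_pair_average``: one distance per reachable
    unordered pair.
    """
    _check_method(method)
    S = sorted(set(S))
    if len(S) < 2:
        raise DataError(f"within-set distances need >=2 genes, got {len(S)}")
    missing = [x for x in S if x not in g]
    if missing:
        raise DataError(f"genes not in interactome: {missing[:5]}")
    cache = cache or DistanceCache(g)
    distances: list = []
    excluded: set = set()
    if method == NEAREST:
        for x in S:
            dmap = cache.from_source(x)
            best = min((dmap[y] for y in S if y != x and y in dmap), default=None)
            if best is None:
                excluded.add(x)
            else:
                distances.append(best)
    else:
        reached: set = set()
        for i, x in enumerate(S):
            dmap = cache.from_source(x)
            for y in S[i + 1:]:
                d = dmap.get(y)
                if d is not None:
                    distances.append(d)
                    reached.update((x, y))
        excluded = set(S) - reached
    if excluded:
        log.warning("within-set: %d gene(s) unreachable, excluded", len(excluded))
    if not distances:
        raise DataError("all within-set genes mutually unreachable")
    return distances, excluded


def between_distances(g: nx.Graph, A, B, method: str = NEAREST, cache: DistanceCache | None = None):
    """Cross-set distance list for <d_AB>.

    Returns ``(distances, excluded_a, excluded_b)``. ``nearest``: each gene of
    A contributes its distance to the nearest member of B, then each gene of B
    its distance to the nearest member of A; a shared gene contributes 0 from
    each side. ``all_pair_average``: all pairs (a, b) with a != b.
    """
    _check_method(method)
    A, B = sorted(set(A)), sorted(set(B))
    if not A or not B:
        raise DataError("between-set distances need two non-empty gene sets")
    cache = cache or DistanceCache(g)
    distances: list = []
    excluded_a: set = set()
    excluded_b: set = set()
    if method == NEAREST:
        for side, other, excluded in ((A, B, excluded_a), (B, A, excluded_b)):
            other_set = set(other)
            for x in side:
                if x in other_set:
                    distances.append(0)
                    continue
                dmap = cache.from_source(x)
                best = min((dmap[y] for y in other if y in dmap), default=None)
                if best is None:
                    excluded.add(x)
                else:
                    distances.append(best)
    else:
        b_set = set(B)
        reached_a: set = set()
        reached_b: set = set()
        for a in A:
            dmap = cache.from_source(a)
            for b in B:
                if a == b:
                    continue
                d = dmap.get(b)
                if d is not None:
                    distances.append(d)
                    reached_a.add(a)
                    reached_b.add(b)
        excluded_a = set(A) - reached_a - b_set
        excluded_b = set(B) - reached_b - set(A)
    if excluded_a or excluded_b:
        log.warning("between-set: %d+%d gene(s) unreachable, excluded",
                    len(excluded_a), len(excluded_b))
    if not distances:
        raise DataError("gene sets are mutually unreachable")
    return distances, excluded_a, excluded_b


def separation(g: nx.Graph, A, B, method: str = NEAREST,
               cache: DistanceCache | None = None) -> SeparationResult:
    """Compute S_AB (or the all-pair variant S_<AB>) between two gene sets."""
    _check_method(method)
    A, B = set(A), set(B)
    if len(A) < 2 or len(B) < 2:
        raise DataError(
            f"separation needs >=2 mapped genes per disease, got |A|={len(A)}, |B|={len(B)}")
    cache = cache or DistanceCache(g)
    wa, exa_w = within_distances(g, A, method, cache)
    wb, exb_w = within_distances(g, B, method, cache)
    ab, exa_b, exb_b = between_distances(g, A, B, method, cache)
    d_aa = _mean(wa, "<d_AA>")
    d_bb = _mean(wb, "<d_BB>")
    d_ab = _mean(ab, "<d_AB>")
    return SeparationResult(
        d_aa=d_aa, d_bb=d_bb, d_ab=d_ab,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        method=method,
        excluded_a=frozenset(exa_w | exa_b),
        excluded_b=frozenset(exb_w | exb_b),
    )


def jaccard(A, B) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| of two gene sets."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise DataError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(union)
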