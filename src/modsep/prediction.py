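"""Missing common-gene prediction by minimising module separation.

A gene already associated with exactly one disease of a comorbid pair is a
candidate missing common gene. Marking candidate x as shared (adding it to
both gene sets) and recomputing the separation gives S_AB[+x]; the predicted
missing gene is

    x* = argmin S_AB[+x],   x ∈ (G_A ∪ G_B) − (G_A ∩ G_B)

with the prediction score s(x) = S_AB − S_AB[+x] (larger = marking x shared
closes the gap between the two modules more). The search is exhaustive over
the candidate set; a k-subset variant minimises S_AB[+X] over all C(n, k)
subsets, and a sequential procedure applies the single-gene argmin
repeatedly. The sequential result may legitimately differ from the k-subset
optimum — graph topology makes the objective non-separable across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

from .exceptions import BudgetError, DataError
from .separation import NEAREST, DistanceCache, SeparationResult, separation

log = logging.getLogger(__name__)

__all__ = [
    "CandidateScore", "Ranking", "SubsetResult",
    "candidate_set", "separation_with_shared", "rank_candidates",
    "best_subset", "iterative_recovery",
]

#: default cap on the number of subsets best_subset may enumerate
MAX_SUBSET_EVALUATIONS = 2_000_000


@dataclass(frozen=True)
class CandidateScore:
    """One candidate gene with its post-sharing separation and score."""

    gene: str
    side: str  # "A_only" | "B_only"
    s_ab_plus: float
    score: float


@dataclass(frozen=True)
class Ranking:
    """All candidates of a pair, ordered by descending prediction score.

    Ties in score are broken by lexicographic gene id. ``n_evaluated`` counts
    separation evaluations and always equals the candidate-set size.
    """

    base: SeparationResult
    items: tuple
    normalized: bool = False

    @property
    def n_evaluated(self) -> int:
        return len(self.items)

    @property
    def top(self) -> CandidateScore:
        return self.items[0]


@dataclass(frozen=True)
class SubsetResult:
    """Optimal size-k subset X* minimising S_AB[+X]."""

    k: int
    genes: frozenset
    s_ab_plus: float
    n_evaluated: int


def candidate_set(A, B) -> set:
    """Genes distinctly associated with exactly one disease of the pair."""
    cands = set(A) ^ set(B)
    if not cands:
        raise DataError("no candidates: the two gene sets are identical")
    return cands


def separation_with_shared(g, A, B, X, method: str = NEAREST,
                           cache: DistanceCache | None = None) -> SeparationResult:
    """S_AB[+X]: separation after every gene of X is marked as shared."""
    A, B, X = set(A), set(B), set(X)
    extra = X - candidate_set(A, B)
    if extra:
        raise DataError(
            f"genes not in the candidate set (already shared or unassociated): "
            f"{sorted(extra)[:5]}")
    return separation(g, A | X, B | X, method, cache)


def rank_candidates(g, A, B, method: str = NEAREST, normalize: bool = False,
                    cache: DistanceCache | None = None) -> Ranking:
    """Exhaustively score every candidate and rank by descending s(x).

    With ``normalize=True`` the score is (S_AB − S_AB[+x]) / S_AB, which is
    undefined (error) when the base separation is exactly zero.
    """
    A, B = set(A), set(B)
    cands = candidate_set(A, B)
    cache = cache or DistanceCache(g)
    base = separation(g, A, B, method, cache)
    if normalize and base.s_ab == 0.0:
        raise DataError("normalized score undefined: base S_AB is zero")
    items = []
    for x in sorted(cands):
        sp = separation_with_shared(g, A, B, {x}, method, cache)
        score = base.s_ab - sp.s_ab
        if normalize:
            score /= base.s_ab
        items.append(CandidateScore(
            gene=x,
            side="A_only" if x in A else "B_only",
            s_ab_plus=sp.s_ab,
            score=score,
        ))
    items.sort(key=lambda c: (-c.score, c.gene))
    return Ranking(base=base, items=tuple(items), normalized=normalize)


def best_subset(g, A, B, k: int, method: str = NEAREST,
                max_evaluations: int = MAX_SUBSET_EVALUATIONS,
                cache: DistanceCache | None = None) -> SubsetResult:
    """Minimise S_AB[+X] over all size-k subsets of the candidate set.

    Exhaustive enumeration; ties broken by the lexicographically smallest
    sorted gene list (enumeration order guarantees it). Refuses to start when
    C(n, k) exceeds ``max_evaluations``.
    """
    A, B = set(A), set(B)
    cands = sorted(candidate_set(A, B))
    n = len(cands)
    if not 1 <= k <= n:
        raise DataError(f"k={k} out of range 1..{n}")
    n_subsets = comb(n, k)
    if n_subsets > max_evaluations:
        raise BudgetError(
            f"C({n},{k})={n_subsets} subsets exceeds budget {max_evaluations}; "
            f"use a smaller k or the sequential procedure")
    cache = cache or DistanceCache(g)
    best_genes = None
    best_s = None
    n_evaluated = 0
    for X in combinations(cands, k):
        sp = separation_with_shared(g, A, B, set(X), method, cache)
        n_evaluated += 1
        if best_s is None or sp.s_ab < best_s:
            best_s = sp.s_ab
            best_genes = X
    return SubsetResult(k=k, genes=frozenset(best_genes), s_ab_plus=best_s,
                        n_evaluated=n_evaluated)


def iterative_recovery(g, A, B, m: int, method: str = NEAREST,
                       cache: DistanceCache | None = None) -> list:
    """Recover up to m missing common genes sequentially.

    Each round takes the top-ranked candidate, marks it shared (moves it into
    both working sets) and re-ranks. Returns genes in selection order; stops
    early with a warning if the candidate set is exhausted.
    """
    if m < 1:
        raise DataError(f"m must be >=1, got {m}")
    A, B = set(A), set(B)
    cache = cache or DistanceCache(g)
    selected: list = []
    for _ in range(m):
        if not (A ^ B):
            log.warning("candidate set exhausted after %d of %d recoveries",
                        len(selected), m)
            break
        ranking = rank_candidates(g, A, B, method, cache=cache)
        top = ranking.top.gene
        selected.append(top)
        A.add(top)
        B.add(top)
    return selected
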