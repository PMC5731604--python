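"""Model/Results front end for a disease pair on the interactome.

:class:`DiseasePairModel` bundles an interactome and two disease gene sets;
``fit()`` runs the exhaustive missing-common-gene search and returns a
:class:`DiseasePairResults` carrying the base separation, the full candidate
ranking and a ``summary()`` table. Subset and sequential searches and
cross-validation hang off the same model object.

    >>> model = DiseasePairModel(graph, genes_a, genes_b)   # doctest: +SKIP
    >>> res = model.fit()                                   # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from .evaluation import EvaluationRecord, evaluate_pair
from .exceptions import DataError
from .graph_io import load_associations, load_interactome, map_to_graph
from .prediction import (Ranking, SubsetResult, best_subset,
                         iterative_recovery, rank_candidates)
from .separation import NEAREST, DistanceCache, SeparationResult, jaccard, separation

__all__ = ["DiseasePairModel", "DiseasePairResults"]


class DiseasePairModel:
    """Two disease gene sets mapped onto an interactome.

    Parameters
    ----------
    graph : networkx.Graph
        The interactome (undirected, unweighted).
    genes_a, genes_b : iterable of str
        Associated gene ids for each disease; genes absent from the graph
        are dropped (recorded on ``mapped_a`` / ``mapped_b``).
    name_a, name_b : str
        Disease labels for reporting.
    method : {"nearest", "all_pair_average"}
        Distance aggregation used throughout.
    """

    def __init__(self, graph, genes_a, genes_b, name_a: str = "A",
                 name_b: str = "B", method: str = NEAREST):
        self.graph = graph
        self.name_a, self.name_b = name_a, name_b
        self.method = method
        self.mapped_a = map_to_graph(graph, genes_a, name_a)
        self.mapped_b = map_to_graph(graph, genes_b, name_b)
        self.genes_a = set(self.mapped_a.in_graph)
        self.genes_b = set(self.mapped_b.in_graph)
        if len(self.genes_a) < 2 or len(self.genes_b) < 2:
            raise DataError(
                f"need >=2 mapped genes per disease, got "
                f"{len(self.genes_a)} ({name_a}) and {len(self.genes_b)} ({name_b})")
        self._cache = DistanceCache(graph)

    @classmethod
    def from_files(cls, graph_path, assoc_path, disease_a: str, disease_b: str,
                   method: str = NEAREST, header: bool = False) -> "DiseasePairModel":
        """Build a model from an edge-list file and an association table."""
        graph = load_interactome(graph_path, header=header)
        assoc = load_associations(assoc_path, header=header)
        for d in (disease_a, disease_b):
            if d not in assoc:
                raise DataError(f"disease {d!r} not found in {assoc_path}")
        return cls(graph, assoc[disease_a], assoc[disease_b],
                   name_a=disease_a, name_b=disease_b, method=method)

    @property
    def candidates(self) -> set:
        return self.genes_a ^ self.genes_b

    @property
    def common_genes(self) -> set:
        return self.genes_a & self.genes_b

    def jaccard(self) -> float:
        return jaccard(self.genes_a, self.genes_b)

    def separation(self) -> SeparationResult:
        return separation(self.graph, self.genes_a, self.genes_b,
                          self.method, self._cache)

    def fit(self, normalize: bool = False) -> "DiseasePairResults":
        """Exhaustively score every candidate missing common gene."""
        ranking = rank_candidates(self.graph, self.genes_a, self.genes_b,
                                  self.method, normalize=normalize,
                                  cache=self._cache)
        return DiseasePairResults(self, ranking)

    def fit_subset(self, k: int, **kwargs) -> SubsetResult:
        """Optimal size-k shared subset (exhaustive over C(n, k))."""
        return best_subset(self.graph, self.genes_a, self.genes_b, k,
                           self.method, cache=self._cache, **kwargs)

    def fit_iterative(self, m: int) -> list:
        """Sequential recovery of up to m missing common genes."""
        return iterative_recovery(self.graph, self.genes_a, self.genes_b, m,
                                  self.method, cache=self._cache)

    def cross_validate(self, n_pos: int = 10, n_neg: int = 10, seed: int = 0,
                       repeats: int = 1, rr: float | None = None,
                       holdout: str = "reserve") -> EvaluationRecord:
        """Hold-out evaluation of this pair (see :mod:`modsep.evaluation`)."""
        return evaluate_pair(self.graph, self.genes_a, self.genes_b,
                             n_pos=n_pos, n_neg=n_neg, seed=seed,
                             method=self.method, rr=rr,
                             pair=(self.name_a, self.name_b), repeats=repeats,
                             holdout=holdout)


class DiseasePairResults:
    """Fitted results: base separation plus the ranked candidate list."""

    def __init__(self, model: DiseasePairModel, ranking: Ranking):
        self.model = model
        self.ranking = ranking
        self.separation = ranking.base

    @property
    def top_gene(self) -> str:
        return self.ranking.top.gene

    def to_frame(self) -> pd.DataFrame:
        """Ranking as a DataFrame (gene, side, s_ab_plus, score)."""
        return pd.DataFrame([{"gene": c.gene, "side": c.side,
                              "s_ab_plus": c.s_ab_plus, "score": c.score}
                             for c in self.ranking.items])

    def summary(self, top: int = 10) -> str:
        """Plain-text summary table in the spirit of a regression summary."""
        m, sep = self.model, self.separation
        lines = [
            "        Disease-pair module separation",
            "=" * 58,
            f"Disease A: {m.name_a}  ({len(m.genes_a)} genes mapped, "
            f"{len(m.mapped_a.dropped)} dropped)",
            f"Disease B: {m.name_b}  ({len(m.genes_b)} genes mapped, "
            f"{len(m.mapped_b.dropped)} dropped)",
            f"Method: {m.method}    Common genes: {len(m.common_genes)}    "
            f"Jaccard: {m.jaccard():.4f}",
            "-" * 58,
            f"<d_AA> {sep.d_aa:8.4f}   <d_BB> {sep.d_bb:8.4f}   "
            f"<d_AB> {sep.d_ab:8.4f}",
            f"S_AB   {sep.s_ab:8.4f}   excluded: "
            f"{len(sep.excluded_a)}+{len(sep.excluded_b)} unreachable",
            "-" * 58,
            f"Top {min(top, len(self.ranking.items))} candidate missing "
            f"common genes (of {self.ranking.n_evaluated}):",
            f"{'gene':<12}{'side':<9}{'S_AB[+x]':>12}{'s(x)':>12}",
        ]
        for c in self.ranking.items[:top]:
            lines.append(f"{c.gene:<12}{c.side:<9}{c.s_ab_plus:>12.4f}{c.score:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_scores(self, ax=None, top: int = 20):
        """Bar plot of the top prediction scores (requires matplotlib)."""
        import matplotlib.pyplot as plt  # local: plotting is optional

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        items = self.ranking.items[:top]
        ax.bar(range(len(items)), [c.score for c in items])
        ax.set_xticks(range(len(items)))
        ax.set_xticklabels([c.gene for c in items], rotation=90, fontsize=7)
        ax.set_ylabel("s(x) = S_AB − S_AB[+x]")
        ax.set_title(f"{self.model.name_a} / {self.model.name_b}")
        return ax
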