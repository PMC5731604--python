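"""Seeded synthetic interactomes with planted comorbid disease pairs.

The generator produces a scale-free background interactome and plants a
disease pair with a known shared-gene core on top of it, so that every other
part of the package can be exercised and benchmarked without any download.

Background substrate
--------------------
A preferential-attachment graph (heavy-tailed degrees, connected, sparse)
stands in for the incomplete background interactome: it supplies realistic
shortcut paths and hub structure but carries no disease signal itself.

Planted pair
------------
The disease structure is planted as *interactions*, the way community
benchmarks plant their communities. Each disease consists of a handful of
hub genes, each hub carrying its own specific interactors, plus a scattered
fringe; the pair's shared genes are wired to every hub of both diseases —
the picture of pleiotropic connector genes that couple two disease
neighbourhoods. Concretely, for one pair:

* ``n_hubs`` hub genes per disease are chosen among low-degree substrate
  nodes (so planted structure, not substrate hubs, dominates distances);
  the two lead hubs are kept several hops apart;
* each shared gene receives a planted edge to *every* hub of both diseases;
* each exclusive gene is, with probability ``locality``, attached to one
  randomly chosen hub of its disease (a clustered module member); otherwise
  it stays wherever it was sampled (a scattered associate, mirroring the
  large fraction of disease genes that fall outside the observed module in
  real association data).

``locality`` is therefore the single compactness knob: at 1.0 every
exclusive gene sits one hop from a hub; near 0 the disease set is almost
entirely scattered and its within-module nearest distances grow.

Everything is driven by integer seeds and is byte-reproducible, including
the files written by :func:`make_benchmark`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DataError
from .graph_io import write_associations, write_interactome

log = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "PlantedPair", "generate_graph", "plant_pair",
           "make_benchmark", "write_pairs_table", "load_pairs_table"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one planted disease pair.

    Defaults give a 500-node sparse scale-free substrate and two 25-gene
    disease sets sharing 8 genes, with 6 hubs per disease and 70% of the
    exclusive genes clustered — small enough to evaluate in seconds, large
    enough that nearest-distance separation has headroom over the all-pair
    variant.
    """

    n_nodes: int = 500
    attachment: int = 2
    n_a: int = 25
    n_b: int = 25
    n_shared: int = 8
    locality: float = 0.7
    n_hubs: int = 6
    max_substrate_degree: int = 4
    min_hub_separation: int = 4
    rr: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 10:
            raise DataError(f"n_nodes must be >=10, got {self.n_nodes}")
        if self.n_shared > min(self.n_a, self.n_b):
            raise DataError("n_shared exceeds a disease set size")
        if self.n_a + self.n_b - self.n_shared > self.n_nodes:
            raise DataError("gene sets larger than the graph")
        if not 0.0 < self.locality <= 1.0:
            raise DataError(f"locality must lie in (0, 1], got {self.locality}")
        if min(self.n_a, self.n_b) < self.n_shared + 1:
            raise DataError("each disease needs at least one exclusive gene")
        if self.n_hubs < 1:
            raise DataError("n_hubs must be >=1")


@dataclass(frozen=True)
class PlantedPair:
    """A graph plus two planted gene sets with a known shared core."""

    graph: nx.Graph
    g_a: frozenset
    g_b: frozenset
    shared: frozenset
    config: SyntheticConfig


def generate_graph(n_nodes: int, attachment: int = 2, seed: int = 0) -> nx.Graph:
    """Connected preferential-attachment substrate with string gene ids.

    Growth starts from a small complete core; each new node attaches to
    ``attachment`` existing nodes chosen proportionally to degree, so the
    edge count is exactly
    ``C(attachment, 2) + attachment * (n_nodes - attachment)``.
    """
    if attachment < 1 or n_nodes < attachment + 1:
        raise DataError(
            f"need n_nodes >= attachment+1 >= 2, got n_nodes={n_nodes}, "
            f"attachment={attachment}")
    # a single node has no edges to attach to, so the m=1 core is one edge
    core = nx.complete_graph(max(attachment, 2))
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed, initial_graph=core)
    width = len(str(n_nodes - 1))
    return nx.relabel_nodes(g, {i: f"g{i:0{width}d}" for i in g.nodes})


def _effective_hubs(config: SyntheticConfig) -> int:
    return max(1, min(config.n_hubs,
                      config.n_a - config.n_shared,
                      config.n_b - config.n_shared))


def plant_pair(g: nx.Graph, config: SyntheticConfig) -> PlantedPair:
    """Plant two overlapping disease gene sets onto a substrate graph.

    Returns a :class:`PlantedPair` whose graph is a copy of ``g`` augmented
    with the planted interaction edges (the substrate itself is never
    modified). The planted intersection is exact:
    ``g_a ∩ g_b == shared`` with ``|shared| == n_shared``.
    """
    rng = np.random.default_rng(config.seed)
    graph = g.copy()
    nodes = sorted(graph.nodes)
    low = [x for x in nodes if graph.degree[x] <= config.max_substrate_degree]
    if len(low) < (config.n_a + config.n_b):
        low = sorted(nodes, key=lambda x: (graph.degree[x], x))[
            : max(config.n_a + config.n_b, len(nodes) // 2)]
    n_hubs = _effective_hubs(config)
    h_a0 = low[rng.integers(len(low))]
    dist_a = nx.single_source_shortest_path_length(graph, h_a0)
    sep = config.min_hub_separation
    while sep > 1:
        far = [x for x in low if dist_a.get(x, 10 ** 9) >= sep]
        if far:
            break
        sep -= 1
    if sep <= 1:
        raise DataError("substrate too small to separate the two disease hubs")
    h_b0 = far[rng.integers(len(far))]

    pool = [x for x in low if x not in (h_a0, h_b0)]
    n_ex_a = config.n_a - config.n_shared - n_hubs
    n_ex_b = config.n_b - config.n_shared - n_hubs
    if n_ex_a < 0 or n_ex_b < 0:  # tiny sets: all non-shared members are hubs
        n_hubs = min(config.n_a, config.n_b) - config.n_shared
        n_ex_a = config.n_a - config.n_shared - n_hubs
        n_ex_b = config.n_b - config.n_shared - n_hubs
    need = config.n_shared + 2 * (n_hubs - 1) + n_ex_a + n_ex_b
    if len(pool) < need:
        raise DataError(f"substrate too small: need {need} plantable nodes, "
                        f"have {len(pool)}")
    picks = rng.choice(pool, size=need, replace=False).tolist()
    i = config.n_shared
    shared = set(picks[:i])
    hubs_a = [h_a0] + picks[i:i + n_hubs - 1]
    i += n_hubs - 1
    hubs_b = [h_b0] + picks[i:i + n_hubs - 1]
    i += n_hubs - 1
    ex_a = picks[i:i + n_ex_a]
    ex_b = picks[i + n_ex_a:]

    for s in sorted(shared):  # pleiotropic connectors: wired to every hub
        for h in hubs_a + hubs_b:
            graph.add_edge(s, h)
    for hubs, members in ((hubs_a, ex_a), (hubs_b, ex_b)):
        for x in members:
            if rng.random() < config.locality:
                graph.add_edge(x, hubs[rng.integers(len(hubs))])

    g_a = frozenset(hubs_a) | shared | set(ex_a)
    g_b = frozenset(hubs_b) | shared | set(ex_b)
    pair = PlantedPair(graph=graph, g_a=frozenset(g_a), g_b=frozenset(g_b),
                       shared=frozenset(g_a & g_b), config=config)
    if pair.shared != frozenset(shared):  # pragma: no cover - construction guard
        raise DataError("planted intersection is not exact")
    return pair


def make_benchmark(n_pairs: int, config: SyntheticConfig | None = None,
                   seed: int = 0, out_dir=None, rr_scale: float = 2.0) -> tuple:
    """Generate a benchmark of independent planted disease pairs.

    Each pair lives on its own substrate (gene ids are prefixed ``p<i>.`` so
    the pairs can share one set of files); RR values are drawn from an
    exponential of mean ``rr_scale``, which spans the standard comorbidity
    bins [0,1), [1,2), [2,3), [3,∞).

    Returns ``(pairs, table)`` where ``table`` has columns
    ``disease_a, disease_b, rr, n_common``. With ``out_dir`` set, writes
    ``graph.tsv`` (the union of all pair graphs), ``assoc.tsv`` and
    ``pairs.tsv`` in the package's tabular formats (byte-stable per seed).
    """
    if n_pairs < 1:
        raise DataError(f"n_pairs must be >=1, got {n_pairs}")
    config = config or SyntheticConfig()
    master = np.random.default_rng(seed)
    width = len(str(max(n_pairs - 1, 1)))
    pairs, rows = [], []
    for i in range(n_pairs):
        substrate = generate_graph(config.n_nodes, config.attachment,
                                   seed=int(master.integers(2 ** 31)))
        cfg = replace(config, seed=int(master.integers(2 ** 31)),
                      rr=float(np.round(master.exponential(rr_scale), 3)))
        pair = plant_pair(substrate, cfg)
        prefix = f"p{i:0{width}d}."
        relabel = {x: prefix + x for x in pair.graph.nodes}
        pair = PlantedPair(
            graph=nx.relabel_nodes(pair.graph, relabel),
            g_a=frozenset(relabel[x] for x in pair.g_a),
            g_b=frozenset(relabel[x] for x in pair.g_b),
            shared=frozenset(relabel[x] for x in pair.shared),
            config=cfg)
        pairs.append(pair)
        rows.append({"disease_a": f"D{i:0{width}d}a",
                     "disease_b": f"D{i:0{width}d}b",
                     "rr": cfg.rr, "n_common": len(pair.shared)})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        union = nx.compose_all([p.graph for p in pairs])
        write_interactome(union, out / "graph.tsv")
        assoc = {}
        for row, pair in zip(rows, pairs):
            assoc[row["disease_a"]] = set(pair.g_a)
            assoc[row["disease_b"]] = set(pair.g_b)
        write_associations(assoc, out / "assoc.tsv")
        write_pairs_table(table, out / "pairs.tsv")
        log.info("benchmark written to %s (%d pairs)", out, n_pairs)
    return pairs, table


def write_pairs_table(table: pd.DataFrame, path) -> None:
    """Write a disease-pair table as TSV with a ``#``-comment header."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# disease_a\tdisease_b\trr\n")
        for _, row in table.iterrows():
            fh.write(f"{row['disease_a']}\t{row['disease_b']}\t{row['rr']:g}\n")


def load_pairs_table(path) -> list:
    """Read a pairs TSV into ``[(disease_a, disease_b, rr-or-None), ...]``."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise DataError(f"{path}: pair line needs >=2 columns: {line!r}")
            rr = float(fields[2]) if len(fields) > 2 and fields[2] != "" else None
            out.append((fields[0], fields[1], rr))
    if not out:
        raise DataError(f"{path}: no disease pairs found")
    return out
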