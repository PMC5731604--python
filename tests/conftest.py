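import networkx as nx
import numpy as np
import pytest

import modsep as m


@pytest.fixture()
def path5():
    """The 5-node path graph 1–2–3–4–5 used in the worked examples."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes})


@pytest.fixture(scope="session")
def benchmark():
    """Planted 50-pair benchmark plus per-pair AUROCs for all three settings.

    Shared session-wide because the nearest / all-pair / randomized-null
    comparisons are all made on the same pairs and splits.
    """
    pairs, table = m.make_benchmark(50, seed=0)
    nearest, allpair, null = [], [], []
    for i, p in enumerate(pairs):
        nearest.append(m.evaluate_pair(p.graph, p.g_a, p.g_b, seed=i).roc_score)
        allpair.append(m.evaluate_pair(p.graph, p.g_a, p.g_b, seed=i,
                                       method=m.ALL_PAIR).roc_score)
        a2, b2 = m.randomize_common_genes(p.graph, p.g_a, p.g_b, seed=i)
        null.append(m.evaluate_pair(p.graph, a2, b2, seed=i).roc_score)
    return {"pairs": pairs, "table": table,
            "nearest": np.array(nearest), "allpair": np.array(allpair),
            "null": np.array(null)}
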