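"""SNP-pair interaction graph and hub extraction.

The post-analysis takes the top pairs by mean test balanced accuracy,
draws them as an undirected graph (nodes = SNPs, or genes when a
SNP-to-gene label map is supplied), and reports hub nodes — those with at
least four edges by default.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .datamodel import ValidationError
from .engine import SearchResult


def build_pair_graph(results: list[SearchResult], top_k: int,
                     label_map: dict[str, str] | None = None) -> nx.Graph:
    """Graph of the ``top_k`` pairs with the highest mean test BA.

    With a label map, parallel edges between the same mapped pair collapse
    to one edge whose ``multiplicity`` counts the underlying SNP pairs and
    whose ``ba`` keeps the best BA.  Self-loops (both SNPs mapping to the
    same label) are dropped.
    """
    if top_k > len(results):
        raise ValidationError(f"top_k={top_k} exceeds {len(results)} results")
    ranked = sorted(results, key=lambda r: (-r.mean_test_ba, r.combo))
    g = nx.Graph()
    for r in ranked[:top_k]:
        if len(r.combo) != 2:
            raise ValidationError("pair graph requires order-2 combinations")
        a, b = r.combo
        if label_map is not None:
            a, b = label_map.get(a, a), label_map.get(b, b)
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["multiplicity"] += 1
            g[a][b]["ba"] = max(g[a][b]["ba"], r.mean_test_ba)
        else:
            g.add_edge(a, b, ba=r.mean_test_ba, multiplicity=1)
    return g


def find_hubs(g: nx.Graph, min_degree: int = 4) -> list[tuple[str, int]]:
    """Nodes with degree >= min_degree (inclusive), sorted by degree
    descending then label."""
    if min_degree < 1:
        raise ValidationError("min_degree must be at least 1")
    hubs = [(n, d) for n, d in g.degree() if d >= min_degree]
    return sorted(hubs, key=lambda nd: (-nd[1], nd[0]))


def write_edgelist_tsv(g: nx.Graph, path) -> None:
    rows = [
        {"node1": a, "node2": b, "mean_test_ba": d.get("ba"),
         "multiplicity": d.get("multiplicity", 1)}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
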