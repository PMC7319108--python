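"""Median-joining haplotype networks.

Construction follows the classic two-step scheme: (1) the minimum spanning
network (MSN) — the union of all minimum spanning trees, optionally relaxed by
an epsilon tolerance on the component-merge threshold; (2) median vectors
(per-character majority consensus of connected triplets) are added greedily
while they reduce the total parsimony cost, then median nodes not lying on any
shortest path between observed haplotypes are removed. Substitution and indel
characters carry equal weight: an indel is one mutational step.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .haplo import MISSING, DistanceMatrix, HaplotypeTable

__all__ = ["HaplotypeNetwork", "minimum_spanning_network", "median_joining_network"]

MAX_MEDIANS = 10_000


@dataclass
class HaplotypeNetwork:
    nodes: list[dict]  # {id, kind: observed|median, state, frequency, populations}
    edges: list[tuple[str, str, int]]  # (u, v, steps)
    epsilon: int = 0

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node["id"], **node)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    def total_cost(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "epsilon": self.epsilon,
                "nodes": self.nodes,
                "edges": [{"source": u, "target": v, "steps": w} for u, v, w in self.edges],
            },
            indent=indent,
        )


def _state_distance(a: tuple, b: tuple) -> int:
    return sum(
        1 for x, y in zip(a, b) if x != MISSING and y != MISSING and x != y
    )


def minimum_spanning_network(
    dists: DistanceMatrix, epsilon: int = 0
) -> list[tuple[str, str, int]]:
    """Union of all minimum spanning trees, epsilon-relaxed.

    An edge (u, v) belongs to the MSN iff its weight does not exceed the
    minimax distance between u and v (the largest edge on the MST path, i.e.
    the threshold at which their components merge in Kruskal's distance-class
    sweep) plus epsilon. Deterministic for fixed input.
    """
    labels = list(dists.labels)
    H = len(labels)
    if H < 2:
        raise ValueError("need >= 2 haplotypes")
    d = dists.values
    g = nx.Graph()
    g.add_nodes_from(range(H))
    for i, j in itertools.combinations(range(H), 2):
        g.add_edge(i, j, weight=float(d[i, j]))
    mst = nx.minimum_spanning_tree(g)
    # minimax distance = max edge weight on the (unique) MST path
    minimax = np.zeros((H, H))
    for i in range(H):
        path_to = nx.single_source_dijkstra_path(mst, i)
        for j in range(H):
            if i == j:
                continue
            path = path_to[j]
            minimax[i, j] = max(
                mst[u][v]["weight"] for u, v in zip(path, path[1:])
            )
    edges = [
        (labels[i], labels[j], int(round(d[i, j])))
        for i, j in itertools.combinations(range(H), 2)
        if d[i, j] <= minimax[i, j] + epsilon
    ]
    return edges


def _majority_median(u: tuple, v: tuple, w: tuple) -> tuple:
    """Per-character majority of a triplet; ties fall back to the state of u."""
    out = []
    for a, b, c in zip(u, v, w):
        states = [s for s in (a, b, c) if s != MISSING]
        if not states:
            out.append(MISSING)
            continue
        vals, counts = np.unique(np.array(states, dtype=object), return_counts=True)
        if counts.max() >= 2:
            out.append(vals[counts.argmax()])
        else:
            out.append(a if a != MISSING else states[0])
    return tuple(out)


def _mst_cost(states: list[tuple]) -> float:
    g = nx.Graph()
    g.add_nodes_from(range(len(states)))
    for i, j in itertools.combinations(range(len(states)), 2):
        g.add_edge(i, j, weight=_state_distance(states[i], states[j]))
    return sum(w for _, _, w in nx.minimum_spanning_tree(g).edges(data="weight"))


def median_joining_network(
    table: HaplotypeTable, epsilon: int = 0
) -> HaplotypeNetwork:
    """Build the median-joining network of a haplotype table.

    Iterates: build the MSN over the current node set; for every triplet
    connected in the MSN, form the per-character majority median; add the
    median that most reduces the minimum-spanning cost; repeat to fixpoint
    (capped at 10,000 additions). Median vectors not on any shortest path
    between observed haplotypes are finally removed.
    """
    observed = list(table.signatures)
    obs_ids = list(table.hap_ids)
    states: list[tuple] = list(observed)
    ids: list[str] = list(obs_ids)

    def msn_edges(current: list[tuple], names: list[str]):
        H = len(current)
        d = np.zeros((H, H))
        for i, j in itertools.combinations(range(H), 2):
            d[i, j] = d[j, i] = _state_distance(current[i], current[j])
        return minimum_spanning_network(DistanceMatrix(names, d), epsilon)

    n_added = 0
    while n_added < MAX_MEDIANS:
        cost = _mst_cost(states)
        edges = msn_edges(states, ids)
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_weighted_edges_from(edges)
        idx = {name: i for i, name in enumerate(ids)}
        candidates: dict[tuple, float] = {}
        for a, b, c in itertools.combinations(sorted(ids), 3):
            sub = g.subgraph([a, b, c])
            if not nx.is_connected(sub):
                continue
            med = _majority_median(states[idx[a]], states[idx[b]], states[idx[c]])
            if med in states or med in candidates:
                continue
            candidates[med] = _mst_cost(states + [med])
        improving = {m: c for m, c in candidates.items() if c < cost}
        if not improving:
            break
        best = min(improving, key=lambda m: (improving[m], tuple(map(str, m))))
        states.append(best)
        n_added += 1
        ids.append(f"mv{n_added}")

    # obsolete-median removal: keep medians on some shortest observed-observed path
    while True:
        edges = msn_edges(states, ids)
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_weighted_edges_from(edges)
        dist = dict(nx.all_pairs_dijkstra_path_length(g))
        removable = []
        for name in ids:
            if not name.startswith("mv"):
                continue
            on_path = any(
                abs(dist[a][name] + dist[name][b] - dist[a][b]) < 1e-9
                for a, b in itertools.combinations(obs_ids, 2)
            )
            if not on_path:
                removable.append(name)
        if not removable:
            break
        keep = [i for i, name in enumerate(ids) if name not in set(removable)]
        states = [states[i] for i in keep]
        ids = [ids[i] for i in keep]

    edges = msn_edges(states, ids) if len(states) > 1 else []
    global_counts = table.global_counts()
    nodes = []
    for name, state in zip(ids, states):
        if name.startswith("mv"):
            nodes.append(
                {"id": name, "kind": "median", "state": list(map(str, state)), "frequency": 0, "populations": {}}
            )
        else:
            pops = {
                p: int(c) for p, c in table.counts.loc[name].items() if c > 0
            }
            nodes.append(
                {
                    "id": name,
                    "kind": "observed",
                    "state": list(map(str, state)),
                    "frequency": int(global_counts[name]),
                    "populations": pops,
                }
            )
    return HaplotypeNetwork(nodes=nodes, edges=edges, epsilon=epsilon)
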