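"""Summary statistics of directed affect networks.

The network is a 6x6 weight matrix W with W[j, k] the lagged effect of
node k on node j.  Metrics follow the conventions of temporal-network
studies of momentary affect: *negative connectivity* (summed absolute
weights among negative-affect nodes), *out-strength centrality* (summed
outgoing weights of a node), cross-valence effect sums, and enumeration of
mutually reinforcing ("vicious") cycles.  Self-loops (autoregressions) are
excluded from summed metrics by default, since the quantities describe
influence *between* nodes; a flag restores them for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .simulate import NODES, POSITIVE_NODES, NEGATIVE_NODES


def _as_matrix(network):
    """Accept an AffectNetwork-like object (``.weights``, ``.nodes``) or a
    bare 6x6 array with the canonical node order."""
    if hasattr(network, "weights"):
        W = np.asarray(network.weights, dtype=float)
        nodes = tuple(network.nodes)
    else:
        W = np.asarray(network, dtype=float)
        nodes = NODES
    if W.shape != (len(nodes), len(nodes)):
        raise ValueError("weight matrix does not match the node list")
    return W, nodes


def _indices(nodes, wanted):
    idx = []
    for n in wanted:
        if n not in nodes:
            raise KeyError(f"unknown node {n!r}")
        idx.append(nodes.index(n))
    return idx


def negative_connectivity(network, include_self_loops: bool = False) -> float:
    """Sum of absolute weights over all paths between negative-affect nodes
    (all estimated paths, significant or not)."""
    W, nodes = _as_matrix(network)
    neg = _indices(nodes, [n for n in NEGATIVE_NODES if n in nodes])
    if not neg:
        raise ValueError("network has no negative nodes")
    total = 0.0
    for j in neg:
        for k in neg:
            if j == k and not include_self_loops:
                continue
            total += abs(W[j, k])
    return float(total)


def out_strength(network, node: str, mode: str = "absolute",
                 include_self_loop: bool = False) -> float:
    """Out-strength centrality: sum of the node's outgoing edge weights
    (column W[., node]) to the other nodes.  ``mode='absolute'`` sums
    magnitudes so inhibitory edges still count as influence; ``'signed'``
    sums raw weights."""
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    W, nodes = _as_matrix(network)
    (k,) = _indices(nodes, [node])
    col = W[:, k].copy()
    if not include_self_loop:
        col[k] = 0.0
    return float(np.sum(np.abs(col)) if mode == "absolute" else np.sum(col))


def cross_valence_effect(network, from_valence: str, to_valence: str,
                         mode: str = "absolute") -> float:
    """Summed effect of one valence block on the other: the 9 directed
    entries from the source-valence nodes to the target-valence nodes."""
    valences = {"positive": POSITIVE_NODES, "negative": NEGATIVE_NODES}
    if from_valence not in valences or to_valence not in valences:
        raise ValueError("valences must be 'positive' or 'negative'")
    if from_valence == to_valence:
        raise ValueError("valences must be distinct")
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    W, nodes = _as_matrix(network)
    src = _indices(nodes, valences[from_valence])
    dst = _indices(nodes, valences[to_valence])
    block = W[np.ix_(dst, src)]
    return float(np.sum(np.abs(block)) if mode == "absolute" else np.sum(block))


def pa_to_na(network, mode: str = "absolute") -> float:
    return cross_valence_effect(network, "positive", "negative", mode=mode)


def na_to_pa(network, mode: str = "absolute") -> float:
    return cross_valence_effect(network, "negative", "positive", mode=mode)


# ---------------------------------------------------------------------------
# Reinforcing ("vicious") cycles
# ---------------------------------------------------------------------------

def _canonical(cycle):
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def find_reinforcing_cycles(network, node_subset=NEGATIVE_NODES,
                            max_length: int = 3,
                            require_positive_edges: bool = True) -> list:
    """Enumerate simple directed cycles of length 2..max_length among
    ``node_subset``.

    Intended for significance-filtered networks: pass a network whose
    non-significant weights are already zeroed.  With
    ``require_positive_edges`` only cycles whose every edge weight is
    positive (mutual reinforcement) are kept.  Each cycle is reported with
    its edge weights and its strength (the weakest edge).
    """
    node_subset = list(node_subset)
    if not node_subset:
        raise ValueError("node subset is empty")
    W, nodes = _as_matrix(network)
    idx = dict(zip(nodes, range(len(nodes))))
    _indices(nodes, node_subset)

    G = nx.DiGraph()
    G.add_nodes_from(node_subset)
    for src in node_subset:
        for dst in node_subset:
            if src == dst:
                continue
            w = W[idx[dst], idx[src]]
            if w != 0.0:
                G.add_edge(src, dst, weight=w)

    out = []
    for cycle in nx.simple_cycles(G):
        if not 2 <= len(cycle) <= max_length:
            continue
        order = _canonical(list(cycle))
        weights = tuple(
            W[idx[order[(i + 1) % len(order)]], idx[order[i]]]
            for i in range(len(order))
        )
        if require_positive_edges and not all(w > 0 for w in weights):
            continue
        out.append({
            "nodes": order,
            "weights": weights,
            "strength": float(min(weights, key=abs)),
        })
    out.sort(key=lambda c: (len(c["nodes"]), c["nodes"]))
    return out


@dataclass
class MetricSet:
    """One network's summary metrics under a fixed option set."""

    negative_connectivity: float
    out_strength: dict
    pa_to_na: float
    na_to_pa: float
    cycles: list
    options: dict = field(default_factory=dict)


def metric_set(network, mode: str = "absolute",
               include_self_loops: bool = False,
               cycle_subset=NEGATIVE_NODES, max_cycle_length: int = 3) -> MetricSet:
    """Compute the full metric battery for one network."""
    _, nodes = _as_matrix(network)
    return MetricSet(
        negative_connectivity=negative_connectivity(network, include_self_loops),
        out_strength={n: out_strength(network, n, mode=mode,
                                      include_self_loop=include_self_loops)
                      for n in nodes},
        pa_to_na=pa_to_na(network, mode=mode),
        na_to_pa=na_to_pa(network, mode=mode),
        cycles=find_reinforcing_cycles(network, node_subset=cycle_subset,
                                       max_length=max_cycle_length),
        options={"mode": mode, "include_self_loops": include_self_loops,
                 "cycle_subset": tuple(cycle_subset),
                 "max_cycle_length": max_cycle_length},
    )
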