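"""Paralog recovery from profile-vs-profile E-value matrices.

Profile search output is an asymmetric query × target E-value table.
Reciprocal-best-match (RBH) logic uses the directional values; the
homology network collapses directions by taking the minimum E-value of the
two as the edge weight.  Connected components then expose transitive
homology: two subunits can belong to one deep-homology group without a
direct significant hit, as long as a path of significant hits links them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ArmrootError

PROFILE_CLASSES = ("subunit", "merged_pair", "external")


def _best_nonself_hit(matrix, query, threshold):
    """Best (lowest-E) non-self target for a query; lexicographic tie-break."""
    row = matrix.loc[query].drop(labels=[query], errors="ignore")
    row = row.dropna()
    row = row[row <= threshold]
    if row.empty:
        return None
    best = row.min()
    candidates = sorted(row.index[row == best])
    return candidates[0]


def reciprocal_best_matches(matrix, threshold):
    """Unordered profile pairs that are each other's best non-self hit.

    A pair (a, b) qualifies iff b is a's best non-self target, a is b's
    best non-self target, and both directional E-values are <= threshold.
    Ties on equal E-values break toward the lexicographically smallest
    target label.  Returns a sorted list of sorted 2-tuples.
    """
    if threshold <= 0:
        raise ArmrootError("RBH threshold must be positive")
    best = {q: _best_nonself_hit(matrix, q, threshold) for q in matrix.index}
    pairs = set()
    for a, b in best.items():
        if b is None or b not in best:
            continue
        if best.get(b) == a:
            pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


@dataclass
class HomologyNetwork:
    """Undirected E-value graph with its connected-component partition."""

    graph: nx.Graph
    threshold: float

    @property
    def components(self):
        return sorted(
            (sorted(c) for c in nx.connected_components(self.graph)),
            key=lambda c: (-len(c), c),
        )

    def linkage(self, a, b):
        """("direct"|"transitive"|None, path length) between two profiles."""
        if a not in self.graph or b not in self.graph:
            return None, None
        if not nx.has_path(self.graph, a, b):
            return None, None
        length = nx.shortest_path_length(self.graph, a, b)
        if length == 0:
            return "self", 0
        return ("direct" if length == 1 else "transitive"), length

    def edge_table(self):
        rows = [
            (a, b, d["evalue"]) for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["profile_a", "profile_b", "evalue"])


def homology_components(matrix, threshold):
    """Build the homology network at an E-value threshold.

    Nodes are all profiles (queries and targets); an undirected edge joins
    a pair when either directional E-value is <= threshold, weighted by the
    smaller of the two.  Self-hits are ignored.
    """
    if threshold <= 0:
        raise ArmrootError("network threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(matrix.index)
    g.add_nodes_from(matrix.columns)
    for q in matrix.index:
        for t in matrix.columns:
            if q == t:
                continue
            e_qt = matrix.at[q, t]
            e_tq = matrix.at[t, q] if (t in matrix.index and q in matrix.columns) else np.nan
            candidates = [v for v in (e_qt, e_tq) if not np.isnan(v)]
            if not candidates:
                continue
            e = min(candidates)
            if e > threshold:
                continue
            if g.has_edge(q, t):
                e = min(e, g.edges[q, t]["evalue"])
            g.add_edge(q, t, evalue=float(e))
    return HomologyNetwork(graph=g, threshold=threshold)


def rank_hit_classes(matrix, node_classes, queries=None):
    """Order each query's hits by E-value and check the class hierarchy.

    ``node_classes`` maps every profile to one of
    ``("subunit", "merged_pair", "external")``.  For each query (default:
    all merged-pair profiles in the index) the hits are sorted ascending by
    E-value and the report flags whether the class ordering
    subunit <= merged_pair <= external holds along that ranking, i.e.
    whether the query hits all subunit profiles before any other pair
    profile and all pair profiles before anything external.

    Returns (hits DataFrame, flags dict query -> bool).
    """
    unknown = (set(matrix.index) | set(matrix.columns)) - set(node_classes)
    if unknown:
        raise ArmrootError(f"profiles without a class: {sorted(unknown)}")
    bad = set(node_classes.values()) - set(PROFILE_CLASSES)
    if bad:
        raise ArmrootError(f"unknown profile classes: {sorted(bad)}")
    if queries is None:
        queries = [q for q in matrix.index if node_classes[q] == "merged_pair"]
    rank_of = {c: i for i, c in enumerate(PROFILE_CLASSES)}
    rows, flags = [], {}
    for q in queries:
        hits = matrix.loc[q].drop(labels=[q], errors="ignore").dropna().sort_values(
            kind="mergesort"
        )
        ranks = [rank_of[node_classes[t]] for t in hits.index]
        flags[q] = all(a <= b for a, b in zip(ranks, ranks[1:]))
        for order, (t, e) in enumerate(hits.items(), start=1):
            rows.append((q, order, t, node_classes[t], float(e)))
    report = pd.DataFrame(
        rows, columns=["query", "rank", "target", "target_class", "evalue"]
    )
    return report, flags
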