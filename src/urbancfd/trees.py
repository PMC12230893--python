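"""Unrooted trees with branch lengths: construction, I/O and patristic distances.

The functional-diversity workflow represents a species pool twice — once as a
neighbour-joining tree built from trait dissimilarities and once as a
phylogeny — and all community metrics are read off tip-to-tip (patristic)
path lengths.  This module provides the shared tree container plus the
classical Saitou–Nei neighbour-joining algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Tree", "nj_tree", "patristic", "validate_distance_matrix"]


@dataclass
class Tree:
    """An unrooted tree: integer nodes, weighted edges, labelled tips.

    Parameters
    ----------
    edges
        List of ``(u, v, length)`` tuples; lengths must be ``>= 0``.
    tip_labels
        Mapping from node id to tip label for every leaf.
    """

    edges: list[tuple[int, int, float]]
    tip_labels: dict[int, str]
    _graph: nx.Graph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = nx.Graph()
        for u, v, w in self.edges:
            if w < 0:
                raise ValueError(f"negative branch length {w} on edge ({u},{v})")
            g.add_edge(u, v, length=float(w))
        if len(self.tip_labels) == 1 and not self.edges:
            g.add_node(next(iter(self.tip_labels)))
        if len(set(self.tip_labels.values())) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        object.__setattr__(self, "_graph", g)

    # -- basic accessors ---------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return sorted(self.tip_labels.values())

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def total_length(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Tree":
        ids: dict[dendropy.Node, int] = {}

        def nid(node: dendropy.Node) -> int:
            if node not in ids:
                ids[node] = len(ids)
            return ids[node]

        edges, labels = [], {}
        for node in tree.preorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                labels[u] = node.taxon.label
            for child in node.child_nodes():
                length = child.edge.length if child.edge.length is not None else 0.0
                edges.append((u, nid(child), float(max(length, 0.0))))
        return cls(edges=edges, tip_labels=labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    def to_newick(self) -> str:
        """Serialize via an arbitrary rooting at the highest-degree node."""
        g = self._graph
        if len(self.tip_labels) == 1:
            return f"({next(iter(self.tip_labels.values()))}:0.0);"
        if len(self.tip_labels) == 2 and len(self.edges) == 1:
            (u, v, w) = self.edges[0]
            return f"({self.tip_labels[u]}:{w / 2:.10g},{self.tip_labels[v]}:{w / 2:.10g});"
        root = max(g.nodes, key=lambda n: (g.degree(n), -n))

        def render(node: int, parent: int | None) -> str:
            children = [n for n in g.neighbors(node) if n != parent]
            if not children:
                return self.tip_labels[node]
            inner = ",".join(
                f"{render(c, node)}:{g.edges[node, c]['length']:.10g}" for c in children
            )
            label = self.tip_labels.get(node, "")
            return f"({inner}){label}"

        return render(root, None) + ";"

    def relabel(self, mapping: dict[str, str]) -> "Tree":
        """Return a copy with tip labels substituted through ``mapping``."""
        new_labels = {n: mapping.get(lab, lab) for n, lab in self.tip_labels.items()}
        return Tree(edges=list(self.edges), tip_labels=new_labels)


def validate_distance_matrix(d: pd.DataFrame, *, tol: float = 1e-8) -> None:
    """Raise on asymmetric, negative, or nonzero-diagonal input."""
    a = np.asarray(d, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    if list(d.index) != list(d.columns):
        raise ValueError("index and columns must agree")
    if np.any(a < -tol):
        raise ValueError("negative distances")
    if np.max(np.abs(a - a.T)) > tol:
        raise ValueError("asymmetric distance matrix")
    if np.max(np.abs(np.diag(a))) > tol:
        raise ValueError("nonzero diagonal")


def patristic(tree: Tree) -> pd.DataFrame:
    """Tip-to-tip path lengths (sum of branch lengths on the unique path).

    Returns a symmetric zero-diagonal DataFrame indexed by sorted tip label.
    """
    labels = tree.tips
    node_of = {lab: n for n, lab in tree.tip_labels.items()}
    g = tree.graph
    m = len(labels)
    out = np.zeros((m, m))
    for i, lab in enumerate(labels):
        dist = nx.single_source_dijkstra_path_length(g, node_of[lab], weight="length")
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = dist[node_of[labels[j]]]
    return pd.DataFrame(out, index=labels, columns=labels)


def _three_taxon(d: pd.DataFrame, labels: list[str]) -> Tree:
    # unique unrooted star: x+y=dAB, x+z=dAC, y+z=dBC
    a, b, c = labels
    dab, dac, dbc = d.loc[a, b], d.loc[a, c], d.loc[b, c]
    x = max((dab + dac - dbc) / 2.0, 0.0)
    y = max(dab - x, 0.0)
    z = max(dac - x, 0.0)
    return Tree(
        edges=[(3, 0, x), (3, 1, y), (3, 2, z)],
        tip_labels={0: a, 1: b, 2: c},
    )


def nj_tree(d: pd.DataFrame) -> Tree:
    """Classical neighbour joining (Saitou & Nei 1987) on a distance matrix.

    For additive input the patristic distances of the result reproduce the
    input exactly.  Deterministic: ties on the Q criterion are broken by the
    lexicographically smallest pair of subtree representative labels, and
    negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch so the pair's path length is preserved.
    """
    validate_distance_matrix(d)
    labels = list(d.index)
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return Tree(edges=[], tip_labels={0: labels[0]})
    if n == 2:
        return Tree(edges=[(0, 1, float(d.iloc[0, 1]))], tip_labels={0: labels[0], 1: labels[1]})
    if n == 3:
        return _three_taxon(d, labels)

    D = np.asarray(d, dtype=float).copy()
    # active[i] -> (graph node id, representative label for tie-breaking)
    nodes = list(range(n))
    reps = list(labels)
    tip_labels = dict(enumerate(labels))
    edges: list[tuple[int, int, float]] = []
    next_id = n

    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        i, j = min(
            ((int(a), int(b)) for a, b in ties if a < b),
            key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))),
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, keeping li + lj = dij
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        edges.append((u, nodes[i], li))
        edges.append((u, nodes[j], lj))
        # distances from the new node to every remaining cluster
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dk[keep][None, :]])
        D = np.hstack([D, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [u]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # join the final three clusters on a central node
    (a, b, c) = range(3)
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max(dab - la, 0.0)
    lc = max(dac - la, 0.0)
    center = next_id
    edges.extend([(center, nodes[a], la), (center, nodes[b], lb), (center, nodes[c], lc)])
    return Tree(edges=edges, tip_labels=tip_labels)
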