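"""Neighbor-joining trees from distance matrices, with Newick and PHYLIP
interchange.

Classic Saitou–Nei agglomeration: at each step join the pair minimising

    Q_ij = (N - 2) d_ij - r_i - r_j,      r_i = Σ_k d_ik,

attach the joined clusters to a new internal node with the standard
branch-length split, and reduce the matrix. On an additive matrix the
result is the unique generating tree: its path-length metric reproduces
the input exactly. Ties in Q break on the lexicographically smallest
(cluster, cluster) label pair, so the output is deterministic. Negative
branch lengths (possible on non-additive input) are clamped to zero and
the deficit logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .binding import DistanceMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

_QTOL = 1e-12


@dataclass(frozen=True)
class Tree:
    """Unrooted leaf-labelled tree with non-negative branch lengths.

    Internal nodes are named ``_nj<i>``; every internal node of a binary
    NJ tree has degree 3 (the 3-taxon terminal join may leave a single
    degree-3 star centre).
    """

    graph: nx.Graph
    leaves: tuple[str, ...]

    def branch_length(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["length"])

    def path_length(self, a: str, b: str) -> float:
        return float(
            nx.shortest_path_length(self.graph, a, b, weight="length")
        )

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path metric, in leaf-label order."""
        n = len(self.leaves)
        out = np.zeros((n, n))
        for i in range(n):
            lengths = nx.single_source_dijkstra_path_length(
                self.graph, self.leaves[i], weight="length"
            )
            for j in range(n):
                out[i, j] = lengths[self.leaves[j]]
        np.fill_diagonal(out, 0.0)
        out = (out + out.T) / 2.0
        return DistanceMatrix(labels=self.leaves, values=out)


def _clamped(length: float, context: str) -> float:
    if length < 0.0:
        logger.warning(
            "negative NJ branch length %.6g at %s clamped to 0", length, context
        )
        return 0.0
    return length


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Build the neighbor-joining tree for a distance matrix.

    Two taxa produce the single-edge tree split at the midpoint. Input
    must be symmetric with zero diagonal (enforced by
    :class:`~hlapop.binding.DistanceMatrix`).
    """
    labels = list(d.labels)
    if len(labels) < 2:
        raise InputError("need at least 2 taxa")
    if len(set(labels)) != len(labels):
        raise InputError("duplicate taxon labels")
    g = nx.Graph()
    g.add_nodes_from(labels)
    next_id = 0

    def new_internal() -> str:
        nonlocal next_id
        next_id += 1
        return f"_nj{next_id}"

    if len(labels) == 2:
        centre = new_internal()
        half = d.values[0, 1] / 2.0
        g.add_edge(labels[0], centre, length=_clamped(half, labels[0]))
        g.add_edge(labels[1], centre, length=_clamped(half, labels[1]))
        return Tree(graph=g, leaves=tuple(labels))

    # active clusters: node id -> tie-break key (smallest descendant leaf)
    active = list(labels)
    minleaf = {l: l for l in labels}
    dm = {a: {b: float(d.get(a, b)) for b in labels if b != a} for a in labels}

    while len(active) > 3:
        n_act = len(active)
        r = {a: sum(dm[a].values()) for a in active}
        best = None
        for ii in range(n_act):
            for jj in range(ii + 1, n_act):
                a, b = active[ii], active[jj]
                q = (n_act - 2) * dm[a][b] - r[a] - r[b]
                key = tuple(sorted((minleaf[a], minleaf[b])))
                if (
                    best is None
                    or q < best[0] - _QTOL
                    or (abs(q - best[0]) <= _QTOL and key < best[1])
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        u = new_internal()
        dab = dm[a][b]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n_act - 2))
        lb = dab - la
        g.add_edge(a, u, length=_clamped(la, f"{a}-{u}"))
        g.add_edge(b, u, length=_clamped(lb, f"{b}-{u}"))
        minleaf[u] = min(minleaf[a], minleaf[b])
        dm[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = (dm[a][c] + dm[b][c] - dab) / 2.0
            dm[u][c] = duc
            dm[c][u] = duc
            del dm[c][a], dm[c][b]
        del dm[a], dm[b]
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: minleaf[x])
    centre = new_internal()
    la = (dm[a][b] + dm[a][c] - dm[b][c]) / 2.0
    lb = (dm[a][b] + dm[b][c] - dm[a][c]) / 2.0
    lc = (dm[a][c] + dm[b][c] - dm[a][b]) / 2.0
    g.add_edge(a, centre, length=_clamped(la, a))
    g.add_edge(b, centre, length=_clamped(lb, b))
    g.add_edge(c, centre, length=_clamped(lc, c))
    return Tree(graph=g, leaves=tuple(labels))


_NEWICK_META = set("();:,[]*' \t\n")


def _render_label(label: str, escape: bool) -> str:
    if not set(label) & _NEWICK_META:
        return label
    if not escape:
        raise InputError(
            f"label {label!r} contains Newick metacharacters"
        )
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: Tree, escape: bool = True) -> str:
    """Serialise as Newick with branch lengths, deterministically.

    The unrooted tree is written rooted at the internal node adjacent to
    the lexicographically smallest leaf; children order by their smallest
    descendant leaf. Labels containing Newick metacharacters (HLA names
    always do: '*' and ':') are single-quoted; with ``escape=False`` such
    labels are rejected instead.
    """
    g = tree.graph
    if len(tree.leaves) == 1:
        return f"{_render_label(tree.leaves[0], escape)};"
    start_leaf = min(tree.leaves)
    root = next(iter(g.neighbors(start_leaf)))

    def min_desc(node: str, parent: str) -> str:
        if g.degree(node) == 1:
            return node
        return min(
            min_desc(c, node) for c in g.neighbors(node) if c != parent
        )

    def render(node: str, parent: str) -> str:
        length = g.edges[node, parent]["length"]
        if g.degree(node) == 1:
            return f"{_render_label(node, escape)}:{length:.10g}"
        children = sorted(
            (c for c in g.neighbors(node) if c != parent),
            key=lambda c: min_desc(c, node),
        )
        inner = ",".join(render(c, node) for c in children)
        return f"({inner}):{length:.10g}"

    children = sorted(
        g.neighbors(root), key=lambda c: min_desc(c, root)
    )
    inner = ",".join(render(c, root) for c in children)
    return f"({inner});"


def phylip_distance_text(d: DistanceMatrix) -> str:
    """Square PHYLIP distance format: taxon-count line, then padded rows."""
    lines = [f"{len(d.labels):5d}"]
    for i, label in enumerate(d.labels):
        if len(label) > 10:
            name = label[:10]
        else:
            name = label.ljust(10)
        row = " ".join(f"{v:.6f}" for v in d.values[i])
        lines.append(f"{name}{row}")
    return "\n".join(lines) + "\n"


def write_phylip_distance(d: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(phylip_distance_text(d))
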