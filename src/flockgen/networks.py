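"""Distance-based topologies: neighbor-joining trees and neighbor-net
split networks, with Newick and NEXUS (SPLITS block) serialization.

The neighbor-net agglomeration produces a circular ordering of taxa; split
weights are then estimated by non-negative least squares of the circular
split system against the input distances, which preserves the
distance-reproduction property on circularly decomposable metrics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import nnls

from .structure import DistanceMatrix

# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def neighbor_joining(distances: DistanceMatrix, clamp_negative: bool = False) -> nx.Graph:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree as a networkx Graph whose leaf nodes are the
    input ids and whose internal nodes are strings ``"#0", "#1", ...``;
    every edge carries a ``length`` attribute. Q-criterion ties are broken
    by the lexicographically smallest pair of cluster ids (a cluster's id is
    its smallest leaf). Negative branch lengths are retained unless
    ``clamp_negative``.
    """
    ids = list(distances.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    tree = nx.Graph()
    tree.add_nodes_from(ids)
    if n == 2:
        tree.add_edge(ids[0], ids[1], length=float(distances.values[0, 1]))
        return tree

    D: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((ids[i], ids[j]))] = float(distances.values[i, j])

    def d(a, b):
        return 0.0 if a == b else D[frozenset((a, b))]

    active = list(ids)
    label = {t: t for t in ids}  # cluster id = smallest leaf in the cluster
    counter = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d(a, k) for k in active) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = tuple(sorted((label[a], label[b])))
                if best is None or q < best[0] - 1e-15 or (abs(q - best[0]) <= 1e-15 and key < best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        u = f"#{counter}"
        counter += 1
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d(a, b) - la
        if clamp_negative:
            la, lb = max(la, 0.0), max(lb, 0.0)
        tree.add_edge(a, u, length=float(la))
        tree.add_edge(b, u, length=float(lb))
        for k in active:
            if k in (a, b):
                continue
            D[frozenset((u, k))] = 0.5 * (d(a, k) + d(b, k) - d(a, b))
        label[u] = min(label[a], label[b])
        active = [k for k in active if k not in (a, b)] + [u]
    a, b = active
    lab = d(a, b)
    if clamp_negative:
        lab = max(lab, 0.0)
    tree.add_edge(a, b, length=float(lab))
    return tree


def leaves(tree: nx.Graph) -> list[str]:
    return sorted(v for v in tree.nodes if not str(v).startswith("#"))


def terminal_branch_lengths(tree: nx.Graph) -> dict[str, float]:
    out = {}
    for leaf in leaves(tree):
        (nbr,) = list(tree.neighbors(leaf))
        out[leaf] = float(tree.edges[leaf, nbr]["length"])
    return out


def tree_distance_matrix(tree: nx.Graph) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) distances of a tree."""
    lv = leaves(tree)
    paths = dict(nx.all_pairs_dijkstra_path_length(tree, weight="length"))
    vals = np.array([[paths[a][b] for b in lv] for a in lv])
    return DistanceMatrix(lv, vals)


def tree_splits(tree: nx.Graph) -> dict[frozenset, float]:
    """Each edge's leaf bipartition (the side without the smallest leaf) -> length."""
    lv = leaves(tree)
    ref = min(lv)
    out = {}
    for a, b in tree.edges:
        t2 = tree.copy()
        t2.remove_edge(a, b)
        side = {v for v in nx.node_connected_component(t2, a) if not str(v).startswith("#")}
        if ref in side:
            side = set(lv) - side
        if side and len(side) < len(lv):
            out[frozenset(side)] = out.get(frozenset(side), 0.0) + float(tree.edges[a, b]["length"])
    return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: nx.Graph) -> str:
    """Serialize a tree to Newick with deterministic child ordering.

    A 2-leaf tree splits its single edge evenly between the two terminal
    branches. Otherwise the tree is written rooted at the internal node
    adjacent to the lexicographically smallest leaf, with children ordered
    by the smallest leaf in each subtree.
    """
    lv = leaves(tree)
    if len(lv) == 2:
        h = float(tree.edges[lv[0], lv[1]]["length"]) / 2.0
        return f"({_quote(lv[0])}:{h:.10g},{_quote(lv[1])}:{h:.10g});"

    root = next(iter(tree.neighbors(min(lv))))

    def min_leaf(node, parent):
        if not str(node).startswith("#"):
            return node
        return min(min_leaf(c, node) for c in tree.neighbors(node) if c != parent)

    def render(node, parent):
        length = float(tree.edges[node, parent]["length"])
        if not str(node).startswith("#"):
            return f"{_quote(node)}:{length:.10g}"
        children = sorted(
            (c for c in tree.neighbors(node) if c != parent),
            key=lambda c: min_leaf(c, node),
        )
        inner = ",".join(render(c, node) for c in children)
        return f"({inner}):{length:.10g}"

    children = sorted(tree.neighbors(root), key=lambda c: min_leaf(c, root))
    inner = ",".join(render(c, root) for c in children)
    return f"({inner});"


def parse_newick(text: str) -> nx.Graph:
    """Parse Newick into the unrooted networkx representation."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    tree = nx.Graph()
    counter = [0]
    names: dict = {}

    def name_of(node):
        if node not in names:
            if node.taxon is not None:
                names[node] = node.taxon.label
            else:
                names[node] = f"#{counter[0]}"
                counter[0] += 1
        return names[node]

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        tree.add_edge(
            name_of(edge.tail_node),
            name_of(edge.head_node),
            length=float(edge.length or 0.0),
        )
    # suppress a degree-2 root left by rooted Newick
    for node in list(tree.nodes):
        if str(node).startswith("#") and tree.degree(node) == 2:
            (a, b) = list(tree.neighbors(node))
            total = tree.edges[node, a]["length"] + tree.edges[node, b]["length"]
            tree.remove_node(node)
            tree.add_edge(a, b, length=total)
    return tree


# ---------------------------------------------------------------------------
# Split systems / neighbor-net
# ---------------------------------------------------------------------------


@dataclass
class SplitSystem:
    """Weighted circular split system.

    ``splits`` holds, for each split, the side that does not contain the
    first taxon of ``circular_order``; every split is an interval of the
    circular order and all weights are non-negative.
    """

    taxa: list[str]
    circular_order: list[str]
    splits: list[frozenset]
    weights: list[float]

    def __post_init__(self) -> None:
        if sorted(self.taxa) != sorted(self.circular_order):
            raise ValueError("circular_order must be a permutation of taxa")
        if any(w < 0 for w in self.weights):
            raise ValueError("split weights must be non-negative")

    def induced_distance_matrix(self) -> DistanceMatrix:
        n = len(self.taxa)
        idx = {t: i for i, t in enumerate(self.taxa)}
        vals = np.zeros((n, n))
        for side, w in zip(self.splits, self.weights):
            inside = np.zeros(n, dtype=bool)
            for t in side:
                inside[idx[t]] = True
            sep = inside[:, None] != inside[None, :]
            vals += w * sep
        return DistanceMatrix(self.taxa, vals)

    def as_dict(self) -> dict[frozenset, float]:
        return dict(zip(self.splits, self.weights))

    def canonical_splits(self) -> dict[frozenset, float]:
        """Splits keyed by the side not containing the smallest taxon label
        (a representation-independent form for comparisons)."""
        ref = min(self.taxa)
        out: dict[frozenset, float] = {}
        for side, w in zip(self.splits, self.weights):
            if ref in side:
                side = frozenset(self.taxa) - side
            out[side] = out.get(side, 0.0) + w
        return out


def _circular_splits(order: list[str]) -> list[frozenset]:
    """All n(n-1)/2 interval splits of a circular order (sides avoid order[0])."""
    n = len(order)
    out = []
    for i in range(1, n):
        for j in range(i + 1, n + 1):
            out.append(frozenset(order[i:j]))
    return out


def _fit_split_weights(order: list[str], distances: DistanceMatrix) -> tuple[list[frozenset], list[float]]:
    taxa = distances.ids
    idx = {t: k for k, t in enumerate(taxa)}
    splits = _circular_splits(order)
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    A = np.zeros((len(pairs), len(splits)))
    for s, side in enumerate(splits):
        inside = np.zeros(len(taxa), dtype=bool)
        for t in side:
            inside[idx[t]] = True
        for r, (i, j) in enumerate(pairs):
            A[r, s] = inside[i] != inside[j]
    dvec = np.array([distances.values[i, j] for i, j in pairs])
    w, _ = nnls(A, dvec, maxiter=10 * A.shape[1])
    keep = w > 1e-9
    return [s for s, k in zip(splits, keep) if k], [float(x) for x, k in zip(w, keep) if k]


def neighbor_net(distances: DistanceMatrix) -> SplitSystem:
    """Bryant-Moulton neighbor-net.

    Agglomerative selection yields a circular ordering of the taxa; split
    weights come from non-negative least squares of the circular splits
    against the input distances, and zero-weight splits are dropped.
    Negative input entries (possible FST artifacts) are clamped to 0 with a
    warning before ordering.
    """
    taxa = list(distances.ids)
    vals = distances.values.copy()
    if (vals < 0).any():
        warnings.warn("negative distances clamped to 0 for network input", stacklevel=2)
        vals = np.clip(vals, 0.0, None)
    n = len(taxa)
    if n <= 3:
        order = list(taxa)
        splits, weights = _fit_split_weights(order, DistanceMatrix(taxa, vals))
        return SplitSystem(taxa, order, splits, weights)

    order = _neighbor_net_order(taxa, vals)
    splits, weights = _fit_split_weights(order, DistanceMatrix(taxa, vals))
    return SplitSystem(taxa, order, splits, weights)


def _neighbor_net_order(taxa: list[str], vals: np.ndarray) -> list[str]:
    """Circular taxon ordering by neighbor-net agglomeration.

    Active nodes live in chains of one or two nodes (clusters). Cluster
    pairs are chosen by the NJ Q-criterion on average cluster distances;
    within the chosen pair, the node pair minimizing the node-level
    criterion is linked, and chains longer than two nodes are reduced by
    the 3-point reduction, recording each reduction for later expansion
    back into the full circular order.
    """
    n = len(taxa)
    D: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((i, j))] = float(vals[i, j])

    def d(a, b):
        return 0.0 if a == b else D[frozenset((a, b))]

    clusters: list[list[int]] = [[i] for i in range(n)]
    next_id = n
    expansions: list[tuple[int, int, int, int, int]] = []  # (u, v, a, b, c)

    def cluster_dist(A, B):
        return float(np.mean([[d(x, y) for y in B] for x in A]))

    def reduce3(a, b, c, others):
        nonlocal next_id
        u, v = next_id, next_id + 1
        next_id += 2
        for z in others:
            D[frozenset((u, z))] = (2.0 / 3.0) * d(a, z) + (1.0 / 3.0) * d(b, z)
            D[frozenset((v, z))] = (2.0 / 3.0) * d(c, z) + (1.0 / 3.0) * d(b, z)
        D[frozenset((u, v))] = (d(a, b) + d(b, c) + d(a, c)) / 3.0
        expansions.append((u, v, a, b, c))
        return u, v

    while len(clusters) > 1:
        N = len(clusters)
        # --- cluster-level selection (NJ Q on average distances)
        cd = np.zeros((N, N))
        for i in range(N):
            for j in range(i + 1, N):
                cd[i, j] = cd[j, i] = cluster_dist(clusters[i], clusters[j])
        r = cd.sum(axis=1)
        best = None
        for i in range(N):
            for j in range(i + 1, N):
                q = (N - 2) * cd[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, ci, cj = best
        A, B = clusters[ci], clusters[cj]

        # --- node-level selection
        if len(A) == 1 and len(B) == 1:
            x, y = A[0], B[0]
        else:
            others = [clusters[k] for k in range(N) if k not in (ci, cj)]
            m = len(others) + len(A) + len(B)
            union = A + B
            best2 = None
            for x in A:
                for y in B:
                    q = (m - 2) * d(x, y)
                    for grp in others:
                        q -= cluster_dist([x], grp) + cluster_dist([y], grp)
                    q -= sum(d(x, z) for z in union if z != x)
                    q -= sum(d(y, z) for z in union if z != y)
                    if best2 is None or q < best2[0] - 1e-15:
                        best2 = (q, x, y)
            _, x, y = best2

        w = A[0] if len(A) == 2 and A[1] == x else (A[1] if len(A) == 2 else None)
        b2 = B[0] if len(B) == 2 and B[1] == y else (B[1] if len(B) == 2 else None)

        remaining = [c for k, c in enumerate(clusters) if k not in (ci, cj)]
        other_nodes = [z for c in remaining for z in c]

        if w is None and b2 is None:
            new_cluster = [x, y]
        elif w is not None and b2 is None:
            u, v = reduce3(w, x, y, other_nodes)
            new_cluster = [u, v]
        elif w is None and b2 is not None:
            u, v = reduce3(x, y, b2, other_nodes)
            new_cluster = [u, v]
        else:
            u, v = reduce3(w, x, y, other_nodes + [b2])
            s, t = reduce3(u, v, b2, other_nodes)
            new_cluster = [s, t]
        clusters = remaining + [new_cluster]

    # --- expansion back to the circular order
    chain = list(clusters[0])
    for u, v, a, b, c in reversed(expansions):
        for k in range(len(chain) - 1):
            if chain[k] == u and chain[k + 1] == v:
                chain[k : k + 2] = [a, b, c]
                break
            if chain[k] == v and chain[k + 1] == u:
                chain[k : k + 2] = [c, b, a]
                break
        else:  # endpoints wrap around the circle
            if chain[0] == u and chain[-1] == v:
                chain = [b, c] + chain[1:-1] + [a]
            elif chain[0] == v and chain[-1] == u:
                chain = [b, a] + chain[1:-1] + [c]
            else:
                raise AssertionError("expansion nodes not adjacent in chain")
    assert sorted(chain) == list(range(n))
    return [taxa[i] for i in chain]


# ---------------------------------------------------------------------------
# NEXUS SPLITS serialization
# ---------------------------------------------------------------------------


def write_nexus_splits(system: SplitSystem) -> str:
    """NEXUS file with TAXA and SPLITS blocks (SplitsTree-compatible)."""
    n = len(system.taxa)
    idx = {t: i + 1 for i, t in enumerate(system.taxa)}
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={n};", "TAXLABELS"]
    for t in system.taxa:
        lines.append(f"  '{t}'")
    lines += [";", "END;", "", "BEGIN SPLITS;",
              f"DIMENSIONS NTAX={n} NSPLITS={len(system.splits)};",
              "FORMAT LABELS=NO WEIGHTS=YES;",
              "CYCLE " + " ".join(str(idx[t]) for t in system.circular_order) + ";",
              "MATRIX"]
    order = sorted(range(len(system.splits)),
                   key=lambda s: sorted(idx[t] for t in system.splits[s]))
    for s in order:
        members = " ".join(str(i) for i in sorted(idx[t] for t in system.splits[s]))
        lines.append(f"  {system.weights[s]:.10g}\t{members},")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def read_nexus_splits(text: str) -> SplitSystem:
    """Parse the NEXUS produced by :func:`write_nexus_splits`."""
    taxa: list[str] = []
    cycle: list[int] = []
    splits: list[frozenset] = []
    weights: list[float] = []
    mode = None
    for raw in text.splitlines():
        line = raw.strip()
        up = line.upper()
        if up == "TAXLABELS":
            mode = "taxa"
            continue
        if up.startswith("CYCLE"):
            cycle = [int(x) for x in line[5:].rstrip(";").split()]
            continue
        if up == "MATRIX":
            mode = "matrix"
            continue
        if line == ";":
            mode = None
            continue
        if mode == "taxa" and line:
            taxa.append(line.strip("'"))
        elif mode == "matrix" and line:
            w_str, members = line.rstrip(",").split("\t")
            weights.append(float(w_str))
            splits.append(frozenset(taxa[int(i) - 1] for i in members.split()))
    return SplitSystem(taxa, [taxa[i - 1] for i in cycle], splits, weights)
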