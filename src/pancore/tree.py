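"""Distance-based phylogeny: p-distances from the concatenated alignment,
neighbor joining, and Newick output.

Neighbor joining is the standard agglomerative algorithm on the Q-matrix
criterion; it is exact on additive distance matrices.  Determinism is pinned
down by a fixed tie-break (smallest Q, then the lexicographically smallest
pair of node keys, where a node's key is its smallest descendant leaf name).
Negative branch lengths, which NJ can produce on noisy matrices, are clamped
to zero with the deficit transferred to the sister branch so path lengths
through the parent are preserved.  The result is an unrooted tree written
with a trifurcation at the last join.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Concatenate
from .distances import DistanceMatrix

GAP_ORD = ord("-")


@dataclass
class Node:
    """Tree node: leaves carry a name, internal nodes carry children with
    branch lengths."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(
            f"{child._newick_part()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"


@dataclass
class PhyloTree:
    root: Node

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        values = np.zeros((n, n))

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for child, length in node.children:
                cmap = {k: v + length for k, v in walk(child).items()}
                child_maps.append(cmap)
            for i, ci in enumerate(child_maps):
                for cj in child_maps[i + 1 :]:
                    for a, da in ci.items():
                        for b, db in cj.items():
                            d = da + db
                            values[index[a], index[b]] = d
                            values[index[b], index[a]] = d
                below.update({k: v for cmap in child_maps for k, v in cmap.items()})
            return below

        walk(self.root)
        return DistanceMatrix(ids=names, values=values)


def p_distances(c: Concatenate) -> DistanceMatrix:
    """Pairwise mismatch fractions with pairwise deletion of gap columns."""
    if len(c.genomes) < 2:
        raise ValueError("need at least 2 genomes for distances")
    ids = list(c.genomes)
    arrays = {
        g: np.frombuffer(c.rows[g].encode("ascii"), dtype=np.uint8) for g in ids
    }
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[ids[i]], arrays[ids[j]]
            valid = (a != GAP_ORD) & (b != GAP_ORD)
            m = int(valid.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            d = int(((a != b) & valid).sum()) / m
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic tie-breaks and non-negative
    branch lengths (clamp-and-transfer)."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: dict[int, Node] = {i: Node(name=gid) for i, gid in enumerate(dm.ids)}
    keys: dict[int, str] = {i: gid for i, gid in enumerate(dm.ids)}
    D: dict[frozenset, float] = {
        frozenset((i, j)): float(dm.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return D[frozenset((i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            D[frozenset((u, k))] = (dist(i, k) + dist(j, k) - dij) / 2
        active -= {i, j}
        active.add(u)
        nodes[u] = parent
        keys[u] = min(keys[i], keys[j])
    a, b, c = sorted(active, key=lambda x: keys[x])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = Node(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return PhyloTree(root=root)
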