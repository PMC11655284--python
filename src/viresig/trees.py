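"""Agglomerative dendrograms and bootstrap branch support.

The linkage implementation is native so that tie-breaking is fully
specified: when several cluster pairs are equidistant the pair whose
(creation-order) ids are lexicographically smallest is merged first, making
trees reproducible across platforms. Heights follow the ultrametric
half-distance convention: a node joining two clusters at distance d sits at
height d/2, so leaf-to-leaf path depth equals the merge distance.

Six linkage methods are provided (single, complete, average/UPGMA, weighted,
centroid, ward) via Lance-Williams updates; UPGMA is the default everywhere.
"""
from __future__ import annotations

import numpy as np

LINKAGE_METHODS = ("single", "complete", "average", "weighted", "centroid", "ward")


def linkage_matrix(D: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns a (n-1, 4) array in the usual linkage layout: columns are the
    two merged cluster ids (originals 0..n-1, new clusters n, n+1, ...),
    the merge distance, and the size of the new cluster. Ties are broken by
    the lexicographically smallest id pair.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix over >=2 items")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    squared = method in ("centroid", "ward")
    W = D.copy() ** 2 if squared else D.copy()
    np.fill_diagonal(W, np.inf)

    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        m = len(ids)
        # locate global minimum; break ties on (id_i, id_j)
        best = (np.inf, None, None)
        for p in range(m):
            row = W[p, p + 1 : m]
            if row.size == 0:
                continue
            q = int(np.argmin(row)) + p + 1
            d = W[p, q]
            a, b = sorted((ids[p], ids[q]))
            if (d, a, b) < best:
                best = (d, a, b)
                bp, bq = p, q
        d = best[0]
        p, q = bp, bq
        i, j = ids[p], ids[q]
        ni, nj = sizes[i], sizes[j]
        merged = ni + nj
        a, b = sorted((i, j))
        Z[step] = (a, b, np.sqrt(d) if squared else d, merged)

        # Lance-Williams update of distances to every other cluster
        new_row = np.empty(m)
        for r in range(m):
            if r in (p, q):
                new_row[r] = np.inf
                continue
            dik, djk = W[p, r], W[q, r]
            nk = sizes[ids[r]]
            if method == "single":
                v = min(dik, djk)
            elif method == "complete":
                v = max(dik, djk)
            elif method == "average":
                v = (ni * dik + nj * djk) / merged
            elif method == "weighted":
                v = 0.5 * (dik + djk)
            elif method == "centroid":
                v = (ni * dik + nj * djk) / merged - ni * nj * d / merged**2
            else:  # ward
                v = ((ni + nk) * dik + (nj + nk) * djk - nk * d) / (merged + nk)
            new_row[r] = v
        W[p, :m] = new_row
        W[:m, p] = new_row
        W[p, p] = np.inf
        # drop position q
        keep = [r for r in range(m) if r != q]
        W = W[np.ix_(keep, keep)]
        ids = [ids[r] for r in keep]
        ids[p if p < q else p - 1] = next_id
        sizes[next_id] = merged
        next_id += 1
    return Z


class Dendrogram:
    """Rooted ultrametric tree from a linkage matrix plus leaf labels.

    Internal node t (t = 0 .. n-2) corresponds to linkage row t and carries
    cluster id n+t, merge distance Z[t,2] and height Z[t,2]/2. ``supports``
    maps internal node index -> bootstrap support in [0,1] (optional).
    """

    def __init__(self, Z: np.ndarray, labels: list[str], method: str = "average"):
        self.Z = np.asarray(Z, dtype=float)
        self.labels = list(labels)
        self.method = method
        self.supports: dict[int, float] = {}
        n = len(self.labels)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match label count")
        self._leafsets: list[frozenset[str]] = []
        for t in range(n - 1):
            sets = []
            for child in (int(self.Z[t, 0]), int(self.Z[t, 1])):
                if child < n:
                    sets.append(frozenset([self.labels[child]]))
                else:
                    sets.append(self._leafsets[child - n])
            self._leafsets.append(sets[0] | sets[1])

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafset(self, t: int) -> frozenset[str]:
        return self._leafsets[t]

    def clades(self, include_root: bool = False) -> list[frozenset[str]]:
        """Leaf sets of internal nodes (root excluded by default)."""
        out = list(self._leafsets)
        return out if include_root else out[:-1]

    def heights(self) -> np.ndarray:
        """Internal node heights (half the merge distance)."""
        return self.Z[:, 2] / 2.0

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the planar embedding."""
        n = self.n_leaves
        order: list[str] = []

        def walk(node: int) -> None:
            if node < n:
                order.append(self.labels[node])
            else:
                t = node - n
                walk(int(self.Z[t, 0]))
                walk(int(self.Z[t, 1]))

        walk(2 * n - 2)
        return order

    def cut(self, distance_threshold: float) -> dict[str, int]:
        """Group labels by cutting the tree at a merge-distance threshold.

        Two leaves share a group iff they are joined below (<=) the
        threshold. Group ids are assigned in leaf-order of appearance.
        """
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t in range(n - 1):
            if self.Z[t, 2] <= distance_threshold + 1e-12:
                for child in (int(self.Z[t, 0]), int(self.Z[t, 1])):
                    parent[find(child)] = find(n + t)
        groups: dict[int, int] = {}
        out: dict[str, int] = {}
        for leaf in range(n):
            root = find(leaf)
            if root not in groups:
                groups[root] = len(groups)
            out[self.labels[leaf]] = groups[root]
        return out

    def newick(
        self,
        include_support: bool = False,
        support_cutoff: float | None = None,
        decimals: int = 6,
    ) -> str:
        """Serialise to newick; supports (if any) become internal node labels.

        With ``support_cutoff`` set, supports below the cutoff are omitted
        from the string (the conventional "hide weak support" display rule).
        """
        n = self.n_leaves
        heights = self.heights()

        def node_height(node: int) -> float:
            return 0.0 if node < n else heights[node - n]

        def fmt(node: int, parent_h: float) -> str:
            bl = parent_h - node_height(node)
            if node < n:
                return f"{_escape(self.labels[node])}:{bl:.{decimals}f}"
            t = node - n
            left = fmt(int(self.Z[t, 0]), node_height(node))
            right = fmt(int(self.Z[t, 1]), node_height(node))
            label = ""
            if include_support and t in self.supports:
                s = self.supports[t]
                if support_cutoff is None or s >= support_cutoff:
                    label = f"{s:.3f}"
            return f"({left},{right}){label}:{bl:.{decimals}f}"

        root = 2 * n - 2
        t = root - n
        left = fmt(int(self.Z[t, 0]), node_height(root))
        right = fmt(int(self.Z[t, 1]), node_height(root))
        return f"({left},{right});"


def _escape(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Bootstrap branch support


def _bipartition(clade: frozenset[str], all_leaves: frozenset[str], anchor: str):
    """Canonical unrooted bipartition: the side not containing the anchor leaf."""
    return clade if anchor not in clade else all_leaves - clade


def consensus_supports(
    reference: Dendrogram, replicates: list[Dendrogram]
) -> dict[int, float]:
    """Fraction of replicate trees containing each reference bipartition."""
    leaves = frozenset(reference.labels)
    anchor = min(leaves)
    rep_sets = [
        {_bipartition(c, leaves, anchor) for c in rep.clades(include_root=True)}
        for rep in replicates
    ]
    out = {}
    for t, clade in enumerate(reference.clades(include_root=True)):
        bp = _bipartition(clade, leaves, anchor)
        out[t] = sum(bp in s for s in rep_sets) / len(rep_sets)
    return out


def transfer_supports(
    reference: Dendrogram, replicates: list[Dendrogram]
) -> dict[int, float]:
    """Transfer-bootstrap-expectation support per internal branch.

    For a reference branch with lighter side of p leaves, the transfer
    index against one replicate tree is the minimum Hamming distance
    between the branch's bipartition and any bipartition (including
    trivial ones) of the replicate; support is 1 - mean(index)/(p-1).
    Branches with p = 1 are trivially supported (1.0).
    """
    leaves = frozenset(reference.labels)
    n = len(leaves)
    rep_bips = []
    for rep in replicates:
        bips = [frozenset([x]) for x in rep.labels]
        bips += list(rep.clades(include_root=True))
        rep_bips.append(bips)
    out = {}
    for t, clade in enumerate(reference.clades(include_root=True)):
        A = clade
        p = min(len(A), n - len(A))
        if p <= 1:
            out[t] = 1.0
            continue
        deltas = []
        for bips in rep_bips:
            best = p - 1  # distance to a trivial bipartition, always attainable
            for B in bips:
                sym = len(A ^ B)
                d = min(sym, n - sym)
                if d < best:
                    best = d
                    if best == 0:
                        break
            deltas.append(best)
        out[t] = 1.0 - (sum(deltas) / len(deltas)) / (p - 1)
    return out
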