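"""Directional gene-set over-representation analysis.

Up- and down-regulated gene sets (positive / negative association with
a trait gradient) are tested separately against each annotation term by
the right-sided hypergeometric test, with BH-FDR applied jointly across
term x direction tests.  The urn is the set of genes actually tested in
the organ (post abundance filter), not the whole genome.  Signed
-log10(q) scores feed a Ward / Euclidean clustering of the
term x trait significance matrix; the clustering uses a deterministic
tie-break (merge the lexicographically smallest minimal-distance pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trait_association import bh_fdr

__all__ = [
    "GeneSetCollection",
    "EnrichmentError",
    "read_gmt",
    "hypergeom_right",
    "enrich",
    "overlap_significance",
    "ward_linkage",
    "ward_cluster",
    "WardClustering",
]


class EnrichmentError(ValueError):
    """Raised for inconsistent enrichment inputs."""


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term id -> description + members."""

    terms: dict[str, set]
    names: dict[str, str]

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise EnrichmentError(f"empty gene set: {term}")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (term, description, members... per tab-separated line)."""
    terms: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"malformed GMT line: {line[:60]!r}")
            term, name, members = parts[0], parts[1], parts[2:]
            if term in terms:
                raise EnrichmentError(f"duplicate term id: {term}")
            terms[term] = {m for m in members if m}
            names[term] = name
    return GeneSetCollection(terms, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, members in collection.terms.items():
            fh.write("\t".join([term, collection.names.get(term, term),
                                *sorted(members)]) + "\n")


def hypergeom_right(k: int, K: int, n: int, N: int) -> float:
    """Right tail P(X >= k) of Hypergeometric(N, K, n).

    ``N`` genes in the urn, ``K`` in the category, ``n`` drawn, ``k``
    drawn from the category.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise EnrichmentError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(up_genes, down_genes, universe, sets: GeneSetCollection,
           alpha: float = 0.05) -> pd.DataFrame:
    """Directional over-representation of each term.

    Tests the up- and down-regulated query against every term
    restricted to the universe, BH-corrects across all term x direction
    tests, and emits a signed score ``-log10(q)`` (negative for the
    down direction) for cluster maps.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    up = set(up_genes)
    down = set(down_genes)
    for label, query in (("up", up), ("down", down)):
        extra = query - universe
        if extra:
            raise EnrichmentError(
                f"{label} query contains genes outside the universe: "
                f"{sorted(extra)[:5]}")
    N = len(universe)
    rows = []
    for term, members in sets.terms.items():
        K_set = members & universe
        if not K_set:
            continue
        for direction, query in (("up", up), ("down", down)):
            k = len(query & K_set)
            rows.append({
                "term": term,
                "name": sets.names.get(term, term),
                "direction": direction,
                "k": k, "K": len(K_set), "n": len(query), "N": N,
                "p": hypergeom_right(k, len(K_set), len(query), N),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    sign = np.where(out["direction"] == "up", 1.0, -1.0)
    with np.errstate(divide="ignore"):
        out["signed_score"] = sign * -np.log10(np.maximum(out["q"], 1e-300))
    out["significant"] = out["q"] < alpha
    return out


def overlap_significance(set_a, set_b, universe) -> float:
    """Right-sided hypergeometric p for the overlap of two gene sets."""
    universe = set(universe)
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise EnrichmentError("sets must be subsets of the universe")
    return hypergeom_right(len(a & b), len(a), len(b), len(universe))


# ---------------------------------------------------------------------------
# Ward / Euclidean clustering with a deterministic tie-break
# ---------------------------------------------------------------------------

@dataclass
class WardClustering:
    """Agglomerative clustering result for one axis of a matrix.

    ``linkage`` follows the scipy convention: each row is
    ``(id_a, id_b, height, size)`` with new clusters numbered from n.
    """

    linkage: np.ndarray
    order: list[int]

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels from a constant-height cut."""
        n = self.linkage.shape[0] + 1
        parent = list(range(2 * n - 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m, (a, b, h, _) in enumerate(self.linkage):
            if h <= height:
                parent[find(int(a))] = n + m
                parent[find(int(b))] = n + m
        roots = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
        return labels


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward linkage on Euclidean distances, Lance-Williams recurrence.

    Among all minimal-distance pairs the lexicographically smallest
    ``(i, j)`` cluster-id pair is merged, which makes the merge tree
    deterministic under ties.  Heights are Euclidean-scale (square
    roots of the Ward objective), matching scipy's convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise EnrichmentError("ward_linkage expects a 2-d matrix")
    n = X.shape[0]
    if n < 2:
        return np.empty((0, 4))
    # squared Euclidean distances
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = sq[i, j]
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), d_ab = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = active.pop(a), active.pop(b)
        Z[step] = (a, b, np.sqrt(d_ab), na + nb)
        new = next_id
        next_id += 1
        for k, nk in active.items():
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            d_new = ((na + nk) * d_ak + (nb + nk) * d_bk - nk * d_ab) / (na + nb + nk)
            dist[(min(new, k), max(new, k))] = d_new
        del dist[(a, b)]
        active[new] = na + nb
    return Z


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    if n == 1:
        return [0]
    children = {n + m: (int(Z[m, 0]), int(Z[m, 1])) for m in range(Z.shape[0])}
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            stack.append(b)
            stack.append(a)  # left child (first merge partner) pops first
    return order


def ward_cluster(matrix: pd.DataFrame,
                 cut_height: float | None = None
                 ) -> tuple[WardClustering, WardClustering]:
    """Cluster rows and columns of a term x trait score matrix.

    Returns ``(row_clustering, col_clustering)``; pass the orders to a
    heatmap renderer.  ``cut_height`` (optional) is applied by the
    caller via :meth:`WardClustering.cut`.
    """
    X = matrix.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise EnrichmentError("score matrix must be finite")
    rz = ward_linkage(X)
    cz = ward_linkage(X.T)
    rows = WardClustering(rz, _leaf_order(rz, X.shape[0]))
    cols = WardClustering(cz, _leaf_order(cz, X.shape[1]))
    return rows, cols
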