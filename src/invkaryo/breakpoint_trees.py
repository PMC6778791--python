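"""Genetic-distance dendrograms around inversion breakpoints.

SNPs tightly flanking inversion breakpoints recombine very little with the
arrangement, so distance trees built from them reflect inversion history and
taxon structure. The pipeline: select biallelic SNPs within a fixed flank of
each breakpoint (minor allele frequency >= 0.01), convert alternate-allele
counts to a Euclidean distance matrix, build an unrooted neighbor-joining
(NJ) tree, and attach edge support from site-resampled bootstrap trees using
the transfer bootstrap estimate (TBE).

TBE support for a reference edge e with lighter side of size p is

    1 - mean_b [ delta(e, T_b) / (p - 1) ]

over bootstrap trees T_b, where delta is the transfer distance: the minimum
number of taxa that must be moved for some edge of T_b to induce e's
bipartition. delta is computed exactly by scanning every bipartition of the
bootstrap tree. The classical bootstrap proportion (fraction of replicates
containing the bipartition exactly) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import geno_io
from .types import MISSING, DataError, GenotypeMatrix, InversionDef


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any() or (v < 0).any():
            raise DataError("distances must be non-negative with zero diagonal")
        self.values = v


def _mean_impute(ac: np.ndarray) -> np.ndarray:
    X = ac.astype(float)
    miss = ac == MISSING
    if miss.any():
        col = np.nanmean(np.where(miss, np.nan, X), axis=0)
        col = np.where(np.isfinite(col), col, 0.0)
        X = np.where(miss, col[None, :], X)
    return X


def select_breakpoint_sites(
    gm: GenotypeMatrix,
    inv: InversionDef,
    flank: int | None = None,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Biallelic SNPs within ``flank`` bp of either breakpoint (inclusive
    windows, union) with minor allele frequency >= ``maf_min``."""
    flank = inv.flank if flank is None else flank
    windows = [(bp - flank, bp + flank) for bp in inv.breakpoints]
    sub = geno_io.site_filter(
        gm, maf_min=maf_min, spans=windows, chrom=inv.chrom, maf_mode="minor"
    )
    if sub.n_sites == 0:
        raise DataError(f"no breakpoint-flanking sites survive filters for {inv.name}")
    return sub


def euclidean_distances(gm: GenotypeMatrix | np.ndarray,
                        ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances over alternate-allele counts.

    Missing cells are mean-imputed per site first (the same policy as the
    karyotyping PCA), which preserves symmetry of the result.
    """
    if isinstance(gm, GenotypeMatrix):
        ac, ids = gm.alt_counts, list(gm.samples)
    else:
        ac = np.asarray(gm)
        ids = ids if ids is not None else [str(i) for i in range(ac.shape[0])]
    if ac.shape[0] < 4:
        raise DataError("need >= 4 samples for distance-tree analysis")
    X = _mean_impute(ac)
    return DistanceMatrix(ids=ids, values=squareform(pdist(X, metric="euclidean")))


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None                  # leaf label, None for internal
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """An unrooted tree stored rooted at the final NJ trifurcation."""

    root: Node
    ids: list[str]
    n_clamped: int = 0  # negative NJ branch lengths clamped to zero

    def bipartitions(self, include_trivial: bool = False) -> list[tuple[int, Node]]:
        """(leafset bitmask below each edge, child node of that edge).

        By default only internal (non-trivial) edges — both sides with at
        least two taxa — are returned.
        """
        return _collect_edges(self, include_trivial)

    def newick(self, labels: dict[int, str] | None = None) -> str:
        """Newick string; ``labels`` maps ``id(node)`` to an internal label."""
        labels = labels or {}

        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                s = f"({inner}){labels.get(id(node), '')}"
            return s if length is None else f"{s}:{length:.6g}"

        inner = ",".join(fmt(c, l) for c, l in self.root.children)
        return f"({inner}){labels.get(id(self.root), '')};"


def _collect_edges(tree: Tree, include_trivial: bool) -> list[tuple[int, Node]]:
    index = {s: i for i, s in enumerate(tree.ids)}
    n = len(tree.ids)
    out: list[tuple[int, Node]] = []

    def walk(node: Node, is_root: bool) -> int:
        if node.is_leaf:
            m = 1 << index[node.name]
        else:
            m = 0
            for child, _ in node.children:
                m |= walk(child, False)
        if not is_root:
            p = bin(m).count("1")
            if include_trivial or (2 <= p <= n - 2 and not node.is_leaf):
                out.append((m, node))
        return m

    walk(tree.root, True)
    return out


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Canonical Saitou-Nei neighbor-joining.

    Ties in the Q criterion break deterministically on the lowest
    (row, column) index pair; negative branch lengths are clamped to zero
    and counted in ``Tree.n_clamped``.
    """
    D = dist.values.copy()
    n = len(dist.ids)
    if n < 4:
        raise DataError("neighbor-joining here requires >= 4 taxa")
    nodes: list[Node] = [Node(name=s) for s in dist.ids]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major first minimum -> lowest-index pair
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        new = Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    root = Node(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root=root, ids=list(dist.ids), n_clamped=clamped)


# ---------------------------------------------------------------------------
# transfer bootstrap support
# ---------------------------------------------------------------------------

def transfer_index(edge_mask: int, tree_masks: list[int], n_taxa: int) -> int:
    """Exact transfer distance from a bipartition to the closest edge of a
    tree, scanning every bipartition (trivial ones included)."""
    best = n_taxa
    for m in tree_masks:
        h = bin(edge_mask ^ m).count("1")
        best = min(best, h, n_taxa - h)
        if best == 0:
            break
    return best


@dataclass
class SupportTree:
    tree: Tree
    n_bootstraps: int
    tbe: dict[int, float]        # id(node) of the child below each internal edge
    classical: dict[int, float]

    def newick(self, statistic: str = "tbe") -> str:
        src = self.tbe if statistic == "tbe" else self.classical
        labels = {k: f"{v:.3f}" for k, v in src.items()}
        return self.tree.newick(labels)

    def edge_table(self) -> pd.DataFrame:
        index = {i: s for i, s in enumerate(self.tree.ids)}
        rows = []
        for mask, node in _collect_edges(self.tree, include_trivial=False):
            members = [index[i] for i in range(len(self.tree.ids)) if mask >> i & 1]
            rows.append(
                {
                    "size": len(members),
                    "tbe": self.tbe[id(node)],
                    "classical": self.classical[id(node)],
                    "taxa": ",".join(members),
                }
            )
        return pd.DataFrame(rows)


def tbe_support(
    reference: Tree,
    alt_counts: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> SupportTree:
    """Transfer-bootstrap support for every internal edge of a reference tree.

    Bootstrap trees are built by resampling sites (columns) with
    replacement, recomputing Euclidean distances and NJ. For each internal
    reference edge with lighter side p, each replicate contributes
    ``1 - delta/(p-1)``; the TBE is the mean contribution. The classical
    proportion (``delta == 0``) is computed from the same replicates.
    """
    n = len(reference.ids)
    full = (1 << n) - 1
    ref_edges = _collect_edges(reference, include_trivial=False)
    if alt_counts.shape[0] != n:
        raise DataError("alt_counts rows must match the reference tree's taxa")
    rng = np.random.default_rng(seed)
    n_sites = alt_counts.shape[1]

    sums_delta = {id(node): 0.0 for _, node in ref_edges}
    hits = {id(node): 0 for _, node in ref_edges}
    p_of = {}
    for mask, node in ref_edges:
        pc = bin(mask).count("1")
        p_of[id(node)] = min(pc, n - pc)

    for _ in range(n_boot):
        cols = rng.integers(0, n_sites, size=n_sites)
        boot = alt_counts[:, cols]
        dm = euclidean_distances(boot, ids=list(reference.ids))
        btree = nj_tree(dm)
        bmasks = [m for m, _ in _collect_edges(btree, include_trivial=True)]
        for mask, node in ref_edges:
            delta = transfer_index(mask, bmasks, n)
            sums_delta[id(node)] += delta
            if delta == 0:
                hits[id(node)] += 1

    tbe, classical = {}, {}
    for mask, node in ref_edges:
        key = id(node)
        p = p_of[key]
        if p < 2:
            continue
        tbe[key] = 1.0 - (sums_delta[key] / n_boot) / (p - 1)
        classical[key] = hits[key] / n_boot
    return SupportTree(tree=reference, n_bootstraps=n_boot, tbe=tbe, classical=classical)


def breakpoint_tree(
    gm: GenotypeMatrix,
    inv: InversionDef,
    flank: int | None = None,
    maf_min: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> SupportTree:
    """Select flanking sites, build the NJ tree and attach TBE support."""
    sub = select_breakpoint_sites(gm, inv, flank=flank, maf_min=maf_min)
    dm = euclidean_distances(sub)
    tree = nj_tree(dm)
    return tbe_support(tree, _mean_impute(sub.alt_counts), n_boot=n_boot, seed=seed)
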