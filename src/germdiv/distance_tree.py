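"""Cavalli-Sforza & Edwards chord distances and distance-based trees.

Individuals are compared through their within-individual allele "frequencies"
(0, 0.5 or 1 for a diploid call).  For one locus the chord distance between
profiles x and y is

    d_l = (2/pi) * sqrt( 2 * (1 - sum_a sqrt(x_a * y_a)) )

and the overall distance is the arithmetic mean of d_l over the loci where
both individuals were scored.  The theoretical maximum per locus (disjoint
homozygotes) is 2*sqrt(2)/pi ~= 0.9003.  The prefactor and the aggregation are
isolated behind keyword arguments (``scale``, ``agg``) because distance
software differs in this normalisation.

Trees: Saitou-Nei neighbour joining (hand-rolled for deterministic tie
handling and non-negative branch clamping) and UPGMA via average-linkage
agglomeration; both are returned as :class:`dendropy.Tree`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .data_model import MISSING, GenotypeMatrix

#: Theoretical single-locus maximum of the (2/pi)-scaled chord distance.
MAX_CHORD = 2.0 * math.sqrt(2.0) / math.pi


class IncomparablePairError(ValueError):
    """Two accessions share no non-missing locus."""


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray
    #: per-pair count of loci both members were scored at (None if unknown)
    shared_loci: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("labels/matrix size mismatch")
        if np.isnan(self.values).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")

    def summary(self) -> dict:
        iu = np.triu_indices(len(self.labels), k=1)
        off = self.values[iu]
        return {
            "min": float(off.min()),
            "mean": float(off.mean()),
            "max": float(off.max()),
        }


# ---------------------------------------------------------------------------
# chord distance
# ---------------------------------------------------------------------------

def _locus_profile(call) -> dict | None:
    a, b = int(call[0]), int(call[1])
    if a == MISSING:
        return None
    return {a: 1.0} if a == b else {a: 0.5, b: 0.5}


def chord_distance(g1, g2, scale: str = "cavalli", agg: str = "mean") -> float:
    """Chord distance between two (n_loci, 2) genotype profiles.

    ``scale="cavalli"`` applies the 2/pi prefactor; ``scale="none"`` omits it.
    ``agg`` is ``"mean"`` (default) or ``"sum"`` over shared loci.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape or g1.ndim != 2 or g1.shape[1] != 2:
        raise ValueError("profiles must both be (n_loci, 2)")
    pref = 2.0 / math.pi if scale == "cavalli" else 1.0
    if scale not in ("cavalli", "none"):
        raise ValueError(f"unknown scale {scale!r}")
    dsum, shared = 0.0, 0
    for l in range(g1.shape[0]):
        x = _locus_profile(g1[l])
        y = _locus_profile(g2[l])
        if x is None or y is None:
            continue
        sim = sum(math.sqrt(x[a] * y[a]) for a in x.keys() & y.keys())
        dsum += pref * math.sqrt(max(0.0, 2.0 * (1.0 - sim)))
        shared += 1
    if shared == 0:
        raise IncomparablePairError("no shared non-missing locus")
    return dsum / shared if agg == "mean" else dsum


def distance_matrix(
    gm: GenotypeMatrix, scale: str = "cavalli", agg: str = "mean"
) -> DistanceMatrix:
    """All-pairs chord distances (vectorised per locus over the panel)."""
    if gm.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    n = gm.n_accessions
    pref = 2.0 / math.pi if scale == "cavalli" else 1.0
    if scale not in ("cavalli", "none"):
        raise ValueError(f"unknown scale {scale!r}")
    dsum = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    miss = gm.missing_mask()
    for j in range(gm.n_loci):
        col = gm.calls[:, j, :]
        obs = ~miss[:, j]
        codes = np.unique(col[obs])
        idx = {c: k for k, c in enumerate(codes)}
        X = np.zeros((n, len(codes)))
        for c in (0, 1):
            for i in np.nonzero(obs)[0]:
                X[i, idx[col[i, c]]] += 0.5
        S = np.sqrt(X)
        sim = np.clip(S @ S.T, None, 1.0)
        d_l = pref * np.sqrt(np.maximum(0.0, 2.0 * (1.0 - sim)))
        valid = np.outer(obs, obs)
        dsum += np.where(valid, d_l, 0.0)
        cnt += valid
    np.fill_diagonal(cnt, np.diag(cnt).clip(min=1))
    iu = np.triu_indices(n, k=1)
    if (cnt[iu] == 0).any():
        i, j = next(zip(*[a[cnt[iu] == 0] for a in iu]))
        raise IncomparablePairError(
            f"accessions {gm.ids[i]!r} and {gm.ids[j]!r} share no scored locus"
        )
    D = dsum / cnt if agg == "mean" else dsum
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(labels=gm.ids, values=D, shared_loci=cnt)


# ---------------------------------------------------------------------------
# PHYLIP square-matrix I/O
# ---------------------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for lbl, row in zip(dm.labels, dm.values):
            fh.write(str(lbl) + "  " + "  ".join(f"{x:.10g}" for x in row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        toks = [ln.split() for ln in fh if ln.strip()]
    n = int(toks[0][0])
    labels = [row[0] for row in toks[1 : n + 1]]
    values = np.array([[float(x) for x in row[1:]] for row in toks[1 : n + 1]])
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei NJ; ties in Q broken by lowest (row, col) pair, negative
    branch lengths clamped to zero."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 labels")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    taxa = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    nodes = {i: dendropy.Node(taxon=taxa[i]) for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                q = (r - 2) * sub[ai, bi] - R[ai] - R[bi]
                if best is None or q < best[0]:
                    best = (q, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[bi]) / (2.0 * (r - 2))
        lj = dij - li
        u = dendropy.Node()
        for child, ln_ in ((nodes[i], li), (nodes[j], lj)):
            child.edge.length = max(0.0, ln_)
            u.add_child(child)
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, ln_ in ((a, la), (b, lb), (c, lc)):
        nodes[k].edge.length = max(0.0, ln_)
        root.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage dendrogram as a rooted ultrametric binary tree."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 labels")
    Z = linkage(squareform(dm.values, checks=False), method="average")
    taxa = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    nodes = {i: dendropy.Node(taxon=taxa[i]) for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    for step, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        u = dendropy.Node()
        h = dist / 2.0  # merge height: half the average pairwise distance
        for child in (a, b):
            nodes[child].edge.length = max(0.0, h - height[child])
            u.add_child(nodes[child])
        idx = n + step
        nodes[idx] = u
        height[idx] = h
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[n + len(Z) - 1]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Newick I/O and path-length utilities
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                real_value_format_specifier=".6g",
                suppress_rooting=True,
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_distance_matrix(tree: dendropy.Tree, labels) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix in the given label order."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    taxa = {t.label: t for t in tns}
    n = len(labels)
    out = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[str(li)], taxa[str(labels[j])])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=list(labels), values=out)
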