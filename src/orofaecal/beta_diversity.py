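"""Pairwise community dissimilarities and principal coordinate analysis.

The four indices used for the oral/faecal contrast: Bray-Curtis and binary
Jaccard on the count table alone, and unweighted / weighted UniFrac on the
table plus a rooted OTU phylogeny.  Distance matrices feed the ordination
(classical scaling / PCoA with Gower double-centering; negative eigenvalues
are reported, not corrected) and the distance-based tests in
:mod:`orofaecal.community_tests`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tables import CountTable, PhyloTree

__all__ = [
    "DistanceMatrix", "OrdinationResult",
    "bray_curtis", "jaccard_binary", "unweighted_unifrac", "weighted_unifrac",
    "distance_matrix", "pcoa", "METRICS",
]

METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample identifiers."""

    sample_ids: tuple
    data: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        d = np.asarray(self.data, dtype=float).copy()
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(d < -1e-12):
            raise ValueError("negative dissimilarities")
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "data", d)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        iu = np.tril_indices(self.n, k=-1)
        return self.data[iu]

    def subset(self, sample_ids) -> "DistanceMatrix":
        sample_ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in distance matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.data[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.data, index=list(self.sample_ids),
                          columns=list(self.sample_ids))
        df.index.name = "sample_id"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy())


# ---------------------------------------------------------------------------
# pairwise indices
# ---------------------------------------------------------------------------


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D abundance vectors")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both communities are empty")
    return x, y


def bray_curtis(x, y) -> float:
    """sum |x_i - y_i| / sum (x_i + y_i)."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard_binary(x, y) -> float:
    """1 - |shared taxa| / |union taxa| on presence/absence."""
    x, y = _check_pair(x, y)
    a, b = x > 0, y > 0
    union = np.count_nonzero(a | b)
    shared = np.count_nonzero(a & b)
    return float(1.0 - shared / union)


def jaccard_quantitative(x, y) -> float:
    """Abundance-weighted Jaccard, 2 BC / (1 + BC) with BC = Bray-Curtis."""
    bc = bray_curtis(x, y)
    return float(2.0 * bc / (1.0 + bc))


class _TreeIncidence:
    """Branch incidence structure of a rooted tree over a fixed OTU order.

    ``B`` is a (branches x OTUs) boolean matrix marking which OTUs descend
    from each branch, ``lengths`` the corresponding branch lengths, and
    ``tip_depths`` root-to-tip distances aligned to the OTU order.
    """

    def __init__(self, tree: PhyloTree, otu_ids):
        otu_ids = list(otu_ids)
        pos = {o: j for j, o in enumerate(otu_ids)}
        tip_names = set(tree.leaf_names())
        missing = [o for o in otu_ids if o not in tip_names]
        if missing:
            raise KeyError(f"OTUs absent from the tree: {missing[:10]}"
                           + ("..." if len(missing) > 10 else ""))
        rows, lengths = [], []
        below = {}
        for node in tree.tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(otu_ids), dtype=bool)
                if node.name in pos:
                    mask[pos[node.name]] = True
                below[id(node)] = mask
            else:
                mask = np.zeros(len(otu_ids), dtype=bool)
                for child in node.children:
                    mask |= below[id(child)]
                below[id(node)] = mask
            if node.parent is not None:  # every non-root node is a branch
                rows.append(mask)
                lengths.append(float(node.length))
        self.B = np.array(rows)
        self.lengths = np.asarray(lengths, dtype=float)
        depths = np.zeros(len(otu_ids))
        for tip in tree.tree.tips():
            if tip.name in pos:
                d, node = 0.0, tip
                while node.parent is not None:
                    d += float(node.length)
                    node = node.parent
                depths[pos[tip.name]] = d
        self.tip_depths = depths

    def branch_presence(self, x) -> np.ndarray:
        return self.B @ (np.asarray(x) > 0)

    def branch_mass(self, p) -> np.ndarray:
        return self.B @ np.asarray(p, dtype=float)


def _unweighted_from_incidence(inc: _TreeIncidence, x, y) -> float:
    in_x = inc.branch_presence(x)
    in_y = inc.branch_presence(y)
    either = in_x | in_y
    unique = in_x ^ in_y
    denom = inc.lengths[either].sum()
    if denom == 0:
        raise ValueError("no tree branch leads to any present OTU")
    return float(inc.lengths[unique].sum() / denom)


def _weighted_from_incidence(inc: _TreeIncidence, x, y,
                             normalized: bool) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    px = x / x.sum()
    py = y / y.sum()
    raw = float(inc.lengths @ np.abs(inc.branch_mass(px) - inc.branch_mass(py)))
    if not normalized:
        return raw
    denom = float(inc.tip_depths @ (px + py))
    if denom == 0:
        raise ValueError("zero total root-to-tip mass; check branch lengths")
    return raw / denom


def unweighted_unifrac(tree: PhyloTree, x, y, otu_ids=None) -> float:
    """Fraction of tree branch length unique to one community.

    (branch length leading exclusively to one community's OTUs) / (branch
    length leading to either community's OTUs).  Depends only on which OTUs
    are present.  `x` and `y` are abundance vectors aligned to `otu_ids`
    (default: the tree's own tip order).
    """
    x, y = _check_pair(x, y)
    if otu_ids is None:
        otu_ids = tree.leaf_names()
    inc = _TreeIncidence(tree, otu_ids)
    return _unweighted_from_incidence(inc, x, y)


def weighted_unifrac(tree: PhyloTree, x, y, otu_ids=None,
                     normalized: bool = True) -> float:
    """Abundance-weighted UniFrac between two communities.

    Raw form: sum over branches of l_b |p_b(x) - p_b(y)| with p_b a
    community's read fraction descending from branch b.  The normalised form
    (default) divides by sum over tips of d_j (p_j(x) + p_j(y)), d_j the
    root-to-tip distance, bounding the index to [0, 1].
    """
    x, y = _check_pair(x, y)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("weighted UniFrac needs both communities non-empty")
    if otu_ids is None:
        otu_ids = tree.leaf_names()
    inc = _TreeIncidence(tree, otu_ids)
    return _weighted_from_incidence(inc, x, y, normalized)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


def distance_matrix(table: CountTable, metric: str,
                    tree: PhyloTree = None,
                    normalized_weighted: bool = True) -> DistanceMatrix:
    """All pairwise dissimilarities for one metric.

    UniFrac metrics require `tree`; the incidence structure is built once
    and all pairs are evaluated by vectorised branch sums.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    n = table.n_samples
    out = np.zeros((n, n))
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        inc = _TreeIncidence(tree, table.otu_ids)
        if metric == "unweighted_unifrac":
            pres = (inc.B @ table.presence().T.astype(np.int64)) > 0  # (branches, samples)
            for i in range(n):
                for j in range(i + 1, n):
                    in_x, in_y = pres[:, i], pres[:, j]
                    denom = inc.lengths[in_x | in_y].sum()
                    out[i, j] = out[j, i] = inc.lengths[in_x ^ in_y].sum() / denom
        else:
            P = table.relative_abundance()          # (samples, otus)
            mass = P @ inc.B.T                      # (samples, branches)
            depth_mass = P @ inc.tip_depths         # (samples,)
            for i in range(n):
                for j in range(i + 1, n):
                    raw = inc.lengths @ np.abs(mass[i] - mass[j])
                    if normalized_weighted:
                        raw /= depth_mass[i] + depth_mass[j]
                    out[i, j] = out[j, i] = raw
    else:
        fn = bray_curtis if metric == "bray_curtis" else jaccard_binary
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = fn(table.counts[i], table.counts[j])
    return DistanceMatrix(table.sample_ids, out)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling ordination of a dissimilarity matrix.

    Eigenvalues are sorted descending and may be negative (reported, never
    corrected); coordinates span the axes with positive eigenvalues, and
    ``proportion_explained`` is relative to the sum of positive eigenvalues.
    """

    sample_ids: tuple
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    proportion_explained: np.ndarray

    def write(self, prefix) -> tuple:
        prefix = str(prefix)
        eig = pd.DataFrame({"eigenvalue": self.eigenvalues})
        eig.index.name = "axis"
        p1 = prefix + "_eigenvalues.tsv"
        with open(p1, "w", encoding="utf-8", newline="\n") as fh:
            eig.to_csv(fh, sep="\t")
        coords = pd.DataFrame(
            self.coordinates, index=list(self.sample_ids),
            columns=[f"PCo{k + 1}" for k in range(self.coordinates.shape[1])])
        coords.index.name = "sample_id"
        p2 = prefix + "_coordinates.tsv"
        with open(p2, "w", encoding="utf-8", newline="\n") as fh:
            coords.to_csv(fh, sep="\t")
        return p1, p2


def gower_eigensystem(d: DistanceMatrix):
    """Eigendecomposition of the Gower-centred matrix -1/2 J d^2 J.

    Returns (eigenvalues, eigenvectors) sorted by descending eigenvalue.
    """
    D2 = d.data ** 2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(d: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis (classical multidimensional scaling)."""
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    vals, vecs = gower_eigensystem(d)
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eps * scale
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    possum = vals[pos].sum()
    prop = vals[pos] / possum if possum > 0 else vals[pos]
    return OrdinationResult(sample_ids=d.sample_ids, eigenvalues=vals,
                            coordinates=coords, proportion_explained=prop)
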