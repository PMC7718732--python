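"""Population structure from CNV matrices: filtering, distances, PCoA,
cluster trees and a label-concordance permutation test.

Four filter schemes produce the sample-by-region matrices the ordination
runs on: ``all_cds`` (CDS-overlapping windows where at least one sample
deviates from CN=2), ``top1pct_cds`` (those intersected with the V_ST
top-outlier flags), ``any_gain`` (windows with at least one CN>2) and
``any_zero`` (windows with at least one CN=0).

Distances are Euclidean on integer copy-number vectors by default
(Manhattan available). PCoA is classical scaling (Gower): double-center
-1/2 D^2, eigendecompose, scale eigenvectors by sqrt(eigenvalue); axes with
negative eigenvalues are dropped and their magnitude reported. The cluster
tree is neighbor-joining by default (UPGMA available). Because the source
study judged population clustering by eye, a quantitative concordance
check is added: mean silhouette of the population labels on the distance
matrix with a label-permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .calling import CopyNumberMatrix
from .genome import Feature, Window, overlap
from .vst import VstTrack

logger = logging.getLogger(__name__)

FILTER_SCHEMES = ("all_cds", "top1pct_cds", "any_gain", "any_zero")


def build_matrix(
    cnm: CopyNumberMatrix,
    scheme: str,
    features: list[Feature] | None = None,
    vst_track: VstTrack | None = None,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Sample-by-region copy-number submatrix for one filter scheme.

    Columns are labeled ``scaffold:start-end``. ``per_gene`` aggregates the
    CDS-based schemes to one column per gene (mean CN over the gene's
    CDS-overlapping windows) instead of one per window. Raises if the
    scheme selects nothing.
    """
    if scheme not in FILTER_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {FILTER_SCHEMES}")
    cn = cnm.cn
    if scheme in ("all_cds", "top1pct_cds"):
        if features is None:
            raise ValueError(f"scheme {scheme!r} needs annotation features")
        cds = [f for f in features if f.type == "CDS"]
        hits, _ = overlap(cnm.windows, cds, ["CDS"]) if cds else ([[] for _ in cnm.windows], {})
        in_cds = np.array([bool(h) for h in hits])
        deviant = (cn != 2).any(axis=0)
        keep = in_cds & deviant
        if scheme == "top1pct_cds":
            if vst_track is None:
                raise ValueError("scheme 'top1pct_cds' needs a vst_track")
            flagged = {(w.scaffold, w.start) for w in vst_track.flagged_windows}
            top = np.array([(w.scaffold, w.start) in flagged for w in cnm.windows])
            keep &= top
    elif scheme == "any_gain":
        keep = (cn > 2).any(axis=0)
    else:  # any_zero
        keep = (cn == 0).any(axis=0)

    if not keep.any():
        raise ValueError(f"filter scheme {scheme!r} selected no regions")

    idx = np.flatnonzero(keep)
    cols = [f"{cnm.windows[i].scaffold}:{cnm.windows[i].start}-{cnm.windows[i].end}"
            for i in idx]
    mat = pd.DataFrame(cn[:, idx], index=cnm.samples, columns=cols)
    if per_gene and scheme in ("all_cds", "top1pct_cds"):
        mat = _aggregate_per_gene(mat, [cnm.windows[i] for i in idx],
                                  [h for h, k in zip(hits, keep) if k])
    return mat


def _aggregate_per_gene(mat: pd.DataFrame, windows: list[Window], hits) -> pd.DataFrame:
    gene_cols: dict[str, list[int]] = {}
    for j, hit in enumerate(hits):
        for f in hit:
            gene_cols.setdefault(f.gene_id, []).append(j)
    data = {g: mat.iloc[:, cols].mean(axis=1) for g, cols in sorted(gene_cols.items())}
    return pd.DataFrame(data, index=mat.index)


def distance(matrix: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix on CN vectors."""
    if metric not in ("euclidean", "cityblock", "manhattan"):
        raise ValueError(f"unsupported metric {metric!r}")
    if len(matrix) < 2:
        raise ValueError("need >= 2 samples")
    m = "cityblock" if metric == "manhattan" else metric
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric=m))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame       # samples x retained axes
    eigenvalues: np.ndarray         # retained (positive), non-increasing
    proportion_explained: np.ndarray
    negative_magnitude: float       # sum |negative eigenvalues| dropped

    def to_tsv(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t")


def pcoa(dist: pd.DataFrame, eps: float = 1e-9) -> Ordination:
    """Classical scaling of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and returns coordinates
    ``eigenvector * sqrt(eigenvalue)`` for axes whose eigenvalue exceeds
    ``eps`` times the largest. Negative-eigenvalue axes are dropped and
    their total magnitude reported (zero for Euclidean input).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = float(np.abs(eigval[eigval < 0]).sum())
    cutoff = eps * max(eigval.max(), 1.0)
    keep = eigval > cutoff
    vals = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(vals)
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    total = vals.sum()
    return Ordination(
        coordinates=frame,
        eigenvalues=vals,
        proportion_explained=vals / total if total > 0 else vals,
        negative_magnitude=neg,
    )


def cluster_tree(dist: pd.DataFrame, method: str = "nj") -> str:
    """Newick cluster tree from a distance matrix (NJ default, UPGMA option).

    NJ clamps negative branch lengths to zero (the standard adjustment);
    UPGMA is average-linkage agglomeration.
    """
    ids = [str(i) for i in dist.index]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs")
    if method == "nj":
        if len(ids) < 3:
            raise ValueError("neighbor joining needs >= 3 samples")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        tree = skbio_nj(DistanceMatrix(np.asarray(dist, dtype=float), ids))
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        return str(tree).strip()
    if method == "upgma":
        if len(ids) < 2:
            raise ValueError("UPGMA needs >= 2 samples")
        from skbio.tree import TreeNode

        linkage = hierarchy.linkage(squareform(np.asarray(dist, dtype=float)),
                                    method="average")
        tree = TreeNode.from_linkage_matrix(linkage, ids)
        return str(tree).strip()
    raise ValueError(f"unknown method {method!r}")


@dataclass
class Concordance:
    silhouette: float
    permutation_p: float
    n_permutations: int


def label_concordance(
    dist: pd.DataFrame,
    labels: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> Concordance:
    """How well population labels explain the distance matrix.

    Mean silhouette of the labels on the (precomputed) distances, with a
    permutation p-value: the fraction of label permutations whose silhouette
    is at least the observed one, with +1 smoothing so that
    p is in [1/(B+1), 1].
    """
    ids = list(dist.index)
    y = np.array([labels[s] for s in ids])
    pops, counts = np.unique(y, return_counts=True)
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, got {list(pops)}")
    if counts.min() < 2:
        raise ValueError("each population needs >= 2 samples")
    d = np.asarray(dist, dtype=float)
    observed = float(silhouette_score(d, y, metric="precomputed"))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if len(np.unique(perm)) < 2:  # cannot happen with fixed counts; safety
            continue
        if silhouette_score(d, perm, metric="precomputed") >= observed:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return Concordance(silhouette=observed, permutation_p=float(p),
                       n_permutations=n_permutations)
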