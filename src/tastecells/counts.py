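"""Count-matrix I/O, normalization, and quality control.

Implements the standard bulk-style workflow applied to single-cell aRNA
libraries: median-of-ratios size factors, detected-gene thresholding at 1-50
normalized counts, a log2(x+1) variance-stabilizing surrogate, PCA on the 500
highest-variance genes, Euclidean-distance hierarchical clustering, and the
100-quantile gene-body coverage statistic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "CountFormatError",
    "NormalizationError",
    "read_counts",
    "write_counts",
    "validate_counts",
    "drop_all_zero_genes",
    "size_factors",
    "normalize",
    "detected_genes",
    "vst",
    "PCAResult",
    "pca_top_variance",
    "ClusterResult",
    "distance_cluster",
    "gene_body_coverage",
]

DEFAULT_THRESHOLDS = (1, 2, 5, 10, 20, 50)


class CountFormatError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check identifiers are unique and entries are non-negative integers."""
    dup_g = counts.index[counts.index.duplicated()].unique()
    if len(dup_g):
        raise CountFormatError(f"duplicated gene_id(s): {list(map(str, dup_g[:5]))}")
    dup_c = counts.columns[counts.columns.duplicated()].unique()
    if len(dup_c):
        raise CountFormatError(f"duplicated cell_id(s): {list(map(str, dup_c[:5]))}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)):
        bad = counts.index[~np.all(np.isfinite(counts.to_numpy(dtype=float)), axis=1)]
        raise CountFormatError(f"non-numeric or non-finite counts in gene(s): {list(bad[:5])}")
    neg = np.any(arr < 0, axis=1)
    if neg.any():
        raise CountFormatError(f"negative counts in gene(s): {list(counts.index[neg][:5])}")
    frac = np.any(arr != np.floor(arr), axis=1)
    if frac.any():
        raise CountFormatError(f"non-integer counts in gene(s): {list(counts.index[frac][:5])}")
    return counts.astype(np.int64)


def read_counts(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a genes x cells count matrix.

    ``tsv``: first column gene_id, remaining columns one per cell.
    ``mtx``: MatrixMarket file with ``genes.tsv`` and ``cells.tsv`` sidecars
    (one identifier per line) in the same directory.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0]
        df = pd.DataFrame(
            np.asarray(sp.coo_matrix(mat).todense()),
            index=pd.Index(genes, name="gene_id"),
            columns=list(cells),
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(counts.to_numpy()), field="integer")
        pd.Series(counts.index).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.columns).to_csv(path.parent / "cells.tsv", sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def drop_all_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every cell (unexpressed genes)."""
    return counts.loc[counts.sum(axis=1) > 0]


def size_factors(counts: pd.DataFrame, positive_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across cells, computed over
    genes with nonzero counts in every cell; each cell's factor is the median
    over those genes of count/reference, rescaled so the factors have
    geometric mean 1.

    Sparse matrices may have no all-nonzero gene; ``positive_reference=True``
    opts into a pseudo-reference using the geometric mean over nonzero
    entries only (logged via a warning so the deviation is visible).
    """
    arr = counts.to_numpy(dtype=float)
    if positive_reference:
        warnings.warn(
            "size_factors: using positive-counts pseudo-reference "
            "(geometric mean over nonzero entries only)",
            stacklevel=2,
        )
        expressed = arr.sum(axis=1) > 0
        sub = arr[expressed]
        logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        all_nonzero = np.all(arr > 0, axis=1)
        if not all_nonzero.any():
            raise NormalizationError(
                "no gene has nonzero counts in every cell; re-run with "
                "positive_reference=True to use the positive-counts pseudo-reference"
            )
        sub = arr[all_nonzero]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise NormalizationError("size factors are not all positive and finite")
    factors = factors / np.exp(np.mean(np.log(factors)))  # fix scale: geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each cell's counts by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise NormalizationError("size factors missing for some cells")
    return counts / factors


def detected_genes(
    normalized: pd.DataFrame, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Number of genes at or above each normalized-count threshold, per cell.

    Rows are thresholds (1-50 by default), columns cells; counts are
    non-increasing down the threshold grid.
    """
    rows = {t: (normalized >= t).sum(axis=0) for t in thresholds}
    out = pd.DataFrame(rows).T
    out.index.name = "threshold"
    return out


def vst(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) variance-stabilizing surrogate (monotone, 0 -> 0).

    Used only for PCA, distances and visualisation, where the exact
    dispersion-fit transform and this surrogate behave alike.
    """
    return np.log2(normalized + 1)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # cells x components
    variance_ratio: np.ndarray
    top_genes: pd.Index
    degenerate: bool


def pca_top_variance(transformed: pd.DataFrame, n_top: int = 500) -> PCAResult:
    """PCA of cells over the ``n_top`` highest-row-variance genes.

    Genes are ranked by row variance; the cell x gene submatrix is centered
    per gene and decomposed. ``degenerate`` is set when there is no variance
    to decompose (e.g. identical cells).
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs at least 2 cells")
    if n_top > transformed.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds the {transformed.shape[0]} available genes")
    rv = transformed.var(axis=1, ddof=1)
    top = rv.sort_values(ascending=False).index[:n_top]
    x = transformed.loc[top].to_numpy().T  # cells x genes
    total_var = float(np.var(x, axis=0, ddof=1).sum())
    n_comp = min(x.shape[0] - 1, x.shape[1])
    if total_var <= 1e-12:
        scores = pd.DataFrame(
            np.zeros((x.shape[0], n_comp)),
            index=transformed.columns,
            columns=[f"PC{i+1}" for i in range(n_comp)],
        )
        return PCAResult(scores, np.full(n_comp, np.nan), top, True)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    return PCAResult(
        pd.DataFrame(
            scores, index=transformed.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
        ),
        pca.explained_variance_ratio_,
        top,
        False,
    )


@dataclass(frozen=True)
class ClusterResult:
    distances: pd.DataFrame  # cells x cells, Euclidean
    linkage_matrix: np.ndarray
    newick: str

    def cut(self, n_clusters: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.distances.index, name="cluster")


def distance_cluster(transformed: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Euclidean distances between cells (all genes) + agglomerative tree.

    Complete linkage by default; the dendrogram is also rendered as a newick
    string with cell identifiers as tips.
    """
    if transformed.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    x = transformed.to_numpy().T
    cond = pdist(x, metric="euclidean")
    dist = pd.DataFrame(
        squareform(cond), index=transformed.columns, columns=transformed.columns
    )
    z = linkage(cond, method=method)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, list(map(str, transformed.columns)))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return ClusterResult(dist, z, buf.getvalue().strip())


def gene_body_coverage(read_fractions: np.ndarray) -> np.ndarray:
    """100-bin gene-body coverage profile, percent of the maximum bin.

    ``read_fractions`` are per-read relative positions in [0, 1] along the
    5'->3' gene body (callers restrict them to the 1000 most highly expressed
    genes). Bins are half-open [i/100, (i+1)/100) with the last bin closed;
    the profile is rescaled so its maximum bin equals 100.
    """
    frac = np.asarray(read_fractions, dtype=float)
    if frac.size == 0:
        raise ValueError("no read positions supplied")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("read fractions must lie in [0, 1]")
    hist, _ = np.histogram(frac, bins=100, range=(0.0, 1.0))
    return 100.0 * hist / hist.max()
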