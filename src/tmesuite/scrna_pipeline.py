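"""Single-cell stage: QC, normalization, HVG selection, PCA, graph
clustering, marker detection, and marker-set cluster annotation.

Conventions follow the standard droplet-data toolchain: counts are
library-size normalized to 10^4 and log1p-transformed; highly variable genes
are ranked by variance standardized against a binned mean-variance trend;
clustering is Leiden modularity optimization on a shared-nearest-neighbor
graph with Jaccard edge weights; markers are rank-sum tested per cluster
against all other cells with Benjamini-Hochberg correction, and clusters are
annotated by hypergeometric enrichment of their positive markers in
reference cell-type marker sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io_core import SignatureCollection, ValidationError
from .synthetic_data import SCCountMatrix

logger = logging.getLogger("tmesuite")

__all__ = [
    "SCCountMatrix",
    "SCExpression",
    "CellClustering",
    "qc_filter",
    "normalize",
    "select_hvg",
    "pca_embed",
    "cluster_cells",
    "find_markers",
    "annotate_clusters",
    "read_mtx_dir",
    "write_mtx_dir",
]


@dataclass
class SCExpression:
    """Log-normalized genes x cells expression (sparse)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("expression shape mismatch")


@dataclass
class CellClustering:
    """Cell -> cluster assignment with optional cell-type labels per cluster."""

    cell_ids: list[str]
    clusters: np.ndarray                 # consecutive ints from 0
    type_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.clusters = np.asarray(self.clusters, dtype=int)
        if len(self.cell_ids) != len(self.clusters):
            raise ValidationError("clustering length mismatch")
        uniq = np.unique(self.clusters)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValidationError("clusters must be consecutive integers from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.clusters.max()) + 1


def qc_filter(
    counts: SCCountMatrix,
    min_cells: int = 5,
    min_genes: int = 100,
    max_mito: float = 0.05,
) -> SCCountMatrix:
    """Standard droplet QC in a fixed order.

    (1) drop cells whose mitochondrial count fraction exceeds ``max_mito``,
    (2) drop cells expressing fewer than ``min_genes`` genes,
    (3) drop genes expressed in fewer than ``min_cells`` of the remaining cells.
    """
    c = counts.counts.tocsc()
    mito = counts.mito_mask
    totals = np.asarray(c.sum(axis=0)).ravel()
    mito_counts = np.asarray(c[mito].sum(axis=0)).ravel() if mito.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep_cells = frac <= max_mito
    genes_per_cell = np.asarray((c > 0).sum(axis=0)).ravel()
    keep_cells &= genes_per_cell >= min_genes
    if not keep_cells.any():
        raise ValidationError("QC removed all cells")
    c = c[:, keep_cells]
    cells_per_gene = np.asarray((c > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells
    logger.info("QC: kept %d/%d cells, %d/%d genes",
                int(keep_cells.sum()), counts.n_cells,
                int(keep_genes.sum()), counts.n_genes)
    return SCCountMatrix(
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        [s for s, k in zip(counts.cell_ids, keep_cells) if k],
        sp.csr_matrix(c[keep_genes]),
    )


def normalize(counts: SCCountMatrix, scale: float = 1e4) -> SCExpression:
    """ln(1 + scale * count / cell_total) per entry."""
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise ValidationError("zero-total cell: run qc_filter first")
    x = counts.counts.tocsc().astype(float)
    x = x.multiply(scale / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return SCExpression(list(counts.gene_ids), list(counts.cell_ids), x)


def _gene_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(norm: SCExpression, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-n genes by variance standardized against a binned mean trend.

    Genes are placed into ``n_bins`` equal-occupancy bins of mean expression;
    the trend value of a bin is its median variance, and each gene's variance
    is divided by its bin's trend before ranking.  Zero-variance genes are
    never selected while variable genes remain.
    """
    mean, var = _gene_mean_var(norm.values)
    positive = var > 0
    if positive.sum() <= n:
        if positive.sum() < n:
            logger.warning("only %d genes with positive variance (< %d requested)",
                           int(positive.sum()), n)
        return [g for g, p in zip(norm.gene_ids, positive) if p]
    idx = np.where(positive)[0]
    order = np.argsort(mean[idx], kind="stable")
    bins = np.array_split(order, n_bins)
    standardized = np.zeros(len(idx))
    for b in bins:
        if len(b) == 0:
            continue
        trend = np.median(var[idx][b])
        standardized[b] = var[idx][b] / max(trend, np.finfo(float).tiny)
    top_local = np.argsort(-standardized, kind="stable")[:n]
    chosen = set(idx[top_local])
    return [g for i, g in enumerate(norm.gene_ids) if i in chosen]


def pca_embed(norm: SCExpression, hvg: list[str], n_pcs: int = 20) -> np.ndarray:
    """Cells x n_pcs principal-component embedding on scaled HVG expression.

    HVG rows are centered and unit-scaled across cells; the embedding is the
    projection onto the top right-singular directions, with each component's
    sign fixed so its largest-magnitude gene loading is positive (making
    repeat runs bit-identical).
    """
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in hvg if g not in pos]
    if missing:
        raise ValidationError(f"HVGs missing from matrix: {missing[:5]}")
    x = np.asarray(norm.values[[pos[g] for g in hvg]].todense(), dtype=float)
    if n_pcs > min(x.shape[0], x.shape[1]):
        raise ValidationError(f"n_pcs={n_pcs} exceeds data dimensions {x.shape}")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = ((x - mean) / sd).T  # cells x genes
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    flip = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return u * s * flip


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> igraph.Graph:
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, knn_idx = nn.kneighbors(embedding)
    knn_idx = knn_idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, knn_idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()  # |kNN(i) & kNN(j)|
    union_edges = ((adj + adj.T) > 0).tocoo()
    mask = union_edges.row < union_edges.col
    pairs = set(zip(union_edges.row[mask].tolist(), union_edges.col[mask].tolist()))
    edges, weights = [], []
    shared_lookup = {}
    smask = shared.row < shared.col
    for i, j, v in zip(shared.row[smask], shared.col[smask], shared.data[smask]):
        shared_lookup[(int(i), int(j))] = float(v)
    for i, j in sorted(pairs):
        s = shared_lookup.get((i, j), 0.0)
        jac = s / (2 * k_neighbors - s)
        if jac > 0:
            edges.append((i, j))
            weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(
    embedding: np.ndarray,
    cell_ids: list[str],
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> CellClustering:
    """Leiden modularity clustering on a shared-nearest-neighbor graph.

    Edges connect cells in each other's k-NN union, weighted by Jaccard
    overlap of their neighbor sets.  Clusters are relabeled by decreasing
    size.
    """
    if embedding.shape[0] < k_neighbors + 1:
        raise ValidationError("fewer cells than k_neighbors + 1")
    g = _snn_graph(embedding, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    counts = np.bincount(raw)
    order = np.argsort(-counts, kind="stable")
    rank = {int(o): r for r, o in enumerate(order) if counts[o] > 0}
    return CellClustering(list(cell_ids), np.array([rank[int(r)] for r in raw]))


def find_markers(
    norm: SCExpression,
    clustering: CellClustering,
    max_fdr: float = 0.05,
    min_abs_lfc: float = 0.25,
) -> pd.DataFrame:
    """Per-cluster marker genes versus all other cells.

    Two-sided Wilcoxon rank-sum test (normal approximation with tie
    correction) per gene; log2 fold change of (mean expm1 + 1); BH correction
    within each cluster; rows filtered to fdr < ``max_fdr`` and
    |log2FC| > ``min_abs_lfc``.  Singleton clusters are skipped.
    """
    if clustering.n_clusters < 2:
        raise ValidationError("marker detection needs >= 2 clusters")
    dense = np.asarray(norm.values.todense(), dtype=float)  # genes x cells
    expm1 = np.expm1(dense)
    rows = []
    for cl in range(clustering.n_clusters):
        mask = clustering.clusters == cl
        if mask.sum() < 3:
            logger.warning("cluster %d has < 3 cells; skipped in marker detection", cl)
            continue
        x_in = dense[:, mask]
        x_out = dense[:, ~mask]
        stat_res = stats.mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided",
                                      method="asymptotic")
        pvals = stat_res.pvalue
        mean_in = expm1[:, mask].mean(axis=1)
        mean_out = expm1[:, ~mask].mean(axis=1)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        fdr = multipletests(pvals, method="fdr_bh")[1]
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        keep = (fdr < max_fdr) & (np.abs(lfc) > min_abs_lfc)
        for gi in np.where(keep)[0]:
            rows.append((cl, norm.gene_ids[gi], float(lfc[gi]), float(pvals[gi]),
                         float(fdr[gi]), float(pct_in[gi]), float(pct_out[gi])))
    return pd.DataFrame(
        rows,
        columns=["cluster", "gene", "log2_fold_change", "p_value", "fdr",
                 "pct_in", "pct_out"],
    )


def annotate_clusters(
    markers: pd.DataFrame,
    reference: SignatureCollection,
    universe: list[str],
) -> dict[int, str]:
    """Cell-type label per cluster by hypergeometric marker enrichment.

    The label is the reference set with the smallest enrichment p-value of
    the cluster's retained positive markers against ``universe`` (all tested
    genes).  A cluster with no positive markers gets "unknown"; a p-value tie
    between reference sets leaves the cluster "unlabeled".
    """
    if len(reference) == 0:
        raise ValidationError("empty reference marker collection")
    uni = set(universe)
    n_universe = len(uni)
    labels: dict[int, str] = {}
    clusters = sorted(markers["cluster"].unique()) if len(markers) else []
    for cl in clusters:
        pos = set(markers.loc[(markers["cluster"] == cl)
                              & (markers["log2_fold_change"] > 0), "gene"])
        if not pos:
            labels[int(cl)] = "unknown"
            continue
        best_p, best_name, tie = np.inf, "unknown", False
        for name, genes in reference.entries.items():
            ref = set(genes) & uni
            overlap = len(pos & ref)
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(ref), len(pos)))
            if p < best_p - 1e-15:
                best_p, best_name, tie = p, name, False
            elif abs(p - best_p) <= 1e-15:
                tie = True
        labels[int(cl)] = "unlabeled" if tie else best_name
    return labels


# ---------------------------------------------------------------------------
# MatrixMarket directory IO (matrix.mtx + genes.tsv + barcodes.tsv)
# ---------------------------------------------------------------------------

def read_mtx_dir(path) -> SCCountMatrix:
    import os

    from scipy.io import mmread

    mat = sp.csr_matrix(mmread(os.path.join(path, "matrix.mtx")))
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0].tolist()
    return SCCountMatrix([str(g) for g in genes], [str(c) for c in cells], mat)


def write_mtx_dir(counts: SCCountMatrix, path) -> None:
    import os

    from scipy.io import mmwrite

    os.makedirs(path, exist_ok=True)
    mmwrite(os.path.join(path, "matrix.mtx"), counts.counts.tocoo())
    pd.Series(counts.gene_ids).to_csv(os.path.join(path, "genes.tsv"),
                                      sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(os.path.join(path, "barcodes.tsv"),
                                      sep="\t", header=False, index=False)
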