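"""Expression normalisation, nodule aggregation, phenotype binarisation and
coexpression networks.

The chain mirrors the standard spatial workflow: counts are filtered
(genes with <10 or >1e6 raw counts on any slide are dropped, barcodes
excluded), scaled to 1e4 per spot and log1p-transformed; highly variable
genes are picked per slide and intersected; expression is aggregated per
nodule (mean or 95th percentile), rescaled per gene by
``(x - q25) / (q99 - q25)`` over all nodules of all slides, and thresholded at
0.5 to call phenotypes from core-marker averages (tumour-intrinsic signatures
use the mean aggregate, microenvironment signatures the q95 aggregate).
A sparse coexpression graph comes from an L1-penalised Gaussian graphical
model with a post-hoc Pearson-correlation edge filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr
from sklearn.covariance import GraphicalLasso

from .data import CountMatrix, NoduleMap
from .errors import ConfigurationError

__all__ = [
    "PhenotypeSignature",
    "default_signatures",
    "normalize_counts",
    "select_hvgs",
    "aggregate_nodules",
    "quantile_rescale",
    "binarize_phenotype",
    "coexpression_network",
    "cluster_heatmap_data",
]


@dataclass
class PhenotypeSignature:
    """A named phenotype with its core marker genes.

    ``kind`` decides the nodule aggregate used for binarisation:
    tumour-intrinsic phenotypes use the mean aggregate, TME (tumour
    microenvironment) phenotypes the quantile (q95) aggregate.
    """

    name: str
    markers: list[str]
    kind: str = "tumour"  # "tumour" | "tme"

    def __post_init__(self) -> None:
        if not self.markers:
            raise ConfigurationError(f"signature {self.name}: empty marker list")
        if self.kind not in ("tumour", "tme"):
            raise ConfigurationError(f"signature {self.name}: unknown kind {self.kind}")


# Partial default marker sets for the liver tumour phenotypes scored by the
# pipeline; users are expected to extend these via signature CSV files
# (columns: phenotype, class, gene).
_DEFAULTS = [
    ("cholangiocarcinoma", "tumour", ["Krt19", "Cldn7", "Epcam", "Krt7", "Gp2", "Slc15a2"]),
    ("portal_like", "tumour", ["Sds", "Sdsl"]),
    ("central_like", "tumour", ["Cyp2e1", "Oat", "Gstm3", "Gulo"]),
    ("midlobular_like", "tumour", ["Hamp", "Hamp2", "Upp2"]),
    ("fibroblast", "tme", ["Col1a1", "Col3a1", "Col1a2", "Gas6", "Thbs1"]),
    ("erythroblast", "tme", ["Hbb-bt", "Slc4a1"]),
    ("platelet", "tme", ["Pf4", "Itga2"]),
    ("mast_cell", "tme", ["Cpa3", "Cma1"]),
    ("b_cell", "tme", ["Jchain", "Igkc"]),
    ("neutrophil", "tme", ["Elane", "Mpo", "Ngp", "Camp"]),
    ("kupffer", "tme", ["Marco", "Clec4f", "Csf1r", "C1qa"]),
]


def default_signatures() -> list[PhenotypeSignature]:
    return [PhenotypeSignature(n, list(m), k) for n, k, m in _DEFAULTS]


def load_signatures(path) -> list[PhenotypeSignature]:
    """Read signatures from CSV with columns phenotype, class, gene."""
    df = pd.read_csv(path)
    sigs = []
    for (name, kind), sub in df.groupby(["phenotype", "class"], sort=False):
        sigs.append(PhenotypeSignature(name, list(sub["gene"]), kind))
    return sigs


def normalize_counts(
    gene_counts: CountMatrix,
    slides: np.ndarray | None = None,
    target_sum: float = 1e4,
    min_count: int = 10,
    max_count: float = 1e6,
) -> pd.DataFrame:
    """Filter genes, scale each spot to ``target_sum`` and log1p-transform.

    Genes whose raw total on any individual slide is below ``min_count`` or
    above ``max_count`` are removed (``slides`` labels spots by slide; one
    slide if omitted).  Spots with zero total are dropped with a warning.
    Returns a dense spots x genes DataFrame (columns = gene ids, index =
    positional spot indices into the input).
    """
    dense = gene_counts.dense().astype(float)
    genes = gene_counts.feature_ids
    slides = np.zeros(dense.shape[0], dtype=int) if slides is None else np.asarray(slides)
    keep_gene = np.ones(dense.shape[1], dtype=bool)
    for s in np.unique(slides):
        totals = dense[slides == s].sum(axis=0)
        keep_gene &= (totals >= min_count) & (totals <= max_count)
    dense = dense[:, keep_gene]
    genes = genes[keep_gene]
    totals = dense.sum(axis=1)
    ok = totals > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-total spots")
    scaled = dense[ok] * (target_sum / totals[ok])[:, None]
    return pd.DataFrame(np.log1p(scaled), index=np.flatnonzero(ok), columns=genes)


def select_hvgs(
    normalized_by_slide: dict | list, n_per_slide: int = 15_000
) -> list[str]:
    """Highly variable genes per slide (Seurat-style dispersion within mean
    bins, via scanpy), intersected across slides.

    ``normalized_by_slide`` maps slide id to a normalised DataFrame from
    :func:`normalize_counts` (or is a list of them).  If a slide has fewer
    genes than ``n_per_slide``, all its genes qualify.
    """
    import anndata as ad
    import scanpy as sc

    frames = (normalized_by_slide.values()
              if isinstance(normalized_by_slide, dict) else normalized_by_slide)
    selected: set[str] | None = None
    for df in frames:
        if df.shape[1] <= n_per_slide:
            genes = set(df.columns)
        else:
            adata = ad.AnnData(df.to_numpy())
            adata.var_names = df.columns
            sc.pp.highly_variable_genes(adata, flavor="seurat",
                                        n_top_genes=n_per_slide)
            genes = set(adata.var_names[adata.var["highly_variable"]])
        selected = genes if selected is None else (selected & genes)
    if selected is None:
        raise ConfigurationError("no slides provided")
    return sorted(selected)


def aggregate_nodules(
    normalized: pd.DataFrame,
    nodule_map: NoduleMap,
    spot_ids: np.ndarray,
    method: str = "mean",
) -> pd.DataFrame:
    """Aggregate normalised expression per nodule: 'mean' or 'q95'.

    ``spot_ids`` labels the rows of ``normalized`` so spots can be matched to
    nodules; nodules without spots are reported missing with a warning.
    Returns a nodules x genes DataFrame.
    """
    if method not in ("mean", "q95"):
        raise ConfigurationError(f"unknown aggregation method {method!r}")
    spot_ids = np.asarray(spot_ids)[normalized.index]
    assign = dict(zip(nodule_map.df["spot_id"], nodule_map.df["region_id"]))
    regions = nodule_map.region_ids("nodule")
    rows = {}
    for r in regions:
        mask = np.array([assign.get(s) == r for s in spot_ids])
        if not mask.any():
            warnings.warn(f"nodule {r} has no spots after filtering")
            rows[r] = np.full(normalized.shape[1], np.nan)
            continue
        block = normalized.to_numpy()[mask]
        rows[r] = block.mean(axis=0) if method == "mean" else np.quantile(block, 0.95, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=normalized.columns)


def quantile_rescale(aggregates: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene rescale (x - q25) / (q99 - q25) over all nodules (not clipped).

    Quantiles use linear interpolation.  Genes with q99 == q25 are flagged
    degenerate and their rescaled values are missing.
    Returns (rescaled DataFrame, boolean degenerate flags per gene).
    """
    x = aggregates.to_numpy(dtype=float)
    q25 = np.nanquantile(x, 0.25, axis=0)
    q99 = np.nanquantile(x, 0.99, axis=0)
    span = q99 - q25
    degenerate = span == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rescaled = (x - q25[None, :]) / span[None, :]
    rescaled[:, degenerate] = np.nan
    return (
        pd.DataFrame(rescaled, index=aggregates.index, columns=aggregates.columns),
        pd.Series(degenerate, index=aggregates.columns, name="degenerate"),
    )


def binarize_phenotype(
    rescaled: pd.DataFrame,
    signatures: list[PhenotypeSignature],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Binary nodule x phenotype calls.

    A nodule is positive for a phenotype when the average of its core
    markers' rescaled values exceeds ``threshold`` strictly.  The caller
    passes the rescaled mean-based aggregates for tumour-intrinsic signatures
    and the rescaled q95-based aggregates for TME signatures.
    """
    out = {}
    for sig in signatures:
        present = [g for g in sig.markers if g in rescaled.columns]
        if not present:
            raise ConfigurationError(
                f"signature {sig.name}: none of its markers are in the data")
        out[sig.name] = (rescaled[present].mean(axis=1) > threshold).astype(int)
    return pd.DataFrame(out, index=rescaled.index)


def coexpression_network(
    normalized: pd.DataFrame,
    penalty: float = 0.3,
    min_corr: float = 0.25,
    max_iter: int = 200,
) -> nx.Graph:
    """Sparse gene coexpression graph.

    Estimates an L1-penalised inverse covariance (graphical lasso) on the
    gene-gene correlation matrix at the given penalty, keeps edges with a
    nonzero precision entry and an absolute pairwise Pearson correlation of at
    least ``min_corr``, then drops isolated genes.
    """
    genes = list(normalized.columns)
    X = normalized.to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    model = GraphicalLasso(alpha=penalty, covariance="precomputed",
                           max_iter=max_iter, assume_centered=True)
    try:
        model.fit(corr)
    except Exception as exc:
        raise ConfigurationError(
            f"graphical lasso failed to converge at penalty {penalty}: {exc}"
        ) from exc
    precision = model.precision_
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(precision[i, j]) > 1e-8 and abs(corr[i, j]) >= min_corr:
                graph.add_edge(genes[i], genes[j],
                               weight=float(corr[i, j]),
                               precision=float(precision[i, j]))
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def cluster_heatmap_data(
    aggregates: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    presence_power: int = 10,
) -> dict:
    """Heatmap-ready ordering of nodules x genes with presence annotation.

    Rows (nodules) and columns (genes) are ordered by hierarchical clustering
    (average linkage) on 1 - Spearman correlation; the plasmid presence
    annotation is the probability raised to ``presence_power`` (sharpening
    calls toward 0/1 for display).
    """
    x = aggregates.to_numpy(dtype=float)

    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3:
            return np.arange(mat.shape[0])
        rho = spearmanr(mat, axis=1).statistic
        rho = np.atleast_2d(rho)
        dist = 1.0 - np.nan_to_num(rho, nan=0.0)
        iu = np.triu_indices(mat.shape[0], k=1)
        Z = linkage(dist[iu], method="average")
        return np.asarray(leaves_list(Z))

    row_order = order(x)
    col_order = order(x.T)
    result = {
        "matrix": aggregates.iloc[row_order, col_order],
        "row_order": row_order,
        "col_order": col_order,
        "spearman_rows": np.atleast_2d(spearmanr(x, axis=1).statistic),
    }
    if presence is not None:
        ann = presence.reindex(aggregates.index) ** presence_power
        result["presence_annotation"] = ann.iloc[row_order]
    return result
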