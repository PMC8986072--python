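"""Sample-structure analyses: PCA on a DEG-restricted gene set and
hierarchical clustering with a quantitative family-structure metric.

Clustering uses correlation distance (1 - Pearson over the gene set) with
average linkage — the common microarray-heatmap convention; both are
configurable.  ``family_adjacency`` turns the qualitative "participants
cluster by family" observation into a number: the fraction of trio samples
whose cophenetic nearest neighbour belongs to the same family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("triomics")


def pca_embed(expr: ExpressionMatrix, genes, meta: pd.DataFrame | None = None,
              n_components: int | None = None
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a standardized gene subset.

    Genes are standardized to zero mean / unit variance across samples
    (zero-variance genes dropped with a warning); returns the coordinate
    table (samples x components) and the variance-explained fractions.
    """
    genes = list(genes)
    if len(expr.sample_ids) < 2:
        raise ValidationError("PCA requires >= 2 samples")
    sub = expr.subset_genes(genes)
    if sub.shape[0] < 2:
        raise ValidationError("PCA requires >= 2 genes present in the matrix")
    X = sub.values.to_numpy()
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("PCA: dropped %d zero-variance gene(s)",
                       int((~keep).sum()))
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X.T)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    table = pd.DataFrame(coords, index=pd.Index(sub.sample_ids,
                                                name="sample_id"), columns=cols)
    return table, pca.explained_variance_ratio_


@dataclass
class ClusteringResult:
    sample_ids: list
    linkage: np.ndarray               # scipy merge record
    cophenetic: pd.DataFrame          # square, symmetric, zero diagonal

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if not (np.diff(heights) >= -1e-12).all():
            raise ValidationError("non-monotone merge heights")


def hier_cluster(expr: ExpressionMatrix, genes, meta: pd.DataFrame | None = None,
                 linkage: str = "average",
                 distance: str = "correlation") -> ClusteringResult:
    """Agglomerative clustering of samples on the given gene set."""
    genes = list(genes)
    sub = expr.subset_genes(genes)
    if sub.shape[0] < 2:
        raise ValidationError("clustering requires >= 2 genes")
    if sub.shape[1] < 3:
        raise ValidationError("clustering requires >= 3 samples")
    X = sub.values.T.to_numpy()     # samples x genes
    if distance == "correlation":
        const = X.std(axis=1) == 0
        if const.any():
            bad = np.asarray(sub.sample_ids)[const][0]
            raise ValidationError(
                f"sample {bad!r} has a constant profile; correlation distance "
                "is undefined")
    d = pdist(X, metric=distance)
    Z = hierarchy.linkage(d, method=linkage)
    coph = squareform(hierarchy.cophenet(Z))
    coph_df = pd.DataFrame(coph, index=sub.sample_ids, columns=sub.sample_ids)
    return ClusteringResult(list(sub.sample_ids), Z, coph_df)


def family_adjacency(cluster: ClusteringResult,
                     meta: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Fraction of trio samples whose cophenetic nearest neighbour is kin.

    For every non-HC sample the cophenetic nearest neighbour (smallest
    cophenetic distance; ties broken by sample order) is found among all
    clustered samples; the indicator is 1 when it shares the family_id.
    """
    meta = meta.set_index("sample_id").loc[cluster.sample_ids]
    coph = cluster.cophenetic.to_numpy().copy()
    np.fill_diagonal(coph, np.inf)
    fam = meta["family_id"].to_numpy()
    grp = meta["group"].to_numpy()
    rows = []
    for i, sid in enumerate(cluster.sample_ids):
        if grp[i] == "HC":
            continue
        j = int(np.argmin(coph[i]))
        rows.append({"sample_id": sid, "family_id": fam[i],
                     "nearest": cluster.sample_ids[j],
                     "same_family": bool(fam[j] == fam[i])})
    detail = pd.DataFrame(rows)
    frac = float(detail["same_family"].mean()) if len(detail) else float("nan")
    logger.info("family adjacency: %.3f over %d trio samples", frac, len(detail))
    return frac, detail
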