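"""Trajectory mapping: clustering, PCA, and cross-platform projection.

Differentiation time courses are compared by average-linkage hierarchical
clustering of log2 expression profiles (correlation distance by default) and
by PCA with samples as observations; external datasets (microarray
intensities, spatial transcriptome sections) are harmonized by quantile
matching to the sequencing-data distribution and/or per-gene mean centering,
then projected into the fitted PCA coordinate frame using the training
means and loadings restricted to shared genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .counts import ExpressionMatrix
from .errors import InputError

logger = logging.getLogger("germnet.trajectories")


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over samples.

    ``merges`` is a scipy-style linkage matrix (pair indices, merge height,
    cluster size); merge heights are nondecreasing for average linkage on a
    metric distance.
    """

    merges: np.ndarray
    leaf_ids: list[str]
    metric: str = "correlation"

    def to_newick(self) -> str:
        root = to_tree(self.merges)

        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(root, root.dist) + ";"


def correlation_distances(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed 1 − Pearson distances between sample columns."""
    X = profiles.values.T
    if np.any(X.std(axis=1) == 0):
        bad = [profiles.columns[i] for i in np.flatnonzero(X.std(axis=1) == 0)]
        raise InputError(
            f"constant expression vector under correlation distance: {bad}")
    return pdist(X, metric="correlation")


def cluster_samples(expr: ExpressionMatrix, genes: list[str] | None = None,
                    metric: str = "correlation") -> ClusterTree:
    """Average-linkage tree over samples on log2 expression of ``genes``."""
    data = expr.log2_expr if genes is None else expr.log2_expr.loc[genes]
    if data.shape[1] < 2:
        raise InputError("clustering needs >= 2 samples")
    if metric == "correlation":
        dists = correlation_distances(data)
    elif metric == "euclidean":
        dists = pdist(data.values.T, metric="euclidean")
    else:
        raise InputError(f"unsupported metric {metric!r}")
    Z = linkage(dists, method="average")
    return ClusterTree(Z, list(data.columns), metric)


def linkage_from_distances(dist: np.ndarray, ids: list[str]) -> ClusterTree:
    """Average-linkage tree from a square or condensed distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    return ClusterTree(linkage(d, method="average"), list(ids), "precomputed")


# ---------------------------------------------------------------------------
# PCA and projection


@dataclass
class PCAModel:
    """Gene-centered PCA with samples as observations.

    ``loadings`` (genes x components) are orthonormal right singular
    vectors; ``scores`` are the training-sample coordinates; variance
    fractions come from the squared singular values.
    """

    gene_ids: list[str]
    means: pd.Series                 # per-gene centering means
    loadings: pd.DataFrame           # genes x components
    variance_fractions: np.ndarray
    scores: pd.DataFrame             # samples x components


def fit_pca(expr: ExpressionMatrix | pd.DataFrame,
            genes: list[str] | None = None,
            n_components: int | None = None) -> PCAModel:
    """Singular value decomposition of gene-centered log2 expression.

    With all components kept the variance fractions sum to 1; the number of
    informative components is at most n_samples − 1 after centering.
    """
    data = expr.log2_expr if isinstance(expr, ExpressionMatrix) else expr
    if genes is not None:
        if len(genes) == 0:
            raise InputError("empty gene filter for PCA")
        data = data.loc[genes]
    n_samples = data.shape[1]
    if n_samples < 3:
        raise InputError("PCA needs >= 3 samples")
    max_comp = min(n_samples, data.shape[0])
    k = max_comp if n_components is None else n_components
    if k > max_comp:
        raise InputError(f"requested {k} components but at most {max_comp} "
                         "are available")
    means = data.mean(axis=1)
    X = (data.values - means.values[:, None]).T  # samples x genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S ** 2).sum())
    var_frac = (S ** 2) / total if total > 0 else np.zeros_like(S)
    comps = [f"PC{i + 1}" for i in range(len(S))]
    model = PCAModel(
        gene_ids=list(data.index),
        means=means,
        loadings=pd.DataFrame(Vt.T[:, :k], index=data.index, columns=comps[:k]),
        variance_fractions=var_frac[:k],
        scores=pd.DataFrame((U * S)[:, :k], index=data.columns,
                            columns=comps[:k]))
    logger.info("PCA over %d genes, %d samples; leading variance fractions %s",
                len(model.gene_ids), n_samples,
                np.round(model.variance_fractions[:3], 3))
    return model


def project(model: PCAModel, external: pd.DataFrame,
            min_overlap: float = 0.5) -> pd.DataFrame:
    """Project external log2 profiles (genes x samples) into the model frame.

    Profiles are restricted to genes shared with the model, centered with
    the *model's* per-gene means (the coordinate frame is not re-fitted),
    and multiplied onto the loadings restricted to the same genes.
    """
    shared = [g for g in model.gene_ids if g in external.index]
    frac = len(shared) / len(model.gene_ids)
    if frac < min_overlap:
        raise InputError(
            f"only {frac:.1%} of model genes present in external data "
            f"(threshold {min_overlap:.0%})")
    logger.info("projection: %d/%d model genes present (%.1f%% missing)",
                len(shared), len(model.gene_ids), 100 * (1 - frac))
    Xc = external.loc[shared].values - model.means.loc[shared].values[:, None]
    scores = Xc.T @ model.loadings.loc[shared].values
    return pd.DataFrame(scores, index=external.columns,
                        columns=model.loadings.columns)


# ---------------------------------------------------------------------------
# cross-platform harmonization


def quantile_match(external: pd.DataFrame,
                   reference: np.ndarray | pd.Series) -> pd.DataFrame:
    """Map each sample's values onto the reference distribution's quantiles.

    Each value is replaced by the reference quantile of its within-sample
    rank (average ranks for ties), so every output column is distributed as
    the reference up to tie granularity.
    """
    ref = np.sort(np.asarray(reference, dtype=float).ravel())
    if ref.size == 0:
        raise InputError("empty reference distribution")
    out = np.empty(external.shape, dtype=float)
    n = external.shape[0]
    for j in range(external.shape[1]):
        ranks = rankdata(external.values[:, j], method="average")
        q = (ranks - 1) / (n - 1) if n > 1 else np.full(n, 0.5)
        out[:, j] = np.quantile(ref, q)
    return pd.DataFrame(out, index=external.index, columns=external.columns)


def center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (batch-effect correction)."""
    if matrix.shape[1] < 1:
        raise InputError("centering needs >= 1 sample")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def collapse_probes(intensities: pd.DataFrame,
                    probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe rows to genes, keeping the highest-mean probe."""
    df = intensities.copy()
    df["_gene"] = [probe_to_gene.get(p) for p in df.index]
    df = df.dropna(subset=["_gene"])
    order = df.drop(columns="_gene").mean(axis=1).sort_values(ascending=False)
    df = df.loc[order.index]
    df = df[~df["_gene"].duplicated()]
    return df.set_index("_gene").rename_axis("gene_id")


# ---------------------------------------------------------------------------
# variation filters for external comparisons


def fold_change(matrix: pd.DataFrame, samples: list[str],
                pseudocount: float = 1.0) -> pd.Series:
    sub = matrix[samples]
    return (sub.max(axis=1) + pseudocount) / (sub.min(axis=1) + pseudocount)


def variation_filter(rpm: pd.DataFrame,
                     groups: dict[str, list[str]],
                     clauses: list[tuple[tuple[str, ...], float]],
                     pseudocount: float = 1.0) -> list[str]:
    """Fold-change gene filter over named sample groups.

    Each clause is ``(group_names, fold)`` and passes for a gene when the
    pseudocounted max/min ratio reaches ``fold`` (inclusive) in ANY of the
    listed groups; clauses are combined with AND.  The two shipped presets:

    - ``episc``: 16-fold within endoderm, mesoderm or ectoderm differentiation;
    - ``geoseq``: the 16-fold clause AND 8-fold across embryo sections.
    """
    keep = pd.Series(True, index=rpm.index)
    for names, fold in clauses:
        unknown = [n for n in names if n not in groups]
        if unknown:
            raise InputError(f"unknown sample groups: {unknown}")
        clause_pass = pd.Series(False, index=rpm.index)
        for name in names:
            clause_pass |= fold_change(rpm, groups[name], pseudocount) >= fold
        keep &= clause_pass
    return list(rpm.index[keep])


def preset_clauses(preset: str,
                   lineages: tuple[str, ...] = ("endoderm", "mesoderm", "ectoderm"),
                   section_group: str = "sections",
                   ) -> list[tuple[tuple[str, ...], float]]:
    """Named variation-filter presets for the external comparisons."""
    if preset == "episc":
        return [(tuple(lineages), 16.0)]
    if preset == "geoseq":
        return [(tuple(lineages), 16.0), ((section_group,), 8.0)]
    raise InputError(f"unknown preset {preset!r} (available: episc, geoseq)")
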