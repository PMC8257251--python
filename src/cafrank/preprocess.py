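"""Count preprocessing and exploratory embeddings.

The fixed pipeline order is: minimum-count filter -> quantile
normalization -> flooring at 20 -> protein-coding subset -> per-group
top-1% CV exclusion.  Flooring before fold-change computation damps
ratio inflation for lowly expressed genes, which is why the signature
stage works on linear floored means rather than a variance-modelled
statistic.  Each step is idempotent and records itself in the
provenance flags of the returned matrix.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_min_counts",
    "quantile_normalize",
    "floor_values",
    "subset_protein_coding",
    "cv_filter",
    "zscore_rows",
    "hcluster",
    "pca_project",
    "preprocess_counts",
]


def filter_min_counts(counts: CountMatrix, min_count: int = 20,
                      min_samples: int = 3) -> CountMatrix:
    """Keep genes with at least ``min_count`` counts in at least
    ``min_samples`` samples (any samples, not per group).

    An empty survivor set is returned as an empty matrix with a warning
    rather than raised, so callers can report the condition themselves.
    """
    arr = counts.values.to_numpy()
    keep = (arr >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("no gene passed the minimum-count filter")
    out = counts.values.loc[keep]
    logger.info("min-count filter: %d/%d genes retained", keep.sum(), len(keep))
    return CountMatrix(values=out, design=counts.design)


def quantile_normalize(counts: CountMatrix | NormalizedMatrix) -> NormalizedMatrix:
    """Quantile-normalize columns to the mean order-statistic distribution.

    Each column's value at rank r becomes the mean across columns of the
    r-th smallest value; tied entries within a column receive the average
    of the reference values at the tied ranks, so the output is invariant
    to how the sort orders ties.
    """
    values = counts.values
    if values.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return NormalizedMatrix(values=values.astype(float), design=counts.design,
                                provenance={"normalized": True})
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = ref
        # average reference values over runs of tied column values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = ref[s:e].mean()
        out[:, j] = ranked
    prov = getattr(counts, "provenance", {}).copy()
    prov["normalized"] = True
    return NormalizedMatrix(values=pd.DataFrame(out, index=values.index,
                                                columns=values.columns),
                            design=counts.design, provenance=prov)


def floor_values(matrix: NormalizedMatrix, floor: float = 20.0) -> NormalizedMatrix:
    """Raise every entry below ``floor`` to ``floor``."""
    return matrix.with_values(matrix.values.clip(lower=floor), floored=True)


def subset_protein_coding(matrix: NormalizedMatrix,
                          coding_ids) -> NormalizedMatrix:
    """Restrict to protein-coding genes, preserving row order.

    An empty intersection signals an ID-space mismatch (e.g. symbols vs
    Ensembl IDs) and raises rather than silently emptying the matrix.
    """
    coding = set(coding_ids)
    if not coding:
        raise ValueError("coding_ids is empty")
    keep = matrix.values.index.isin(coding)
    if not keep.any():
        raise ValueError("no overlap between matrix genes and coding_ids "
                         "(gene ID spaces probably differ)")
    dropped = int((~keep).sum())
    logger.info("coding subset: dropped %d non-coding genes", dropped)
    return matrix.with_values(matrix.values.loc[keep], coding_filtered=True)


def cv_filter(matrix: NormalizedMatrix, top_frac: float = 0.01) -> NormalizedMatrix:
    """Exclude the union over groups of each group's top-1% CV genes.

    CV = within-group standard deviation (ddof=1) over within-group mean,
    per gene.  In each group the ceil(top_frac * n_genes) largest CVs are
    flagged; flagged-in-any-group genes are removed.  Requires >= 2
    replicates per group and a strictly positive matrix (guaranteed after
    flooring).
    """
    values = matrix.values
    n_top = math.ceil(top_frac * len(values))
    flagged: set = set()
    for group, samples in matrix.groups().items():
        sub = values[samples]
        if sub.shape[1] < 2:
            raise ValueError(f"group {group} has < 2 replicates; CV undefined")
        mean = sub.mean(axis=1)
        assert (mean > 0).all(), "CV filter requires positive (floored) values"
        cv = sub.std(axis=1, ddof=1) / mean
        worst = cv.sort_values(ascending=False, kind="stable").index[:n_top]
        flagged.update(worst)
    keep = ~values.index.isin(flagged)
    logger.info("CV filter: removed %d genes (top %.1f%% per group, union)",
                len(values) - keep.sum(), 100 * top_frac)
    return matrix.with_values(values.loc[keep], cv_filtered=True)


def preprocess_counts(counts: CountMatrix, min_count: int = 20,
                      min_samples: int = 3, floor: float = 20.0,
                      coding_ids=None, top_cv_frac: float = 0.01) -> NormalizedMatrix:
    """Run the full preprocessing chain in its fixed order."""
    filtered = filter_min_counts(counts, min_count=min_count, min_samples=min_samples)
    norm = floor_values(quantile_normalize(filtered), floor=floor)
    if coding_ids is not None:
        norm = subset_protein_coding(norm, coding_ids)
    return cv_filter(norm, top_frac=top_cv_frac)


def zscore_rows(matrix: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across samples (population sd).

    Constant rows map to all-zero rather than NaN so that downstream
    clustering stays total; the convention is logged.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.info("zscore_rows: %d constant rows set to 0", int(constant.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def hcluster(values: pd.DataFrame, axis: int = 1):
    """Average-linkage agglomerative clustering on Euclidean distances.

    axis=1 clusters columns (samples), axis=0 clusters rows (genes).
    Returns (linkage matrix, leaf labels in dendrogram order).  SciPy's
    linkage breaks ties by the smallest cluster-index pair, which makes
    the merge tree deterministic.
    """
    data = values.T.to_numpy(dtype=float) if axis == 1 else values.to_numpy(dtype=float)
    labels = list(values.columns if axis == 1 else values.index)
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    link = sch.linkage(pdist(data, metric="euclidean"), method="average")
    order = sch.leaves_list(link)
    return link, [labels[i] for i in order]


def pca_project(values: pd.DataFrame, n_components: int = 2, axis: int = 1):
    """PCA of samples (axis=1) or genes (axis=0) after per-feature centering.

    Returns (scores DataFrame, loadings DataFrame, variance fractions).
    Uses an SVD with a deterministic sign convention (largest-magnitude
    loading coefficient positive per component).
    """
    data = values.T.to_numpy(dtype=float) if axis == 1 else values.to_numpy(dtype=float)
    labels = list(values.columns if axis == 1 else values.index)
    n_obs, n_feat = data.shape
    if n_components > min(n_obs, n_feat):
        raise ValueError(f"n_components={n_components} exceeds min(dim)={min(n_obs, n_feat)}")
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic signs
    for k in range(len(s)):
        i = np.argmax(np.abs(vt[k]))
        if vt[k, i] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    pcs = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=labels, columns=pcs)
    loadings = pd.DataFrame(vt[:n_components].T, columns=pcs)
    return scores, loadings, frac[:n_components]
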