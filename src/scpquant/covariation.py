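"""Protein (and mRNA) covariation: pairwise correlation matrices, cosine
clustering of correlation vectors, cross-dataset concordance, and nulls.

The covariation of two features is summarized by their correlation across
single cells, computed over cells where both are observed. A feature's row of
the correlation matrix — its *correlation vector* — is a covariation
fingerprint; fingerprints are clustered by cosine distance, and the agreement
of fingerprints between two datasets (two days, or mRNA vs protein) is the
*concordance*: the correlation between corresponding correlation vectors.

Because system-wide trends (batch effects, cell size, growth rate) inflate all
pairwise correlations, the null distribution for gene-set analyses is built
after subtracting the first singular-vector pair from the data matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import mannwhitneyu, pearsonr

from .quantify import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Symmetric feature x feature correlation matrix with per-entry support."""

    matrix: pd.DataFrame  # NaN where support < min_pairs or variance vanishes
    method: str
    support: pd.DataFrame  # complete-pair counts
    min_pairs: int

    @property
    def feature_ids(self) -> pd.Index:
        return self.matrix.index


@dataclass
class ConcordanceResult:
    concordance: pd.Series  # per shared feature, NaN where undefined
    median: float
    mean: float


@dataclass
class ClusterLabels:
    labels: pd.Series  # feature -> cluster label (1-based)
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    distance: str = "cosine"


def pairwise_correlations(
    m: QuantMatrix | pd.DataFrame, method: str = "pearson", min_pairs: int = 3
) -> CorrelationResult:
    """All pairwise feature-feature correlations across cells.

    Entry (i, j) is computed over cells where both features are observed
    (imputed entries are excluded when ``m`` is a :class:`QuantMatrix`);
    entries with fewer than ``min_pairs`` complete pairs, or with zero
    variance over the shared cells, are missing.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if isinstance(m, QuantMatrix):
        values = m.values.where(m.observed_mask)
    else:
        values = m
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    data = values.T  # cells x features; pandas corr is pairwise-complete
    corr = data.corr(method=method, min_periods=max(min_pairs, 2))
    obs = values.notna().to_numpy(dtype=float)
    support = pd.DataFrame(obs @ obs.T, index=values.index, columns=values.index).astype(int)
    corr = corr.where(support >= min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationResult(matrix=corr, method=method, support=support, min_pairs=min_pairs)


def _pairwise_cosine_rows(R: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows of a correlation matrix, excluding for
    each pair (i, j) the self-entries (columns i and j) and any column missing
    in either row."""
    n = R.shape[0]
    sim = np.full((n, n), np.nan)
    finite = np.isfinite(R)
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            mask[i] = mask[j] = False
            if mask.sum() < 2:
                continue
            x, y = R[i, mask], R[j, mask]
            nx, ny = np.linalg.norm(x), np.linalg.norm(y)
            if nx == 0 or ny == 0:
                continue
            sim[i, j] = sim[j, i] = float(x @ y / (nx * ny))
    return sim


def cluster_correlation_vectors(
    c: CorrelationResult,
    n_clusters: int | None = None,
    height: float | None = None,
    min_present: float = 0.25,
) -> ClusterLabels:
    """Hierarchically cluster correlation vectors by cosine distance.

    Distance between features i and j is 1 - cosine of their correlation
    vectors (self-entries excluded), average linkage. Features whose
    correlation vector has fewer than ``min_present`` non-missing entries are
    dropped and reported. Cut either at a fixed cluster count or at a height.
    """
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    R = c.matrix.to_numpy(dtype=float)
    present = np.isfinite(R).mean(axis=1)
    keep = present >= min_present
    dropped = c.matrix.index[~keep]
    if len(dropped):
        logger.warning("clustering: dropped %d feature(s) with sparse correlation vectors",
                       len(dropped))
    ids = c.matrix.index[keep]
    R = R[np.ix_(keep, keep)]
    if R.shape[0] < 2:
        raise ValueError("fewer than 2 clusterable features")
    sim = _pairwise_cosine_rows(R)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    # undefined pairs get the maximum cosine distance
    dist = np.where(np.isfinite(dist), dist, 2.0)
    dist = (dist + dist.T) / 2
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = linkage(condensed, method="average")
    if n_clusters is not None:
        lab = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        lab = fcluster(Z, t=height, criterion="distance")
    order = [ids[i] for i in leaves_list(Z)]
    return ClusterLabels(labels=pd.Series(lab, index=ids), linkage_matrix=Z, leaf_order=order)


def concordance_of_correlations(
    a: CorrelationResult, b: CorrelationResult, min_partners: int = 3
) -> ConcordanceResult:
    """Per-feature concordance between two correlation structures.

    For each feature present in both, the Pearson correlation between its two
    correlation vectors restricted to shared partners (self-entries excluded);
    features with fewer than ``min_partners`` complete shared partners get NaN.
    """
    shared = a.matrix.index.intersection(b.matrix.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    A = a.matrix.loc[shared, shared].to_numpy(dtype=float)
    B = b.matrix.loc[shared, shared].to_numpy(dtype=float)
    n = len(shared)
    out = np.full(n, np.nan)
    for i in range(n):
        mask = np.isfinite(A[i]) & np.isfinite(B[i])
        mask[i] = False
        if mask.sum() < min_partners:
            continue
        x, y = A[i, mask], B[i, mask]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[i] = pearsonr(x, y).statistic
    conc = pd.Series(out, index=shared)
    return ConcordanceResult(
        concordance=conc,
        median=float(conc.median(skipna=True)),
        mean=float(conc.mean(skipna=True)),
    )


def remove_first_singular_pair(m: QuantMatrix | pd.DataFrame) -> pd.DataFrame:
    """Subtract the first singular-vector pair: X' = X - s1 * u1 v1^T.

    The leading pair concentrates global, system-wide effects (batch, cell
    size); removing it deflates the positive bias of the all-pairs correlation
    null. Requires a complete matrix.
    """
    values = m.values if isinstance(m, QuantMatrix) else m
    X = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix must be complete (impute or filter first)")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Xp = X - s[0] * np.outer(U[:, 0], Vt[0, :])
    return pd.DataFrame(Xp, index=values.index, columns=values.columns)


@dataclass
class GeneSetDistribution:
    set_name: str
    correlations: np.ndarray
    n_features: int
    p_value: float  # rank-sum test vs null, alternative: set > null


def geneset_correlation_distributions(
    c: CorrelationResult,
    gene_sets: dict[str, list[str]],
    null: CorrelationResult,
) -> tuple[list[GeneSetDistribution], np.ndarray]:
    """Within-set correlation distributions against a global-trend-free null.

    For each gene set, collects the off-diagonal correlations among its
    quantified members from ``c``; the null is all off-diagonal correlations
    of ``null`` (typically computed after :func:`remove_first_singular_pair`).
    Each set gets a one-sided rank-sum p-value for being shifted above the
    null. Sets with fewer than 2 quantified members are skipped.
    """
    Rn = null.matrix.to_numpy(dtype=float)
    iu = np.triu_indices_from(Rn, k=1)
    null_vals = Rn[iu]
    null_vals = null_vals[np.isfinite(null_vals)]
    results: list[GeneSetDistribution] = []
    for name, members in gene_sets.items():
        idx = c.matrix.index.intersection(pd.Index(members))
        if len(idx) < 2:
            logger.warning("gene set %s: <2 quantified members, skipped", name)
            continue
        R = c.matrix.loc[idx, idx].to_numpy(dtype=float)
        vals = R[np.triu_indices_from(R, k=1)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        p = float(mannwhitneyu(vals, null_vals, alternative="greater").pvalue)
        results.append(GeneSetDistribution(name, vals, len(idx), p))
    return results, null_vals


def jaccard_cluster_overlap(a: ClusterLabels, b: ClusterLabels) -> pd.DataFrame:
    """Jaccard coefficients |A∩B| / |A∪B| between every pair of clusters,
    restricted to the shared feature universe. Empty clusters score 0."""
    shared = a.labels.index.intersection(b.labels.index)
    la, lb = a.labels.loc[shared], b.labels.loc[shared]
    rows = {}
    for ca in sorted(la.unique()):
        A = set(la.index[la == ca])
        rows[ca] = {}
        for cb in sorted(lb.unique()):
            B = set(lb.index[lb == cb])
            union = A | B
            rows[ca][cb] = len(A & B) / len(union) if union else 0.0
    return pd.DataFrame(rows).T.sort_index()


def filter_mrna(counts: pd.DataFrame, min_mean_reads: float = 2.5) -> pd.DataFrame:
    """Keep genes (rows) with mean reads per cell >= threshold (inclusive)."""
    return counts.loc[counts.mean(axis=1) >= min_mean_reads]


def filter_protein_support(m: QuantMatrix, min_cells: int = 12) -> QuantMatrix:
    """Keep proteins observed (not imputed) in at least ``min_cells`` cells."""
    from dataclasses import replace

    n_obs = m.observed_mask.sum(axis=1)
    keep = n_obs.index[n_obs >= min_cells]
    return replace(
        m,
        values=m.values.loc[keep],
        imputed=None if m.imputed is None else m.imputed.loc[keep],
        normalization_state=list(m.normalization_state),
    )
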