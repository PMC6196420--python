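"""Cell classification: principal-component projection of single-cell
proteomes and two-sample marker-protein discovery.

Before the decomposition each protein's mean level across cells is set to one,
so highly and lowly abundant proteins contribute equally to the projection.
Each component is correlated against declared covariates — differentiation
day, cell-type indicator, and the per-cell fraction of missing data — to flag
components that track technical rather than biological structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # features x components
    variance_explained: pd.Series  # fraction per component
    covariate_correlations: pd.DataFrame | None  # components x covariates
    feature_ids: pd.Index = None

    def __post_init__(self) -> None:
        if self.feature_ids is None:
            self.feature_ids = self.loadings.index


def _row_scale_mean1(values: pd.DataFrame) -> pd.DataFrame:
    means = values.mean(axis=1)
    if (means == 0).any():
        raise ValueError("feature with zero mean cannot be scaled to mean 1")
    return values.div(means, axis=0)


def project_pca(
    m: QuantMatrix,
    covariates: pd.DataFrame | None = None,
    n_components: int | None = None,
) -> PcaResult:
    """Project cells onto the principal components of the row-scaled matrix.

    Requires a complete matrix (impute or filter first). Rows are scaled to
    mean 1 and then centered; the SVD of the centered matrix gives loadings
    (left singular vectors) and cell scores. Constant features are dropped and
    reported. Component signs are fixed by making each component's
    largest-magnitude loading positive.

    ``covariates`` is a cells x covariates frame (e.g. day, type indicator,
    missing-data fraction); each component is Pearson-correlated against each
    covariate.
    """
    values = m.values
    if values.isna().any().any():
        raise ValueError("PCA requires a complete matrix; impute or filter first")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    const = values.index[values.std(axis=1) == 0]
    if len(const):
        logger.warning("project_pca: dropped %d constant feature(s)", len(const))
        values = values.drop(index=const)
    scaled = _row_scale_mean1(values)
    Xc = scaled.to_numpy(dtype=float) - 1.0  # centering: row means are exactly 1
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] *= -1
            Vt[j, :] *= -1
    comps = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame((Vt[:k, :].T * s[:k]), index=values.columns, columns=comps)
    loadings = pd.DataFrame(U[:, :k], index=values.index, columns=comps)
    var = pd.Series(s[:k] ** 2 / np.sum(s**2), index=comps)

    cov_corr = None
    if covariates is not None:
        covariates = covariates.loc[scores.index]
        rows = {}
        for comp in comps:
            rows[comp] = {
                name: _safe_pearson(scores[comp].to_numpy(), covariates[name].to_numpy(dtype=float))
                for name in covariates.columns
            }
        cov_corr = pd.DataFrame(rows).T
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var,
        covariate_correlations=cov_corr,
    )


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan")
    return float(stats.pearsonr(x[ok], y[ok]).statistic)


def project_new_samples(pca: PcaResult, m_new: QuantMatrix) -> pd.DataFrame:
    """Map additional samples (e.g. bulk averages) into an existing component
    space without refitting.

    The new matrix must cover the fitted feature space; it receives the same
    treatment (rows scaled to mean 1, centered at 1) and is projected on the
    stored loadings. Missing features raise an error listing the absentees.
    """
    values = m_new.values
    absent = [f for f in pca.feature_ids if f not in values.index]
    if absent:
        raise ValueError(f"{len(absent)} fitted feature(s) absent from new samples: "
                         f"{absent[:5]}{'...' if len(absent) > 5 else ''}")
    values = values.loc[pca.feature_ids]
    if values.isna().any().any():
        raise ValueError("new samples must be complete over the fitted features")
    Xc = _row_scale_mean1(values).to_numpy(dtype=float) - 1.0
    scores = Xc.T @ pca.loadings.to_numpy()
    return pd.DataFrame(scores, index=values.columns, columns=pca.loadings.columns)


@dataclass
class MarkerResult:
    table: pd.DataFrame  # t, p, q, direction, log2_fc, n per group
    fdr: float
    groups: tuple[str, str]
    n_skipped: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] <= self.fdr]


def find_markers(
    m: QuantMatrix,
    labels: pd.Series,
    fdr: float = 0.02,
    min_cells_per_group: int = 3,
) -> MarkerResult:
    """Cell-type marker proteins by Welch two-sample t-test at a target FDR.

    A protein is tested only where observed in at least ``min_cells_per_group``
    cells of each group; skipped proteins are counted. P-values are adjusted
    by Benjamini-Hochberg; ``direction`` is the sign of group-1-minus-group-2.
    """
    labels = labels.loc[m.values.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1_cols = labels.index[labels == groups[0]]
    g2_cols = labels.index[labels == groups[1]]
    if len(g1_cols) < min_cells_per_group or len(g2_cols) < min_cells_per_group:
        raise ValueError("each group needs at least min_cells_per_group cells")
    obs = m.observed_mask
    rows = []
    n_skipped = 0
    for prot in m.values.index:
        x = m.values.loc[prot, g1_cols][obs.loc[prot, g1_cols]].to_numpy(dtype=float)
        y = m.values.loc[prot, g2_cols][obs.loc[prot, g2_cols]].to_numpy(dtype=float)
        if len(x) < min_cells_per_group or len(y) < min_cells_per_group:
            n_skipped += 1
            continue
        if np.std(x) == 0 and np.std(y) == 0:
            if x.mean() == y.mean():
                n_skipped += 1
                continue
            t, p = np.inf if x.mean() > y.mean() else -np.inf, 0.0
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = float(np.log2(x.mean() / y.mean())) if x.mean() > 0 and y.mean() > 0 else np.nan
        rows.append({"protein": prot, "t": t, "p": p, "log2_fc": lfc,
                     "direction": "up" if t > 0 else "down",
                     "n_1": len(x), "n_2": len(y)})
    if not rows:
        table = pd.DataFrame(columns=["t", "p", "q", "log2_fc", "direction", "n_1", "n_2"])
        return MarkerResult(table=table, fdr=fdr, groups=(groups[0], groups[1]),
                            n_skipped=n_skipped)
    table = pd.DataFrame(rows).set_index("protein")
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    table = table.sort_values("p")
    return MarkerResult(table=table, fdr=fdr, groups=(groups[0], groups[1]), n_skipped=n_skipped)
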