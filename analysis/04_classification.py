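"""Classify the simulated single cells: PCA of the imputed proteome matrix
(rows scaled to mean 1 so abundant and scarce proteins weigh equally),
component-covariate correlations (cell type, day, missing-data fraction),
projection of per-type bulk averages, and marker discovery at FDR < 2%.

Reads results/quant/, writes results/classification/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import scpquant as sq

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "classification"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prot = sq.read_matrix(BASE / "quant" / "proteins_imputed", level="protein")
    cells = pd.read_csv(BASE / "sim" / "truth.cells.tsv", sep="\t", index_col=0)
    truth_markers = pd.read_csv(
        BASE / "sim" / "truth.proteins.tsv", sep="\t", index_col=0
    )["marker_log2_fc"]
    missing = pd.read_csv(
        BASE / "quant" / "missing_fraction.tsv", sep="\t", index_col=0
    )["missing_fraction"]

    complete = sq.QuantMatrix(values=prot.values.dropna(axis=0), level="protein",
                              col_meta=prot.col_meta)
    cols = complete.values.columns
    covariates = pd.DataFrame({
        "type_indicator": (cells.loc[cols, "cell_type"] == "B").astype(float),
        "day": cells.loc[cols, "day"].astype(float),
        "missing_fraction": missing.loc[cols],
    })
    pca = sq.project_pca(complete, covariates=covariates, n_components=5)
    pca.scores.to_csv(OUT / "pc_scores.tsv", sep="\t")
    pca.covariate_correlations.to_csv(OUT / "pc_covariate_correlations.tsv", sep="\t")
    pd.DataFrame({"variance_explained": pca.variance_explained}).to_csv(
        OUT / "variance_explained.tsv", sep="\t"
    )
    v = pca.variance_explained
    print(f"PC1+PC2 explain {100 * (v.iloc[0] + v.iloc[1]):.0f}% of variance")
    cc = pca.covariate_correlations
    best_pc = cc["type_indicator"].abs().idxmax()
    print(f"{best_pc} tracks cell type (r = {cc.loc[best_pc, 'type_indicator']:.2f}); "
          f"missing-data correlations per PC: "
          + ", ".join(f"{p}: {r:.2f}" for p, r in cc['missing_fraction'].items()))

    # bulk samples = per-type averages, projected without refitting
    types = cells.loc[cols, "cell_type"]
    bulk_vals = pd.DataFrame({
        f"bulk_{t}": complete.values.loc[:, (types == t).to_numpy()].mean(axis=1)
        for t in sorted(types.unique())
    })
    bulk = sq.QuantMatrix(values=bulk_vals, level="protein")
    bulk_scores = sq.project_new_samples(pca, bulk)
    bulk_scores.to_csv(OUT / "bulk_scores.tsv", sep="\t")
    for t in sorted(types.unique()):
        cent = pca.scores.loc[(types == t).to_numpy(), "PC1"].mean()
        print(f"bulk_{t} lands at PC1 = {bulk_scores.loc[f'bulk_{t}', 'PC1']:.2f} "
              f"(type-{t} cell centroid: {cent:.2f})")

    markers = sq.find_markers(prot, cells.loc[prot.values.columns, "cell_type"], fdr=0.02)
    markers.table.to_csv(OUT / "markers.tsv", sep="\t")
    called = set(markers.significant.index)
    planted = set(truth_markers.index[truth_markers != 0])
    tp = len(called & planted)
    print(f"markers at FDR < 2%: {len(called)} proteins called, "
          f"{tp}/{len(planted)} planted markers recovered, "
          f"{len(called) - tp} false positives")


if __name__ == "__main__":
    main()
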