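"""Coordinated mRNA and protein covariation: filter both layers (mRNAs with
>= 2.5 mean reads per cell, proteins observed in >= 12 cells), cluster each
correlation matrix, compare cluster memberships by Jaccard overlap, and
compute the per-gene mRNA-protein covariation concordance.

Reads results/sim/ and results/quant/, writes results/mrna_protein/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import scpquant as sq

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "mrna_protein"
N_CLUSTERS = 3


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(BASE / "sim" / "mrna_counts.tsv", sep="\t", index_col=0)
    prot = sq.read_matrix(BASE / "quant" / "proteins_observed", level="protein")
    modules = pd.read_csv(BASE / "sim" / "truth.proteins.tsv", sep="\t", index_col=0)["module"]

    counts = sq.filter_mrna(counts, min_mean_reads=2.5)
    prot = sq.filter_protein_support(prot, min_cells=12)
    shared_genes = counts.index.intersection(prot.values.index)
    print(f"{counts.shape[0]} mRNAs pass the 2.5-reads filter, "
          f"{prot.values.shape[0]} proteins pass the 12-cell filter, "
          f"{len(shared_genes)} genes quantified at both levels")

    mrna_corr = sq.pairwise_correlations(np.log1p(counts.loc[shared_genes]))
    prot_corr = sq.pairwise_correlations(
        sq.QuantMatrix(values=prot.values.loc[shared_genes], level="protein",
                       col_meta=prot.col_meta),
        min_pairs=6,
    )

    mrna_clusters = sq.cluster_correlation_vectors(mrna_corr, n_clusters=N_CLUSTERS)
    prot_clusters = sq.cluster_correlation_vectors(prot_corr, n_clusters=N_CLUSTERS)
    J = sq.jaccard_cluster_overlap(mrna_clusters, prot_clusters)
    J.to_csv(OUT / "cluster_jaccard.tsv", sep="\t")
    best = J.max(axis=1)
    print(f"best Jaccard overlap per mRNA cluster: "
          + ", ".join(f"{100 * v:.0f}%" for v in best))

    conc = sq.concordance_of_correlations(mrna_corr, prot_corr)
    conc.concordance.rename("concordance").to_csv(OUT / "gene_concordance.tsv", sep="\t")
    print(f"mRNA-protein covariation concordance: median {conc.median:.3f} "
          f"over {int(conc.concordance.notna().sum())} genes")
    per_module = conc.concordance.groupby(modules.reindex(conc.concordance.index)).median()
    per_module.rename("median_concordance").to_csv(
        OUT / "module_concordance.tsv", sep="\t"
    )
    print("per-module median concordance: "
          + ", ".join(f"m{int(m)}: {v:.2f}" for m, v in per_module.items()))


if __name__ == "__main__":
    main()
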