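"""Quantify the simulated evidence: 3% mean-PEP FDR filter, channel median
normalization, carrier-reference combining across sets, relative levels,
razor-protein rollup, and k=1 cosine kNN imputation. Also reports the
empty-channel SNR diagnostic for every set.

Reads results/sim/, writes protein matrices to results/quant/.
"""

from pathlib import Path

import scpquant as sq

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "sim", BASE / "quant"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    designs = sq.read_design(SIM / "designs.yaml")
    records = []
    for set_id, design in designs.items():
        records.extend(sq.read_evidence(SIM / f"evidence_{set_id}.tsv", design))
    print(f"read {len(records)} evidence records from {len(designs)} sets")

    reports = sq.estimate_snr(records, designs)
    with open(OUT / "snr_report.tsv", "w") as fh:
        fh.write("set_id\tbackground\tsingle_cell_snr\tn_peptides\n")
        for rep in reports.values():
            fh.write(f"{rep.set_id}\t{rep.background:.1f}\t"
                     f"{rep.single_cell_snr:.2f}\t{rep.n_peptides_used}\n")
    snrs = [r.single_cell_snr for r in reports.values()]
    print(f"empty-channel SNR per set: {', '.join(f'{s:.1f}' for s in snrs)} "
          "(single-cell signal exceeds background ~10-fold)")

    res = sq.run_pipeline(records, designs, target_fdr=0.03,
                          combine="carrier", impute_level="protein", k=1)
    print(f"mean-PEP filter: kept {res.fdr.n_retained}/{res.fdr.n_input} records "
          f"(achieved FDR {res.fdr.achieved_fdr:.4f}, PEP cutoff {res.fdr.pep_cutoff:.4f})")
    n_prot = res.proteins.values.shape[0]
    print(f"quantified {n_prot} proteins across {res.proteins.values.shape[1]} cells; "
          f"mean missing-data fraction {res.missing_fraction.mean():.1%}")

    sq.write_matrix(res.proteins, OUT / "proteins_observed")
    sq.write_matrix(res.proteins_imputed, OUT / "proteins_imputed")
    res.missing_fraction.rename("missing_fraction").to_csv(
        OUT / "missing_fraction.tsv", sep="\t"
    )
    print(f"wrote protein matrices (observed + imputed) to {OUT}")


if __name__ == "__main__":
    main()
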