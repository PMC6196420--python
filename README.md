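# scpquant

Quantification and analysis of carrier-channel single-cell TMT proteomics
(SCoPE-MS-style experiments), for proteomics researchers who want a tested,
scriptable pipeline from peptide evidence tables to normalized single-cell
protein matrices — plus the downstream covariation, concordance, and
cell-classification analyses that such data support.

In this experimental design, each TMT-10 set multiplexes eight single cells
with a ~200-cell **carrier channel** (which supplies the ions used for peptide
identification and absorbs surface losses) and one deliberately **empty
channel** (130N), whose reporter intensity measures background noise plus
isotopic cross-contamination from the adjacent 131 channel. Quantification is
relative: reporter-ion (RI) intensities within a set carry the cell-to-cell
ratios of each peptide.

## What the pipeline computes

Given MaxQuant-style evidence tables and a channel-design file:

1. **Identification filtering.** Peptides are filtered to a target FDR
   (default 3%) by the *mean-PEP* criterion: accept the longest PEP-sorted
   prefix whose mean posterior error probability stays ≤ the target — the
   mean PEP of the accepted set is its estimated FDR.
2. **Normalization.** Each channel's median RI is set to 1 (corrects loading
   differences); each peptide's vector across cells is divided by its mean
   (or median), leaving relative levels.
3. **Combining sets.** Either divide single-cell values by the shared carrier
   channel (carrier-reference mode), or drop the carrier and scale each
   peptide to mean 1 across each set's single cells (balanced mode, for
   sets whose carriers differ).
4. **Protein rollup.** A protein's relative level in a cell is the median
   over its razor peptides observed in that cell.
5. **Imputation.** Missing entries are filled by k-nearest-neighbor cells
   (k = 1) under cosine similarity between proteome vectors; imputed entries
   stay flagged and are excluded from correlation analyses by default.
6. **Diagnostics.** Per-set SNR = median single-cell RI / median empty-channel
   RI; per-cell missing-data fractions; precursor-area-based absolute
   abundance estimates.

Downstream analyses: pairwise protein-protein correlation matrices with
per-entry support counts, hierarchical clustering of correlation vectors by
cosine distance, concordance of covariation between two datasets (the
correlation between corresponding correlation vectors — used day-to-day and
mRNA-vs-protein), gene-set correlation distributions against a null built by
subtracting the first singular-vector pair (which concentrates global
trends), Jaccard overlap of cluster memberships, PCA of row-mean-1-scaled
proteomes with component-covariate correlations, and Welch-t marker discovery
with Benjamini-Hochberg control at FDR < 2%.

A calibrated synthetic-data generator (`scpquant.simulate`) emulates the full
measurement model — carrier-driven shotgun detection, empty-channel
background, 131→130N isotopic impurity, signal-dependent PEPs, planted
covariation modules and cell-type markers — so every stage is validated by
parameter recovery at desk scale.

## Worked example

```python
import scpquant as sq

cfg = sq.SimulationConfig(n_sets=4, n_proteins=200, seed=11)
truth, designs, records = sq.simulate_experiment(cfg)

snr = sq.estimate_snr(records, designs)["set1"].single_cell_snr
res = sq.run_pipeline(records, designs, target_fdr=0.03, combine="carrier")
print(f"SNR {snr:.1f}; kept {res.fdr.n_retained}/{res.fdr.n_input} records "
      f"at achieved FDR {res.fdr.achieved_fdr:.4f}; "
      f"{res.proteins.values.shape[0]} proteins x {res.proteins.values.shape[1]} cells")
```

prints

```
SNR 10.2; kept 1677/1714 records at achieved FDR 0.0299; 193 proteins x 32 cells
```

— the empty-channel diagnostic recovers the simulated 10-fold
signal-to-background ratio, the mean-PEP filter lands on the 3% target, and
193 of 200 simulated proteins are quantified across the 32 cells.

The numbered drivers under `analysis/` run the full study on simulated data
(`01_simulate.py` → `05_mrna_protein.py`), writing tables under `results/`:
quantification with SNR reports, module recovery from clustered correlation
vectors, day-to-day concordance, PCA classification with bulk-sample
projection and marker discovery, and mRNA-protein cluster overlap and
concordance.

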