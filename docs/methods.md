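# Methods

## The measurement model

A carrier-channel single-cell TMT set labels eight single cells, one
~200-cell carrier sample, and leaves one channel (130N) empty. All samples
are pooled and analyzed in one LC-MS/MS run; each identified peptide yields
one reporter-ion (RI) intensity per channel. Three properties of this design
drive everything the pipeline does:

* **The carrier dominates precursor signal.** In shotgun acquisition,
  precursor ions are selected for MS2 by MS1 abundance, which the carrier
  dominates. Peptide detection is therefore an increasing function of
  carrier-channel intensity — missingness is abundance-dependent, not random.
* **Within-set RI ratios carry the quantification.** Ionization efficiency,
  elution, and sampling affect all channels of a peptide identically, so the
  RI ratios across channels estimate the cell-to-cell abundance ratios.
* **The empty channel measures the noise floor.** 130N receives no labeled
  material; its RI reflects background noise plus isotopic
  cross-contamination from the adjacent 131 channel, giving every set an
  internal signal-to-noise control.

## Synthetic-data generator

`simulate_truth` draws, in log2 space, per-(protein, cell) abundances

    log2 A[p, c] = mu_p + sigma_f * F[m(p), c] + beta_p * 1[type(c) = B]
                   + sigma_e * eps[p, c]

with protein baselines `mu_p ~ N(17.6, 2.0)` (median ~2×10⁵ copies per cell,
matching the observation that single-cell-MS-quantifiable proteins sit mostly
above ~5×10⁴ copies), one shared latent factor per covariation module
(`sigma_f = 0.7` by default; within-module correlation of log abundances is
`sigma_f² / (sigma_f² + sigma_e²)`, verified against Monte Carlo), planted
marker fold changes (`beta = ±1` log2 on 20 proteins per direction), and
independent per-cell noise `sigma_e = 0.35` log2. Cells alternate between
two types, so each 8-cell set is balanced 4+4.

`simulate_set` turns truth into evidence. Per peptide and set: an ionization
efficiency drawn log-normal (σ = 1.0) and shared across channels; channel
signal = cell-equivalents × abundance × efficiency (carrier: 200
cell-equivalents of the mean cell profile); detection Bernoulli with logistic
probability in log carrier intensity (slope 1.5 per natural-log unit,
midpoint at the 30th percentile of carrier intensities, so roughly two thirds
of peptide-set pairs are detected); PEP logistic-decreasing in standardized
log total signal (intercept −4, slope 1.2, noise SD 0.5), which makes low
abundance and low identification confidence coincide; precursor area = half
the summed channel intensities. The empty channel receives background plus
`0.04 ×` the 131-channel signal (a typical isotopic-impurity fraction);
missingness arises only through the detection model.

**Background calibration.** The background level is not an independent dial.
For each set the generator solves (by bracketed root finding on the set's own
sampled draws) for the background scale at which

    median single-cell RI over detected peptides
    ----------------------------------------------  =  snr_target  (default 10)
    median empty-channel RI (background + impurity)

i.e. the generator is calibrated in exactly the statistic the downstream SNR
diagnostic measures. Background draws are log-normal (σ = 0.4) around that
level and added to every channel.

`simulate_mrna` produces paired counts by Poisson sampling of the same true
abundances, scaled so the expected total per cell is `capture_rate × depth`.
This shares the module/marker structure with the protein layer (the basis of
the concordance analyses) but deliberately omits transcript-specific
regulation: mRNA and protein differ only by sampling noise, so simulated
concordance is an upper bound on what real data would show.

What the generator does **not** emulate: co-isolation interference,
chromatographic elution shapes, charge-state-specific behavior,
search-engine score distributions, peptide-level modifications, and any
post-transcriptional decoupling of mRNA from protein. Passing recovery tests
therefore demonstrates the pipeline's correctness under the stated
measurement model, not robustness to every artifact of real instruments.

## Pipeline conventions

* **Mean-PEP FDR filter.** The cutoff is the largest PEP value at which the
  mean PEP of all records at or below it stays ≤ the target (maximal
  retention). Ties at the boundary stand or fall together, making the result
  independent of input order. Filtering pools records across sets by default
  (maximizes cross-set comparability); a per-set option exists. If no prefix
  qualifies, the result is empty with the achieved FDR flagged NaN rather
  than an exception.
* **Zeros are missing.** A zero reporter intensity is treated as
  not-observed, never as a true zero, since background is strictly positive.
* **Duplicate evidence rows** for one (peptide, set) — charge states,
  repeated PSMs — are summed before normalization; they carry the same ratio
  information.
* **Order of operations.** Channel median normalization per set → combining
  (carrier division or per-set mean-1 scaling) → peptide vector
  normalization (mean by default; median available) → median rollup to razor
  proteins → imputation. The applied transforms are recorded in
  `normalization_state` for audit.
* **Imputation.** Cosine similarity between cells is computed over jointly
  observed features; for each missing entry the donor is the most similar
  cell that has the feature observed (k = 1; k > 1 averages donors
  unweighted). Imputation runs at the protein level by default, which
  minimizes the number of imputed entries; imputed values remain flagged and
  are excluded from correlation analyses unless explicitly included. When
  two cells share exactly one feature their cosine is set to the exact sign
  of the product (the mathematical value), avoiding spurious
  floating-point distinctions among tied donors; remaining ties break toward
  the lower column index.
* **Correlations** are pairwise-complete with per-entry support counts;
  entries with fewer than `min_pairs` complete pairs (default 3) or zero
  variance are missing. Clustering of correlation vectors uses
  1 − cosine distance with self-entries excluded per pair, average linkage;
  features with < 25% present correlation entries are dropped; pairs with
  undefined cosine get the maximum distance (2). Concordance between two
  correlation structures is the Pearson correlation of corresponding
  correlation vectors over shared partners, self-entries excluded, requiring
  ≥ 3 complete shared partners.
* **Null for gene-set correlation distributions.** The first singular pair
  `s₁u₁v₁ᵀ` is subtracted from the complete matrix before computing the
  all-pairs null, deflating the shared positive bias that global trends
  (batch, cell size, growth) put on every correlation. A side effect of
  removing the leading component is a small negative bias of order −1/k
  between k modules (the protein-mean profile is removed); the gene-set test
  is one-sided (rank-sum, set > null), so this makes it conservative.
* **PCA** scales each protein to mean 1 across cells (equalizing abundant
  and scarce proteins), centers at 1, and decomposes by SVD without column
  standardization. Component signs are fixed by making the
  largest-magnitude loading positive. New samples (e.g. bulk averages) are
  projected with the same scaling and the stored loadings, without
  refitting — a single projected sample is degenerate under this convention
  (row scaling maps it to the origin).
* **Markers** use Welch's unequal-variance t-test (robust to the unequal
  spreads typical of cell types) on relative levels, with
  Benjamini-Hochberg adjustment to the target FDR (2% default); proteins
  need ≥ 3 observed cells per group.

## Problem sizes and tolerances

Validation runs at desk scale: 2–6 TMT-10 sets (16–48 cells), 200–300
proteins, ~3 peptides per protein — large enough for every statistical check
yet seconds-fast. Oracle-equivalence checks (FDR filter, imputation,
correlations) require exact agreement; Monte Carlo recovery checks use
tolerances derived from their sampling noise: SNR within 20% of target over
≥ 1000 peptides, planted log2 fold change 1.0 recovered within ±0.2 at 16
cells/type (the residual ~0.1 attenuation comes from additive background at
1/10 of signal — a real property of the measurement, not an estimator bug),
module recovery at adjusted Rand ≥ 0.9 when per-cell noise is 0.25× the
factor scale, marker sensitivity ≥ 80% with empirical FDR ≤ 5% at nominal
2%. Numerical tolerances: channel medians equal 1 within 1e-9; singular-pair
residuals orthogonal within 1e-8 of s₁.

## Design choices on genuinely open points

* Whether analyses should use imputed values is left to the caller;
  correlations default to observed-only, PCA requires the imputed (or
  filtered-complete) matrix.
* The marker-recovery validation plants fold changes on otherwise
  independent proteins (module factor off): module covariance would change
  the per-protein noise scale without being part of the property under test
  (FDR control and sensitivity of the per-protein test).
* Cluster count for the mRNA/protein comparison is caller-supplied (the
  analysis scripts use 3); no automatic cut selection is attempted.
* The evidence reader accepts both positional ("Reporter intensity 0") and
  label ("Reporter intensity 126") column dialects, since exporter versions
  differ.

## Known limitations

Background is additive log-normal — real empty-channel distributions are
empirical and may be heavier-tailed. No co-isolation model exists, so
reporter ratios are cleaner than real ones at equal SNR. The razor-protein
mapping is taken from the evidence table as given; protein-group inference
is out of scope. FDR estimation is PEP-based only (no decoy counting), and
match-between-runs is not implemented.
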