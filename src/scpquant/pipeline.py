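"""End-to-end assembly: evidence -> filtered, normalized, combined,
imputed protein matrix. Thin orchestration over the module functions; every
step is individually importable and tested."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import ChannelDesign
from .evidence import PeptideEvidence
from .fdr import FdrFilterResult, filter_by_mean_pep
from .quantify import (
    QuantMatrix,
    build_peptide_matrix,
    channel_median_normalize,
    combine_sets_balanced,
    combine_sets_carrier_reference,
    impute_knn,
    peptide_vector_normalize,
    rollup_to_proteins,
)


@dataclass
class PipelineResult:
    fdr: FdrFilterResult
    peptides: QuantMatrix  # combined, row-normalized peptide relative levels
    proteins: QuantMatrix  # rolled up, before imputation
    proteins_imputed: QuantMatrix | None
    missing_fraction: pd.Series  # per cell, protein level, pre-imputation


def run_pipeline(
    records: list[PeptideEvidence],
    designs: dict[str, ChannelDesign],
    target_fdr: float = 0.03,
    center: str = "mean",
    combine: str = "carrier",
    impute_level: str = "protein",
    k: int = 1,
) -> PipelineResult:
    """Filtered evidence to a normalized protein x cell matrix.

    Steps: mean-PEP filter at ``target_fdr`` (pooled across sets), per-set
    channel median normalization, set combining (``carrier`` divides by the
    shared carrier channel; ``balanced`` scales each peptide to mean 1 across
    each set's single cells), row normalization by ``center``, median rollup
    to razor proteins, then k-nearest-neighbor imputation.
    """
    if combine not in ("carrier", "balanced"):
        raise ValueError("combine must be 'carrier' or 'balanced'")
    if impute_level not in ("protein", "peptide", "none"):
        raise ValueError("impute_level must be 'protein', 'peptide', or 'none'")

    fdr_result = filter_by_mean_pep(records, target_fdr)
    peptide_to_protein: dict[str, str] = {}
    mats = []
    for set_id, design in designs.items():
        set_records = [r for r in fdr_result.retained if r.set_id == set_id]
        if not set_records:
            continue
        m = build_peptide_matrix(set_records, design)
        peptide_to_protein.update(m.peptide_to_protein)
        mats.append(channel_median_normalize(m))
    if not mats:
        raise ValueError("no evidence survived filtering")

    if combine == "carrier":
        combined = combine_sets_carrier_reference(mats, designs)
    else:
        combined = combine_sets_balanced(mats, designs)
    peptides = peptide_vector_normalize(combined, center=center)
    if impute_level == "peptide":
        peptides = impute_knn(peptides, k=k)
    proteins = rollup_to_proteins(peptides, peptide_to_protein)
    missing_fraction = proteins.missing_fraction_per_cell
    proteins_imputed = impute_knn(proteins, k=k) if impute_level == "protein" else None
    return PipelineResult(
        fdr=fdr_result,
        peptides=peptides,
        proteins=proteins,
        proteins_imputed=proteins_imputed,
        missing_fraction=missing_fraction,
    )
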