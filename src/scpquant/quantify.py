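"""Reporter-ion quantification: evidence -> normalized relative-level matrices.

The chain implemented here follows the standard carrier-channel single-cell
TMT workflow:

1. assemble a peptide x channel matrix per TMT set (zeros treated as missing);
2. set the median reporter intensity of each channel to one (corrects
   channel-specific loading/labeling differences);
3. combine sets either by dividing single-cell values by the shared carrier
   channel, or — when carriers differ — by scaling each peptide to mean 1
   across the single cells of its set;
4. divide each peptide's vector across cells by its mean (or median), leaving
   relative levels;
5. roll peptides up to razor proteins by the median;
6. impute remaining missing values by k-nearest-neighbor cells under cosine
   similarity (k = 1 by default).

Every operation consumes and returns a :class:`QuantMatrix`, which carries the
missing mask and an audit trail of applied transforms. Missing entries carry
no numeric meaning: all statistics are computed over observed entries only.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ChannelDesign, DesignError
from .evidence import PeptideEvidence

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class QuantMatrix:
    """Features (peptides or proteins) x cells matrix of relative levels.

    ``values`` holds NaN where an entry is missing. ``imputed`` (same shape,
    boolean) marks entries that were filled by imputation; observed entries
    are those that are non-missing and not imputed.
    """

    values: pd.DataFrame
    level: str  # "peptide" | "protein"
    col_meta: pd.DataFrame = None  # index = column ids; set_id/channel/role/cell_type/day
    normalization_state: list[str] = field(default_factory=list)
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.col_meta is None:
            self.col_meta = pd.DataFrame(index=self.values.columns)
        if not self.values.columns.equals(self.col_meta.index):
            raise ValueError("col_meta index must match value columns")
        if self.imputed is not None and self.imputed.shape != self.values.shape:
            raise ValueError("imputed mask shape mismatch")

    @property
    def observed_mask(self) -> pd.DataFrame:
        obs = self.values.notna()
        if self.imputed is not None:
            obs &= ~self.imputed
        return obs

    @property
    def missing_fraction_per_cell(self) -> pd.Series:
        """Fraction of features not observed (missing or imputed) per column."""
        return 1.0 - self.observed_mask.mean(axis=0)

    def subset_roles(self, roles: set[str]) -> "QuantMatrix":
        keep = self.col_meta.index[self.col_meta["role"].isin(roles)]
        return replace(
            self,
            values=self.values[keep],
            col_meta=self.col_meta.loc[keep],
            imputed=None if self.imputed is None else self.imputed[keep],
            normalization_state=list(self.normalization_state),
        )


def build_peptide_matrix(records: list[PeptideEvidence], design: ChannelDesign) -> QuantMatrix:
    """Assemble one TMT set's evidence into a peptide x channel matrix.

    Duplicate rows for the same peptide (charge states, repeated PSMs) have
    their reporter intensities summed — they carry the same ratio information.
    Zero intensities are treated as missing, not as true zeros, since the
    background never measures exactly zero.

    Columns are cell_ids for single-cell channels and ``set/channel`` for the
    carrier, empty, and reference channels.
    """
    recs = [r for r in records if r.set_id == design.set_id]
    agg: dict[str, np.ndarray] = {}
    prot: dict[str, str] = {}
    for r in recs:
        row = np.array([r.reporter_intensity.get(c, 0.0) for c in design.channels])
        if r.peptide_sequence in agg:
            agg[r.peptide_sequence] = agg[r.peptide_sequence] + row
        else:
            agg[r.peptide_sequence] = row
            prot[r.peptide_sequence] = r.razor_protein
    values = pd.DataFrame.from_dict(agg, orient="index", columns=design.channels)
    values = values.where(values > 0)  # zeros -> missing

    col_ids, meta_rows = [], []
    for chan in design.channels:
        role = design.roles[chan]
        if role == "single_cell":
            ann = design.cells[chan]
            col_ids.append(ann.cell_id)
            meta_rows.append(
                {"set_id": design.set_id, "channel": chan, "role": role,
                 "cell_type": ann.cell_type, "day": ann.day}
            )
        else:
            col_ids.append(f"{design.set_id}/{chan}")
            meta_rows.append(
                {"set_id": design.set_id, "channel": chan, "role": role,
                 "cell_type": None, "day": None}
            )
    values.columns = col_ids
    col_meta = pd.DataFrame(meta_rows, index=col_ids)
    m = QuantMatrix(values=values, level="peptide", col_meta=col_meta)
    m.peptide_to_protein = prot  # carried alongside for the rollup
    return m


def channel_median_normalize(m: QuantMatrix) -> QuantMatrix:
    """Set the median of each channel (column) over observed entries to one."""
    medians = m.values.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()]
    if len(dead):
        raise NormalizationError(f"channel(s) with no observed entries: {list(dead)}")
    out = replace(
        m,
        values=m.values.div(medians, axis=1),
        normalization_state=m.normalization_state + ["channel_median"],
    )
    if hasattr(m, "peptide_to_protein"):
        out.peptide_to_protein = m.peptide_to_protein
    return out


def peptide_vector_normalize(m: QuantMatrix, center: str = "mean") -> QuantMatrix:
    """Divide each feature's vector across cells by its mean or median over
    observed entries, leaving relative levels."""
    if center == "mean":
        c = m.values.mean(axis=1, skipna=True)
    elif center == "median":
        c = m.values.median(axis=1, skipna=True)
    else:
        raise ValueError("center must be 'mean' or 'median'")
    dead = c.index[c.isna()]
    if len(dead):
        raise NormalizationError(f"feature(s) with no observed entries: {list(dead[:5])}")
    out = replace(
        m,
        values=m.values.div(c, axis=0),
        normalization_state=m.normalization_state + [f"row_{center}"],
    )
    if hasattr(m, "peptide_to_protein"):
        out.peptide_to_protein = m.peptide_to_protein
    return out


def rollup_to_proteins(m: QuantMatrix, peptide_to_protein: dict[str, str]) -> QuantMatrix:
    """Roll peptide relative levels up to razor proteins by the median.

    A protein's value in a cell is the median over its peptides observed in
    that cell; it is missing iff no peptide is observed. Peptides absent from
    the mapping are dropped and reported.
    """
    if m.level != "peptide":
        raise ValueError("rollup requires a peptide-level matrix")
    unmapped = [p for p in m.values.index if p not in peptide_to_protein]
    if unmapped:
        logger.warning("rollup: %d peptide(s) without a protein mapping dropped", len(unmapped))
    mapped = m.values.drop(index=unmapped)
    groups = pd.Series({p: peptide_to_protein[p] for p in mapped.index})
    values = mapped.groupby(groups).median()
    return QuantMatrix(
        values=values,
        level="protein",
        col_meta=m.col_meta.copy(),
        normalization_state=m.normalization_state + ["protein_median_rollup"],
    )


def combine_sets_carrier_reference(
    mats: list[QuantMatrix], designs: dict[str, ChannelDesign]
) -> QuantMatrix:
    """Combine TMT sets using the (shared) carrier channel as reference.

    Each single-cell value is divided by the same peptide's carrier value in
    its set; peptides missing from a set are missing for that set's cells.
    """
    pieces, metas = [], []
    for m in mats:
        set_id = m.col_meta["set_id"].iloc[0]
        design = designs[set_id]
        carrier_col = f"{set_id}/{design.carrier_channel}"
        if carrier_col not in m.values.columns:
            raise DesignError(f"set {set_id}: carrier column absent from matrix")
        sc_cols = m.col_meta.index[m.col_meta["role"] == "single_cell"]
        carrier = m.values[carrier_col]
        vals = m.values[sc_cols].div(carrier, axis=0)
        pieces.append(vals)
        metas.append(m.col_meta.loc[sc_cols])
    values = pd.concat(pieces, axis=1)  # outer join on peptides
    col_meta = pd.concat(metas, axis=0)
    state = list(mats[0].normalization_state) + ["carrier_reference_combine"]
    return QuantMatrix(values=values, level=mats[0].level, col_meta=col_meta,
                       normalization_state=state)


def combine_sets_balanced(
    mats: list[QuantMatrix], designs: dict[str, ChannelDesign]
) -> QuantMatrix:
    """Combine sets without a shared carrier: per set, scale each peptide to
    mean 1 across its observed single-cell entries, then concatenate.

    Valid when the cell-type composition of each set is balanced; imbalance
    triggers a warning, not an error.
    """
    pieces, metas = [], []
    for m in mats:
        sc_cols = m.col_meta.index[m.col_meta["role"] == "single_cell"]
        comp = Counter(m.col_meta.loc[sc_cols, "cell_type"])
        if len(set(comp.values())) > 1:
            warnings.warn(
                f"set {m.col_meta['set_id'].iloc[0]}: unbalanced composition {dict(comp)}",
                stacklevel=2,
            )
        vals = m.values[sc_cols]
        vals = vals.div(vals.mean(axis=1, skipna=True), axis=0)
        pieces.append(vals)
        metas.append(m.col_meta.loc[sc_cols])
    values = pd.concat(pieces, axis=1)
    col_meta = pd.concat(metas, axis=0)
    state = list(mats[0].normalization_state) + ["balanced_mean1_combine"]
    return QuantMatrix(values=values, level=mats[0].level, col_meta=col_meta,
                       normalization_state=state)


def _cosine_similarity_pairwise(values: pd.DataFrame) -> np.ndarray:
    """Cosine similarity between columns over jointly observed features.

    Entry (c, d) uses only features observed in both c and d; NaN where the
    joint support is empty or a joint norm vanishes.
    """
    X = values.to_numpy(dtype=float)
    M = np.isfinite(X)
    A = np.where(M, X, 0.0)
    num = A.T @ A
    # joint-restricted squared norms: (c,d) -> sum_f A[f,c]^2 * M[f,d]
    P = (A**2).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = num / np.sqrt(P * P.T)
    # one shared feature: the cosine is exactly the sign of the product
    joint = M.astype(np.int64).T @ M.astype(np.int64)
    single = joint == 1
    sim[single] = np.sign(num[single])
    return np.clip(sim, -1.0, 1.0)


def impute_knn(m: QuantMatrix, k: int = 1) -> QuantMatrix:
    """Fill missing entries from the k most similar cells (cosine similarity
    between proteome vectors over jointly observed features).

    For each missing entry (f, c), donors are the cells with f observed,
    ranked by similarity to c; the fill is the unweighted mean of the top k
    donors. Entries with no eligible donor stay missing and are reported.
    The returned matrix marks filled entries in ``imputed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.values.shape[1] < 2:
        raise ValueError("imputation needs at least 2 cells")
    sim = _cosine_similarity_pairwise(m.values)
    np.fill_diagonal(sim, -np.inf)
    X = m.values.to_numpy(dtype=float).copy()
    obs = np.isfinite(X)
    filled = np.zeros_like(obs)
    n_unfillable = 0
    n_cells = X.shape[1]
    # deterministic donor order: similarity desc, then column order asc
    order_per_cell = []
    for c in range(n_cells):
        s = sim[:, c]
        eligible = np.flatnonzero(np.isfinite(s))
        order = eligible[np.lexsort((eligible, -s[eligible]))]
        order_per_cell.append(order)
    for f, c in zip(*np.where(~obs)):
        donors = [d for d in order_per_cell[c] if obs[f, d]][:k]
        if donors:
            X[f, c] = X[f, donors].mean()
            filled[f, c] = True
        else:
            n_unfillable += 1
    if n_unfillable:
        logger.warning("impute_knn: %d entr(ies) had no eligible donor", n_unfillable)
    values = pd.DataFrame(X, index=m.values.index, columns=m.values.columns)
    values = values.where(obs | filled)
    imputed = pd.DataFrame(filled, index=m.values.index, columns=m.values.columns)
    return replace(
        m,
        values=values,
        imputed=imputed,
        normalization_state=m.normalization_state + [f"knn_impute_k{k}"],
    )


@dataclass
class SnrReport:
    """Signal-to-noise diagnostics from the empty-channel control.

    Background is the median empty-channel reporter intensity; SNR per channel
    is that channel's median reporter intensity divided by the background.
    """

    set_id: str
    background: float
    median_per_channel: dict[str, float]
    snr_per_channel: dict[str, float]
    n_peptides_used: int

    @property
    def single_cell_snr(self) -> float:
        return float(np.median(list(self.snr_per_channel.values())))


def estimate_snr(
    records: list[PeptideEvidence], designs: dict[str, ChannelDesign]
) -> dict[str, SnrReport]:
    """Per-set SNR reports from the empty 130N-style control channel.

    The empty channel receives only background noise plus isotopic
    cross-contamination from the adjacent channel, so its median intensity
    estimates the noise floor of the measurement. Refuses sets whose design
    declares no empty channel.
    """
    by_set: dict[str, list[PeptideEvidence]] = defaultdict(list)
    for r in records:
        by_set[r.set_id].append(r)
    reports: dict[str, SnrReport] = {}
    for set_id, recs in by_set.items():
        design = designs[set_id]
        if design.empty_channel is None:
            raise DesignError(
                f"set {set_id}: SNR diagnostics need an empty channel; none declared"
            )
        empty = np.array([r.reporter_intensity.get(design.empty_channel, np.nan) for r in recs])
        empty = empty[np.isfinite(empty) & (empty > 0)]
        if empty.size == 0:
            raise DesignError(f"set {set_id}: empty channel has no usable intensities")
        background = float(np.median(empty))
        med, snr = {}, {}
        for chan in design.single_cell_channels:
            v = np.array([r.reporter_intensity.get(chan, np.nan) for r in recs])
            v = v[np.isfinite(v) & (v > 0)]
            if v.size == 0:
                continue
            med[chan] = float(np.median(v))
            snr[chan] = med[chan] / background
        reports[set_id] = SnrReport(
            set_id=set_id,
            background=background,
            median_per_channel=med,
            snr_per_channel=snr,
            n_peptides_used=len(recs),
        )
    return reports


def distribute_precursor_area(
    record: PeptideEvidence, design: ChannelDesign
) -> dict[str, float] | None:
    """Split one peptide's precursor area over the single-cell channels in
    proportion to their reporter-ion shares. None when the total RI is zero."""
    chans = design.single_cell_channels
    ri = np.array([record.reporter_intensity.get(c, 0.0) for c in chans])
    total = ri.sum()
    if total <= 0:
        return None
    shares = ri / total
    cells = [design.cells[c].cell_id for c in chans]
    return dict(zip(cells, record.precursor_area * shares))


def protein_abundance_from_precursor(
    records: list[PeptideEvidence], designs: dict[str, ChannelDesign]
) -> pd.DataFrame:
    """Absolute-scale protein abundance estimates per cell.

    Each peptide's integrated precursor area is distributed over cells
    according to reporter-ion shares; a protein's abundance in a cell is the
    median over its peptides' distributed areas. Peptides with zero total
    reporter signal are skipped. Used for abundance-distribution summaries.
    """
    per_protein: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for r in records:
        dist = distribute_precursor_area(r, designs[r.set_id])
        if dist is None:
            continue
        for cell, a in dist.items():
            per_protein[r.razor_protein][cell].append(a)
    out = {
        prot: {cell: float(np.median(v)) for cell, v in cells.items()}
        for prot, cells in per_protein.items()
    }
    return pd.DataFrame.from_dict(out, orient="index").sort_index()


def write_matrix(m: QuantMatrix, prefix) -> None:
    """Write values, observed mask, and column metadata as TSV (``<prefix>.tsv``,
    ``<prefix>.mask.tsv``, ``<prefix>.cols.tsv``)."""
    prefix = str(prefix)
    m.values.to_csv(prefix + ".tsv", sep="\t")
    m.observed_mask.astype(int).to_csv(prefix + ".mask.tsv", sep="\t")
    meta = m.col_meta.copy()
    meta.index.name = "column"
    meta.to_csv(prefix + ".cols.tsv", sep="\t")


def read_matrix(prefix, level: str) -> QuantMatrix:
    prefix = str(prefix)
    values = pd.read_csv(prefix + ".tsv", sep="\t", index_col=0)
    mask = pd.read_csv(prefix + ".mask.tsv", sep="\t", index_col=0).astype(bool)
    col_meta = pd.read_csv(prefix + ".cols.tsv", sep="\t", index_col=0)
    imputed = values.notna() & ~mask
    return QuantMatrix(values=values, level=level, col_meta=col_meta,
                       imputed=imputed if imputed.any().any() else None)
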