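"""Synthetic single-cell TMT experiments with known ground truth.

The generator emulates the carrier-channel single-cell TMT measurement model:

* a ~200-cell-equivalent carrier channel that dominates precursor signal and
  drives which peptides are selected for MS2 (shotgun selection is an
  increasing, logistic function of carrier intensity — so detection is
  abundance-dependent and missingness is informative);
* one deliberately empty channel that measures background noise plus isotopic
  cross-contamination from the adjacent 131 channel;
* eight single-cell channels whose reporter intensities are (cell equivalents
  x true abundance x peptide ionization efficiency) + background noise;
* identification confidence (PEP) that degrades with total precursor signal.

Ground truth is a log-normal protein abundance landscape (most proteins above
~5 x 10^4 copies per cell) with planted structure the pipeline should recover:
correlated protein modules (a shared latent factor per module), cell-type
marker fold changes, and per-cell log-normal noise.

The background level is not a free dial: it is calibrated per set so that the
median single-cell reporter intensity over detected peptides divided by the
median empty-channel intensity equals ``snr_target`` — the same statistic the
SNR diagnostic measures downstream.

All randomness flows from a single seed; identical configurations reproduce
bit-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import CellAnnotation, ChannelDesign, DesignError, make_tmt10_design
from .evidence import PeptideEvidence

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQSTVWY"))


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment; defaults are the study
    conditions the generator emulates (TMT-10 sets, ~200-cell carrier, empty
    130N channel, single-cell signal ~10x background)."""

    n_sets: int = 4
    n_proteins: int = 200
    mean_peptides_per_protein: float = 3.0
    carrier_cell_equivalents: float = 200.0
    snr_target: float = 10.0
    background_noise_level: float | None = None  # None: calibrate to snr_target
    background_noise_cv: float = 0.4  # lognormal sigma of the background draws
    impurity_131_to_130N: float = 0.04
    detection_slope: float = 1.5  # per natural-log unit of carrier intensity
    detection_quantile: float = 0.3  # midpoint of the logistic selection curve
    pep_intercept: float = -4.0
    pep_slope: float = 1.2
    pep_noise_sd: float = 0.5
    ionization_sd: float = 1.0  # lognormal sigma of peptide ionization efficiency
    precursor_efficiency: float = 0.5
    n_cells: int | None = None  # default: 8 per set
    cell_types: tuple[str, ...] = ("A", "B")
    days: tuple[int, ...] = (0,)
    baseline_log2_mean: float = 17.6  # ~2e5 copies per cell
    baseline_log2_sd: float = 2.0
    n_modules: int = 10
    module_factor_sd: float = 0.7  # log2 units
    noise_sd: float = 0.35  # per-cell log2 noise
    n_markers_per_direction: int = 20
    marker_log2_fc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sets", "n_proteins", "n_modules"):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive")
        if not (0.0 <= self.impurity_131_to_130N < 1.0):
            raise SimulationConfigError("impurity_131_to_130N must be in [0, 1)")
        if not (0.0 < self.detection_quantile < 1.0):
            raise SimulationConfigError("detection_quantile must be in (0, 1)")
        if self.snr_target <= 1.0:
            raise SimulationConfigError("snr_target must exceed 1")
        if self.background_noise_level is not None and self.background_noise_level < 0:
            raise SimulationConfigError("background_noise_level must be nonnegative")
        if self.mean_peptides_per_protein < 1.0:
            raise SimulationConfigError("mean_peptides_per_protein must be >= 1")
        if self.n_markers_per_direction > 0 and len(self.cell_types) < 2:
            raise SimulationConfigError("marker effects require at least 2 cell types")
        if self.total_cells % (len(self.cell_types)) != 0:
            # not fatal, but the alternating assignment is then unbalanced
            pass

    @property
    def total_cells(self) -> int:
        return self.n_cells if self.n_cells is not None else self.n_sets * 8


@dataclass
class GroundTruth:
    """Latent quantities the pipeline estimates, plus all generative
    parameters for recovery tests."""

    protein_ids: list[str]
    cell_ids: list[str]
    cell_type: pd.Series
    day: pd.Series
    true_abundance: pd.DataFrame  # proteins x cells, copies-per-cell scale
    module_assignment: pd.Series
    marker_effects: pd.Series  # log2 fold change (type B relative to type A)
    peptides: dict[str, list[str]]
    generative_params: dict = field(default_factory=dict)


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 20))
    body = "".join(rng.choice(AMINO_ACIDS, size=length))
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw per-cell true protein abundances with planted modules and markers.

    Log2 abundance = protein baseline (normal across proteins)
    + module_factor_sd x shared per-module latent factor (per cell)
    + marker effect for cells of the second cell type
    + noise_sd x independent per-(protein, cell) noise.
    """
    rng = np.random.default_rng(config.seed)
    P, C = config.n_proteins, config.total_cells
    protein_ids = [f"P{i:04d}" for i in range(P)]
    cell_ids = [f"cell{i:03d}" for i in range(C)]
    types = [config.cell_types[i % len(config.cell_types)] for i in range(C)]
    days = [int(config.days[(i // 8) % len(config.days)]) for i in range(C)]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=P)
    modules = rng.integers(0, config.n_modules, size=P)
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, C))

    marker = np.zeros(P)
    n_mark = config.n_markers_per_direction
    if n_mark > 0:
        if 2 * n_mark > P:
            raise SimulationConfigError("more markers requested than proteins")
        chosen = rng.choice(P, size=2 * n_mark, replace=False)
        marker[chosen[:n_mark]] = config.marker_log2_fc
        marker[chosen[n_mark:]] = -config.marker_log2_fc

    is_type_b = np.array([t == config.cell_types[-1] for t in types], dtype=float)
    noise = rng.normal(0.0, 1.0, size=(P, C))
    log2_abund = (
        baseline[:, None]
        + config.module_factor_sd * factors[modules, :]
        + np.outer(marker, is_type_b)
        + config.noise_sd * noise
    )
    abund = pd.DataFrame(2.0**log2_abund, index=protein_ids, columns=cell_ids)

    pep_rng = np.random.default_rng([config.seed, 7])
    peptides: dict[str, list[str]] = {}
    seen: set[str] = set()
    for prot in protein_ids:
        n_pep = 1 + int(pep_rng.poisson(max(config.mean_peptides_per_protein - 1.0, 0.0)))
        seqs = []
        for _ in range(n_pep):
            s = _random_peptide(pep_rng)
            while s in seen:
                s = _random_peptide(pep_rng)
            seen.add(s)
            seqs.append(s)
        peptides[prot] = seqs

    return GroundTruth(
        protein_ids=protein_ids,
        cell_ids=cell_ids,
        cell_type=pd.Series(types, index=cell_ids, name="cell_type"),
        day=pd.Series(days, index=cell_ids, name="day"),
        true_abundance=abund,
        module_assignment=pd.Series(modules, index=protein_ids, name="module"),
        marker_effects=pd.Series(marker, index=protein_ids, name="marker_log2_fc"),
        peptides=peptides,
        generative_params=asdict(config),
    )


def _set_rng(config: SimulationConfig, set_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(set_id.encode())])


def simulate_set(
    truth: GroundTruth,
    design: ChannelDesign,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[PeptideEvidence]:
    """Simulate one TMT set's peptide evidence under the measurement model.

    Reporter intensity in channel c is (cell equivalents x true abundance x
    peptide ionization efficiency) + background; the empty channel receives
    background plus ``impurity_131_to_130N`` times the 131-channel signal.
    Detection is Bernoulli with logistic probability in log carrier intensity;
    PEP decreases logistically with log total signal. Deterministic given the
    configuration seed and set_id.
    """
    if design.carrier_channel is None:
        raise DesignError(f"set {design.set_id}: simulation requires a carrier channel")
    unknown_cells = [c for c in design.cell_ids if c not in truth.true_abundance.columns]
    if unknown_cells:
        raise DesignError(f"set {design.set_id}: cells not in truth: {unknown_cells}")
    if rng is None:
        rng = _set_rng(config, design.set_id)

    pep_seqs, pep_prot = [], []
    for prot in truth.protein_ids:
        for seq in truth.peptides[prot]:
            pep_seqs.append(seq)
            pep_prot.append(prot)
    n_pep = len(pep_seqs)
    channels = design.channels
    n_chan = len(channels)

    A = truth.true_abundance
    carrier_profile = A.mean(axis=1).to_numpy()  # carrier = mixed cells
    prot_idx = pd.Index(truth.protein_ids).get_indexer(pep_prot)

    efficiency = np.exp(rng.normal(0.0, config.ionization_sd, size=n_pep))

    signal = np.zeros((n_pep, n_chan))
    for j, chan in enumerate(channels):
        role = design.roles[chan]
        if role == "carrier":
            prof = config.carrier_cell_equivalents * carrier_profile[prot_idx]
        elif role == "single_cell":
            prof = A[design.cells[chan].cell_id].to_numpy()[prot_idx]
        else:  # empty or unused reference: no labeled material
            prof = np.zeros(n_pep)
        signal[:, j] = prof * efficiency

    # shotgun MS2 selection driven by carrier intensity
    carrier_j = channels.index(design.carrier_channel)
    log_carrier = np.log(signal[:, carrier_j])
    threshold = np.quantile(log_carrier, config.detection_quantile)
    if np.isinf(config.detection_slope):
        p_detect = (log_carrier > threshold).astype(float)
    else:
        p_detect = expit(config.detection_slope * (log_carrier - threshold))
    detected = rng.random(n_pep) < p_detect
    if not detected.any():
        return []

    sc_j = [channels.index(c) for c in design.single_cell_channels]
    empty_chan = design.empty_channel
    bg_unit = np.exp(rng.normal(0.0, config.background_noise_cv, size=(n_pep, n_chan)))

    impurity_source = signal[:, channels.index("131")] if (
        "131" in channels and empty_chan == "130N"
    ) else np.zeros(n_pep)

    # calibrate the background level so the measured SNR statistic hits target
    det = detected
    sc_signal = signal[np.ix_(det, sc_j)]
    med_sc_nf = float(np.median(sc_signal))
    if config.background_noise_level is not None:
        b_level = float(config.background_noise_level)
    elif empty_chan is not None and med_sc_nf > 0:
        empty_j = channels.index(empty_chan)

        def snr_gap(b: float) -> float:
            num = np.median(sc_signal + b * bg_unit[np.ix_(det, sc_j)])
            den = np.median(b * bg_unit[det, empty_j]
                            + config.impurity_131_to_130N * impurity_source[det])
            return num / den - config.snr_target

        lo, hi = 1e-9 * med_sc_nf, 100.0 * med_sc_nf
        if snr_gap(lo) > 0 > snr_gap(hi):
            b_level = float(brentq(snr_gap, lo, hi, xtol=1e-12 * med_sc_nf))
        else:  # impurity alone already exceeds the target noise budget
            b_level = lo
    else:
        b_level = 0.0

    background = b_level * bg_unit
    intensity = signal + background
    if empty_chan is not None:
        empty_j = channels.index(empty_chan)
        intensity[:, empty_j] = (
            background[:, empty_j] + config.impurity_131_to_130N * impurity_source
        )

    total = intensity.sum(axis=1)
    log_total = np.log(np.maximum(total, 1e-300))
    z = (log_total - log_total[det].mean()) / max(log_total[det].std(), 1e-12)
    pep_val = expit(
        config.pep_intercept
        - config.pep_slope * z
        + config.pep_noise_sd * rng.normal(size=n_pep)
    )
    pep_val = np.clip(pep_val, 1e-6, 0.999)
    area = config.precursor_efficiency * total
    charges = rng.integers(2, 4, size=n_pep)

    records: list[PeptideEvidence] = []
    for i in np.flatnonzero(det):
        records.append(
            PeptideEvidence(
                set_id=design.set_id,
                peptide_sequence=pep_seqs[i],
                razor_protein=pep_prot[i],
                pep=float(pep_val[i]),
                precursor_area=float(area[i]),
                reporter_intensity={
                    chan: float(intensity[i, j]) for j, chan in enumerate(channels)
                },
                charge=int(charges[i]),
            )
        )
    return records


def make_designs(truth: GroundTruth, config: SimulationConfig) -> dict[str, ChannelDesign]:
    """Standard TMT-10 designs: 8 consecutive cells per set, carrier on 126,
    empty 130N."""
    designs: dict[str, ChannelDesign] = {}
    n_sets = int(np.ceil(len(truth.cell_ids) / 8))
    for s in range(n_sets):
        cells = truth.cell_ids[8 * s : 8 * (s + 1)]
        anns = [
            CellAnnotation(cell_id=c, cell_type=truth.cell_type[c], day=int(truth.day[c]))
            for c in cells
        ]
        set_id = f"set{s + 1}"
        designs[set_id] = make_tmt10_design(set_id, anns)
    return designs


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[GroundTruth, dict[str, ChannelDesign], list[PeptideEvidence]]:
    """Truth + designs + evidence for a whole multi-set experiment."""
    truth = simulate_truth(config)
    designs = make_designs(truth, config)
    records: list[PeptideEvidence] = []
    for design in designs.values():
        records.extend(simulate_set(truth, design, config))
    return truth, designs, records


def simulate_mrna(
    truth: GroundTruth, capture_rate: float, depth: int, seed: int
) -> pd.DataFrame:
    """Paired mRNA counts: Poisson sampling of the shared true abundances.

    The expected count of gene g in cell c is proportional to its true
    abundance, scaled so the expected total per cell is ``capture_rate x
    depth``. Deterministic given the seed.
    """
    if not (0.0 < capture_rate <= 1.0):
        raise SimulationConfigError("capture_rate must be in (0, 1]")
    if depth <= 0:
        raise SimulationConfigError("depth must be positive")
    rng = np.random.default_rng(seed)
    A = truth.true_abundance.to_numpy()
    scale = depth / A.sum(axis=0).mean()
    lam = capture_rate * A * scale
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=truth.protein_ids, columns=truth.cell_ids)


def write_truth(truth: GroundTruth, prefix) -> None:
    """Ground truth as delimited tables plus a JSON parameters file."""
    prefix = str(prefix)
    truth.true_abundance.to_csv(prefix + ".abundance.tsv", sep="\t")
    cells = pd.DataFrame({"cell_type": truth.cell_type, "day": truth.day})
    cells.index.name = "cell_id"
    cells.to_csv(prefix + ".cells.tsv", sep="\t")
    prots = pd.DataFrame(
        {"module": truth.module_assignment, "marker_log2_fc": truth.marker_effects}
    )
    prots.index.name = "protein_id"
    prots.to_csv(prefix + ".proteins.tsv", sep="\t")
    with open(prefix + ".params.json", "w", encoding="utf-8") as fh:
        json.dump(truth.generative_params, fh, indent=2, default=str)
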