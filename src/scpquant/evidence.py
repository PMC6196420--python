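"""Reading and writing MaxQuant-style peptide evidence tables.

One row per peptide (or PSM) per TMT set: sequence, razor protein, posterior
error probability (PEP), integrated precursor-ion area, and one reporter-ion
intensity per channel. Two reporter-column dialects are accepted: positional
("Reporter intensity 0" ... bound to channels by the design's declared order)
and explicit channel labels ("Reporter intensity 126", ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .design import ChannelDesign

logger = logging.getLogger(__name__)

SET_COL = "Raw file"
SEQ_COL = "Sequence"
PROT_COL = "Leading razor protein"
PEP_COL = "PEP"
AREA_COL = "Intensity"
CHARGE_COL = "Charge"


class EvidenceFormatError(ValueError):
    """The evidence file does not match the expected dialect."""


@dataclass
class PeptideEvidence:
    """One identified peptide in one TMT set."""

    set_id: str
    peptide_sequence: str
    razor_protein: str
    pep: float
    precursor_area: float
    reporter_intensity: dict[str, float] = field(default_factory=dict)
    charge: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pep <= 1.0):
            raise ValueError(f"PEP {self.pep} outside [0, 1] for {self.peptide_sequence}")
        if not self.razor_protein:
            raise ValueError(f"empty razor protein for {self.peptide_sequence}")
        if self.precursor_area < 0:
            raise ValueError("negative precursor area")
        for chan, v in self.reporter_intensity.items():
            if v < 0:
                raise ValueError(f"negative reporter intensity in channel {chan}")


def _reporter_columns(header: list[str], design: ChannelDesign) -> dict[str, str]:
    """Map design channel labels to reporter column names, accepting either the
    positional or the label dialect. Raises on a channel-count mismatch."""
    by_label = {c: f"Reporter intensity {c}" for c in design.channels}
    if all(col in header for col in by_label.values()):
        return by_label
    positional = [c for c in header if c.startswith("Reporter intensity ")]

    def _pos_key(col: str):
        suffix = col.rsplit(" ", 1)[1]
        return int(suffix) if suffix.isdigit() else None

    positional = sorted(
        (c for c in positional if _pos_key(c) is not None), key=_pos_key
    )
    if len(positional) != len(design.channels):
        raise EvidenceFormatError(
            f"found {len(positional)} positional reporter columns, design declares "
            f"{len(design.channels)} channels"
        )
    return dict(zip(design.channels, positional))


def read_evidence(path, design: ChannelDesign) -> list[PeptideEvidence]:
    """Read a tab-separated evidence table into :class:`PeptideEvidence` records.

    Reporter columns are bound to channel labels by the design's declared order
    (positional dialect) or by explicit labels. Rows with unparseable numerics
    or PEP outside [0, 1] are dropped; the rejection count is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (SET_COL, SEQ_COL, PROT_COL, PEP_COL, AREA_COL):
        if col not in df.columns:
            raise EvidenceFormatError(f"missing mandatory column {col!r}")
    colmap = _reporter_columns(list(df.columns), design)

    records: list[PeptideEvidence] = []
    n_rejected = 0
    for row in df.itertuples(index=False, name=None):
        # itertuples mangles column names with spaces; zip against the header
        d = dict(zip(df.columns, row))
        try:
            pep = float(d[PEP_COL])
            area = float(d[AREA_COL])
            ri = {chan: float(d[col]) for chan, col in colmap.items()}
            if not all(math.isfinite(v) for v in [pep, area, *ri.values()]):
                raise ValueError("non-finite numeric")
            charge_s = d.get(CHARGE_COL, "")
            charge = int(charge_s) if charge_s not in ("", None) else None
            rec = PeptideEvidence(
                set_id=str(d[SET_COL]),
                peptide_sequence=str(d[SEQ_COL]),
                razor_protein=str(d[PROT_COL]),
                pep=pep,
                precursor_area=area,
                reporter_intensity=ri,
                charge=charge,
            )
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("read_evidence: rejected %d unparseable row(s) from %s", n_rejected, path)
    return records


def write_evidence(records: list[PeptideEvidence], path, design: ChannelDesign | None = None) -> None:
    """Write records as a tab-separated evidence table (label dialect).

    Column order is stable; round-trips losslessly through
    :func:`read_evidence` up to float text formatting.
    """
    if design is not None:
        channels = list(design.channels)
    else:
        channels = []
        for r in records:
            for c in r.reporter_intensity:
                if c not in channels:
                    channels.append(c)
    rows = []
    for r in records:
        row = {
            SET_COL: r.set_id,
            SEQ_COL: r.peptide_sequence,
            PROT_COL: r.razor_protein,
            CHARGE_COL: "" if r.charge is None else r.charge,
            PEP_COL: repr(r.pep),
            AREA_COL: repr(r.precursor_area),
        }
        for c in channels:
            row[f"Reporter intensity {c}"] = repr(r.reporter_intensity.get(c, 0.0))
        rows.append(row)
    cols = [SET_COL, SEQ_COL, PROT_COL, CHARGE_COL, PEP_COL, AREA_COL] + [
        f"Reporter intensity {c}" for c in channels
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
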