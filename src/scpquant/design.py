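"""TMT channel designs: which channel holds the carrier, the empty control, and
which single cell.

A SCoPE-MS TMT-10 set dedicates one channel to a ~200-cell carrier (supplies
ions for identification), leaves 130N empty as a background/cross-contamination
control, and distributes single cells over the remaining eight channels. The
design file maps channel labels to these roles and annotates each single-cell
channel with a cell identity, cell type, and differentiation day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

#: TMT-10 reporter channel labels in mass order.
TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

ROLES = frozenset({"carrier", "single_cell", "empty", "reference"})


class DesignError(ValueError):
    """A channel design violates its structural invariants."""


@dataclass(frozen=True)
class CellAnnotation:
    cell_id: str
    cell_type: str
    day: int = 0


@dataclass
class ChannelDesign:
    """Per-set mapping of TMT channel labels to roles and cell annotations.

    Parameters
    ----------
    set_id : str
        Identifier of the TMT set.
    channels : list of str
        Ordered channel labels; the order defines how positional reporter
        columns ("Reporter intensity 0" ...) bind to channels.
    roles : dict
        Channel label -> one of {"carrier", "single_cell", "empty", "reference"}.
    cells : dict
        Single-cell channel label -> :class:`CellAnnotation`.
    """

    set_id: str
    channels: list[str]
    roles: dict[str, str]
    cells: dict[str, CellAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise DesignError(f"set {self.set_id}: duplicate channel labels")
        unknown = set(self.roles) - set(self.channels)
        if unknown:
            raise DesignError(f"set {self.set_id}: roles for undeclared channels {sorted(unknown)}")
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise DesignError(f"set {self.set_id}: unknown role(s) {sorted(bad)}")
        missing_role = [c for c in self.channels if c not in self.roles]
        if missing_role:
            raise DesignError(f"set {self.set_id}: channels without a role: {missing_role}")
        if len(self.carrier_channels) > 1:
            raise DesignError(f"set {self.set_id}: more than one carrier channel")
        if len(self.empty_channels) > 1:
            raise DesignError(f"set {self.set_id}: more than one empty channel")
        stray = set(self.cells) - set(self.single_cell_channels)
        if stray:
            raise DesignError(
                f"set {self.set_id}: cell annotations on non-single-cell channels {sorted(stray)}"
            )
        unannotated = [c for c in self.single_cell_channels if c not in self.cells]
        if unannotated:
            raise DesignError(f"set {self.set_id}: single-cell channels lack annotations: {unannotated}")
        ids = [a.cell_id for a in self.cells.values()]
        if len(set(ids)) != len(ids):
            raise DesignError(f"set {self.set_id}: duplicate cell_ids within the set")
        if not self.single_cell_channels:
            warnings.warn(f"set {self.set_id}: design declares no single-cell channels", stacklevel=2)

    @property
    def carrier_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "carrier"]

    @property
    def carrier_channel(self) -> str:
        if not self.carrier_channels:
            raise DesignError(f"set {self.set_id}: no carrier channel declared")
        return self.carrier_channels[0]

    @property
    def empty_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "empty"]

    @property
    def empty_channel(self) -> str | None:
        return self.empty_channels[0] if self.empty_channels else None

    @property
    def single_cell_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "single_cell"]

    @property
    def cell_ids(self) -> list[str]:
        return [self.cells[c].cell_id for c in self.single_cell_channels]


def make_tmt10_design(
    set_id: str,
    cell_annotations: list[CellAnnotation],
    carrier_channel: str = "126",
    empty_channel: str | None = "130N",
) -> ChannelDesign:
    """Build the standard SCoPE-MS TMT-10 layout: one carrier, empty 130N,
    single cells on the remaining channels (up to eight)."""
    channels = list(TMT10_CHANNELS)
    roles: dict[str, str] = {}
    roles[carrier_channel] = "carrier"
    if empty_channel is not None:
        roles[empty_channel] = "empty"
    sc_channels = [c for c in channels if c not in roles]
    if len(cell_annotations) > len(sc_channels):
        raise DesignError(
            f"set {set_id}: {len(cell_annotations)} cells but only {len(sc_channels)} free channels"
        )
    cells: dict[str, CellAnnotation] = {}
    for chan, ann in zip(sc_channels, cell_annotations):
        roles[chan] = "single_cell"
        cells[chan] = ann
    # channels left over (short sets) are treated as reference/unused
    for chan in channels:
        roles.setdefault(chan, "reference")
    return ChannelDesign(set_id=set_id, channels=channels, roles=roles, cells=cells)


def read_design(path) -> dict[str, ChannelDesign]:
    """Read a YAML design file into one :class:`ChannelDesign` per set.

    Expected layout::

        sets:
          - set_id: set1
            channels: [126, 127N, ...]
            roles: {126: carrier, 130N: empty, 127N: single_cell, ...}
            cells:
              127N: {cell_id: c01, cell_type: A, day: 0}

    Invariant violations raise :class:`DesignError` naming the set and channel.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sets" not in doc:
        raise DesignError("design file must contain a top-level 'sets' list")
    designs: dict[str, ChannelDesign] = {}
    for entry in doc["sets"]:
        set_id = str(entry["set_id"])
        channels = [str(c) for c in entry["channels"]]
        roles = {str(k): str(v) for k, v in entry.get("roles", {}).items()}
        cells = {
            str(chan): CellAnnotation(
                cell_id=str(ann["cell_id"]),
                cell_type=str(ann["cell_type"]),
                day=int(ann.get("day", 0)),
            )
            for chan, ann in (entry.get("cells") or {}).items()
        }
        if set_id in designs:
            raise DesignError(f"duplicate set_id {set_id!r} in design file")
        designs[set_id] = ChannelDesign(set_id=set_id, channels=channels, roles=roles, cells=cells)
    return designs


def write_design(designs: dict[str, ChannelDesign], path) -> None:
    doc = {
        "sets": [
            {
                "set_id": d.set_id,
                "channels": list(d.channels),
                "roles": dict(d.roles),
                "cells": {
                    chan: {"cell_id": a.cell_id, "cell_type": a.cell_type, "day": a.day}
                    for chan, a in d.cells.items()
                },
            }
            for d in designs.values()
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
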