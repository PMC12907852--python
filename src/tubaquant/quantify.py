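"""Spike-in normalization: read tallies -> absolute neoplastic cell numbers.

Each sample receives three benchmark spike-ins of ~1e5 cells; dividing a
pileup's reads by the median read count of those three barcodes and
multiplying by the known cell number converts reads to cells.  The three
100-cell spike-ins are sensitivity controls only and never normalize.
A 400-cell minimum size cutoff is applied after error filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .extract import Pileup
from .pool import PoolDesign
from .sim import SpikeInSet


@dataclass
class QuantConfig:
    min_cells: float = 400.0
    spikein_reference_cells: float = 1e5

    def __post_init__(self) -> None:
        if self.min_cells <= 0 or self.spikein_reference_cells <= 0:
            raise ValueError("min_cells and spikein_reference_cells must be > 0")


@dataclass(frozen=True)
class TumorCall:
    mouse_id: str
    sgRNA_name: str
    target_gene: str
    barcode: str
    reads: int
    cells: float


@dataclass
class SpikeInReadout:
    """Observed reads of every detected spike-in barcode in one sample."""

    reads_by_label: dict[str, int] = field(default_factory=dict)
    normalizer_median: float = float("nan")


def spikein_normalize(
    pileups: Sequence[Pileup],
    spikeins: SpikeInSet,
    config: QuantConfig | None = None,
    pool: PoolDesign | None = None,
) -> tuple[list[TumorCall], SpikeInReadout, list[Pileup]]:
    """Convert pileup read tallies to absolute cell numbers.

    cells = reads / median(reads of the three high spike-ins) x 1e5.
    All high spike-ins must survive into ``pileups``; a missing one makes
    the sample unquantifiable (hard failure naming the missing labels).
    Spike-in pileups and pileups whose sgID is not in the pool design are
    excluded from tumor calls; the latter are returned for reporting.
    When no pool is given every sgID is accepted verbatim.

    Returns (tumor calls, spike-in readout, unrecognized pileups).
    """
    config = config or QuantConfig()
    by_barcode = {p.barcode: p for p in pileups}
    high = spikeins.high(int(config.spikein_reference_cells))
    missing = [e.label for e in high if e.barcode not in by_barcode]
    if missing or len(high) < 3:
        raise ValueError(
            "sample unquantifiable: high spike-ins missing or undetected: "
            + (", ".join(missing) if missing else f"only {len(high)} defined")
        )
    readout = SpikeInReadout()
    for e in spikeins.entries:
        if e.barcode in by_barcode:
            readout.reads_by_label[e.label] = by_barcode[e.barcode].reads
    med = float(np.median([by_barcode[e.barcode].reads for e in high]))
    readout.normalizer_median = med
    spike_barcodes = spikeins.barcodes()
    sgid_map = pool.sgid_map() if pool is not None else None
    calls: list[TumorCall] = []
    unrecognized: list[Pileup] = []
    for p in pileups:
        if p.barcode in spike_barcodes:
            continue
        if sgid_map is None:
            name, gene = p.sgID, p.sgID
        else:
            entry = sgid_map.get(p.sgID)
            if entry is None:
                unrecognized.append(p)
                continue
            name, gene = entry.sgRNA_name, entry.target_gene
        calls.append(
            TumorCall(
                p.mouse_id,
                name,
                gene,
                p.barcode,
                p.reads,
                p.reads / med * config.spikein_reference_cells,
            )
        )
    return calls, readout, unrecognized


def apply_min_cell_cutoff(
    calls: Sequence[TumorCall], config: QuantConfig | None = None
) -> tuple[list[TumorCall], int]:
    """Keep calls with cells >= min_cells (inclusive); return removal count."""
    config = config or QuantConfig()
    kept = [c for c in calls if c.cells >= config.min_cells]
    return kept, len(calls) - len(kept)
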