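"""Ground-truthed synthetic cohorts: tumors, spike-ins, and amplicon reads.

The generator emulates barcoded lentiviral amplicon sequencing: each
transduced cell clone ("tumor") carries an 8-nt sgID identifying its sgRNA
plus a 20-nt random barcode, and is sequenced as a short amplicon with the
dual barcode between two 10-nt constant flanks.  Tumor sizes follow a
log-normal body with an optional Pareto heavy tail; sgRNA effects act
multiplicatively on size (effect_multipliers) and on tumor count
(initiation_multipliers).  Six benchmark spike-ins (three of ~1e5 cells,
three of 100 cells) anchor absolute quantification.

Read errors are injected at the template level — one error draw per
amplicon molecule, shared by both mates — emulating the recurrent
(PCR-derived) errors the denoiser targets.  Single-error events are drawn
exactly per (site, class); double-error molecules are added via a
second-order term; triple-and-higher orders are neglected.
"""

from __future__ import annotations

import gzip
import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SUB_PAIRS, ErrorModel
from .extract import Pileup, revcomp
from .pool import PoolDesign

_BASES = np.array(list("ACGT"))


def _mouse_rng(seed: int, mouse_id: str, stream: int = 0) -> np.random.Generator:
    """Deterministic per-mouse RNG: the global seed is combined with a CRC
    of the mouse id and a stream index."""
    return np.random.default_rng([seed, zlib.crc32(mouse_id.encode()), stream])


@dataclass(frozen=True)
class ConstructTemplate:
    """Layout of the sequenced amplicon.

    The aligned reference is ``left_flank + N*28 + right_flank``; the full
    amplicon adds fixed primer context on both sides.
    """

    left_flank: str = "GCACTGTACG"
    right_flank: str = "TCGAGGTCAC"
    left_context: str = "ATTGCCGAAC"
    right_context: str = "GTCTGCAAGG"
    sgID_length: int = 8
    barcode_length: int = 20

    def __post_init__(self) -> None:
        if len(self.left_flank) != 10 or len(self.right_flank) != 10:
            raise ValueError("flanks must be exactly 10 nt")

    @property
    def dual_barcode_length(self) -> int:
        return self.sgID_length + self.barcode_length

    def reference(self) -> str:
        return self.left_flank + "N" * self.dual_barcode_length + self.right_flank

    def amplicon(self, dual_barcode: str) -> str:
        return self.left_context + self.left_flank + dual_barcode + self.right_flank + self.right_context


@dataclass(frozen=True)
class SpikeInEntry:
    barcode: str  # full dual barcode (sgID-like 8 nt + 20 nt)
    known_cells: int
    label: str


@dataclass
class SpikeInSet:
    """Benchmark cell lines of known number added to every sample."""

    entries: list[SpikeInEntry] = field(default_factory=list)

    def high(self, reference_cells: int) -> list[SpikeInEntry]:
        return [e for e in self.entries if e.known_cells == reference_cells]

    def barcodes(self) -> set[str]:
        return {e.barcode for e in self.entries}


def default_spikeins() -> SpikeInSet:
    """The six-benchmark default: three ~1e5-cell and three 100-cell lines
    with fixed, mutually distant barcodes."""
    high = [
        "TTGACCGTCAGATCGGTAAGCCTAGCAT",
        "CCATGGTAGCGTTACCAGTTGGCATAGC",
        "GGTACCATTACGGCTAATCCGGTTCAGA",
    ]
    low = [
        "AACGTTGCCGATACCGGATTAGCCTGTA",
        "TGCAATCGGTCCGATTACGGCCAATGTC",
        "CATGCAGTAGGCCATTAGCCGGTTACAG",
    ]
    entries = [SpikeInEntry(b, 100_000, f"SpikeHigh{i+1}") for i, b in enumerate(high)]
    entries += [SpikeInEntry(b, 100, f"SpikeLow{i+1}") for i, b in enumerate(low)]
    return SpikeInSet(entries)


@dataclass
class SimConfig:
    """Generative model of a synthetic cohort.

    Defaults describe a mid-sized study: 10 mice, ~100 tumors per sgRNA
    per mouse, a log-normal size body with median exp(6.9) ~ 1000 cells
    and sigma 1.15 on the natural-log scale, a 0.3% Pareto tail starting
    at 44.73x the body median, and sequencing depth of 0.1 reads per cell.
    """

    n_mice: int = 10
    tumors_per_sgRNA_rate: float = 100.0
    body_mu: float = 6.9
    body_sigma: float = 1.15
    tail_fraction: float = 0.003
    tail_alpha: float = 2.0
    tail_xmin_multiplier: float = 44.73
    effect_multipliers: dict[str, float] = field(default_factory=dict)
    initiation_multipliers: dict[str, float] = field(default_factory=dict)
    reads_per_cell: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumors_per_sgRNA_rate < 0 or self.reads_per_cell <= 0:
            raise ValueError("rates must be positive (tumor rate may be 0)")
        if not 0 <= self.tail_fraction < 1:
            raise ValueError("tail_fraction must be in [0, 1)")
        if self.tail_fraction > 0 and self.tail_alpha <= 1:
            raise ValueError("tail_alpha must be > 1 (finite-mean tail)")
        for d in (self.effect_multipliers, self.initiation_multipliers):
            if any(v <= 0 for v in d.values()):
                raise ValueError("multipliers must be > 0")


@dataclass(frozen=True)
class TrueTumor:
    mouse_id: str
    sgID: str
    random_barcode: str
    true_cells: int

    @property
    def dual_barcode(self) -> str:
        return self.sgID + self.random_barcode


def sample_tumors(config: SimConfig, pool: PoolDesign, mouse_id: str) -> list[TrueTumor]:
    """Draw one mouse's ground-truth tumors.

    Per sgRNA, tumor count ~ Poisson(rate x initiation multiplier); each
    size comes from the log-normal body shifted by ln(effect multiplier),
    or (with probability tail_fraction) from a Pareto above
    tail_xmin_multiplier x body median, scaled by the effect multiplier.
    Continuous sizes are floored to integer cells with a >= 1 guard.
    """
    rng = _mouse_rng(config.seed, mouse_id, stream=0)
    xmin = config.tail_xmin_multiplier * np.exp(config.body_mu)
    tumors: list[TrueTumor] = []
    for entry in pool.entries:
        effect = config.effect_multipliers.get(entry.sgRNA_name, 1.0)
        init = config.initiation_multipliers.get(entry.sgRNA_name, 1.0)
        n = rng.poisson(config.tumors_per_sgRNA_rate * init)
        if n == 0:
            continue
        in_tail = rng.random(n) < config.tail_fraction
        sizes = np.empty(n)
        n_body = int((~in_tail).sum())
        sizes[~in_tail] = rng.lognormal(config.body_mu + np.log(effect), config.body_sigma, n_body)
        n_tail = n - n_body
        if n_tail:
            sizes[in_tail] = effect * xmin * (1.0 + rng.pareto(config.tail_alpha, n_tail))
        cells = np.maximum(1, np.floor(sizes)).astype(np.int64)
        barcodes = ["".join(row) for row in rng.choice(_BASES, size=(n, 20))]
        for bc, c in zip(barcodes, cells):
            tumors.append(TrueTumor(mouse_id, entry.sgID, bc, int(c)))
    return tumors


# ---------------------------------------------------------------------------
# error injection


def _apply_events(seq: str, events: list[tuple]) -> str:
    """Apply (kind, pos, base) edits right-to-left so positions stay valid."""
    s = seq
    for kind, pos, base in sorted(events, key=lambda e: -e[1]):
        if kind == "sub":
            s = s[:pos] + base + s[pos + 1 :]
        elif kind == "del":
            s = s[:pos] + s[pos + 1 :]
        else:  # ins: insert before pos
            s = s[:pos] + base + s[pos:]
    return s


def _event_table(seq: str, model: ErrorModel) -> tuple[list[tuple], np.ndarray]:
    """Enumerate every single-error event on ``seq`` with its probability."""
    events: list[tuple] = []
    probs: list[float] = []
    for i, x in enumerate(seq):
        for pair in SUB_PAIRS:
            if x in pair:
                y = pair[1] if pair[0] == x else pair[0]
                events.append(("sub", i, y))
                probs.append(model.sub_rates[pair])
    if model.del_rate > 0:
        for i in range(len(seq)):
            events.append(("del", i, ""))
            probs.append(model.del_rate)
    if model.ins_rate > 0:
        for g in range(len(seq) + 1):
            for b in "ACGT":
                events.append(("ins", g, b))
                probs.append(model.ins_rate / 4.0)
    return events, np.asarray(probs)


def _mutate_counts(
    seq: str, n_reads: int, model: ErrorModel, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Distribute ``n_reads`` molecules of ``seq`` over error variants.

    Returns (sequence, count) with the clean sequence first.  Single-error
    counts are Binomial(n, p) per event; double-error molecules are drawn
    from the second-order term with event pairs weighted by probability.
    """
    if n_reads <= 0:
        return []
    events, probs = _event_table(seq, model)
    if not events or probs.sum() == 0:
        return [(seq, n_reads)]
    p1 = probs.sum()
    p2 = 0.5 * p1 * p1  # second-order term: molecules with two errors
    p_clean = 1.0 - p1 - p2
    if p_clean < 0:
        raise ValueError("error rates too high for the per-molecule error model")
    # one multinomial conserves reads exactly: clean | each single event | double
    counts = rng.multinomial(n_reads, np.concatenate(([p_clean], probs, [p2])))
    variants: dict[str, int] = {}
    for ev, c in zip(events, counts[1:-1]):
        if c:
            v = _apply_events(seq, [ev])
            variants[v] = variants.get(v, 0) + int(c)
    w = probs / p1
    for _ in range(int(counts[-1])):
        i, j = rng.choice(len(events), size=2, p=w)
        v = _apply_events(seq, [events[int(i)]] if i == j else [events[int(i)], events[int(j)]])
        variants[v] = variants.get(v, 0) + 1
    out = [(seq, int(counts[0]))]
    out.extend(sorted(variants.items()))
    return out


# ---------------------------------------------------------------------------
# sample simulation


def _units(
    tumors: Sequence[TrueTumor], spikeins: SpikeInSet | None
) -> list[tuple[str, str, int, bool]]:
    """(mouse-agnostic) sequencing units: (dual_barcode, label, cells, is_spike)."""
    units = [(t.dual_barcode, "", t.true_cells, False) for t in tumors]
    if spikeins is not None:
        tumor_bcs = {t.dual_barcode for t in tumors}
        for e in spikeins.entries:
            if e.barcode in tumor_bcs:
                raise ValueError(f"spike-in barcode collides with a tumor barcode: {e.label}")
            units.append((e.barcode, e.label, e.known_cells, True))
    return units


def simulate_pileups(
    tumors: Sequence[TrueTumor],
    spikeins: SpikeInSet | None,
    error_model: ErrorModel,
    reads_per_cell: float,
    seed: int,
    mouse_id: str | None = None,
) -> tuple[list[Pileup], pd.DataFrame]:
    """Fast path: generate dereplicated pileups directly, skipping FASTQ.

    Statistically matches the FASTQ route (same per-unit Poisson read
    depth and per-event error counts applied to the dual barcode), but
    does not model alignment-score dips from flank errors — every pileup
    gets mean_score_fraction 1.0.  Returns (pileups, truth table).
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be > 0")
    if not tumors and (spikeins is None or not spikeins.entries):
        raise ValueError("nothing to simulate")
    mouse = mouse_id or (tumors[0].mouse_id if tumors else "sample")
    rng = _mouse_rng(seed, mouse, stream=1)
    tally: dict[str, int] = {}
    truth_rows = []
    for dual, label, cells, is_spike in _units(tumors, spikeins):
        n = int(rng.poisson(cells * reads_per_cell))
        for variant, count in _mutate_counts(dual, n, error_model, rng):
            tally[variant] = tally.get(variant, 0) + count
        truth_rows.append(
            {
                "mouse_id": mouse,
                "sgID": dual[:8],
                "barcode": dual[8:],
                "true_cells": cells,
                "reads": n,
                "label": label,
                "is_spikein": is_spike,
            }
        )
    pileups = [Pileup(mouse, bc, n) for bc, n in sorted(tally.items()) if n > 0]
    return pileups, pd.DataFrame(truth_rows)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        # fixed mtime/filename keep gzip output byte-reproducible
        raw = open(path, "wb")
        return io.TextIOWrapper(gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0))
    return open(path, "w")


def simulate_sample(
    tumors: Sequence[TrueTumor],
    spikeins: SpikeInSet | None,
    template: ConstructTemplate,
    error_model: ErrorModel,
    reads_per_cell: float,
    seed: int,
    r1_path: str | Path,
    r2_path: str | Path,
    mouse_id: str | None = None,
) -> pd.DataFrame:
    """Write paired FASTQ for one sample and return its truth table.

    Each tumor/spike-in emits Poisson(cells x reads_per_cell) read pairs;
    errors are drawn once per molecule on the full amplicon, mate 1 is the
    mutated amplicon and mate 2 its reverse complement.  Quality strings
    are constant 'I' (qualities are never consumed downstream).  The truth
    table's ``reads`` column counts emitted pairs, so truth reads always
    equal the number of records in each FASTQ file.
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be > 0")
    if not tumors and (spikeins is None or not spikeins.entries):
        raise ValueError("nothing to simulate")
    mouse = mouse_id or (tumors[0].mouse_id if tumors else "sample")
    rng = _mouse_rng(seed, mouse, stream=2)
    truth_rows = []
    serial = 0
    with _open_maybe_gzip(Path(r1_path)) as f1, _open_maybe_gzip(Path(r2_path)) as f2:
        for dual, label, cells, is_spike in _units(tumors, spikeins):
            n = int(rng.poisson(cells * reads_per_cell))
            amp = template.amplicon(dual)
            for variant, count in _mutate_counts(amp, n, error_model, rng):
                rc = revcomp(variant)
                qual = "I" * len(variant)
                for _ in range(count):
                    serial += 1
                    name = f"@sim:{mouse}:{serial}"
                    f1.write(f"{name}/1\n{variant}\n+\n{qual}\n")
                    f2.write(f"{name}/2\n{rc}\n+\n{qual}\n")
            truth_rows.append(
                {
                    "mouse_id": mouse,
                    "sgID": dual[:8],
                    "barcode": dual[8:],
                    "true_cells": cells,
                    "reads": n,
                    "label": label,
                    "is_spikein": is_spike,
                }
            )
    return pd.DataFrame(truth_rows)
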