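"""Standard-format I/O: FASTQ pairs, tabular artifacts, configuration.

TSV with header is the universal tabular format, JSON holds nested QC,
and FASTQ (gzip auto-detected) is the only sequence format — alignment is
local to the construct, not genomic, so no SAM/BAM is involved.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentScoring
from .errors import ErrorFilterConfig
from .extract import Pileup
from .quantify import QuantConfig, TumorCall
from .sim import SimConfig, SpikeInEntry, SpikeInSet
from .stats import StatsConfig
from .pool import PoolDesign, PoolEntry


# ---------------------------------------------------------------------------
# FASTQ


def _open_auto(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield synchronized (mate1, mate2) sequences from two FASTQ files.

    gzip is auto-detected from the magic bytes.  Unequal record counts or
    a malformed record raise ValueError (with the approximate line).
    """
    with _open_auto(r1_path) as f1, _open_auto(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n1 = n2 = 0
        while True:
            try:
                rec1 = next(it1, None)
            except ValueError as e:
                raise ValueError(f"{r1_path}: malformed record near line {4 * n1 + 1}: {e}") from e
            try:
                rec2 = next(it2, None)
            except ValueError as e:
                raise ValueError(f"{r2_path}: malformed record near line {4 * n2 + 1}: {e}") from e
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                # count the remainder of the longer file for the message
                if rec1 is None:
                    n2 += 1 + sum(1 for _ in it2)
                else:
                    n1 += 1 + sum(1 for _ in it1)
                raise ValueError(
                    f"unequal FASTQ record counts: {r1_path} has {n1} vs {r2_path} has {n2}"
                )
            n1 += 1
            n2 += 1
            yield rec1[1].upper(), rec2[1].upper()


# ---------------------------------------------------------------------------
# tabular artifacts


def write_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def pileups_to_frame(pileups: list[Pileup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [p.mouse_id for p in pileups],
            "sgID": [p.sgID for p in pileups],
            "barcode": [p.barcode for p in pileups],
            "reads": [p.reads for p in pileups],
            "mean_score_fraction": [p.mean_score_fraction for p in pileups],
            "qc_flags": [";".join(sorted(p.qc_flags)) for p in pileups],
        }
    )


def calls_to_frame(calls: list[TumorCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls], columns=[
        "mouse_id", "sgRNA_name", "target_gene", "barcode", "reads", "cells"
    ])


def write_pool_design(pool: PoolDesign, path: str | Path) -> Path:
    frame = pd.DataFrame([dataclasses.asdict(e) for e in pool.entries])
    return write_tsv(frame, path)


def read_pool_design(path: str | Path) -> PoolDesign:
    frame = read_tsv(path)
    return PoolDesign([PoolEntry(r.sgID, r.sgRNA_name, r.target_gene, r.role) for r in frame.itertuples()])


def write_spikein_manifest(spikeins: SpikeInSet, path: str | Path) -> Path:
    frame = pd.DataFrame([dataclasses.asdict(e) for e in spikeins.entries])
    return write_tsv(frame, path)


def read_spikein_manifest(path: str | Path) -> SpikeInSet:
    frame = read_tsv(path)
    return SpikeInSet([SpikeInEntry(r.barcode, int(r.known_cells), r.label) for r in frame.itertuples()])


# ---------------------------------------------------------------------------
# sample sheet


@dataclass
class SampleSheet:
    """One row per sequenced sample: ids, cohort label and FASTQ paths."""

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "mouse_id", "cohort", "fastq_r1", "fastq_r2")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(read_tsv(path))

    def write(self, path: str | Path) -> Path:
        return write_tsv(self.rows, path)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Union of all stage configurations plus the global seed.

    Every default is either a printed study constant (+4/-2/-6/-1 scoring,
    50% score cutoff, top-100 estimation, 1e-10 likelihood threshold,
    1e5-cell spike-in reference, 400-cell cutoff, 44.73x tail multiplier,
    10th-99.99th percentile grid, 2,000,000 bootstrap iterations) or a
    documented package decision.
    """

    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    error_filter: ErrorFilterConfig = field(default_factory=ErrorFilterConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    _SECTIONS = {
        "scoring": AlignmentScoring,
        "error_filter": ErrorFilterConfig,
        "quant": QuantConfig,
        "stats": StatsConfig,
        "sim": SimConfig,
    }

    def to_dict(self) -> dict:
        out = {}
        for name in self._SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            out[name] = {k: list(v) if isinstance(v, tuple) else v for k, v in section.items()}
        out["seed"] = self.seed
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        unknown = set(data) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, klass in cls._SECTIONS.items():
            section = data.get(name) or {}
            valid = {f.name for f in fields(klass)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            for key in ("percentile_grid", "bootstrap_statistics"):
                if key in section and isinstance(section[key], list):
                    section[key] = tuple(section[key])
            kwargs[name] = klass(**section)
        kwargs["seed"] = int(data.get("seed", 0))
        return cls(**kwargs)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; empty file means all defaults.

    Unknown keys are rejected by name, and the config round-trips
    losslessly through :meth:`PipelineConfig.write`.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return PipelineConfig.from_dict(data)
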