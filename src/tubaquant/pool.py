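"""Lentiviral pool design: sgID sequences and their sgRNA/gene identities.

Each vector in a pool carries an 8-nt sgID that encodes which sgRNA (and
hence which candidate gene knockout) the vector delivers.  Pools always
contain at least two inert control sgRNAs (the within-mouse denominator of
every relative statistic), one positive control and one negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SGID_LENGTH = 8
#: minimum pairwise Hamming distance between designed sgIDs; a single
#: sequencing error can then never convert one designed sgID into another
MIN_SGID_DISTANCE = 3

ROLES = ("inert", "active", "positive_control", "negative_control")


@dataclass(frozen=True)
class PoolEntry:
    sgID: str
    sgRNA_name: str
    target_gene: str
    role: str

    def __post_init__(self) -> None:
        if len(self.sgID) != SGID_LENGTH or set(self.sgID) - set("ACGT"):
            raise ValueError(f"sgID must be 8 nt over ACGT, got {self.sgID!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class PoolDesign:
    """A lentiviral sgRNA pool: sgID -> identity/role mapping."""

    entries: list[PoolEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        sgids = [e.sgID for e in self.entries]
        if len(set(sgids)) != len(sgids):
            raise ValueError("sgID sequences must be unique")
        if len(self.inert_names()) < 2:
            raise ValueError("a pool needs at least two inert entries")

    def inert_names(self) -> list[str]:
        return [e.sgRNA_name for e in self.entries if e.role == "inert"]

    def sgid_map(self) -> dict[str, PoolEntry]:
        return {e.sgID: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _draw_spaced_sgids(n: int, rng: np.random.Generator, max_tries: int = 20000) -> list[str]:
    """Rejection-sample n 8-mers with pairwise Hamming distance >= 3."""
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} sgIDs at pairwise Hamming >= {MIN_SGID_DISTANCE}"
            )
        cand = "".join(rng.choice(bases, size=SGID_LENGTH))
        if all(_hamming(cand, s) >= MIN_SGID_DISTANCE for s in chosen):
            chosen.append(cand)
    return chosen


def build_pool_design(n_genes: int, sgRNAs_per_gene: int, seed: int) -> PoolDesign:
    """Build a synthetic pool: ``n_genes`` x ``sgRNAs_per_gene`` active entries
    plus two inerts, one positive and one negative control.

    sgIDs are mutually distinct with pairwise Hamming distance >= 3.
    """
    if n_genes < 0 or sgRNAs_per_gene < 1:
        raise ValueError("need n_genes >= 0 and sgRNAs_per_gene >= 1")
    rng = np.random.default_rng(seed)
    n_total = n_genes * sgRNAs_per_gene + 4
    sgids = _draw_spaced_sgids(n_total, rng)
    entries: list[PoolEntry] = []
    it = iter(sgids)
    for g in range(n_genes):
        gene = f"Gene{g + 1:02d}"
        for k in range(sgRNAs_per_gene):
            entries.append(PoolEntry(next(it), f"sg{gene}_{k + 1}", gene, "active"))
    entries.append(PoolEntry(next(it), "sgNeo1", "Neo", "inert"))
    entries.append(PoolEntry(next(it), "sgNeo2", "Neo", "inert"))
    entries.append(PoolEntry(next(it), "sgRb1", "Rb1", "positive_control"))
    entries.append(PoolEntry(next(it), "sgPcna", "Pcna", "negative_control"))
    return PoolDesign(entries)
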