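"""Barcode extraction, mate-consensus building, dereplication and pileup QC.

Every read pair is either converted into an :class:`ExtractedBarcode` or
dropped with a counted reason, so input reads always reconcile exactly
(losslessness before filtering).  The dual barcode (8-nt sgID + 20-nt
random barcode) is read off between the flank anchors of each mate after
reverse-complementing mate 2; positions where the two mates disagree
become 'N' in the consensus.  Consensus barcodes are then dereplicated
into pileups — the atom of all downstream quantification — and pileups
failing the study's two quality rules (any member with mismatched
forward/reverse extraction lengths, or mean alignment score fraction
below 50%) are removed with machine-readable reasons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .align import AlignmentResult, AlignmentScoring, align_read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: reference coordinates of the dual-barcode region: the 28 degenerate
#: positions between the two 10-nt flanks
BARCODE_REGION = (10, 38)

DROP_UNALIGNABLE = "unalignable"
DROP_REGION_NOT_COVERED = "region_not_covered"

FLAG_LENGTH_MISMATCH = "length_mismatch"
FLAG_LOW_MEAN_SCORE = "low_mean_score"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ExtractedBarcode:
    """Consensus dual barcode from one read pair."""

    sgID_part: str
    bc_part: str
    score_fraction: float
    length_match: bool

    @property
    def barcode(self) -> str:
        return self.sgID_part + self.bc_part


@dataclass
class Pileup:
    """Dereplicated tally of reads sharing one consensus dual barcode."""

    mouse_id: str
    barcode: str
    reads: int
    mean_score_fraction: float = 1.0
    n_length_mismatch: int = 0

    @property
    def sgID(self) -> str:
        return self.barcode[:8]

    @property
    def qc_flags(self) -> set[str]:
        flags = set()
        if self.n_length_mismatch > 0:
            flags.add(FLAG_LENGTH_MISMATCH)
        return flags


def region_from_alignment(aln: AlignmentResult, read: str, region: tuple[int, int] = BARCODE_REGION) -> str | None:
    """Read off the read bases aligned to reference interval ``region``.

    Returns None when the alignment does not span the full region.
    Insertions strictly inside the region are kept (they lengthen the
    extraction); deletions shorten it.
    """
    if not aln.aligned or len(aln.target_blocks) == 0:
        return None
    lo, hi = region
    tb, qb = aln.target_blocks, aln.query_blocks
    if tb[0, 0] > lo or tb[-1, 1] < hi:
        return None
    parts: list[str] = []
    for i in range(len(tb)):
        t0, t1 = tb[i]
        q0, q1 = qb[i]
        # overlap of this aligned block with the barcode region
        s = max(t0, lo)
        e = min(t1, hi)
        if e > s:
            parts.append(read[q0 + (s - t0) : q0 + (e - t0)])
        if i + 1 < len(tb):
            tn0 = tb[i + 1, 0]
            qn0 = qb[i + 1, 0]
            if tn0 == t1 and qn0 > q1 and lo <= t1 <= hi:
                parts.append(read[q1:qn0])  # insertion inside or at the edge of the region
    return "".join(parts)


def extract_barcode_pair(
    fwd_alignment: AlignmentResult,
    rev_alignment: AlignmentResult,
    fwd_read: str,
    rev_read_rc: str,
    region: tuple[int, int] = BARCODE_REGION,
) -> ExtractedBarcode | None:
    """Build the mate-consensus barcode from both mates' alignments.

    ``rev_read_rc`` is mate 2 already reverse-complemented into mate-1
    orientation.  Agreeing positions keep the base; disagreements become
    'N'.  When the two extractions differ in length the forward one is
    used and ``length_match`` is False (such pairs taint their pileup,
    which the pileup filter then removes).  Returns None when the region
    could not be recovered from either mate.
    """
    fwd = region_from_alignment(fwd_alignment, fwd_read, region)
    rev = region_from_alignment(rev_alignment, rev_read_rc, region)
    if fwd is None or rev is None:
        return None
    if len(fwd) == len(rev):
        consensus = "".join(a if a == b else "N" for a, b in zip(fwd, rev))
        length_match = True
    else:
        consensus = fwd
        length_match = False
    frac = (fwd_alignment.score_fraction + rev_alignment.score_fraction) / 2.0
    return ExtractedBarcode(consensus[:8], consensus[8:], frac, length_match)


def extract_read_pairs(
    pairs: Iterable[tuple[str, str]],
    reference: str,
    scoring: AlignmentScoring | None = None,
) -> tuple[Iterator[ExtractedBarcode], Counter]:
    """Extract consensus barcodes from a stream of (mate1, mate2) sequences.

    Returns the list of extracted barcodes and a counter of drop reasons;
    ``len(extracted) + sum(drops.values())`` equals the number of input
    pairs exactly.  Amplicon libraries are massively redundant, so results
    are memoized per distinct (mate1, mate2) sequence pair.
    """
    scoring = scoring or AlignmentScoring()
    drops: Counter = Counter()
    out: list[ExtractedBarcode] = []
    cache: dict[tuple[str, str], tuple[str | None, ExtractedBarcode | None]] = {}
    for s1, s2 in pairs:
        key = (s1, s2)
        hit = cache.get(key)
        if hit is None:
            a1 = align_read(s1, reference, scoring)
            s2rc = revcomp(s2)
            a2 = align_read(s2rc, reference, scoring)
            if not (a1.aligned and a2.aligned):
                hit = (DROP_UNALIGNABLE, None)
            else:
                eb = extract_barcode_pair(a1, a2, s1, s2rc)
                hit = (DROP_REGION_NOT_COVERED, None) if eb is None else (None, eb)
            cache[key] = hit
        reason, eb = hit
        if eb is not None:
            out.append(eb)
        else:
            drops[reason] += 1
    return out, drops


def dereplicate(extracted: Iterable[ExtractedBarcode], mouse_id: str) -> list[Pileup]:
    """Tally extracted barcodes into one pileup per distinct consensus."""
    tally: dict[str, list] = {}
    for eb in extracted:
        rec = tally.setdefault(eb.barcode, [0, 0.0, 0])
        rec[0] += 1
        rec[1] += eb.score_fraction
        rec[2] += 0 if eb.length_match else 1
    return [
        Pileup(mouse_id, bc, n, score_sum / n, n_mismatch)
        for bc, (n, score_sum, n_mismatch) in sorted(tally.items())
    ]


def filter_pileups(
    pileups: Iterable[Pileup], scoring: AlignmentScoring | None = None
) -> tuple[list[Pileup], list[tuple[Pileup, str]]]:
    """Apply the two pileup-level quality rules.

    A pileup is removed when any member pair had mismatched forward and
    reverse extraction lengths, or when its mean alignment score fraction
    falls strictly below ``min_mean_score_fraction`` (0.50 by default).
    """
    scoring = scoring or AlignmentScoring()
    kept: list[Pileup] = []
    removed: list[tuple[Pileup, str]] = []
    for p in pileups:
        if p.n_length_mismatch > 0:
            removed.append((p, FLAG_LENGTH_MISMATCH))
        elif p.mean_score_fraction < scoring.min_mean_score_fraction:
            removed.append((p, FLAG_LOW_MEAN_SCORE))
        else:
            kept.append(p)
    return kept, removed
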