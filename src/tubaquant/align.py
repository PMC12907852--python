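"""Local alignment of amplicon reads to the barcode construct reference.

Reads are aligned to a short reference consisting of the two 10-nt constant
flanks with a degenerate placeholder ('N' x 28) in between.  Placeholder
positions score as matches against any base, so barcode content never
penalizes the alignment; only flank disagreements and indels do.  The
scoring follows the study defaults: match +4, mismatch -2, gap open -6,
gap extension -1, where a gap of length g costs open + (g-1) * extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentScoring:
    """Smith-Waterman scoring parameters and the pileup score-filter cutoff."""

    match: float = 4.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    min_mean_score_fraction: float = 0.50

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if max(self.mismatch, self.gap_open, self.gap_extend) >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if not 0 < self.min_mean_score_fraction <= 1:
            raise ValueError("min_mean_score_fraction must be in (0, 1]")


@dataclass
class AlignmentResult:
    """One local alignment of a read against the construct reference.

    ``target_blocks``/``query_blocks`` are parallel lists of 0-based,
    half-open aligned segments on the reference and the read.
    """

    score: float
    score_fraction: float
    target_blocks: np.ndarray  # (n, 2) reference coordinates
    query_blocks: np.ndarray  # (n, 2) read coordinates
    aligned: bool = True


#: tiny penalty on placeholder matches so that, among equal-scoring
#: alignments, gap placement prefers keeping real flank matches (otherwise
#: an indel in the barcode region can be traded for one at the flank
#: boundary, leaking flank bases into the extraction).  The perturbation
#: (at most 28 * EPS = 0.028) is far below the 1-point score granularity,
#: so the chosen path is always optimal under the canonical scoring too.
_N_EPS = 1e-3


@lru_cache(maxsize=8)
def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = match if a == b else mismatch
    for a in "ACGTN":
        mat["N", a] = match - _N_EPS
        mat[a, "N"] = match - _N_EPS
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _canonical_score(
    reference: str, read: str, tblocks: np.ndarray, qblocks: np.ndarray, scoring: AlignmentScoring
) -> float:
    """Score of an alignment path under the unperturbed scoring scheme
    (placeholder 'N' positions count as full matches)."""
    score = 0.0
    for i in range(len(tblocks)):
        t0, t1 = tblocks[i]
        q0, q1 = qblocks[i]
        for t, q in zip(range(t0, t1), range(q0, q1)):
            ref_base = reference[t]
            if ref_base == "N" or ref_base == read[q]:
                score += scoring.match
            else:
                score += scoring.mismatch
        if i + 1 < len(tblocks):
            for g in (tblocks[i + 1, 0] - t1, qblocks[i + 1, 0] - q1):
                if g > 0:
                    score += scoring.gap_open + (g - 1) * scoring.gap_extend
    return score


def max_attainable_score(read_len: int, ref_len: int, scoring: AlignmentScoring) -> float:
    """Best possible local score for a read of this length: all-match over
    the shorter of the two sequences."""
    return scoring.match * min(read_len, ref_len)


def align_read(read: str, reference: str, scoring: AlignmentScoring | None = None) -> AlignmentResult:
    """Optimal local alignment of ``read`` against ``reference``.

    Reference 'N' placeholder positions match any base at +``match``.
    Reads shorter than one flank (10 nt) are flagged unalignable with
    score 0.  Coordinates are 0-based, half-open.
    """
    scoring = scoring or AlignmentScoring()
    empty = np.empty((0, 2), dtype=int)
    if len(read) < 10 or set(read) - set("ACGTN"):
        return AlignmentResult(0.0, 0.0, empty, empty, aligned=False)
    aligner = _make_aligner(scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    alignments = aligner.align(reference, read)
    try:
        best = alignments[0]
    except IndexError:
        return AlignmentResult(0.0, 0.0, empty, empty, aligned=False)
    tblocks = np.asarray(best.aligned[0], dtype=int)
    qblocks = np.asarray(best.aligned[1], dtype=int)
    score = _canonical_score(reference, read, tblocks, qblocks, scoring)
    frac = score / max_attainable_score(len(read), len(reference), scoring)
    return AlignmentResult(
        score=score,
        score_fraction=float(frac),
        target_blocks=tblocks,
        query_blocks=qblocks,
    )
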