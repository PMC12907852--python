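"""Recurrent read-error estimation, Poisson denoising, and QC diagnostics.

Large barcode pileups shed "satellite" pileups: spurious barcodes one edit
away that arise repeatedly from PCR/sequencing errors.  The error process
is summarized by an eight-parameter model — six symmetric substitution
rates among A/C/G/T plus one insertion and one deletion rate — estimated
once study-wide from the median per-opportunity rate of distance-1
satellites descending from the 100 largest pileups of every mouse.

Each pileup is then scored against its nearest larger neighbor: the
expected number of artifact reads is lambda = neighbor reads x the
per-read error rate of the difference between the two barcodes, and the
upper-tail Poisson probability P(X >= reads) is the likelihood that the
pileup is a recurrent read error.  Pileups with likelihood above 1e-10
are removed (discarded, never merged).

Edits involving 'N' (mate-disagreement positions in a consensus barcode)
are scored with the largest of the six substitution rates, a conservative
choice since the underlying base change is unidentifiable.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extract import Pileup

logger = logging.getLogger(__name__)

#: the six unordered substitution pairs among A/C/G/T, in canonical order
SUB_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

_BASES = "ACGT"


def pair_key(x: str, y: str) -> str:
    return "".join(sorted((x, y)))


@dataclass
class ErrorModel:
    """Eight recurrent-read-error rates, all per read per opportunity."""

    sub_rates: dict[str, float] = field(default_factory=lambda: {p: 0.0 for p in SUB_PAIRS})
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.sub_rates) != set(SUB_PAIRS):
            raise ValueError(f"sub_rates must have exactly the keys {SUB_PAIRS}")
        for name, r in self.iter_rates():
            if not 0 <= r < 0.5:
                raise ValueError(f"rate {name} = {r} out of [0, 0.5)")

    def iter_rates(self):
        for p in SUB_PAIRS:
            yield f"sub_{p}", self.sub_rates[p]
        yield "ins", self.ins_rate
        yield "del", self.del_rate

    @property
    def max_sub_rate(self) -> float:
        return max(self.sub_rates.values())

    def class_rate(self, cls: str) -> float:
        """Per-read rate of a single edit of class ``cls``.

        Classes: ``sub:XY`` (canonical pair), ``sub:N`` (edit involving an
        'N', scored with the max substitution rate), ``ins``, ``del``.
        """
        if cls == "ins":
            return self.ins_rate
        if cls == "del":
            return self.del_rate
        if cls == "sub:N":
            return self.max_sub_rate
        if cls.startswith("sub:"):
            return self.sub_rates[cls[4:]]
        raise ValueError(f"unknown edit class {cls!r}")

    def difference_rate(self, classes: Sequence[str]) -> float:
        """Per-read rate of a specific multi-edit difference (product of
        single-edit rates; independent errors)."""
        rate = 1.0
        for c in classes:
            rate *= self.class_rate(c)
        return rate

    @classmethod
    def flat(cls, per_base_substitution: float = 0.0, ins_rate: float = 0.0, del_rate: float = 0.0) -> "ErrorModel":
        """Uniform model: each base mutates with total probability
        ``per_base_substitution``, split evenly over its three partners."""
        r = per_base_substitution / 3.0
        return cls({p: r for p in SUB_PAIRS}, ins_rate, del_rate)

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls()

    def to_json(self) -> str:
        return json.dumps(dict(self.iter_rates()), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ErrorModel":
        d = json.loads(text)
        return cls({p: d[f"sub_{p}"] for p in SUB_PAIRS}, d["ins"], d["del"])


@dataclass
class ErrorFilterConfig:
    likelihood_threshold: float = 1e-10
    top_n_for_estimation: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.likelihood_threshold < 1:
            raise ValueError("likelihood_threshold must be in (0, 1)")
        if self.top_n_for_estimation < 1:
            raise ValueError("top_n_for_estimation must be >= 1")


@dataclass
class Difference:
    """Minimal edit script (as class labels) between two barcodes."""

    classes: list[str]

    @property
    def distance(self) -> int:
        return len(self.classes)


@dataclass
class PileupAssessment:
    pileup: Pileup
    neighbor: Pileup | None
    difference: Difference | None
    lam: float
    likelihood: float
    kept: bool = True


# ---------------------------------------------------------------------------
# edit enumeration and classification


def _sub_class(x: str, y: str) -> str:
    if "N" in (x, y):
        return "sub:N"
    return f"sub:{pair_key(x, y)}"


def _neighbor_variants(bc: str):
    """All sequences one edit away from ``bc``, labeled with the class of
    the edit that turns the *variant* (putative parent) into ``bc``."""
    L = len(bc)
    for i, x in enumerate(bc):
        for y in _BASES:
            if y != x:
                yield bc[:i] + y + bc[i + 1 :], _sub_class(x, y)
    # variant longer than bc: parent -> bc deletes one base
    for g in range(L + 1):
        for b in _BASES:
            yield bc[:g] + b + bc[g:], "del"
    # variant shorter than bc: parent -> bc inserts one base
    for i in range(L):
        yield bc[:i] + bc[i + 1 :], "ins"


def _satellite_variants(parent: str):
    """All sequences one edit away from ``parent``, labeled with the class
    of the edit parent -> variant (the error direction)."""
    L = len(parent)
    for i, x in enumerate(parent):
        if x not in _BASES:
            continue  # N positions carry no identifiable substitution class
        for y in _BASES:
            if y != x:
                yield parent[:i] + y + parent[i + 1 :], _sub_class(x, y)
    for i in range(L):
        yield parent[:i] + parent[i + 1 :], "del"
    for g in range(L + 1):
        for b in _BASES:
            yield parent[:g] + b + parent[g:], "ins"


def edit_classes(parent: str, child: str) -> list[str]:
    """Classify a minimal edit script turning ``parent`` into ``child``.

    Equal-length pairs use positionwise substitutions when that is minimal;
    otherwise a full Levenshtein backtrace (small strings only).
    """
    if parent == child:
        return []
    la, lb = len(parent), len(child)
    if la == lb:
        subs = [_sub_class(x, y) for x, y in zip(parent, child) if x != y]
        if len(subs) <= 2:
            return subs
    # Levenshtein DP with backtrace
    dp = np.zeros((la + 1, lb + 1), dtype=int)
    dp[:, 0] = np.arange(la + 1)
    dp[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if parent[i - 1] == child[j - 1] else 1
            dp[i, j] = min(dp[i - 1, j - 1] + cost, dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    classes: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (0 if parent[i - 1] == child[j - 1] else 1):
            if parent[i - 1] != child[j - 1]:
                classes.append(_sub_class(parent[i - 1], child[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            classes.append("del")
            i -= 1
        else:
            classes.append("ins")
            j -= 1
    return classes[::-1]


# ---------------------------------------------------------------------------
# likelihood


def recurrent_error_likelihood(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam).

    The likelihood that a pileup of ``k`` reads consists entirely of
    recurrent read errors when ``lam`` artifact reads are expected.
    Computed via the regularized gamma survival function (stable in log
    space for large k).  lam = 0 with k >= 1 gives exactly 0.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if lam == 0.0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


# ---------------------------------------------------------------------------
# nearest-neighbor search


def _byte_matrix(barcodes: list[str]) -> np.ndarray:
    return np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(len(barcodes), -1)


class _MouseIndex:
    """Per-mouse search structures for nearest-larger-neighbor queries."""

    def __init__(self, pileups: Sequence[Pileup]):
        self.pileups = list(pileups)
        self.by_barcode = {p.barcode: p for p in self.pileups}
        if len(self.by_barcode) != len(self.pileups):
            raise ValueError("duplicate barcodes within one mouse")
        self.by_length: dict[int, dict] = {}
        groups: dict[int, list[Pileup]] = defaultdict(list)
        for p in self.pileups:
            groups[len(p.barcode)].append(p)
        for L, plist in groups.items():
            plist.sort(key=lambda p: (-p.reads, p.barcode))
            self.by_length[L] = {
                "pileups": plist,
                "mat": _byte_matrix([p.barcode for p in plist]),
                "reads": np.array([p.reads for p in plist]),
            }
        self.desc = sorted(self.pileups, key=lambda p: (-p.reads, p.barcode))

    def distance_one(self, q: Pileup) -> tuple[Pileup, Difference] | None:
        best: Pileup | None = None
        best_cls: str | None = None
        for variant, cls in _neighbor_variants(q.barcode):
            cand = self.by_barcode.get(variant)
            if cand is not None and cand.reads > q.reads:
                # larger reads wins; on equal reads the lexicographically
                # smaller barcode wins
                if best is None or cand.reads > best.reads or (
                    cand.reads == best.reads and cand.barcode < best.barcode
                ):
                    best, best_cls = cand, cls
        if best is None:
            return None
        return best, Difference([best_cls])

    def hamming_nearest(self, q: Pileup) -> tuple[Pileup, int] | None:
        """Nearest larger pileup of the same barcode length (Hamming)."""
        grp = self.by_length.get(len(q.barcode))
        if grp is None:
            return None
        mask = grp["reads"] > q.reads
        if not mask.any():
            return None
        qv = np.frombuffer(q.barcode.encode(), dtype=np.uint8)
        d = (grp["mat"][mask] != qv).sum(axis=1)
        i = int(np.argmin(d))  # pileups sorted by (-reads, barcode): first
        # minimal index is the largest-reads, then lexicographic winner
        cands = np.flatnonzero(mask)
        return grp["pileups"][int(cands[i])], int(d[i])

    def cross_length_nearest(self, q: Pileup, max_candidates: int = 32) -> tuple[Pileup, list[str]] | None:
        """Nearest larger pileup of a nearby different length (|delta| <= 2),
        probed against the largest such pileups only — the plausible
        parents of multi-edit errors."""
        best: tuple[int, int, str, Pileup, list[str]] | None = None
        Lq = len(q.barcode)
        for L, grp in self.by_length.items():
            if L == Lq or abs(L - Lq) > 2:
                continue
            seen = 0
            for cand in grp["pileups"]:  # sorted by (-reads, barcode)
                if cand.reads <= q.reads or seen >= max_candidates:
                    break
                seen += 1
                classes = edit_classes(cand.barcode, q.barcode)
                key = (len(classes), -cand.reads, cand.barcode)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (len(classes), -cand.reads, cand.barcode, cand, classes)
        if best is None:
            return None
        return best[3], best[4]

    def nearest(self, q: Pileup, cross_length: bool = True) -> tuple[Pileup | None, Difference | None]:
        hit = self.distance_one(q)
        if hit is not None:
            return hit
        return self.nearest_beyond_one(q, cross_length)

    def nearest_beyond_one(self, q: Pileup, cross_length: bool = True) -> tuple[Pileup | None, Difference | None]:
        same = self.hamming_nearest(q)
        cross = self.cross_length_nearest(q) if cross_length else None
        options: list[tuple[int, int, str, Pileup, list[str]]] = []
        if same is not None:
            cand, d = same
            classes = [_sub_class(x, y) for x, y in zip(cand.barcode, q.barcode) if x != y]
            options.append((d, -cand.reads, cand.barcode, cand, classes))
        if cross is not None:
            cand, classes = cross
            options.append((len(classes), -cand.reads, cand.barcode, cand, classes))
        if not options:
            return None, None
        options.sort(key=lambda t: (t[0], t[1], t[2]))
        _, _, _, cand, classes = options[0]
        return cand, Difference(classes)


def nearest_neighbor(pileup: Pileup, pileups: Sequence[Pileup]) -> tuple[Pileup | None, Difference | None]:
    """Nearest larger pileup (minimal edit distance) and the classified
    difference; (None, None) when no larger pileup exists."""
    others = [p for p in pileups if p is not pileup and p.barcode != pileup.barcode]
    if not others:
        return None, None
    return _MouseIndex(others).nearest(pileup)


def assess_pileups(
    pileups: Sequence[Pileup],
    model: ErrorModel,
    config: ErrorFilterConfig | None = None,
) -> list[PileupAssessment]:
    """Score every pileup's probability of being a recurrent read error."""
    config = config or ErrorFilterConfig()
    out: list[PileupAssessment] = []
    by_mouse: dict[str, list[Pileup]] = defaultdict(list)
    for p in pileups:
        by_mouse[p.mouse_id].append(p)
    max_rate = max(r for _, r in model.iter_rates())
    for mouse in sorted(by_mouse):
        index = _MouseIndex(by_mouse[mouse])
        r_max = max(p.reads for p in by_mouse[mouse])
        for q in by_mouse[mouse]:
            hit = index.distance_one(q)
            if hit is not None:
                neighbor, diff = hit
            else:
                # beyond distance 1 lambda is bounded by r_max * max_rate^2;
                # when even that bound cannot push the likelihood over the
                # threshold the verdict is already "kept" and the expensive
                # cross-length probe is skipped (the reported neighbor is
                # then the nearest same-length pileup).
                decided = (
                    recurrent_error_likelihood(q.reads, r_max * max_rate**2)
                    <= config.likelihood_threshold
                )
                neighbor, diff = index.nearest_beyond_one(q, cross_length=not decided)
            if neighbor is None:
                lam, lik = 0.0, 0.0
            else:
                lam = neighbor.reads * model.difference_rate(diff.classes)
                lik = recurrent_error_likelihood(q.reads, lam)
            out.append(
                PileupAssessment(q, neighbor, diff, lam, lik, kept=lik <= config.likelihood_threshold)
            )
    return out


def filter_spurious(
    pileups: Sequence[Pileup],
    model: ErrorModel,
    config: ErrorFilterConfig | None = None,
) -> tuple[list[Pileup], list[PileupAssessment]]:
    """Remove pileups whose recurrent-error likelihood exceeds the
    threshold (1e-10 by default).  Reads are discarded, never reassigned."""
    config = config or ErrorFilterConfig()
    assessments = assess_pileups(pileups, model, config)
    kept = [a.pileup for a in assessments if a.kept]
    removed = [a for a in assessments if not a.kept]
    return kept, removed


# ---------------------------------------------------------------------------
# error-model estimation


def _opportunities(parent: str, cls: str) -> int:
    if cls == "ins":
        return len(parent) + 1
    if cls == "del":
        return len(parent)
    pair = cls[4:]
    return sum(parent.count(b) for b in pair)


def estimate_error_model(
    pileups: Sequence[Pileup],
    config: ErrorFilterConfig | None = None,
) -> ErrorModel:
    """Estimate the eight error rates from distance-1 satellites of the
    ``top_n`` largest pileups of every mouse.

    For each parent, satellite reads of each edit class are converted to a
    per-read, per-opportunity rate (satellite reads / parent reads /
    opportunities); the model rate of a class is the median of these
    per-(mouse, parent) rates across the whole study, zeros included.
    """
    config = config or ErrorFilterConfig()
    by_mouse: dict[str, list[Pileup]] = defaultdict(list)
    for p in pileups:
        by_mouse[p.mouse_id].append(p)
    if not by_mouse:
        raise ValueError("no pileups to estimate from")
    samples: dict[str, list[float]] = defaultdict(list)
    any_satellite = False
    for mouse in sorted(by_mouse):
        plist = by_mouse[mouse]
        index = {p.barcode: p for p in plist}
        parents = sorted(plist, key=lambda p: (-p.reads, p.barcode))[: config.top_n_for_estimation]
        for parent in parents:
            totals: dict[str, int] = defaultdict(int)
            seen: set[str] = set()
            for variant, cls in _satellite_variants(parent.barcode):
                if variant in seen:
                    continue
                seen.add(variant)
                sat = index.get(variant)
                if sat is not None and sat.reads < parent.reads:
                    totals[cls] += sat.reads
                    any_satellite = True
            for cls in [f"sub:{p}" for p in SUB_PAIRS] + ["ins", "del"]:
                opp = _opportunities(parent.barcode, cls)
                if opp == 0:
                    continue
                samples[cls].append(totals.get(cls, 0) / parent.reads / opp)
    if not any_satellite:
        logger.warning("no distance-1 satellites observed; all error rates set to 0")
    sub_rates = {p: float(np.median(samples[f"sub:{p}"])) if samples[f"sub:{p}"] else 0.0 for p in SUB_PAIRS}
    ins = float(np.median(samples["ins"])) if samples["ins"] else 0.0
    dele = float(np.median(samples["del"])) if samples["del"] else 0.0
    return ErrorModel(sub_rates, ins, dele)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class CollisionReport:
    """Cross-mouse barcode-sharing diagnostic.

    ``per_sgid`` has one row per sgID with the number of distinct random
    barcodes, the fraction observed in more than one mouse, the
    method-of-moments effective diversity D-hat, and the implied
    within-mouse collision probability (birthday approximation) at the
    mean per-mouse barcode count.
    """

    estimable: bool
    per_sgid: pd.DataFrame | None = None
    overall_cross_mouse_fraction: float = float("nan")


def estimate_collision_rate(pileups: Sequence[Pileup]) -> CollisionReport:
    """Estimate barcode-collision risk from cross-mouse barcode sharing."""
    mice = {p.mouse_id for p in pileups}
    if len(mice) < 2:
        return CollisionReport(estimable=False)
    groups: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for p in pileups:
        groups[p.sgID][p.barcode[8:]].add(p.mouse_id)
    rows = []
    total_bc = 0
    total_shared = 0
    for sgid in sorted(groups):
        bc_mice = groups[sgid]
        n_bc = len(bc_mice)
        counts = np.array([len(m) for m in bc_mice.values()])
        n_shared = int((counts > 1).sum())
        shared_pairs = int(sum(c * (c - 1) // 2 for c in counts))
        per_mouse: dict[str, int] = defaultdict(int)
        for mset in bc_mice.values():
            for m in mset:
                per_mouse[m] += 1
        ns = np.array(list(per_mouse.values()), dtype=float)
        cross_products = (ns.sum() ** 2 - (ns**2).sum()) / 2.0
        d_hat = cross_products / shared_pairs if shared_pairs > 0 else float("inf")
        n_mean = float(ns.mean())
        if math.isinf(d_hat):
            collision_prob = 0.0
        else:
            collision_prob = 1.0 - math.exp(-n_mean * (n_mean - 1) / (2.0 * d_hat))
        rows.append(
            {
                "sgID": sgid,
                "n_barcodes": n_bc,
                "n_shared": n_shared,
                "cross_mouse_fraction": n_shared / n_bc if n_bc else float("nan"),
                "d_hat": d_hat,
                "collision_prob": collision_prob,
            }
        )
        total_bc += n_bc
        total_shared += n_shared
    frame = pd.DataFrame(rows)
    overall = total_shared / total_bc if total_bc else float("nan")
    return CollisionReport(estimable=True, per_sgid=frame, overall_cross_mouse_fraction=overall)


@dataclass
class GcBiasReport:
    estimable: bool
    slope: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    flagged: bool = False


def assess_gc_bias(pileups: Sequence[Pileup], flag_threshold: float = 1.0) -> GcBiasReport:
    """Least-squares slope of log(reads) on barcode GC fraction.

    A multiplicative amplification bias exp(b * GC) appears as slope b.
    ``flagged`` is set when |slope| exceeds ``flag_threshold`` and the
    confidence interval excludes 0.
    """
    plist = list(pileups)
    if len(plist) < 10:
        return GcBiasReport(estimable=False)
    gc = np.array([(p.barcode.count("G") + p.barcode.count("C")) / len(p.barcode) for p in plist])
    if np.ptp(gc) == 0:
        return GcBiasReport(estimable=False)
    y = np.log([p.reads for p in plist])
    res = stats.linregress(gc, y)
    tcrit = stats.t.ppf(0.975, len(plist) - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    flagged = abs(res.slope) > flag_threshold and not (lo <= 0 <= hi)
    return GcBiasReport(True, float(res.slope), float(lo), float(hi), flagged)
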