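"""Tumor-progression statistics: size spectra, heavy-tail burden, inference.

Three complementary statistics describe how a genotype alters tumor
progression: the number of tumors (initiation), the maximum-likelihood
mean size under a log-normal sampling distribution (LN mean, central
growth), and the summed burden of tumors above a Pareto-tail cutoff
expressed as a multiple (44.73x by default) of the inert median
(exceptional growth).  Percentile spectra from the 10th to the 99.99th
percentile, and Q-Q ratios against the inert controls, resolve where in
the size distribution a genotype acts.

All statistics are normalized to the inert sgRNAs within each mouse and
then averaged across mice.  Confidence intervals and p-values come from a
two-stage bootstrap (mice with replacement, then tumors within each
resampled mouse; 2,000,000 iterations by default, scalable down); tumor
number is tested with Fisher's exact test by exact hypergeometric
enumeration.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

INERT_LABEL = "sgInert"

DEFAULT_PERCENTILE_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 99, 99.9, 99.99)


@dataclass
class StatsConfig:
    percentile_grid: tuple = DEFAULT_PERCENTILE_GRID
    tail_multiplier: float = 44.73
    bootstrap_iterations: int = 2_000_000
    ci_level: float = 0.95
    rng_seed: int = 0
    #: which statistics get bootstrap CIs in genotype_statistics
    bootstrap_statistics: tuple = ("ln_mean",)

    def __post_init__(self) -> None:
        grid = tuple(self.percentile_grid)
        if any(not 0 < p < 100 for p in grid) or list(grid) != sorted(set(grid)):
            raise ValueError("percentile_grid must be strictly increasing in (0, 100)")
        if self.tail_multiplier <= 1:
            raise ValueError("tail_multiplier must be > 1")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# core statistics


@dataclass(frozen=True)
class SizeDistributionFit:
    """Log-normal MLE fit: mu/sigma^2 of log sizes and the implied mean."""

    mu_hat: float
    sigma2_hat: float
    ln_mean: float
    n: int


def ln_mean_mle(sizes: Sequence[float] | np.ndarray) -> SizeDistributionFit:
    """Maximum-likelihood mean under a log-normal sampling distribution.

    mu_hat = mean(ln x), sigma2_hat = (1/n) sum (ln x - mu_hat)^2 (the
    divide-by-n MLE), ln_mean = exp(mu_hat + sigma2_hat / 2).
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("ln_mean_mle requires at least one size")
    if (x <= 0).any():
        raise ValueError("sizes must be positive")
    logs = np.log(x)
    mu = float(logs.mean())
    s2 = float(np.mean((logs - mu) ** 2))
    return SizeDistributionFit(mu, s2, float(np.exp(mu + s2 / 2.0)), x.size)


def size_percentiles(
    sizes: Sequence[float] | np.ndarray, grid: Iterable[float] | None = None
) -> pd.DataFrame:
    """Linear-interpolation empirical quantiles on a percentile grid.

    A percentile beyond the resolution of n (fewer than one expected
    observation above it) returns the maximum with ``saturated`` set.
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("size_percentiles requires at least one size")
    grid = tuple(DEFAULT_PERCENTILE_GRID if grid is None else grid)
    n = x.size
    rows = []
    for p in grid:
        saturated = (100.0 - p) / 100.0 < 1.0 / n
        value = float(x.max()) if saturated else float(np.percentile(x, p))
        rows.append({"percentile": p, "value": value, "saturated": saturated})
    return pd.DataFrame(rows)


def heavy_tail_burden(
    sizes: Sequence[float] | np.ndarray,
    inert_median: float,
    config: StatsConfig | None = None,
) -> float:
    """Summed cells of tumors strictly above tail_multiplier x inert median."""
    if inert_median <= 0:
        raise ValueError("inert_median must be > 0")
    config = config or StatsConfig()
    x = np.asarray(sizes, dtype=float)
    cutoff = config.tail_multiplier * inert_median
    return float(x[x > cutoff].sum())


# ---------------------------------------------------------------------------
# relative (inert-normalized) statistics


def relative_statistics(
    stat_by_mouse: pd.DataFrame,
    inert_label: str = INERT_LABEL,
) -> pd.DataFrame:
    """Normalize per-mouse statistics to the inert group and average.

    ``stat_by_mouse`` has columns (mouse_id, group, value); the inert
    group must appear under ``inert_label``.  For each group the ratio
    value/inert is computed within each mouse and then averaged across
    mice; mice with an undefined (missing or NaN) inert value are
    excluded with a logged count.  Returns one row per group with
    (group, absolute, relative, n_mice, n_excluded).
    """
    frame = stat_by_mouse.copy()
    inert = frame[frame["group"] == inert_label].set_index("mouse_id")["value"]
    inert = inert[np.isfinite(inert) & (inert != 0)]  # zero inert -> ratio undefined
    if inert.empty:
        raise ValueError(f"inert statistic undefined in all mice ({inert_label!r})")
    rows = []
    for group, sub in frame.groupby("group", sort=True):
        sub = sub[np.isfinite(sub["value"])]
        have_inert = sub["mouse_id"].isin(inert.index)
        excluded = int((~have_inert).sum())
        if excluded:
            logger.info("group %s: %d mice excluded (inert statistic undefined)", group, excluded)
        sub = sub[have_inert]
        ratios = sub["value"].to_numpy() / inert.loc[sub["mouse_id"]].to_numpy()
        rows.append(
            {
                "group": group,
                "absolute": float(sub["value"].mean()) if len(sub) else float("nan"),
                "relative": float(ratios.mean()) if len(ratios) else float("nan"),
                "n_mice": int(len(sub)),
                "n_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap inference


SizesByMouse = Mapping[str, Mapping[str, np.ndarray]]

RatioStatistic = Callable[[np.ndarray, np.ndarray], float]


def _named_ratio_statistic(name: str, config: StatsConfig) -> RatioStatistic:
    if name == "ln_mean":
        return lambda sg, inert: ln_mean_mle(sg).ln_mean / ln_mean_mle(inert).ln_mean
    if name == "tumor_number":
        return lambda sg, inert: len(sg) / len(inert)
    if name == "median":
        return lambda sg, inert: float(np.median(sg) / np.median(inert))
    if name == "heavy_tail":

        def _ht(sg: np.ndarray, inert: np.ndarray) -> float:
            med = float(np.median(inert))
            denom = heavy_tail_burden(inert, med, config)
            num = heavy_tail_burden(sg, med, config)
            return num / denom if denom > 0 else float("nan")

        return _ht
    if name.startswith("percentile:"):
        q = float(name.split(":", 1)[1])
        return lambda sg, inert: float(np.percentile(sg, q) / np.percentile(inert, q))
    raise ValueError(f"unknown statistic {name!r}")


def sizes_by_mouse(
    tumor_table: pd.DataFrame,
    group_col: str = "sgRNA_name",
    inert_names: Sequence[str] = (),
    inert_label: str = INERT_LABEL,
) -> dict[str, dict[str, np.ndarray]]:
    """Pivot a tumor table (mouse_id, <group_col>, cells) into per-mouse,
    per-group size arrays, pooling ``inert_names`` under ``inert_label``."""
    inert_set = set(inert_names)
    out: dict[str, dict[str, np.ndarray]] = {}
    labels = np.where(tumor_table[group_col].isin(inert_set), inert_label, tumor_table[group_col])
    for (mouse, group), sub in tumor_table.groupby([tumor_table["mouse_id"], labels], sort=True):
        out.setdefault(mouse, {})[group] = sub["cells"].to_numpy(dtype=float)
    return out


@dataclass
class BootstrapResult:
    group: str
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_mice: int
    unstable: bool


def _point_estimate(data: SizesByMouse, group: str, stat: RatioStatistic, inert_label: str) -> tuple[float, list[str]]:
    mice = []
    ratios = []
    for mouse in sorted(data):
        d = data[mouse]
        if inert_label not in d or len(d[inert_label]) == 0:
            continue
        if group in d and len(d[group]) > 0:
            r = stat(d[group], d[inert_label])
            if np.isfinite(r):
                ratios.append(r)
                mice.append(mouse)
    point = float(np.mean(ratios)) if ratios else float("nan")
    return point, mice


def bootstrap_inference(
    tumor_table: pd.DataFrame,
    statistic: str | RatioStatistic = "ln_mean",
    config: StatsConfig | None = None,
    group_col: str = "sgRNA_name",
    inert_names: Sequence[str] = (),
    groups: Sequence[str] | None = None,
    inert_label: str = INERT_LABEL,
) -> pd.DataFrame:
    """Two-stage bootstrap CI and p-value for an inert-normalized statistic.

    Each iteration resamples mice with replacement, then tumors within
    each resampled mouse, and recomputes mean-over-mice of
    statistic(group)/statistic(inert).  CI is the percentile interval at
    ``ci_level``; the two-sided p-value doubles the smaller tail around
    the null value 1 and is floored at 1/iterations.  With a single
    usable mouse the mouse stage degenerates to tumor-level resampling
    (with a warning).  Fully reproducible given ``rng_seed``.
    """
    config = config or StatsConfig()
    stat = _named_ratio_statistic(statistic, config) if isinstance(statistic, str) else statistic
    data = sizes_by_mouse(tumor_table, group_col, inert_names, inert_label)
    if groups is None:
        groups = sorted({g for d in data.values() for g in d if g != inert_label})
    B = config.bootstrap_iterations
    alpha = (1.0 - config.ci_level) / 2.0
    results = []
    for group in groups:
        point, mice = _point_estimate(data, group, stat, inert_label)
        if not mice:
            results.append(BootstrapResult(group, point, np.nan, np.nan, np.nan, 0, True))
            continue
        if len(mice) == 1:
            logger.warning("group %s: single mouse; falling back to tumor-level resampling", group)
        rng = np.random.default_rng([config.rng_seed, zlib.crc32(str(group).encode())])
        arrays = [(data[m][group], data[m][inert_label]) for m in mice]
        M = len(arrays)
        picks = rng.integers(0, M, size=(B, M))
        boot = np.empty(B)
        for b in range(B):
            vals = np.empty(M)
            for s in range(M):
                sg, inert = arrays[picks[b, s]]
                sg_r = sg[rng.integers(0, len(sg), len(sg))]
                in_r = inert[rng.integers(0, len(inert), len(inert))]
                vals[s] = stat(sg_r, in_r)
            finite = vals[np.isfinite(vals)]
            boot[b] = finite.mean() if finite.size else np.nan
        finite = boot[np.isfinite(boot)]
        unstable = finite.size < 0.5 * B
        if finite.size == 0:
            results.append(BootstrapResult(group, point, np.nan, np.nan, np.nan, M, True))
            continue
        lo, hi = np.percentile(finite, [100 * alpha, 100 * (1 - alpha)])
        p = 2.0 * min((finite <= 1.0).mean(), (finite >= 1.0).mean())
        p = min(1.0, max(p, 1.0 / B))
        results.append(BootstrapResult(group, point, float(lo), float(hi), float(p), M, unstable))
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Fisher's exact test (exact hypergeometric enumeration)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table by exact enumeration.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one; exact
    integer arithmetic throughout.  A zero margin returns p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be >= 0")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        logger.debug("degenerate margin in %s; p = 1", table)
        return 1.0
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = comb(r1, k) * comb(r2, c1 - k)
        if num_k <= num_obs:
            total += num_k
    return float(Fraction(total, comb(n, c1)))


def tumor_number_test(
    n_tumors_sg: int,
    n_tumors_inert: int,
    units_sg: int = 1,
    units_inert: int = 1,
) -> float:
    """Fisher's exact test of tumor number against pool composition.

    Observed tumor counts are compared with the counts expected if tumors
    split between the group and the inerts in proportion to the number of
    sgRNAs each contributes to the pool (``units``).
    """
    if min(n_tumors_sg, n_tumors_inert) < 0 or min(units_sg, units_inert) < 1:
        raise ValueError("counts must be >= 0 and units >= 1")
    total = n_tumors_sg + n_tumors_inert
    e_sg = round(total * units_sg / (units_sg + units_inert))
    return fisher_exact_2x2([[n_tumors_sg, n_tumors_inert], [e_sg, total - e_sg]])


# ---------------------------------------------------------------------------
# Q-Q spectrum


def qq_spectrum(
    sg_sizes: Sequence[float] | np.ndarray,
    inert_sizes: Sequence[float] | np.ndarray,
    grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Percentile-by-percentile size ratio of a genotype to the inerts.

    Returns (percentile, sg_value, inert_value, ratio, saturated,
    undefined); a zero inert quantile leaves the ratio undefined (NaN)
    with ``undefined`` set.
    """
    sg = np.asarray(sg_sizes, dtype=float)
    inert = np.asarray(inert_sizes, dtype=float)
    if sg.size == 0 or inert.size == 0:
        raise ValueError("both groups must be non-empty")
    sg_pct = size_percentiles(sg, grid)
    in_pct = size_percentiles(inert, grid)
    out = pd.DataFrame(
        {
            "percentile": sg_pct["percentile"],
            "sg_value": sg_pct["value"],
            "inert_value": in_pct["value"],
            "saturated": sg_pct["saturated"] | in_pct["saturated"],
        }
    )
    undefined = out["inert_value"] == 0
    out["ratio"] = np.where(undefined, np.nan, out["sg_value"] / out["inert_value"].replace(0, np.nan))
    out["undefined"] = undefined
    return out


# ---------------------------------------------------------------------------
# tail-cutoff re-derivation (non-canonical helper)


def derive_tail_multiplier(
    inert_sizes: Sequence[float] | np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Smallest multiplier of the inert median where the empirical tail
    burden first exceeds (and stays above) the burden expected from the
    fitted log-normal.

    This is a re-derivation helper only; the study-derived default cutoff
    (44.73x) is the canonical value and lives in :class:`StatsConfig`.
    Returns NaN when no such multiplier exists.
    """
    x = np.asarray(inert_sizes, dtype=float)
    fit = ln_mean_mle(x)
    med = float(np.median(x))
    sigma = np.sqrt(fit.sigma2_hat)
    if grid is None:
        # stop before the extreme order statistics, where the empirical
        # burden of a finite sample trivially drops to zero
        upper = float(np.quantile(x, 0.999)) / med
        grid = np.geomspace(1.5, max(2.0, upper), 200)
    excess = np.empty(len(grid))
    for i, m in enumerate(grid):
        t = m * med
        observed = x[x > t].sum()
        # E[X; X > t] per tumor under the fitted log-normal
        expected = x.size * np.exp(fit.mu_hat + fit.sigma2_hat / 2.0) * norm.sf(
            (np.log(t) - fit.mu_hat - fit.sigma2_hat) / sigma
        )
        excess[i] = observed - expected
    positive = excess > 0
    for i in range(len(grid)):
        if positive[i:].all():
            return float(grid[i])
    return float("nan")


# ---------------------------------------------------------------------------
# per-genotype summary


def _per_mouse_values(
    data: SizesByMouse, statistic: str, config: StatsConfig, inert_label: str
) -> pd.DataFrame:
    rows = []
    for mouse in sorted(data):
        d = data[mouse]
        inert_med = float(np.median(d[inert_label])) if inert_label in d else float("nan")
        for group, sizes in d.items():
            if statistic == "tumor_number":
                v = float(len(sizes))
            elif statistic == "ln_mean":
                v = ln_mean_mle(sizes).ln_mean
            elif statistic == "heavy_tail":
                v = heavy_tail_burden(sizes, inert_med, config) if np.isfinite(inert_med) else float("nan")
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
            rows.append({"mouse_id": mouse, "group": group, "value": v})
    return pd.DataFrame(rows)


def genotype_statistics(
    tumor_table: pd.DataFrame,
    pool,
    config: StatsConfig | None = None,
    level: str = "sgRNA",
    bootstrap: bool = True,
) -> pd.DataFrame:
    """Per-genotype summary at sgRNA or gene level.

    For each group, reports tumor number, LN mean and heavy-tail burden —
    absolute and relative to the pooled inert sgRNAs within each mouse —
    with bootstrap CIs/p-values for the statistics named in
    ``config.bootstrap_statistics`` and Fisher's exact p for tumor number.
    Gene-level statistics pool a gene's sgRNAs.
    """
    config = config or StatsConfig()
    inert_sgrnas = pool.inert_names()
    n_inert_units = len(inert_sgrnas)
    if level == "sgRNA":
        group_col = "sgRNA_name"
        inert_names = inert_sgrnas
        units = {e.sgRNA_name: 1 for e in pool.entries}
    elif level == "gene":
        group_col = "target_gene"
        inert_names = sorted({e.target_gene for e in pool.entries if e.role == "inert"})
        units: dict[str, int] = {}
        for e in pool.entries:
            units[e.target_gene] = units.get(e.target_gene, 0) + 1
    else:
        raise ValueError("level must be 'sgRNA' or 'gene'")
    data = sizes_by_mouse(tumor_table, group_col, inert_names, INERT_LABEL)
    groups = sorted({g for d in data.values() for g in d if g != INERT_LABEL})
    out = []
    for statistic in ("tumor_number", "ln_mean", "heavy_tail"):
        per_mouse = _per_mouse_values(data, statistic, config, INERT_LABEL)
        try:
            rel = relative_statistics(per_mouse, INERT_LABEL).set_index("group")
        except ValueError:
            # inert statistic undefined in every mouse (e.g., zero inert
            # heavy-tail burden): report absolute values, relative = NaN
            logger.warning("statistic %s: inert undefined in all mice; relative set to NaN", statistic)
            finite = per_mouse[np.isfinite(per_mouse["value"])]
            rel = (
                finite.groupby("group")["value"]
                .agg(absolute="mean", n_mice="count")
                .assign(relative=float("nan"), n_excluded=0)
            )
        boot = None
        if bootstrap and statistic in config.bootstrap_statistics:
            boot = bootstrap_inference(
                tumor_table, statistic, config, group_col=group_col,
                inert_names=inert_names, groups=groups,
            ).set_index("group")
        for g in groups:
            if g not in rel.index:
                continue
            row = {
                "level": level,
                "group": g,
                "statistic": statistic,
                "absolute": rel.loc[g, "absolute"],
                "relative": rel.loc[g, "relative"],
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "p_value": float("nan"),
                "n_mice": int(rel.loc[g, "n_mice"]),
            }
            if boot is not None and g in boot.index:
                row["ci_low"] = boot.loc[g, "ci_low"]
                row["ci_high"] = boot.loc[g, "ci_high"]
                row["p_value"] = boot.loc[g, "p_value"]
            if statistic == "tumor_number":
                n_sg = int(sum(len(d.get(g, ())) for d in data.values()))
                n_in = int(sum(len(d.get(INERT_LABEL, ())) for d in data.values()))
                row["p_value"] = tumor_number_test(n_sg, n_in, units.get(g, 1), n_inert_units)
            out.append(row)
    return pd.DataFrame(out)
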