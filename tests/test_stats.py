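import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st

import tubaquant as tq
from oracles import fisher_oracle
from tubaquant.stats import INERT_LABEL, StatsConfig


class TestLnMeanMLE:
    def test_constant_sizes(self):
        assert tq.ln_mean_mle([7.0, 7.0, 7.0]).ln_mean == pytest.approx(7.0)

    def test_two_point_closed_form(self):
        fit = tq.ln_mean_mle([1.0, np.e**2])
        assert fit.mu_hat == pytest.approx(1.0)
        assert fit.sigma2_hat == pytest.approx(1.0)
        assert fit.ln_mean == pytest.approx(np.exp(1.5))

    def test_single_size(self):
        assert tq.ln_mean_mle([123.0]).ln_mean == pytest.approx(123.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            tq.ln_mean_mle([])
        with pytest.raises(ValueError):
            tq.ln_mean_mle([1.0, 0.0])

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_ln_mean_at_least_geometric_mean(self, sizes):
        fit = tq.ln_mean_mle(sizes)
        geo = float(np.exp(np.mean(np.log(sizes))))
        assert fit.ln_mean >= geo * (1 - 1e-12)


class TestPercentiles:
    def test_linear_interpolation(self):
        out = tq.size_percentiles(np.arange(1, 101), [50])
        assert out["value"].iloc[0] == pytest.approx(50.5)

    def test_saturation(self):
        out = tq.size_percentiles(np.arange(1, 101), [99.99])
        assert out["value"].iloc[0] == 100 and bool(out["saturated"].iloc[0])

    def test_all_equal(self):
        out = tq.size_percentiles([3.0] * 10)
        assert (out["value"] == 3.0).all()

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            tq.size_percentiles([])


class TestHeavyTailBurden:
    def test_none_above_cutoff(self):
        assert tq.heavy_tail_burden([100, 44729], 1000.0) == 0.0

    def test_sum_above_cutoff(self):
        assert tq.heavy_tail_burden([50_000, 60_000, 100], 1000.0) == 110_000.0

    def test_default_multiplier(self):
        assert StatsConfig().tail_multiplier == 44.73

    def test_monotone_and_scale_equivariant(self):
        rng = np.random.default_rng(3)
        sizes = rng.lognormal(7, 1.5, 500)
        med = 800.0
        base = tq.heavy_tail_burden(sizes, med)
        bigger = sizes.copy()
        bigger[np.argmax(bigger)] *= 2
        assert tq.heavy_tail_burden(bigger, med) >= base
        assert tq.heavy_tail_burden(3 * sizes, 3 * med) == pytest.approx(3 * base)


class TestRelativeStatistics:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["mouse_id", "group", "value"])

    def test_equal_to_inert_gives_one(self):
        rows = [(m, g, 5.0) for m in "ABC" for g in ("sgTS", INERT_LABEL)]
        out = tq.relative_statistics(self._frame(rows)).set_index("group")
        assert out.loc["sgTS", "relative"] == pytest.approx(1.0)

    def test_double_inert_gives_two(self):
        rows = [(m, "sgTS", 8.0) for m in "ABC"] + [(m, INERT_LABEL, 4.0) for m in "ABC"]
        out = tq.relative_statistics(self._frame(rows)).set_index("group")
        assert out.loc["sgTS", "relative"] == pytest.approx(2.0)

    def test_mouse_without_inert_excluded(self):
        rows = [("A", "sgTS", 8.0), ("A", INERT_LABEL, 4.0), ("B", "sgTS", 100.0)]
        out = tq.relative_statistics(self._frame(rows)).set_index("group")
        assert out.loc["sgTS", "relative"] == pytest.approx(2.0)
        assert out.loc["sgTS", "n_excluded"] == 1

    def test_no_inert_anywhere_fails(self):
        with pytest.raises(ValueError):
            tq.relative_statistics(self._frame([("A", "sgTS", 8.0)]))


class TestBootstrap:
    def test_determinism(self, cohort_frame, pool):
        sg, frame = cohort_frame
        cfg = StatsConfig(bootstrap_iterations=300, rng_seed=11)
        kwargs = dict(inert_names=pool.inert_names(), groups=[sg])
        a = tq.bootstrap_inference(frame, "ln_mean", cfg, **kwargs)
        b = tq.bootstrap_inference(frame, "ln_mean", cfg, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_data_zero_width_ci(self):
        rows = []
        for m in "ABC":
            rows += [(m, "sgTS", 100.0)] * 5 + [(m, INERT_LABEL, 50.0)] * 5
        frame = pd.DataFrame(rows, columns=["mouse_id", "sgRNA_name", "cells"])
        res = tq.bootstrap_inference(
            frame, "median", StatsConfig(bootstrap_iterations=200, rng_seed=1),
            inert_names=[INERT_LABEL],
        )
        row = res.iloc[0]
        assert row["ci_low"] == row["ci_high"] == row["point"] == pytest.approx(2.0)

    def test_effect_recovery(self, cohort_frame, pool):
        sg, frame = cohort_frame
        res = tq.bootstrap_inference(
            frame, "ln_mean", StatsConfig(bootstrap_iterations=500, rng_seed=5),
            inert_names=pool.inert_names(), groups=[sg],
        ).iloc[0]
        assert res["point"] == pytest.approx(5.0, rel=0.2)
        assert res["ci_low"] > 1.0 and res["p_value"] <= 0.05


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[10, 10], [10, 10]], 1.0),
            ([[5, 1], [1, 5]], 74 / 924),
            ([[0, 5], [5, 0]], 2 / 252),
        ],
    )
    def test_known_tables(self, table, expected):
        assert tq.fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-15)

    def test_zero_margin(self):
        assert tq.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_rational_oracle_and_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            p = tq.fisher_exact_2x2([[a, b], [c, d]])
            assert p == float(fisher_oracle([[a, b], [c, d]]))
            assert p == pytest.approx(ss.fisher_exact([[a, b], [c, d]])[1], rel=1e-6)

    def test_tumor_number_test(self):
        assert tq.tumor_number_test(10, 10, 1, 1) == 1.0
        # 3x the expected 1:2 split should be strongly significant
        assert tq.tumor_number_test(300, 200, 1, 2) < 1e-6


class TestQQSpectrum:
    def test_identical_distributions(self):
        x = np.arange(1.0, 1001.0)
        out = tq.qq_spectrum(x, x.copy())
        assert np.allclose(out["ratio"], 1.0)

    def test_elementwise_doubling(self):
        x = np.arange(1.0, 1001.0)
        out = tq.qq_spectrum(2 * x, x)
        assert np.allclose(out["ratio"], 2.0)

    def test_zero_inert_quantile_flagged(self):
        out = tq.qq_spectrum([1.0, 2.0], [0.0, 0.0], grid=[50])
        assert bool(out["undefined"].iloc[0]) and np.isnan(out["ratio"].iloc[0])

    def test_location_shift_gives_flat_spectrum(self):
        rng = np.random.default_rng(19)
        inert = rng.lognormal(7, 1.0, 20_000)
        sg = rng.lognormal(7 + np.log(3), 1.0, 20_000)
        out = tq.qq_spectrum(sg, inert, grid=[25, 50, 75, 90, 99])
        assert np.allclose(out["ratio"], 3.0, rtol=0.1)


def test_derive_tail_multiplier_detects_pareto_tail():
    rng = np.random.default_rng(23)
    body = rng.lognormal(7, 1.0, 20_000)
    med = np.median(body)
    tail = 30 * med * (1 + rng.pareto(1.5, 200))
    m = tq.derive_tail_multiplier(np.concatenate([body, tail]))
    assert np.isfinite(m) and 1.5 <= m < 200.0


def test_genotype_statistics_summary(cohort_frame, pool):
    sg, frame = cohort_frame
    cfg = StatsConfig(bootstrap_iterations=200, rng_seed=2)
    out = tq.genotype_statistics(frame, pool, cfg, level="sgRNA")
    out = out.set_index(["group", "statistic"])
    assert out.loc[(sg, "ln_mean"), "relative"] == pytest.approx(5.0, rel=0.25)
    assert out.loc[(sg, "ln_mean"), "p_value"] <= 0.05
    # unperturbed sgRNAs hover near 1
    other = pool.entries[2].sgRNA_name
    assert out.loc[(other, "ln_mean"), "relative"] == pytest.approx(1.0, rel=0.35)
    assert np.isfinite(out.loc[(sg, "tumor_number"), "p_value"])
    gene = tq.genotype_statistics(frame, pool, cfg, level="gene", bootstrap=False)
    assert {"tumor_number", "ln_mean", "heavy_tail"} <= set(gene["statistic"])
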