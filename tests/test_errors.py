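import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tubaquant as tq
from oracles import levenshtein_oracle, poisson_tail_oracle
from tubaquant.errors import Difference, ErrorFilterConfig, edit_classes
from tubaquant.extract import Pileup


class TestLikelihood:
    def test_closed_form_small_k(self):
        assert tq.recurrent_error_likelihood(1, 0.1) == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_zero_lambda(self):
        assert tq.recurrent_error_likelihood(1, 0.0) == 0.0
        assert tq.recurrent_error_likelihood(1000, 0.0) == 0.0

    def test_large_k_below_threshold(self):
        assert tq.recurrent_error_likelihood(100, 5.0) < 1e-10

    def test_matches_direct_summation(self):
        for k in (1, 2, 5, 17, 100, 400):
            for lam in (0.01, 0.5, 1.0, 7.3, 50.0):
                got = tq.recurrent_error_likelihood(k, lam)
                assert got == pytest.approx(poisson_tail_oracle(k, lam), abs=1e-12)

    @given(
        k=st.integers(min_value=1, max_value=500),
        lam=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonicity(self, k, lam):
        lik = tq.recurrent_error_likelihood(k, lam)
        assert tq.recurrent_error_likelihood(k + 1, lam) <= lik + 1e-15
        assert tq.recurrent_error_likelihood(k, lam + 0.5) >= lik - 1e-15


class TestNearestNeighbor:
    def _pile(self, bc, reads):
        return Pileup("M1", bc, reads)

    def test_hamming_one_substitution(self):
        parent = self._pile("AAGGCCTT" + "A" * 20, 10**6)
        query = self._pile("AAGGCCTT" + "G" + "A" * 19, 50)
        nb, diff = tq.nearest_neighbor(query, [parent, query])
        assert nb is parent
        assert diff.classes == ["sub:AG"]

    def test_tie_broken_toward_larger(self):
        q = self._pile("AAGGCCTT" + "A" * 20, 10)
        n1 = self._pile("AAGGCCTT" + "C" + "A" * 19, 100)   # distance 1
        n2 = self._pile("AAGGCCTT" + "T" + "A" * 19, 5000)  # distance 1, larger
        nb, _ = tq.nearest_neighbor(q, [n1, n2, q])
        assert nb is n2

    def test_deletion_difference(self):
        parent = self._pile("AAGGCCTT" + "A" * 20, 10**5)
        query = self._pile("AAGGCCTT" + "A" * 19, 40)  # one base missing
        assert levenshtein_oracle(parent.barcode, query.barcode) == 1
        nb, diff = tq.nearest_neighbor(query, [parent, query])
        assert nb is parent and diff.classes == ["del"]

    def test_no_larger_pileup_means_no_neighbor(self):
        q = self._pile("AAGGCCTT" + "A" * 20, 100)
        small = self._pile("AAGGCCTT" + "C" + "A" * 19, 10)
        nb, diff = tq.nearest_neighbor(q, [small, q])
        assert nb is None and diff is None

    def test_distance_two_matches_oracle(self):
        parent = self._pile("AAGGCCTT" + "A" * 20, 10**6)
        query = self._pile("AAGGCCTT" + "GG" + "A" * 18, 3)
        assert levenshtein_oracle(parent.barcode, query.barcode) == 2
        nb, diff = tq.nearest_neighbor(query, [parent, query])
        assert nb is parent and diff.distance == 2
        assert diff.classes == ["sub:AG", "sub:AG"]


def test_edit_classes_cross_length():
    assert edit_classes("ACGT", "ACGT") == []
    assert edit_classes("ACGT", "AGT") == ["del"]
    assert edit_classes("ACGT", "ACCGT") == ["ins"]
    assert sorted(edit_classes("AACGTA", "ACGTAT")) == sorted(["del", "ins"])


class TestEstimateErrorModel:
    def test_recovers_injected_substitution_rate(self, pool, spikeins):
        cfg = tq.SimConfig(seed=21, tumors_per_sgRNA_rate=100)
        tumors = tq.sample_tumors(cfg, pool, "M1")
        em = tq.ErrorModel.flat(3e-3)  # 1e-3 per pair, no indels
        piles, _ = tq.simulate_pileups(tumors, spikeins, em, 0.2, seed=21)
        model = tq.estimate_error_model(piles)
        for p, r in model.sub_rates.items():
            assert 0.5e-3 < r < 2e-3, (p, r)
        assert model.ins_rate == 0.0 and model.del_rate == 0.0

    def test_error_free_study_gives_zero_rates(self, pool, spikeins):
        cfg = tq.SimConfig(seed=22, tumors_per_sgRNA_rate=30)
        tumors = tq.sample_tumors(cfg, pool, "M1")
        piles, _ = tq.simulate_pileups(tumors, spikeins, tq.ErrorModel.zero(), 0.1, seed=22)
        model = tq.estimate_error_model(piles)
        assert all(r == 0.0 for _, r in model.iter_rates())

    def test_fewer_pileups_than_top_n_is_fine(self):
        piles = [Pileup("M1", "AAGGCCTT" + "A" * 20, 100)]
        model = tq.estimate_error_model(piles, ErrorFilterConfig(top_n_for_estimation=100))
        assert all(r == 0.0 for _, r in model.iter_rates())

    def test_depth_invariance(self, pool, spikeins):
        """Doubling read depth leaves per-read rates unchanged within noise."""
        cfg = tq.SimConfig(seed=23, tumors_per_sgRNA_rate=100)
        tumors = tq.sample_tumors(cfg, pool, "M1")
        em = tq.ErrorModel.flat(3e-3)
        rates = []
        for rpc in (0.1, 0.2):
            piles, _ = tq.simulate_pileups(tumors, spikeins, em, rpc, seed=23)
            model = tq.estimate_error_model(piles)
            rates.append(np.mean(list(model.sub_rates.values())))
        assert rates[0] == pytest.approx(rates[1], rel=0.3)


class TestFilterSpurious:
    def test_threshold_sides(self):
        model = tq.ErrorModel.flat(3e-3)  # every pair rate 1e-3
        parent = Pileup("M1", "AAGGCCTT" + "A" * 20, 1000)  # lam = 1 for satellites
        sat = "AAGGCCTT" + "G" + "A" * 19
        import scipy.stats as ss
        k_removed = 1  # P(X>=1 | lam=1) ~ 0.63 > 1e-10
        k_kept = 30  # P(X>=30 | lam=1) < 1e-10
        assert ss.poisson.sf(k_kept - 1, 1.0) < 1e-10 < ss.poisson.sf(k_removed - 1, 1.0)
        piles = [parent, Pileup("M1", sat, k_removed)]
        kept, removed = tq.filter_spurious(piles, model)
        assert parent in kept and len(removed) == 1
        assert removed[0].pileup.barcode == sat
        piles = [parent, Pileup("M1", sat, k_kept)]
        kept, removed = tq.filter_spurious(piles, model)
        assert len(kept) == 2 and not removed

    def test_empty_input(self):
        kept, removed = tq.filter_spurious([], tq.ErrorModel.zero())
        assert kept == [] and removed == []

    def test_denoising_on_synthetic_mouse(self, pool, spikeins):
        cfg = tq.SimConfig(seed=24, tumors_per_sgRNA_rate=100)
        tumors = tq.sample_tumors(cfg, pool, "M1")
        em = tq.ErrorModel.flat(1e-3)
        piles, _ = tq.simulate_pileups(tumors, spikeins, em, 0.1, seed=24)
        model = tq.estimate_error_model(piles)
        kept, removed = tq.filter_spurious(piles, model)
        true_bcs = {t.dual_barcode for t in tumors} | spikeins.barcodes()
        satellites = [p for p in piles if p.barcode not in true_bcs]
        false_kept = [p for p in kept if p.barcode not in true_bcs]
        assert len(false_kept) <= 0.01 * len(satellites)
        # no well-covered true barcode may be discarded
        missing = [a for a in removed if a.pileup.barcode in true_bcs and a.pileup.reads >= 100]
        assert not missing


class TestCollision:
    def _piles(self, assignment):
        # assignment: {(mouse, barcode20)} under one sgID
        return [Pileup(m, "AAGGCCTT" + bc, 10) for m, bc in assignment]

    def test_all_unique(self):
        piles = self._piles({("M1", "A" * 20), ("M2", "C" * 20)})
        rep = tq.estimate_collision_rate(piles)
        assert rep.estimable and rep.overall_cross_mouse_fraction == 0.0

    def test_all_shared(self):
        piles = self._piles({("M1", "A" * 20), ("M2", "A" * 20)})
        rep = tq.estimate_collision_rate(piles)
        assert rep.overall_cross_mouse_fraction == 1.0

    def test_single_mouse_not_estimable(self):
        rep = tq.estimate_collision_rate(self._piles({("M1", "A" * 20)}))
        assert not rep.estimable

    def test_birthday_expectation(self):
        """Uniform draws from D=1e4 across 2 mice of 1e3 tumors: shared
        barcode count agrees with a Monte-Carlo oracle within 3 SE."""
        D, n = 10_000, 1000
        rng = np.random.default_rng(31)
        pool_bcs = ["".join(s) for s in rng.choice(list("ACGT"), size=(D, 20))]
        # Monte-Carlo oracle for the number of cross-mouse shared barcodes
        counts = []
        for _ in range(120):
            s1 = set(rng.integers(0, D, n).tolist())
            s2 = set(rng.integers(0, D, n).tolist())
            counts.append(len(s1 & s2))
        mc_mean, mc_sd = np.mean(counts), np.std(counts)
        i1, i2 = rng.integers(0, D, n), rng.integers(0, D, n)
        piles = [Pileup("M1", "AAGGCCTT" + pool_bcs[i], 5) for i in set(i1.tolist())]
        piles += [Pileup("M2", "AAGGCCTT" + pool_bcs[i], 5) for i in set(i2.tolist())]
        rep = tq.estimate_collision_rate(piles)
        n_shared = int(rep.per_sgid["n_shared"].iloc[0])
        assert abs(n_shared - mc_mean) < 3 * mc_sd
        d_hat = float(rep.per_sgid["d_hat"].iloc[0])
        assert 0.5 * D < d_hat < 2 * D


class TestGcBias:
    def _piles_with_gc(self, rng, slope, n=400):
        piles = []
        for _ in range(n):
            bc = "".join(rng.choice(list("ACGT"), 28))
            gc = (bc.count("G") + bc.count("C")) / 28
            mean_reads = 200 * np.exp(slope * gc)
            piles.append(Pileup("M1", bc, max(1, int(rng.poisson(mean_reads)))))
        return piles

    def test_no_bias_ci_covers_zero(self):
        rep = tq.assess_gc_bias(self._piles_with_gc(np.random.default_rng(41), 0.0))
        assert rep.estimable and rep.ci_low <= 0.0 <= rep.ci_high

    def test_injected_bias_recovered(self):
        rep = tq.assess_gc_bias(self._piles_with_gc(np.random.default_rng(42), 2.0))
        assert rep.ci_low <= 2.0 <= rep.ci_high
        assert rep.flagged

    def test_constant_gc_not_estimable(self):
        # identical GC content in every barcode => zero variance
        piles = [Pileup("M1", "ACGT" * 7, r) for r in range(10, 30)]
        assert not tq.assess_gc_bias(piles).estimable
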