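import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pln_pmf_oracle
from sadnet import sad, synthetic
from sadnet.io_tables import AbundanceVector
from sadnet.sad import (ModelComparison, OctaveHistogram, akaike_weights,
                        count_modes, expected_octave_proportions, fit_sad,
                        nb_pmf, octave_bin, pln_pmf, truncated_pmf)


class TestPlnPmf:
    def test_degenerate_sigma_is_poisson(self):
        assert pln_pmf(2, 0.0, 1e-6) == pytest.approx(math.exp(-1) / 2, abs=1e-4)

    def test_normalization(self):
        total = np.sum(pln_pmf(np.arange(0, 5001), 1.0, 1.5))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_oracle_at_zero(self):
        assert pln_pmf(0, 0.0, 1.0) == pytest.approx(
            pln_pmf_oracle(0, 0.0, 1.0), abs=1e-8)

    @pytest.mark.parametrize("mu", [-1.0, 0.0, 1.0, 3.0])
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [0, 1, 5, 50, 500])
    def test_oracle_grid(self, mu, sigma, n):
        assert pln_pmf(n, mu, sigma) == pytest.approx(
            pln_pmf_oracle(n, mu, sigma), abs=1e-8)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            pln_pmf(1, 0.0, 0.0)

    def test_large_n_quad_route(self):
        val = pln_pmf(20_000, 8.0, 1.0)
        assert 0.0 < val < 1.0
        assert val == pytest.approx(pln_pmf_oracle(20_000, 8.0, 1.0), rel=1e-6)


class TestNbPmf:
    def test_hand_value_at_zero(self):
        assert nb_pmf(0, 2.0, 1.0) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_poisson_limit(self):
        from scipy.stats import poisson
        for n in range(11):
            assert nb_pmf(n, 1.0, 1e6) == pytest.approx(poisson.pmf(n, 1.0),
                                                        abs=1e-4)

    def test_normalization(self):
        total = np.sum(nb_pmf(np.arange(0, 200_000), 5.0, 0.5))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy(self):
        from scipy.stats import nbinom
        m, k = 7.3, 0.8
        grid = np.arange(0, 50)
        expect = nbinom.pmf(grid, k, k / (k + m))
        assert np.allclose(nb_pmf(grid, m, k), expect, atol=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            nb_pmf(1, -1.0, 1.0)


class TestTruncatedPmf:
    def test_zero_is_error(self):
        with pytest.raises(ValueError):
            truncated_pmf(lambda n: nb_pmf(n, 2.0, 1.0), 0)

    def test_sums_to_one(self):
        pmf = lambda n: nb_pmf(n, 2.0, 1.0)
        total = sum(truncated_pmf(pmf, n) for n in range(1, 3000))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_hand_case(self):
        # NB(m=2, k=1): P(1)/(1-P(0)) = (1/3 * 2/3) / (2/3) = 1/3
        pmf = lambda n: nb_pmf(n, 2.0, 1.0)
        assert truncated_pmf(pmf, 1) == pytest.approx(1.0 / 3.0, abs=1e-12)


class TestFitSad:
    def test_pln_parameter_recovery(self):
        spec = synthetic.CommunitySpec(S=2000, model="pln",
                                       params={"mu": 1.0, "sigma": 1.5}, seed=11)
        vec = synthetic.simulate_sad(spec)
        fit = fit_sad(vec, "PLN")
        assert fit.converged
        assert 0.9 <= fit.params["mu"] <= 1.1
        assert 1.4 <= fit.params["sigma"] <= 1.6

    def test_small_vector_unconverged(self):
        fit = fit_sad(np.array([3, 1, 7]), "PLN")
        assert not fit.converged
        assert math.isnan(fit.aic)

    def test_optimum_beats_starts(self):
        spec = synthetic.CommunitySpec(S=300, model="nb",
                                       params={"m": 10.0, "k": 0.7}, seed=3)
        vec = synthetic.simulate_sad(spec)
        fit = fit_sad(vec, "NB")
        assert fit.converged
        uniq, cnt = np.unique(vec.counts, return_counts=True)
        nll = sad._nll_factory(uniq.astype(float), cnt.astype(float), "NB", True)
        for start in sad._moment_starts(vec.counts, "NB"):
            assert -fit.log_lik <= nll(start) + 1e-9

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            fit_sad(np.array([], dtype=int), "PLN")

    def test_aic_identity(self):
        spec = synthetic.CommunitySpec(S=200, model="nb",
                                       params={"m": 5.0, "k": 1.0}, seed=5)
        fit = fit_sad(synthetic.simulate_sad(spec), "NB")
        assert fit.aic == pytest.approx(4 - 2 * fit.log_lik, abs=1e-9)


class TestAkaikeWeights:
    def _fit(self, family, aic, group="g"):
        return sad.SADFitResult(family=family, params={}, log_lik=(4 - aic) / 2,
                                aic=aic, converged=True, n_species=100,
                                group=group)

    def test_equal_aics(self):
        cmp_ = akaike_weights([self._fit("PLN", 100.0), self._fit("NB", 100.0)])
        assert cmp_.w_pln == pytest.approx(0.5)
        assert cmp_.w_nb == pytest.approx(0.5)

    def test_delta_ten(self):
        cmp_ = akaike_weights([self._fit("PLN", 100.0), self._fit("NB", 110.0)])
        assert cmp_.w_pln == pytest.approx(0.99331, abs=1e-5)
        assert cmp_.w_nb == pytest.approx(0.00669, abs=1e-5)

    def test_na_propagation(self):
        bad = sad._unconverged("NB", 3, "g")
        cmp_ = akaike_weights([self._fit("PLN", 10.0), bad])
        assert math.isnan(cmp_.w_pln) and math.isnan(cmp_.w_nb)

    def test_group_mismatch(self):
        with pytest.raises(ValueError):
            akaike_weights([self._fit("PLN", 1.0, "a"), self._fit("NB", 2.0, "b")])

    @given(st.floats(1.0, 500.0), st.floats(1.0, 500.0), st.floats(-50.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one_and_shift_invariant(self, a1, a2, shift):
        c1 = akaike_weights([self._fit("PLN", a1), self._fit("NB", a2)])
        c2 = akaike_weights([self._fit("PLN", a1 + shift),
                             self._fit("NB", a2 + shift)])
        assert c1.w_pln + c1.w_nb == pytest.approx(1.0, abs=1e-12)
        assert c1.w_pln == pytest.approx(c2.w_pln, abs=1e-9)


class TestOctaves:
    def test_hand_binning(self):
        hist = octave_bin(np.array([1, 1, 2, 3, 4, 8]))
        assert list(hist.counts) == [2, 2, 1, 1]

    def test_all_singletons(self):
        hist = octave_bin(np.array([1, 1, 1]))
        assert list(hist.counts) == [3]

    def test_counts_conserved(self, rng):
        abunds = rng.integers(1, 1000, size=250)
        hist = octave_bin(abunds)
        assert hist.n_species == 250


class TestCountModes:
    def test_single_peak(self):
        hist = OctaveHistogram(np.array([10, 40, 30, 15, 5]))
        assert count_modes(hist) == 1

    def test_two_modes_hand(self):
        hist = OctaveHistogram(np.array([30, 10, 5, 25, 30]))
        assert count_modes(hist) == 2

    def test_uniform_plateau_counts_once(self):
        hist = OctaveHistogram(np.array([10, 10, 10, 10]))
        assert count_modes(hist) == 1

    def test_too_few_octaves_is_na(self):
        assert count_modes(OctaveHistogram(np.array([5, 5]))) is None

    def test_low_prominence_bump_ignored(self):
        hist = OctaveHistogram(np.array([50, 30, 31, 30, 10]))
        assert count_modes(hist, min_prominence=0.05) == 1


class TestFitSadSuite:
    def test_regional_model_selection(self, tiny_bundle):
        table = tiny_bundle.tables["archaea"]
        comp, curves = sad.fit_sad_suite(table, "regional")
        assert set(comp["group"]) == {"Vestfold", "Windmill"}
        assert {"wPLN", "wNB"} <= set(comp.columns)
        converged = comp.dropna(subset=["wPLN"])
        assert (converged["wPLN"] + converged["wNB"]).round(9).eq(1.0).all()

    def test_octave_curves_normalized(self, tiny_bundle):
        table = tiny_bundle.tables["eukarya"]
        _, curves = sad.fit_sad_suite(table, "regional")
        for group, sub in curves.groupby("group"):
            for col in ("fitted_PLN", "fitted_NB"):
                vals = sub[col].dropna()
                if len(vals):
                    assert vals.sum() == pytest.approx(1.0, abs=1e-6)

    def test_bad_scale(self, tiny_bundle):
        with pytest.raises(ValueError):
            sad.fit_sad_suite(tiny_bundle.tables["archaea"], "global")


def test_expected_octave_proportions_sum():
    props = expected_octave_proportions("NB", {"m": 20.0, "k": 0.5})
    assert props.sum() == pytest.approx(1.0, abs=1e-6)
    props = expected_octave_proportions("PLN", {"mu": 1.0, "sigma": 1.5})
    assert props.sum() == pytest.approx(1.0, abs=1e-6)


def test_likelihood_ratio_sanity():
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        spec = synthetic.CommunitySpec(S=1500, model="pln",
                                       params={"mu": 0.5, "sigma": 2.0},
                                       seed=seed)
        vec = synthetic.simulate_sad(spec)
        pln = fit_sad(vec, "PLN")
        nb = fit_sad(vec, "NB")
        if pln.converged and nb.converged and pln.log_lik >= nb.log_lik:
            wins += 1
    assert wins >= round(0.95 * n_rep)
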