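import math
from dataclasses import replace

import numpy as np
import pytest

from goosepop.demography import (
    DemographicParams,
    FitResult,
    FitSettings,
    GOOSE_MLE,
    akaike_weights,
    build_model,
    composite_log_likelihood,
    fit_sfs,
    generations_to_calendar,
    migrants_per_generation,
    parametric_bootstrap,
    simulate_sfs,
)
from goosepop.sfs import Sfs2D


class TestParamsAndModels:
    def test_table_of_fitted_values_is_valid_9_param_model(self):
        model = build_model("iii", GOOSE_MLE)
        assert model.model_id == "changing_migration"
        assert model.n_free_params == 9
        kinds = [e[0] for e in model.events]
        assert kinds == ["switch_migration", "merge_into_ancestor"]

    def test_no_migration_rejects_nonzero_rates(self):
        p = replace(GOOSE_MLE)
        with pytest.raises(ValueError, match="no_migration"):
            build_model("i", p)

    def test_constant_migration_requires_tied_epochs(self):
        with pytest.raises(ValueError, match="identical rates"):
            build_model("ii", GOOSE_MLE)

    def test_t2_after_t1_rejected(self):
        with pytest.raises(ValueError, match="T2"):
            DemographicParams(anc_size=100, t1=10, n_wild=100, n_dom=100, t2=20)

    def test_model_ii_equals_iii_with_tied_rates(self):
        p = replace(GOOSE_MLE, t2=0.0, m2_wd=GOOSE_MLE.m1_wd, m2_dw=GOOSE_MLE.m1_dw)
        m2 = build_model("ii", p)
        m3 = build_model("iii", p)
        assert m2.params == m3.params


class TestSimulateSfs:
    def test_zero_mutation_rate_all_monomorphic(self):
        m = build_model("iii", GOOSE_MLE)
        sfs = simulate_sfs(m, n_sites=1000, mu=0.0, n_reps=50, seed=1)
        assert sfs.polymorphic == 0
        assert sfs.monomorphic == 1000

    def test_panmictic_watterson(self):
        """T1 = 0 collapses to a panmictic sample of 52 chromosomes whose
        expected segregating-site density is 4*N*mu*H_51."""
        N, mu, sites = 1000.0, 1.38e-7, 10**6
        p = DemographicParams(anc_size=N, t1=0, n_wild=N, n_dom=N, mu=mu)
        m = build_model("i", p)
        reps = 4000
        sfs = simulate_sfs(m, n_sites=sites, n_reps=reps, seed=42, mode="expected", folded=False)
        expected = 4 * N * mu * sum(1.0 / i for i in range(1, 52)) * sites
        # MC standard error of total branch length ~ L_sd/sqrt(reps)
        assert sfs.polymorphic == pytest.approx(expected, rel=0.03)

    def test_deep_isolation_no_shared_polymorphism(self):
        p = DemographicParams(anc_size=500, t1=40_000, n_wild=500, n_dom=500)
        m = build_model("i", p)
        sfs = simulate_sfs(m, n_sites=10**6, n_reps=500, seed=3, folded=False)
        assert sfs.counts[1:, 1:].sum() == 0.0

    def test_sampled_mode_is_multinomial_around_expected(self):
        m = build_model("iii", GOOSE_MLE)
        exp = simulate_sfs(m, n_sites=10**6, n_reps=4000, seed=9, mode="expected")
        smp = simulate_sfs(m, n_sites=10**6, n_reps=4000, seed=9, mode="sampled")
        assert smp.total_sites == 10**6
        assert float(smp.counts.sum() + smp.monomorphic) == 10**6
        assert smp.polymorphic == pytest.approx(exp.polymorphic, rel=0.05)
        # folding splits exact-tie cells in half; everything else is integral
        assert np.allclose(2 * smp.counts, np.round(2 * smp.counts))

    def test_nesting_identities_bitwise(self):
        """Under a shared seed, model iii with tied epochs reproduces model
        ii exactly, and model ii with zero rates reproduces model i."""
        tied = replace(GOOSE_MLE, t2=0.0, m2_wd=GOOSE_MLE.m1_wd, m2_dw=GOOSE_MLE.m1_dw)
        s_iii = simulate_sfs(build_model("iii", tied), n_sites=10**5, n_reps=500, seed=11)
        s_ii = simulate_sfs(build_model("ii", tied), n_sites=10**5, n_reps=500, seed=11)
        np.testing.assert_array_equal(s_iii.counts, s_ii.counts)
        none = replace(tied, m1_wd=0.0, m1_dw=0.0, m2_wd=0.0, m2_dw=0.0)
        s_ii0 = simulate_sfs(build_model("ii", none), n_sites=10**5, n_reps=500, seed=11)
        s_i = simulate_sfs(build_model("i", none), n_sites=10**5, n_reps=500, seed=11)
        np.testing.assert_array_equal(s_ii0.counts, s_i.counts)

    def test_expected_mode_converges(self):
        m = build_model("iii", GOOSE_MLE)
        a = simulate_sfs(m, n_sites=10**6, n_reps=8000, seed=21)
        b = simulate_sfs(m, n_sites=10**6, n_reps=8000, seed=22)
        assert a.polymorphic == pytest.approx(b.polymorphic, rel=0.05)


class TestCompositeLikelihood:
    def test_hand_arithmetic_two_cells(self):
        obs = Sfs2D(np.array([[0.0, 3.0], [1.0, 0.0]]), monomorphic=0.0, folded=False)
        exp = Sfs2D(np.array([[0.0, 0.75], [0.25, 0.0]]), monomorphic=0.0, folded=False)
        lncl = composite_log_likelihood(obs, exp)
        assert lncl == pytest.approx(3 * math.log(0.75) + math.log(0.25), abs=1e-10)

    def test_single_cell_probability_one(self):
        obs = Sfs2D(np.array([[0.0, 5.0], [0.0, 0.0]]), monomorphic=0.0, folded=False)
        assert composite_log_likelihood(obs, obs) == pytest.approx(0.0)

    def test_observed_proportions_maximize(self):
        counts = np.array([[0.0, 30.0], [20.0, 10.0]])
        obs = Sfs2D(counts, monomorphic=40.0, folded=False)
        best = composite_log_likelihood(obs, obs)
        worse = composite_log_likelihood(
            obs, Sfs2D(counts[::-1, ::-1].copy() * 0 + [[0, 10], [30, 20]], 40.0, False)
        )
        assert best > worse

    def test_zero_probability_cells_floored(self):
        obs = Sfs2D(np.array([[0.0, 1.0], [0.0, 0.0]]), monomorphic=0.0, folded=False)
        exp = Sfs2D(np.array([[0.0, 0.0], [1.0, 0.0]]), monomorphic=0.0, folded=False)
        lncl = composite_log_likelihood(obs, exp)
        assert lncl == pytest.approx(math.log(1e-10))

    def test_dimension_mismatch_rejected(self):
        a = Sfs2D(np.zeros((3, 3)), monomorphic=1.0, folded=False)
        b = Sfs2D(np.zeros((4, 4)), monomorphic=1.0, folded=False)
        with pytest.raises(ValueError, match="dimensions"):
            composite_log_likelihood(a, b)


class TestAkaike:
    def _fit(self, model_id, k, lncl, fp="x"):
        return FitResult(
            model_id=model_id,
            params=GOOSE_MLE,
            log_composite_likelihood=lncl,
            n_free_params=k,
            aic=2 * k - 2 * lncl,
            observed_fingerprint=fp,
        )

    def test_equal_aic_equal_weights(self):
        fits = [self._fit("no_migration", 4, -100.0), self._fit("changing_migration", 9, -95.0)]
        akaike_weights(fits)
        assert fits[0].akaike_weight == pytest.approx(0.5)
        assert fits[1].akaike_weight == pytest.approx(0.5)

    def test_delta_two_gives_ratio_e(self):
        fits = [self._fit("no_migration", 4, -100.0), self._fit("constant_migration", 5, -100.0)]
        akaike_weights(fits)
        assert fits[0].akaike_weight / fits[1].akaike_weight == pytest.approx(math.e)

    def test_large_delta_vanishes(self):
        fits = [self._fit("no_migration", 4, -100.0), self._fit("changing_migration", 4, -125.0)]
        akaike_weights(fits)
        assert fits[1].akaike_weight < 1e-10
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0)

    def test_mismatched_observed_rejected(self):
        fits = [self._fit("no_migration", 4, -100.0, "a"), self._fit("constant_migration", 6, -99.0, "b")]
        with pytest.raises(ValueError, match="different observed"):
            akaike_weights(fits)


class TestFitting:
    def test_no_migration_size_and_time_recovery(self):
        """Divergence-only data refit within loose factors of truth."""
        truth = DemographicParams(anc_size=1200, t1=4000, n_wild=2500, n_dom=900)
        obs = simulate_sfs(
            build_model("i", truth), n_sites=1_681_316, n_reps=10_000, seed=5, mode="sampled"
        )
        fit = fit_sfs(
            obs,
            "i",
            settings=FitSettings(n_reps=2000, n_cycles=1, n_restarts=2,
                                 polish_rounds=2, polish_maxiter=200),
            seed=2,
        )
        assert np.isfinite(fit.log_composite_likelihood)
        assert fit.aic == pytest.approx(2 * 4 - 2 * fit.log_composite_likelihood)
        assert truth.t1 / 2.5 < fit.params.t1 < truth.t1 * 2.5
        assert truth.n_wild / 2 < fit.params.n_wild < truth.n_wild * 2
        assert truth.n_dom / 2 < fit.params.n_dom < truth.n_dom * 2

    def test_empty_observed_rejected(self):
        empty = Sfs2D(np.zeros((23, 31)), monomorphic=0.0, folded=True)
        with pytest.raises(ValueError, match="empty"):
            fit_sfs(empty, "i")


class TestBootstrap:
    def test_minimum_replicates_enforced(self):
        fit = FitResult(
            model_id="no_migration",
            params=GOOSE_MLE,
            log_composite_likelihood=-1.0,
            n_free_params=4,
            aic=10.0,
        )
        obs = Sfs2D(np.zeros((23, 31)), monomorphic=10.0, folded=True)
        with pytest.raises(ValueError, match="at least 20"):
            parametric_bootstrap(fit, obs, b=2)

    def test_percentile_cis_bracket_stable_estimates(self):
        truth = DemographicParams(anc_size=1500, t1=3000, n_wild=1500, n_dom=1500)
        obs = simulate_sfs(
            build_model("i", truth), n_sites=400_000, n_reps=6000, seed=8, mode="sampled"
        )
        fit = fit_sfs(
            obs, "i",
            settings=FitSettings(n_reps=1500, n_cycles=1, n_restarts=1,
                                 polish_rounds=2, polish_maxiter=150),
            seed=4,
        )
        ci = parametric_bootstrap(
            fit, obs, b=20,
            settings=FitSettings(n_reps=800, n_cycles=1, n_restarts=1,
                                 polish_rounds=1, polish_maxiter=80),
            seed=6,
        )
        assert set(ci) == {"anc_size", "t1", "n_wild", "n_dom"}
        for lo, hi in ci.values():
            assert lo <= hi
        assert ci["t1"][0] <= fit.params.t1 * 1.5
        assert ci["t1"][1] >= fit.params.t1 * 0.67


class TestDerivedQuantities:
    def test_migrant_numbers_from_fitted_history(self):
        assert migrants_per_generation(GOOSE_MLE.n_dom, GOOSE_MLE.m1_wd) == 0.41
        assert migrants_per_generation(GOOSE_MLE.n_wild, GOOSE_MLE.m1_dw) == 1.34
        assert migrants_per_generation(GOOSE_MLE.n_dom, GOOSE_MLE.m2_wd) == 1.65
        assert migrants_per_generation(0, 0.5) == 0.0

    def test_migrant_rate_validation(self):
        with pytest.raises(ValueError):
            migrants_per_generation(100, 1.5)
        with pytest.raises(ValueError):
            migrants_per_generation(-1, 0.1)

    def test_recent_shift_to_calendar(self):
        date = generations_to_calendar(159)
        assert date.years_before_present == 477
        assert date.years_bp_nearest_decade == 480
        assert not date.is_bce

    def test_divergence_to_calendar(self):
        date = generations_to_calendar(5319)
        assert date.years_before_present == 15957
        assert date.is_bce
        assert date.calendar_nearest_millennium == 14000

    def test_zero_generations_is_present(self):
        date = generations_to_calendar(0, present_year=2020)
        assert date.calendar_year == 2020
        assert not date.is_bce
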