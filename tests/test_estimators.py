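import numpy as np
import pytest

from sharedrisk import (DegenerateInputError, SimulationConfig, heterogeneity,
                        mr_egger, mr_ivw, run_all, sensitivity_suite,
                        simulate_instruments, wald_ratios, weighted_median,
                        weighted_median_estimate, weighted_mode,
                        weighted_mode_estimate)
from .conftest import make_instrument


def instruments_from_ratios(ratios, se=0.4, gamma=1.0):
    """Instruments whose Wald ratios are exactly `ratios` with ratio-se `se`."""
    return [make_instrument(variant_id=f"rs{i}", chrom="1", pos=1000 + i,
                            gamma=gamma, se_gamma=1e-6,
                            Gamma=r * gamma, se_Gamma=se * gamma)
            for i, r in enumerate(ratios)]


class TestWaldRatios:
    def test_arithmetic(self):
        (wr,) = wald_ratios([make_instrument(gamma=0.25, Gamma=0.5,
                                             se_Gamma=0.1)])
        assert wr.ratio == pytest.approx(2.0)
        assert wr.se == pytest.approx(0.4)

    def test_zero_outcome_effect(self):
        (wr,) = wald_ratios([make_instrument(gamma=0.25, Gamma=0.0)])
        assert wr.ratio == 0.0

    def test_negative_gamma_flips_consistently(self):
        (a,) = wald_ratios([make_instrument(gamma=0.25, Gamma=0.5)])
        (b,) = wald_ratios([make_instrument(gamma=-0.25, Gamma=0.5)])
        assert b.ratio == pytest.approx(-a.ratio)
        assert b.se == pytest.approx(a.se)

    def test_zero_gamma_dropped_with_diagnostic(self, caplog):
        insts = [make_instrument(variant_id="bad", gamma=0.0),
                 make_instrument(variant_id="ok", gamma=0.2)]
        with caplog.at_level("WARNING"):
            ratios = wald_ratios(insts)
        assert [w.variant_id for w in ratios] == ["ok"]
        assert any("bad" in m for m in caplog.messages)


class TestIVW:
    def test_two_identical_instruments_closed_form(self):
        insts = instruments_from_ratios([2.0, 2.0])
        res = mr_ivw(insts, model="fixed")
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.4 / np.sqrt(2), rel=1e-9)

    def test_equals_weighted_average_of_wald_ratios(self, rng):
        insts = [make_instrument(variant_id=f"rs{i}",
                                 gamma=float(rng.uniform(0.05, 0.5)),
                                 Gamma=float(rng.normal(0.1, 0.2)),
                                 se_Gamma=float(rng.uniform(0.02, 0.2)))
                 for i in range(15)]
        res = mr_ivw(insts, model="fixed")
        g = np.array([i.gamma for i in insts])
        G = np.array([i.Gamma for i in insts])
        w = 1 / np.array([i.se_Gamma for i in insts]) ** 2
        b = G / g
        oracle = np.sum(w * g**2 * b) / np.sum(w * g**2)
        assert res.beta == pytest.approx(oracle, abs=1e-10)

    def test_mre_never_deflates(self):
        insts = instruments_from_ratios([2.0, 2.0001])  # tiny heterogeneity
        fixed = mr_ivw(insts, model="fixed")
        mre = mr_ivw(insts, model="mre")
        assert mre.se >= fixed.se

    def test_recovers_simulated_effect(self):
        insts, _ = simulate_instruments(SimulationConfig(
            n_instruments=30, theta=0.5, selection_threshold=None, seed=11))
        res = mr_ivw(insts)
        assert abs(res.beta - 0.5) < 3 * res.se

    def test_single_instrument_rejected(self):
        with pytest.raises(DegenerateInputError, match="Wald"):
            mr_ivw([make_instrument()])


class TestEgger:
    def test_exact_line_recovered(self):
        gammas = (0.1, 0.2, 0.4)
        insts = [make_instrument(variant_id=f"rs{i}", gamma=g,
                                 Gamma=0.1 + 0.5 * g,
                                 se_Gamma=0.03 + 0.01 * i)
                 for i, g in enumerate(gammas)]
        res = mr_egger(insts)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)
        het = heterogeneity(insts)
        assert het[1].Q == pytest.approx(0.0, abs=1e-16)

    def test_orientation_invariance(self):
        """Flipping the allele coding of any instrument leaves Egger unchanged."""
        insts = [make_instrument(variant_id=f"rs{i}", gamma=g, Gamma=G)
                 for i, (g, G) in enumerate([(0.1, 0.06), (0.2, 0.11),
                                             (0.3, 0.14), (0.4, 0.22)])]
        flipped = [make_instrument(variant_id=i.variant_id,
                                   gamma=-i.gamma, Gamma=-i.Gamma)
                   for i in insts[:2]] + list(insts[2:])
        a, b = mr_egger(insts), mr_egger(flipped)
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        intercepts = []
        for rep in range(100):
            insts, _ = simulate_instruments(SimulationConfig(
                n_instruments=50, theta=0.5, mu_alpha=0.0, sd_alpha=0.03,
                seed=1000 + rep))
            intercepts.append(mr_egger(insts).intercept)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts, ddof=1) / 10
        # winner's-curse slope attenuation leaks a small positive term into
        # the intercept; "no directional pleiotropy" means small, not 0 +/- mc
        assert abs(mean) < max(3 * mc_se, 0.01)

    def test_directional_pleiotropy_intercept_recovered(self):
        # significance selection stays on: Egger's gamma > 0 orientation
        # presumes sign-identified (robustly associated) instruments
        intercepts, slopes = [], []
        for rep in range(100):
            insts, _ = simulate_instruments(SimulationConfig(
                n_instruments=50, theta=0.5, mu_alpha=0.05, sd_alpha=0.02,
                seed=2000 + rep))
            res = mr_egger(insts)
            intercepts.append(res.intercept)
            slopes.append(res.beta)
        mc = np.std(intercepts, ddof=1) / 10
        assert np.mean(intercepts) == pytest.approx(0.05, abs=3 * mc)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)

    def test_needs_three(self):
        with pytest.raises(DegenerateInputError):
            mr_egger(instruments_from_ratios([1.0, 2.0]))


class TestWeightedMedian:
    def test_median_of_equal_weights(self):
        insts = instruments_from_ratios([1.0, 2.0, 9.0])
        res = weighted_median(insts, n_boot=50, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_estimate_matches_half_weight_definition(self):
        b = np.array([1.0, 2.0, 3.0, 10.0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        assert weighted_median_estimate(b, w) == pytest.approx(2.5)
        # weight concentrated on one ratio pins the median there
        w2 = np.array([0.05, 10.0, 0.05, 0.05])
        assert weighted_median_estimate(b, w2) == pytest.approx(2.0, abs=0.05)

    def test_bootstrap_reproducible(self):
        insts = instruments_from_ratios([0.8, 1.0, 1.2, 3.0])
        a = weighted_median(insts, n_boot=200, seed=42)
        b = weighted_median(insts, n_boot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se

    def test_robust_to_minority_pleiotropy(self):
        wins = 0
        for rep in range(60):
            insts, _ = simulate_instruments(SimulationConfig(
                n_instruments=30, theta=0.5, mu_alpha=0.3, sd_alpha=0.05,
                pleiotropic_fraction=0.4, selection_threshold=None,
                seed=3000 + rep))
            wm = weighted_median(insts, n_boot=2, seed=rep)
            ivw = mr_ivw(insts)
            if abs(wm.beta - 0.5) < abs(ivw.beta - 0.5):
                wins += 1
        assert wins >= 0.8 * 60


class TestWeightedMode:
    def test_clustered_ratios_beat_outlier(self):
        insts = instruments_from_ratios([0.48, 0.50, 0.52, 3.0])
        res = weighted_mode(insts, n_boot=50, seed=5)
        assert res.beta == pytest.approx(0.50, abs=0.05)

    def test_dense_grid_oracle(self):
        b = np.array([0.48, 0.50, 0.52, 3.0])
        w = np.ones(4)
        from sharedrisk.estimators import mode_bandwidth
        h = mode_bandwidth(b, w)
        grid = np.linspace(-1, 4, 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert weighted_mode_estimate(b, w) == pytest.approx(oracle, abs=1e-4)

    def test_degenerate_all_equal(self):
        insts = instruments_from_ratios([1.5, 1.5, 1.5])
        res = weighted_mode(insts, n_boot=20, seed=3)
        assert res.beta == pytest.approx(1.5)

    def test_outlier_removal_moves_less_than_bandwidth(self):
        from sharedrisk.estimators import mode_bandwidth
        b = np.array([0.48, 0.50, 0.52, 3.0])
        w = np.ones(4)
        h = mode_bandwidth(b, w)
        with_outlier = weighted_mode_estimate(b, w)
        without = weighted_mode_estimate(b[:3], w[:3])
        assert abs(with_outlier - without) < h


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q(self):
        insts = instruments_from_ratios([2.0, 2.0, 2.0])
        het = heterogeneity(insts)
        assert het[0].Q == pytest.approx(0.0, abs=1e-20)
        assert het[0].p == pytest.approx(1.0)

    def test_hand_computed_q(self):
        # ratios 1 and 3 with ratio-se 1: IVW fit is 2, Q = 1 + 1 = 2
        insts = instruments_from_ratios([1.0, 3.0], se=1.0)
        het = heterogeneity(insts)
        assert het[0].Q == pytest.approx(2.0, rel=1e-9)
        assert het[0].df == 1

    def test_egger_q_never_exceeds_ivw_q(self, rng):
        for _ in range(20):
            insts = [make_instrument(variant_id=f"rs{i}",
                                     gamma=float(rng.uniform(0.05, 0.5)),
                                     Gamma=float(rng.normal(0.1, 0.15)),
                                     se_Gamma=float(rng.uniform(0.02, 0.1)))
                     for i in range(8)]
            het = heterogeneity(insts)
            assert het[1].Q <= het[0].Q + 1e-9


class TestSensitivitySuite:
    def test_leave_one_out_row_count(self, simple_instruments):
        tables = sensitivity_suite(simple_instruments)
        assert len(tables.leave_one_out) == len(simple_instruments) + 1
        assert tables.leave_one_out.iloc[-1]["excluded"] == "All"

    def test_identical_instruments_loo_equals_overall(self):
        insts = [make_instrument(variant_id=f"rs{i}", gamma=0.2, Gamma=0.1)
                 for i in range(4)]
        tables = sensitivity_suite(insts)
        betas = tables.leave_one_out["beta"]
        assert np.allclose(betas, betas.iloc[-1])

    def test_single_snp_overall_rows_match_estimators(self, simple_instruments):
        tables = sensitivity_suite(simple_instruments)
        ivw = mr_ivw(simple_instruments)
        egger = mr_egger(simple_instruments)
        row_ivw = tables.single_snp[
            tables.single_snp.variant_id == "All - Inverse-variance weight"]
        row_egger = tables.single_snp[tables.single_snp.variant_id == "All - MR Egger"]
        assert row_ivw.beta.iloc[0] == pytest.approx(ivw.beta)
        assert row_egger.beta.iloc[0] == pytest.approx(egger.beta)

    def test_funnel_is_precision_vs_ratio(self, simple_instruments):
        tables = sensitivity_suite(simple_instruments)
        i0 = simple_instruments[0]
        assert tables.funnel.precision.iloc[0] == pytest.approx(
            abs(i0.gamma) / i0.se_Gamma)


class TestRunAll:
    def test_four_methods_at_four_instruments(self):
        insts = [make_instrument(variant_id=f"rs{i}", gamma=g, Gamma=0.5 * g + d)
                 for i, (g, d) in enumerate([(0.1, 0.01), (0.2, -0.02),
                                             (0.3, 0.015), (0.4, -0.01)])]
        report = run_all(insts, n_boot=30, seed=7)
        methods = [r.method for r in report.results]
        assert methods == ["Inverse-variance weight", "Weighted median",
                           "Weighted mode", "MR Egger"]
        assert all(r.n_snps == 4 for r in report.results)
        assert not report.not_applicable

    def test_single_instrument_falls_back_to_wald(self):
        report = run_all([make_instrument(gamma=0.25, Gamma=0.5, se_Gamma=0.1)])
        assert [r.method for r in report.results] == ["Wald ratio"]
        assert report.results[0].beta == pytest.approx(2.0)
        assert len(report.not_applicable) == 4

    def test_methods_agree_on_clean_simulation(self):
        insts, _ = simulate_instruments(SimulationConfig(
            n_instruments=30, theta=0.5, selection_threshold=None, seed=99))
        report = run_all(insts, n_boot=200, seed=123)
        for r in report.results:
            assert abs(r.beta - 0.5) < 4 * r.se

    def test_seeded_run_reproducible(self, simple_instruments):
        a = run_all(simple_instruments, n_boot=100, seed=11)
        b = run_all(simple_instruments, n_boot=100, seed=11)
        assert [(r.method, r.beta, r.se) for r in a.results] == \
               [(r.method, r.beta, r.se) for r in b.results]

    def test_ci_brackets_estimate_on_or_scale(self, simple_instruments):
        for r in run_all(simple_instruments, n_boot=30, seed=2).results:
            assert r.ci_low <= r.odds_ratio <= r.ci_high


class TestEquivariance:
    def test_sign_and_scale(self, simple_instruments):
        negated = [make_instrument(variant_id=i.variant_id, gamma=i.gamma,
                                   se_gamma=i.se_gamma, Gamma=-i.Gamma,
                                   se_Gamma=i.se_Gamma)
                   for i in simple_instruments]
        scaled = [make_instrument(variant_id=i.variant_id, gamma=2 * i.gamma,
                                  se_gamma=i.se_gamma, Gamma=i.Gamma,
                                  se_Gamma=i.se_Gamma)
                  for i in simple_instruments]
        for fn in (lambda x: mr_ivw(x).beta,
                   lambda x: mr_egger(x).beta,
                   lambda x: weighted_median(x, n_boot=10, seed=1).beta,
                   lambda x: weighted_mode(x, n_boot=10, seed=1).beta):
            base = fn(simple_instruments)
            assert fn(negated) == pytest.approx(-base, rel=1e-6)
            assert fn(scaled) == pytest.approx(base / 2, rel=1e-6)

    def test_egger_with_zero_intercept_is_fixed_ivw(self, simple_instruments):
        """Constraining the Egger intercept to zero reproduces fixed IVW."""
        ivw = mr_ivw(simple_instruments, model="fixed")
        g = np.array([i.gamma for i in simple_instruments])
        G = np.array([i.Gamma for i in simple_instruments])
        w = 1 / np.array([i.se_Gamma for i in simple_instruments]) ** 2
        constrained = np.sum(w * g * G) / np.sum(w * g**2)
        assert constrained == pytest.approx(ivw.beta, abs=1e-12)
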