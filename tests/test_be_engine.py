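"""Tests of TOST, the two decision workflows, power/type-I, sensitivity
and safe-space mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vbekit import be_engine as be
from vbekit import population_model as pm
from vbekit import trial_simulator as ts
from vbekit.structural_pk import PP1M, DosingRegimen


def standardized(rng, n, mean, sd):
    """A sample whose sample mean and sample SD are exactly as requested."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTost:
    def test_identical_formulations_pass(self, rng):
        logs = np.log(50.0) + 1e-6 * rng.standard_normal(50)
        r = be.tost(logs, np.log(50.0) + 1e-6 * rng.standard_normal(50))
        assert r.passed
        assert r.gmr == pytest.approx(1.0, abs=1e-5)

    def test_wide_interval_fails_despite_unit_gmr(self, rng):
        """n = 25/arm with pooled log-SD 0.5: the 90% CI half-width
        t(0.95, 48) * 0.5 * sqrt(2/25) = 0.237 exceeds ln 1.25 = 0.223,
        so TOST must fail even at GMR = 1."""
        x = standardized(rng, 25, 0.0, 0.5)
        y = standardized(rng, 25, 0.0, 0.5)
        r = be.tost(x, y)
        half = stats.t.ppf(0.95, 48) * 0.5 * np.sqrt(2 / 25)
        assert half > np.log(1.25)
        assert r.gmr == pytest.approx(1.0)
        assert not r.passed
        np.testing.assert_allclose(r.ci90, (np.exp(-half), np.exp(half)),
                                   rtol=1e-12)

    def test_abbreviated_trial_regime_fails(self, rng):
        """A 1.38 GMR with ~48% CV at 25/arm cannot conclude BE."""
        x = standardized(rng, 25, np.log(1.38), 0.48)
        y = standardized(rng, 25, 0.0, 0.48)
        assert not be.tost(x, y).passed

    def test_matches_closed_form_ci_oracle(self, rng):
        """Pass/fail coincides with direct 90% CI inclusion on 100 random
        constructed datasets."""
        for _ in range(100):
            n1, n2 = rng.integers(5, 60, size=2)
            x = rng.normal(rng.uniform(-0.3, 0.3), rng.uniform(0.05, 0.6),
                           n1)
            y = rng.normal(0.0, rng.uniform(0.05, 0.6), n2)
            r = be.tost(x, y)
            d = x.mean() - y.mean()
            s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (
                n1 + n2 - 2)
            half = stats.t.ppf(0.95, n1 + n2 - 2) * np.sqrt(
                s2 * (1 / n1 + 1 / n2))
            oracle = (np.exp(d - half) >= 0.8) and (np.exp(d + half) <= 1.25)
            assert r.passed == oracle

    def test_welch_variant(self, rng):
        x = rng.normal(0, 0.1, 40)
        y = rng.normal(0, 0.5, 10)
        rp = be.tost(x, y, variance="pooled")
        rw = be.tost(x, y, variance="welch")
        assert rw.ci90 != rp.ci90  # different SE/df, same point estimate
        assert rw.gmr == pytest.approx(rp.gmr)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            be.tost(np.zeros(5), np.zeros(5))

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            be.tost([0.1], [0.0, 0.1])


class TestWorkflowA:
    def _dataset(self, pop, n, rng_seed, scale=1.0):
        design = ts.TrialDesign(n_per_arm=n, regimen=ts.standard_regimen(),
                                sampling_times=ts.SCHEDULES["weeks_54_63"])
        return be.simulate_trial_scaled(design, pop,
                                        np.random.default_rng(rng_seed),
                                        test_scale=scale)

    def test_mirrored_arms_pass(self, pop_null):
        """Test records that duplicate the reference records under new ids
        must pass (arm size large enough for the CI to fit the limits)."""
        data = ts.simulate_trial(ts.large_design(), pop_null, rng=31,
                                 keep_true_params=False)
        ref = data.arm(pm.REFERENCE)
        jitter = 1.0 + 1e-9  # duplicates, not exact ties
        test = ref.assign(arm=pm.TEST,
                          subject=ref["subject"].str.replace("R", "T"),
                          conc_ng_per_ml=ref["conc_ng_per_ml"] * jitter)
        mirrored = ts.ConcentrationDataset(
            pd.concat([ref, test], ignore_index=True))
        assert be.be_decision_workflow_A(mirrored).passed

    def test_fifty_percent_difference_fails(self, pop_null):
        data = self._dataset(pop_null, 40, 32, scale=1.5)
        res = be.be_decision_workflow_A(data)
        assert not res.passed
        assert res.cmax.gmr > 1.25

    def test_large_trial_verdict_consistent_with_its_interval(self, cfg):
        """A 130/arm trial at the recalibrated shift yields a verdict that
        matches its own CI inclusion (one stochastic realization)."""
        pop = cfg.population(delta=(1.0, 1.42, 1.0, 1.0, 1.0, 1.0))
        data = self._dataset(pop, 130, 33)
        res = be.be_decision_workflow_A(data)
        for m in (res.cmax, res.auc):
            inside = 0.8 <= m.ci90[0] and m.ci90[1] <= 1.25
            assert m.passed == inside
        assert res.passed == (res.cmax.passed and res.auc.passed)


class TestWorkflowB:
    def test_all_unit_ratios_pass(self):
        r = be.RatioSamples(np.ones(200), np.ones(200), n_per_arm=100)
        d = be.be_decision_workflow_B(r)
        assert d.passed and d.p_both_within == 1.0

    def test_constructed_mixture_fails_at_half(self):
        dc = np.r_[np.full(100, 1.3), np.full(100, 1.0)]
        d = be.be_decision_workflow_B(be.RatioSamples(dc, dc, 100))
        assert d.p_both_within == 0.5
        assert not d.passed
        assert d.p_cmax_above == 0.5

    def test_order_invariance(self, rng):
        dc = rng.lognormal(0.1, 0.1, 300)
        da = rng.lognormal(0.05, 0.1, 300)
        d1 = be.be_decision_workflow_B(be.RatioSamples(dc, da, 50))
        perm = rng.permutation(300)
        d2 = be.be_decision_workflow_B(be.RatioSamples(dc[perm], da[perm],
                                                       50))
        assert d1.to_dict() == d2.to_dict()

    def test_null_point_mass_concentrates_near_one(self, pop_null):
        """With delta2 = 1 the ratio pair concentrates near 1; at 150/arm
        most trials sit within a few percent of unity."""
        r = be.posterior_predictive_ratios(1.0, pop_null, n_trials=120,
                                           n_per_arm=150, rng=41)
        assert r.n_trials == 120
        frac = np.mean(np.abs(np.log(r.dcmax)) < 0.2)
        assert frac >= 0.99
        d = be.be_decision_workflow_B(r)
        assert d.passed

    def test_delta2_input_forms(self, pop_null):
        a = be.posterior_predictive_ratios((1.1, 1.05), pop_null, 100, 20,
                                           rng=1)
        b = be.posterior_predictive_ratios(np.full(500, 1.1), pop_null, 100,
                                           20, rng=1)
        assert a.delta2_source == "lognormal_summary"
        assert b.delta2_source == "posterior"
        with pytest.raises(ValueError):
            be.posterior_predictive_ratios(np.array([-1.0]), pop_null, 100,
                                           20)
        with pytest.raises(ValueError):
            be.be_decision_workflow_B(
                be.RatioSamples(np.ones(50), np.ones(50), 10))


class TestPowerAndTypeI:
    def test_gross_inequivalence_never_passes(self, pop_null):
        design = ts.TrialDesign(n_per_arm=25, regimen=ts.standard_regimen(),
                                sampling_times=ts.SCHEDULES["weeks_54_63"])
        res = be.power_type1(design, pop_null, placement="boundary",
                             boundary=2.0, n_reps=30, rng=51)
        assert res.pass_fraction == 0.0

    def test_power_declines_toward_the_limit(self, pop_null):
        """Pass fraction is monotone non-increasing as the true GMR moves
        from 1 to 1.1 to 1.25 (2 MC SEs of slack)."""
        design = ts.TrialDesign(n_per_arm=40, regimen=ts.standard_regimen(),
                                sampling_times=ts.SCHEDULES["weeks_54_63"])
        fractions = {}
        for gmr in (1.0, 1.1, 1.25):
            r = be.power_type1(design, pop_null, placement="boundary",
                               boundary=gmr, n_reps=200, rng=52)
            fractions[gmr] = (r.pass_fraction, r.mc_se)
        assert (fractions[1.0][0]
                >= fractions[1.1][0] - 2 * fractions[1.1][1])
        assert (fractions[1.1][0]
                >= fractions[1.25][0] - 2 * fractions[1.25][1])
        assert fractions[1.25][0] < fractions[1.0][0]

    def test_placement_validation(self, pop_null):
        design = ts.abbreviated_design()
        with pytest.raises(ValueError, match="placement"):
            be.power_type1(design, pop_null, placement="nowhere")
        with pytest.raises(ValueError, match="delta"):
            be.power_type1(design, pop_null, placement="custom")
        with pytest.raises(ValueError):
            be.power_type1(design, pop_null, n_reps=5)


class TestSensitivity:
    def test_pp3m_parameters_inert_under_pp1m_only_regimen(self, pop_null):
        """Shift components without an effect pathway produce exactly zero
        exposure change."""
        reg = DosingRegimen.from_events(
            [(28.0 * j, 150.0, PP1M) for j in range(4)])
        table = be.sensitivity_ranking(pop_null, regimen=reg,
                                       interval=(60.0, 110.0))
        inert = table.set_index("parameter")
        for p in ("kas3_max", "kar3_max", "kas3_50", "kar3_50", "gamma",
                  "f3"):
            assert inert.loc[p, "influence"] == pytest.approx(0.0, abs=1e-9)

    def test_kas3_max_most_influential_under_default_regimen(self, pop_null):
        table = be.sensitivity_ranking(pop_null)
        assert table["parameter"].iloc[0] == "kas3_max"
        assert len(table) == 6

    def test_five_percent_shift_moves_exposure_by_a_few_percent(self,
                                                                pop_null):
        """delta2 = 1.05 changes the typical subject's exposure by a couple
        of percent — nowhere near the 38% a small trial once suggested."""
        table = be.sensitivity_ranking(pop_null).set_index("parameter")
        assert 0.1 < abs(table.loc["kas3_max", "pct_change_cmax"]) < 10.0


class TestSafeSpace:
    def test_map_size_and_pass_rate_at_null(self, pop_null):
        """Degenerate delta sampling at exactly 1 reduces mode A to the
        null-power experiment."""
        design = ts.TrialDesign(n_per_arm=100, regimen=ts.standard_regimen(),
                                sampling_times=ts.SCHEDULES["weeks_54_63"])
        m = be.safe_space_A(pop_null, design, n_trials=30, rng=61,
                            delta_low=1.0, delta_high=1.0)
        assert len(m.table) == 30
        assert m.mode == "A_fuzzy"
        assert m.table["pass"].mean() > 0.5  # null power is high

    def test_extreme_ratios_never_pass(self, pop_null):
        """TOST dominance: any evaluated point whose realized GMR exceeds
        1.6 must fail."""
        design = ts.TrialDesign(n_per_arm=30, regimen=ts.standard_regimen(),
                                sampling_times=ts.SCHEDULES["weeks_54_63"])
        m = be.safe_space_A(pop_null, design, n_trials=50, rng=62)
        extreme = m.table[(m.table["gmr_cmax"] > 1.6)
                          | (m.table["gmr_auc"] > 1.6)]
        assert len(extreme) > 0
        assert not extreme["pass"].any()

    def test_reference_point_inside_safe_space(self, pop_null):
        m = be.safe_space_B(pop_null, [(1.0, 1.0)], n_trials=10,
                            n_per_arm=60, rng=63)
        assert bool(m.table["in_safe_space"].iloc[0])
        assert m.mode == "B_crisp"

    def test_crisp_boundary_single_flip_along_delta2(self, pop_null):
        """Along a monotone delta2 slice the mean-ratio decision flips
        exactly once (Monte-Carlo noise well below the grid resolution)."""
        grid = [(1.0, d2) for d2 in (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)]
        m = be.safe_space_B(pop_null, grid, n_trials=25, n_per_arm=200,
                            rng=64)
        flags = m.table["in_safe_space"].to_numpy()
        assert flags.sum() > 0 and (~flags).sum() > 0
        assert int(np.abs(np.diff(flags.astype(int))).sum()) <= 2

    def test_bisection_refines_boundary(self, pop_null):
        d2 = be.refine_boundary_delta2(pop_null, delta1=1.0, lo=1.0, hi=3.0,
                                       n_trials=4, n_per_arm=40, rng=65,
                                       tol=0.1)
        assert 1.0 < d2 < 3.0

    def test_grid_and_rule_validation(self, pop_null):
        with pytest.raises(ValueError, match="grid"):
            be.safe_space_B(pop_null, [], 5, 10)
        with pytest.raises(ValueError, match="rule"):
            be.safe_space_B(pop_null, [(1.0, 1.0)], 2, 10, rule="median")
        with pytest.raises(ValueError):
            be.safe_space_A(pop_null, ts.abbreviated_design(), n_trials=5)
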