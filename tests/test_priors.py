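"""Birth-death, relaxed-clock, calibration, brace and hyperprior densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import lognorm

import bracedate as bd
from bracedate.priors import bd_log_g
from bracedate.synthetic import simulate_time_tree, SimulationRecipe


class TestBirthDeath:
    @pytest.mark.parametrize("lam,mu", [(1.0, 0.0), (2.0, 1.0), (1.0, 0.9)])
    def test_per_age_density_normalizes(self, lam, mu):
        params = bd.BirthDeathParams(birth=lam, death=mu)
        t_root = 7.3
        total, err = quad(lambda t: math.exp(bd_log_g(t, params, t_root)),
                          0.0, t_root, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_yule_limit(self):
        t_root = 5.0
        ts = np.linspace(0.1, 4.9, 25)
        exact = bd_log_g(ts, bd.BirthDeathParams(birth=1.0, death=0.0), t_root)
        tiny = bd_log_g(ts, bd.BirthDeathParams(birth=1.0, death=1e-9), t_root)
        np.testing.assert_allclose(tiny, exact, atol=1e-8)

    def test_relabeling_tips_leaves_value_unchanged(self):
        params = bd.BirthDeathParams()
        t1, _ = bd.parse_newick("((A,B),(C,D));")
        t2, _ = bd.parse_newick("((C,D),(B,A));")
        ages1 = np.zeros(t1.n_nodes)
        ages2 = np.zeros(t2.n_nodes)
        # same multiset of internal ages on both labelings
        inner_ages = [300.0, 500.0]
        for top, ages in ((t1, ages1), (t2, ages2)):
            kids = sorted(
                (v for v in top.internal_nodes if v != top.root),
                key=lambda v: sorted(top.clades[int(v)]),
            )
            for v, a in zip(kids, inner_ages):
                ages[int(v)] = a
            ages[top.root] = 1000.0
        v1 = bd.log_birth_death(bd.TimeTree(t1, ages1), params)
        v2 = bd.log_birth_death(bd.TimeTree(t2, ages2), params)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            bd.BirthDeathParams(birth=1.0, death=1.0)
        with pytest.raises(ValueError):
            bd.BirthDeathParams(birth=-1.0, death=0.0)


class TestUcln:
    def test_single_branch_median_closed_form(self):
        mu_r, s = 3e-4, 0.6
        median = mu_r * math.exp(-0.5 * s * s)
        clock = bd.ClockState(rates=np.array([median]), mu=mu_r, sigma=s)
        expect = -math.log(median * s * math.sqrt(2 * math.pi))
        assert bd.log_ucln(clock) == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_lognorm_and_doubles_with_two_branches(self):
        mu_r, s = 2.6e-4, 0.3
        r = 4.0e-4
        loc = math.log(mu_r) - 0.5 * s * s
        one = bd.log_ucln(bd.ClockState(rates=np.array([r]), mu=mu_r, sigma=s))
        oracle = lognorm.logpdf(r, s=s, scale=math.exp(loc))
        assert one == pytest.approx(oracle, abs=1e-10)
        two = bd.log_ucln(bd.ClockState(rates=np.array([r, r]), mu=mu_r,
                                        sigma=s))
        assert two == pytest.approx(2 * one, abs=1e-10)

    def test_mean_parameterisation_by_simulation(self):
        mu_r, s = 2.6e-4, 0.5
        rng = np.random.default_rng(5)
        draws = rng.lognormal(mean=math.log(mu_r) - 0.5 * s * s, sigma=s,
                              size=10**5)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - mu_r) < 3 * se

    def test_strict_mode_rejected(self):
        clock = bd.ClockState(rates=np.array([1e-4]), mu=1e-4, sigma=0.0)
        with pytest.raises(ValueError):
            bd.log_ucln(clock)


class TestCalibration:
    def test_plateau_and_tails(self):
        cal = bd.Calibration(node=0, min_age=3800.0, max_age=4520.0,
                             steepness_min=95.0, steepness_max=113.0)
        assert bd.log_calibration(cal, 4000.0) == 0.0
        assert bd.log_calibration(cal, 4520.0 + 113.0) == pytest.approx(-0.5)
        assert bd.log_calibration(cal, 3800.0 - 2 * 95.0) == pytest.approx(-2.0)

    def test_one_sided(self):
        lo_only = bd.Calibration(node=0, min_age=100.0, steepness_min=10.0)
        assert bd.log_calibration(lo_only, 1e6) == 0.0
        assert bd.log_calibration(lo_only, 90.0) == pytest.approx(-0.5)
        hi_only = bd.Calibration(node=0, max_age=100.0, steepness_max=10.0)
        assert bd.log_calibration(hi_only, 0.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=10_000.0))
    def test_continuous_and_monotone(self, age):
        cal = bd.Calibration(node=0, min_age=1000.0, max_age=2000.0,
                             steepness_min=50.0, steepness_max=50.0)
        v = bd.log_calibration(cal, age)
        assert v <= 0.0
        # continuity at boundaries: values near a boundary are near 0
        eps = 1e-6
        assert bd.log_calibration(cal, 2000.0 + eps) == pytest.approx(0, abs=1e-9)
        assert bd.log_calibration(cal, 1000.0 - eps) == pytest.approx(0, abs=1e-9)
        # monotone: one step further out never increases the density
        if age > 2000.0:
            assert bd.log_calibration(cal, age + 1) <= v
        if age < 1000.0:
            assert v >= bd.log_calibration(cal, max(age - 1, 0.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            bd.Calibration(node=0)
        with pytest.raises(ValueError):
            bd.Calibration(node=0, min_age=10.0, max_age=5.0)


class TestBrace:
    def test_equal_ages_zero(self):
        br = bd.Brace(nodes=(1, 2, 3), sigma=5.0)
        assert bd.log_brace(br, [100.0, 100.0, 100.0]) == 0.0

    def test_one_sigma_pair(self):
        br = bd.Brace(nodes=(1, 2), sigma=5.0)
        assert bd.log_brace(br, [100.0, 105.0]) == pytest.approx(-0.5)

    def test_triple_anchored_at_first(self):
        br = bd.Brace(nodes=(1, 2, 3), sigma=5.0)
        assert bd.log_brace(br, [100.0, 105.0, 95.0]) == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=-500, max_value=500))
    def test_translation_invariance(self, shift):
        br = bd.Brace(nodes=(1, 2, 3), sigma=7.0)
        ages = np.array([900.0, 930.0, 880.0])
        assert bd.log_brace(br, ages + shift) == pytest.approx(
            bd.log_brace(br, ages), abs=1e-9)


class TestRelative:
    def test_satisfied_is_zero(self):
        con = bd.RelativeConstraint(younger=1, older=2, softness=10.0)
        assert bd.log_relative(con, 1800.0, 1900.0) == 0.0

    @pytest.mark.parametrize("k,expect", [(1.0, -0.5), (3.0, -4.5)])
    def test_violation_tails(self, k, expect):
        con = bd.RelativeConstraint(younger=1, older=2, softness=10.0)
        assert bd.log_relative(con, 100.0 + k * 10.0, 100.0) == pytest.approx(
            expect)

    def test_monotone_in_violation(self):
        con = bd.RelativeConstraint(younger=1, older=2, softness=10.0)
        vals = [bd.log_relative(con, 100.0 + d, 100.0) for d in
                np.linspace(0, 100, 20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestHyperpriors:
    def test_all_fixed_is_zero(self):
        clock = bd.ClockState(rates=np.array([1e-4]), mu=1e-4, sigma=0.3)
        cfg = bd.HyperPriorConfig(sample_clock_mean=False,
                                  sample_clock_sigma=False)
        assert bd.log_hyperpriors(clock, bd.BirthDeathParams(), cfg) == 0.0

    def test_exponential_sigma_closed_form(self):
        clock = bd.ClockState(rates=np.array([1e-4]), mu=1e-4, sigma=1.0)
        cfg = bd.HyperPriorConfig(sample_clock_mean=False,
                                  sample_clock_sigma=True)
        assert bd.log_hyperpriors(clock, bd.BirthDeathParams(),
                                  cfg) == pytest.approx(-1.0)

    def test_out_of_support_is_minus_inf(self):
        clock = bd.ClockState(rates=np.array([1.0]), mu=1.0, sigma=0.3)
        val = bd.log_hyperpriors(clock, bd.BirthDeathParams(),
                                 bd.HyperPriorConfig())
        assert val == -math.inf


class TestTotalPriorFiniteness:
    def test_total_is_finite_sum_on_valid_state(self):
        rec = SimulationRecipe(seed=2)
        tree = simulate_time_tree(rec)
        clock = bd.ClockState(
            rates=np.full(tree.topology.n_branches, 2.6e-4),
            mu=2.6e-4, sigma=0.3)
        total = (bd.log_birth_death(tree, bd.BirthDeathParams())
                 + bd.log_ucln(clock)
                 + bd.log_hyperpriors(clock, bd.BirthDeathParams(),
                                      bd.HyperPriorConfig()))
        assert np.isfinite(total)
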