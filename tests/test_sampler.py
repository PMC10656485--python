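"""MCMC correctness: diagnostics, posterior summaries, and agreement with
quadrature oracles on small targets."""

import math

import numpy as np
import pytest

import bracedate as bd
from bracedate.sampler import COMPONENT_NAMES
from bracedate.synthetic import (SimulationRecipe, calibrations_from_truth,
                                 simulate_branch_sample, simulate_time_tree,
                                 simulate_ucln_rates)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


class TestEss:
    def test_iid_normal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        assert 8500 <= bd.ess(x) <= 11_500

    def test_ar1_closed_form(self):
        rho, n = 0.5, 20_000
        rng = np.random.default_rng(1)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * math.sqrt(1 - rho * rho)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expect = n * (1 - rho) / (1 + rho)
        assert abs(bd.ess(x) - expect) < 0.15 * expect

    def test_constant_series_convention(self):
        assert bd.ess(np.full(100, 3.7)) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bd.ess(np.arange(5))

    def test_cross_check_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        n = 20_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = 0.7 * x[i - 1] + rng.normal() * math.sqrt(1 - 0.49)
        ours = bd.ess(x)
        theirs = float(arviz.ess(x[None, :]))
        assert abs(ours - theirs) < 0.2 * theirs


class TestHpd:
    def test_shortest_window_outlier(self):
        assert bd.hpd_interval([0, 0, 0, 0, 100], 0.8) == (0.0, 0.0)

    def test_sorted_1_to_100_level_95(self):
        x = np.arange(1, 101, dtype=float)
        lo, hi = bd.hpd_interval(x, 0.95)
        # exhaustive window-search oracle
        m = math.ceil(0.95 * 100)
        widths = [(x[i + m - 1] - x[i], x[i], x[i + m - 1])
                  for i in range(100 - m + 1)]
        w, olo, ohi = min(widths)
        assert hi - lo == w == 94.0
        assert (lo, hi) == (olo, ohi)

    def test_bounds_are_sample_members(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=257)
        lo, hi = bd.hpd_interval(x, 0.9)
        assert lo in x and hi in x

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bd.hpd_interval([1.0, 2.0], 0.95)
        with pytest.raises(ValueError):
            bd.hpd_interval(np.arange(10.0), 1.5)


# ---------------------------------------------------------------------------
# small-target oracle runs
# ---------------------------------------------------------------------------


from tests_support_three_tip import (three_tip_grid_posterior as
                                     _three_tip_grid_posterior,
                                     three_tip_problem as _three_tip_problem)


class TestThreeTipOracle:
    def test_posterior_mean_within_2pct_of_quadrature(self):
        top, approx, constraints, bdp, hyper, rate = _three_tip_problem()
        cfg = bd.McmcConfig(iterations=60_000, seed=5, clock_mode="strict",
                            init_clock_mean=rate)
        trace = bd.run_mcmc(approx, top, constraints, config=cfg, bd=bdp,
                            hyper=hyper)
        inner = bd.mrca(top, {"A", "B"})
        mcmc_mean = trace.node_ages(inner).mean()
        t, w = _three_tip_grid_posterior(top, approx, bdp, rate)
        grid_mean = np.trapezoid(t * w, t)
        assert mcmc_mean == pytest.approx(grid_mean, rel=0.02)

    def test_marginal_matches_grid_cdf(self):
        # detailed-balance smoke test: KS distance between the empirical
        # marginal and the quadrature CDF stays small
        from scipy.stats import kstest

        top, approx, constraints, bdp, hyper, rate = _three_tip_problem()
        cfg = bd.McmcConfig(iterations=60_000, seed=6, clock_mode="strict",
                            init_clock_mean=rate, stride=8)
        trace = bd.run_mcmc(approx, top, constraints, config=cfg, bd=bdp,
                            hyper=hyper)
        inner = bd.mrca(top, {"A", "B"})
        samples = trace.node_ages(inner)[:5000]
        t, w = _three_tip_grid_posterior(top, approx, bdp, rate)
        cdf_grid = np.concatenate([[0.0], np.cumsum(
            0.5 * (w[1:] + w[:-1]) * np.diff(t))])
        cdf_grid /= cdf_grid[-1]
        stat = kstest(samples, lambda x: np.interp(x, t, cdf_grid)).statistic
        assert stat < 0.05

    def test_determinism_same_seed(self):
        top, approx, constraints, bdp, hyper, rate = _three_tip_problem()
        cfg = bd.McmcConfig(iterations=5_000, seed=7, clock_mode="strict",
                            init_clock_mean=rate)
        t1 = bd.run_mcmc(approx, top, constraints, config=cfg, bd=bdp,
                         hyper=hyper)
        t2 = bd.run_mcmc(approx, top, constraints, config=cfg, bd=bdp,
                         hyper=hyper)
        np.testing.assert_array_equal(t1.ages, t2.ages)
        np.testing.assert_array_equal(t1.log_posterior, t2.log_posterior)


# ---------------------------------------------------------------------------
# trace invariants and summaries
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_run():
    rec = SimulationRecipe(n_tips=8, seed=21, sample_size=400)
    rng = np.random.default_rng(21)
    tree = simulate_time_tree(rec, rng)
    clock = simulate_ucln_rates(tree, rec.clock_mean, rec.clock_sigma, rng)
    sample = simulate_branch_sample(tree, clock, rec.sample_size,
                                    rec.noise_cv, rng)
    approx = bd.fit_mvn(sample)
    constraints = bd.assemble_constraints(tree.topology,
                                          calibrations_from_truth(tree))
    cfg = bd.McmcConfig(iterations=20_000, seed=21)
    trace = bd.run_mcmc(approx, tree.topology, constraints, config=cfg)
    return tree, trace


class TestTraceInvariants:
    def test_every_state_satisfies_age_ordering(self, small_run):
        tree, trace = small_run
        top = trace.topology
        full = np.zeros((trace.n_kept, top.n_nodes))
        full[:, top.n_tips:] = trace.ages
        nonroot = np.arange(top.n_branches)
        dur = full[:, top.parent[nonroot]] - full[:, nonroot]
        assert np.all(dur > 0)

    def test_components_sum_to_log_posterior(self, small_run):
        _, trace = small_run
        np.testing.assert_allclose(trace.components.sum(axis=1),
                                   trace.log_posterior, atol=1e-8)
        assert trace.components.shape[1] == len(COMPONENT_NAMES)

    def test_summary_covers_exactly_the_internal_nodes(self, small_run):
        _, trace = small_run
        summ = bd.summarize(trace)
        top = trace.topology
        finite = np.where(np.isfinite(summ.mean_age))[0]
        np.testing.assert_array_equal(finite, top.internal_nodes)
        assert np.all(summ.hpd_lower[finite] <= summ.mean_age[finite])
        assert np.all(summ.mean_age[finite] <= summ.hpd_upper[finite])
        assert np.all(summ.ess_age[finite] <= trace.n_kept)

    def test_trace_save_round_trip(self, small_run, tmp_path):
        _, trace = small_run
        p = tmp_path / "trace.tsv"
        trace.save(p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t", comment="#")
        assert len(df) == trace.n_kept
        np.testing.assert_allclose(df["log_posterior"].to_numpy(),
                                   trace.log_posterior)


class TestDerivedComparisons:
    def test_age_difference_constant_and_antisymmetry(self, small_run):
        _, trace = small_run
        top = trace.topology
        a, b = (int(v) for v in top.internal_nodes[:2])
        m_ab, (lo_ab, hi_ab) = bd.age_difference(trace, a, b)
        m_ba, (lo_ba, hi_ba) = bd.age_difference(trace, b, a)
        assert m_ab == pytest.approx(-m_ba)
        assert lo_ab == pytest.approx(-hi_ba) and hi_ab == pytest.approx(-lo_ba)

    def test_age_difference_degenerate_case(self, small_run):
        _, trace = small_run
        top = trace.topology
        v = int(top.internal_nodes[0])
        m, (lo, hi) = bd.age_difference(trace, v, v)
        assert (m, lo, hi) == (0.0, 0.0, 0.0)

    def test_compare_rates_identical_traces(self, small_run):
        _, trace = small_run
        z, p = bd.compare_rates_z(trace, trace)
        assert (z, p) == (0.0, 1.0)

    def test_compare_rates_closed_form_and_sign(self, small_run):
        _, trace = small_run
        import copy
        slower = copy.copy(trace)
        rng = np.random.default_rng(0)
        noise = 1.0 + 0.01 * rng.normal(size=trace.rates.shape[1])
        slower.rates = trace.rates * 0.9 * noise[None, :]
        z, p = bd.compare_rates_z(slower, trace)
        d = slower.rates.mean(axis=0) - trace.rates.mean(axis=0)
        expect = d.mean() * math.sqrt(d.size) / d.std(ddof=1)
        assert z == pytest.approx(expect, rel=1e-12)
        assert z < 0 and p < 0.05

    def test_unknown_node_rejected(self, small_run):
        _, trace = small_run
        with pytest.raises(KeyError):
            bd.age_difference(trace, 0, 1)  # tips are not in the trace
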