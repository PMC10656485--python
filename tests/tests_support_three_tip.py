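"""Shared 3-tip dating problem with a 1-D quadrature oracle.

The tree ((A,B),C) has a single free internal age once the root is
pinned by a narrow calibration and the clock is strict and fixed, so the
posterior can be integrated on a grid and compared with the sampler.
"""

import numpy as np

import bracedate as bd
from bracedate.mvn import observed_branch_map
from bracedate.priors import bd_log_g


def three_tip_problem():
    top, _ = bd.parse_newick("((A,B),C);")
    rate = 0.01
    m = np.array([0.05, 0.05, 0.16])  # obs space: A, B, merged root pair
    var = np.array([1e-4, 1e-4, 4e-4])
    approx = bd.MVNApprox(mean=m, cov=np.diag(var), mode="diagonal",
                          ridge=0.0, obs_map=observed_branch_map(top))
    cals = [bd.Calibration(node=top.root, min_age=9.99, max_age=10.01,
                           steepness_min=0.005, steepness_max=0.005,
                           name="root_pin")]
    constraints = bd.assemble_constraints(top, cals)
    bdp = bd.BirthDeathParams(birth=0.3, death=0.1)
    hyper = bd.HyperPriorConfig(sample_clock_mean=False,
                                sample_clock_sigma=False)
    return top, approx, constraints, bdp, hyper, rate


def three_tip_grid_posterior(top, approx, bdp, rate, t_root=10.0, n=4001):
    """Quadrature of the identical target density over the free age."""
    t = np.linspace(1e-6, t_root - 1e-6, n)
    inv_var = 1.0 / np.diag(approx.cov)
    x_a = rate * t
    x_b = rate * t
    x_root = rate * (t_root - t) + rate * t_root
    d = np.stack([x_a - approx.mean[0], x_b - approx.mean[1],
                  x_root - approx.mean[2]])
    loglik = -0.5 * np.einsum("ij,i->j", d * d, inv_var)
    logpost = loglik + bd_log_g(t, bdp, t_root)
    w = np.exp(logpost - logpost.max())
    w /= np.trapezoid(w, t)
    return t, w
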