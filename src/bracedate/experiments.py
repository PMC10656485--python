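"""End-to-end validation experiments on fully known synthetic data.

These drivers wire the simulators to the sampler for the three standard
checks of a dating engine:

* **recovery** — simulate, date, and measure 95% HPD coverage of the true
  internal-node ages;
* **brace propagation** — a duplicated gene tree calibrated in one copy
  only, dated with and without cross-braces, to measure how bracing
  transports calibration information to the uncalibrated copy and shifts
  the inferred rates;
* **root clash** — a root maximum set younger than the truth, to verify
  that the root-age posterior accumulates against the calibration
  boundary instead of leaking past it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bracing import assemble_constraints, find_equivalent_nodes
from .mvn import fit_mvn
from .priors import BirthDeathParams, Calibration
from .sampler import McmcConfig, compare_rates_z, run_mcmc, summarize
from .synthetic import (SimulationRecipe, calibrations_from_truth,
                        make_duplicated_gene_tree, simulate_branch_sample,
                        simulate_time_tree, simulate_ucln_rates)

__all__ = ["recovery_experiment", "brace_experiment", "root_clash_experiment",
           "RecoveryResult", "BraceResult", "RootClashResult"]


@dataclass
class RecoveryResult:
    covered: int
    total: int
    mean_rate: float

    @property
    def coverage(self) -> float:
        return self.covered / self.total


def recovery_experiment(seed: int, n_tips: int = 16, cv: float = 0.05,
                        iterations: int = 50_000,
                        n_internal_cals: int = 3) -> RecoveryResult:
    """One seeded simulate-and-date round trip.

    A 16-tip birth-death tree with UCLN rates and a 5% noise
    pseudo-posterior, dated under a root calibration plus three internal
    calibrations bracketing the truth.
    """
    rec = SimulationRecipe(n_tips=n_tips, noise_cv=cv, seed=seed)
    rng = np.random.default_rng(seed)
    tree = simulate_time_tree(rec, rng)
    clock = simulate_ucln_rates(tree, rec.clock_mean, rec.clock_sigma, rng)
    sample = simulate_branch_sample(tree, clock, rec.sample_size, cv, rng)
    approx = fit_mvn(sample)
    constraints = assemble_constraints(
        tree.topology, calibrations_from_truth(tree, n_internal_cals))
    trace = run_mcmc(approx, tree.topology, constraints,
                     config=McmcConfig(iterations=iterations, seed=seed))
    summ = summarize(trace)
    top = tree.topology
    covered = sum(
        bool(summ.hpd_lower[int(v)] <= tree.ages[int(v)] <= summ.hpd_upper[int(v)])
        for v in top.internal_nodes)
    return RecoveryResult(covered=covered, total=top.n_nodes - top.n_tips,
                          mean_rate=summ.overall_mean_rate)


@dataclass
class BraceResult:
    max_twin_mean_diff: float     # |posterior mean age difference|, braced
    sigma_brace: float
    copy2_width_braced: float     # mean 95% HPD width, copy-2 nodes
    copy2_width_unbraced: float
    rate_braced: float
    rate_unbraced: float
    rate_z: float                 # paired Z across branches, braced - unbraced
    rate_z_p: float


def brace_experiment(seed: int, n_species: int = 6,
                     iterations: int = 30_000) -> BraceResult:
    """Calibration propagation on a duplicated gene tree (matched seeds).

    The duplication (gene root) long predates the species crowns, so the
    two replicas hang from long stems — the geometry of a pre-divergence
    paralog pair.  Calibrations are placed on copy-1 nodes only (plus the
    gene root); the braced run adds discovered cross-braces between the
    copies, the unbraced run omits them.  Everything else, including the
    seed, is identical.  Without braces the uncalibrated copy's nodes can
    drift up the long stem toward older ages, lowering the inferred
    rates; braces pin them to the calibrated copy.
    """
    rec = SimulationRecipe(n_tips=n_species, root_age=1500.0, noise_cv=0.1,
                           birth=2.5e-4, death=1.25e-4, seed=seed)
    rng = np.random.default_rng(seed)
    species = simulate_time_tree(rec, rng)
    gene, copies = make_duplicated_gene_tree(species, copies=2,
                                             root_age=4500.0)
    top = gene.topology
    clock = simulate_ucln_rates(gene, rec.clock_mean, rec.clock_sigma, rng)
    sample = simulate_branch_sample(gene, clock, rec.sample_size,
                                    rec.noise_cv, rng)
    approx = fit_mvn(sample)

    # root calibration plus plateaus around the truth on copy-1 nodes
    root_max = 1.1 * gene.root_age
    cals = [Calibration(node=top.root, min_age=0.9 * gene.root_age,
                        max_age=root_max,
                        steepness_min=0.025 * 0.9 * gene.root_age,
                        steepness_max=0.025 * root_max, name="root")]
    copy1 = copies.tips_of_copy(copies.copy_labels[0])
    for v in top.internal_nodes:
        v = int(v)
        if v == top.root or not top.clades[v] <= copy1:
            continue
        t = float(gene.ages[v])
        cals.append(Calibration(node=v, min_age=0.85 * t, max_age=1.15 * t,
                                steepness_min=0.025 * 0.85 * t,
                                steepness_max=0.025 * 1.15 * t,
                                name=f"copy1_node{v}"))

    sigma_brace = 1e-3 * root_max  # effectively-hard default
    braces = find_equivalent_nodes(top, copies, sigma=sigma_brace)
    copy2 = copies.tips_of_copy(copies.copy_labels[1])
    copy2_nodes = [int(v) for v in top.internal_nodes
                   if top.clades[int(v)] <= copy2]

    results = {}
    traces = {}
    model_bd = BirthDeathParams(birth=rec.birth, death=rec.death)
    for label, brace_list in (("braced", braces), ("unbraced", [])):
        constraints = assemble_constraints(top, cals, brace_list)
        trace = run_mcmc(approx, top, constraints, bd=model_bd,
                         config=McmcConfig(iterations=iterations, seed=seed))
        traces[label] = trace
        summ = summarize(trace)
        widths = [summ.hpd_upper[v] - summ.hpd_lower[v] for v in copy2_nodes]
        results[label] = (summ, float(np.mean(widths)),
                          summ.overall_mean_rate)

    z, p = compare_rates_z(traces["braced"], traces["unbraced"])
    summ_braced = results["braced"][0]
    twin_diffs = [abs(float(summ_braced.mean_age[a] - summ_braced.mean_age[b]))
                  for br in braces
                  for a, b in zip(br.nodes, br.nodes[1:])]
    return BraceResult(
        max_twin_mean_diff=max(twin_diffs),
        sigma_brace=sigma_brace,
        copy2_width_braced=results["braced"][1],
        copy2_width_unbraced=results["unbraced"][1],
        rate_braced=results["braced"][2],
        rate_unbraced=results["unbraced"][2],
        rate_z=z,
        rate_z_p=p,
    )


@dataclass
class RootClashResult:
    root_max: float
    steepness: float
    hpd_upper: float
    mean_root_age: float
    true_root_age: float

    @property
    def clashes(self) -> bool:
        """Upper 95% HPD bound within one steepness unit of the maximum."""
        return abs(self.hpd_upper - self.root_max) <= self.steepness

    @property
    def pressed(self) -> bool:
        """Posterior straddles the boundary: mean below the maximum while
        the upper HPD edge reaches it (within the tail zone)."""
        return (self.mean_root_age < self.root_max
                and self.hpd_upper >= self.root_max - self.steepness)


def root_clash_experiment(seed: int, n_tips: int = 8,
                          iterations: int = 30_000) -> RootClashResult:
    """Date with a root maximum younger than the simulated truth.

    Under an under-informative clock the data demand more time than the
    calibration allows, so the root-age posterior should pile up against
    the maximum: the upper 95% HPD bound lands within one steepness unit
    of the boundary.
    """
    rec = SimulationRecipe(n_tips=n_tips, seed=seed, clock_sigma=0.2)
    rng = np.random.default_rng(seed)
    tree = simulate_time_tree(rec, rng)
    clock = simulate_ucln_rates(tree, rec.clock_mean, rec.clock_sigma, rng)
    sample = simulate_branch_sample(tree, clock, rec.sample_size,
                                    rec.noise_cv, rng)
    approx = fit_mvn(sample)
    # shallow (cherry) calibrations identify the rate without imposing any
    # deep minimum, so the likelihood demands the true (older) root age
    # while the maximum is set 12.5% younger than the truth: the
    # posterior accumulates against the boundary, with its mean just
    # below the maximum and its upper tail pressed into the steepness
    # zone
    top = tree.topology
    root_max = 0.875 * tree.root_age
    steepness = 0.025 * root_max
    cals = [Calibration(node=top.root, min_age=0.25 * tree.root_age,
                        max_age=root_max, steepness_min=0.025 * tree.root_age,
                        steepness_max=steepness, name="root_max")]
    shallow = sorted((int(v) for v in top.internal_nodes if int(v) != top.root),
                     key=lambda v: len(top.clades[v]))[:3]
    for v in shallow:
        t = float(tree.ages[v])
        cals.append(Calibration(node=v, min_age=0.85 * t, max_age=1.15 * t,
                                steepness_min=0.025 * 0.85 * t,
                                steepness_max=0.025 * 1.15 * t,
                                name=f"shallow_node{v}"))
    constraints = assemble_constraints(top, cals)
    trace = run_mcmc(approx, tree.topology, constraints,
                     config=McmcConfig(iterations=iterations, seed=seed))
    summ = summarize(trace)
    return RootClashResult(root_max=root_max, steepness=steepness,
                           hpd_upper=float(summ.hpd_upper[top.root]),
                           mean_root_age=float(summ.mean_age[top.root]),
                           true_root_age=tree.root_age)
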