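"""Ground-truth simulators: dated trees, relaxed-clock rates, pseudo-
posterior branch-length samples, and duplicated "gene trees".

Every other module is testable against these generators without any
external download: the time-tree simulator is the generative twin of the
birth-death prior, the rate simulator of the UCLN prior, and the
pseudo-posterior emulates the scatter of a Bayesian branch-length sample
around the true rate x duration products.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .bracing import CopyMap
from .priors import BirthDeathParams, Calibration, ClockState, bd_log_normaliser
from .treekit import (PosteriorSample, RootedTopology, TimeTree,
                      branch_durations, parse_newick)

__all__ = ["SimulationRecipe", "simulate_time_tree", "simulate_ucln_rates",
           "simulate_branch_sample", "make_duplicated_gene_tree",
           "calibrations_from_truth", "write_fixture_bundle"]


@dataclass
class SimulationRecipe:
    """Study conditions for a synthetic dating experiment.

    Defaults: a 16-tip tree with a 4000 Ma root under a birth-death
    process with 1.0 births and 0.5 deaths per lineage per Ga; a relaxed
    clock with mean 2.6e-4 substitutions/site/Ma (the magnitude typical
    of deep-time ribosomal datasets) and moderate rate spread; a 1000-tree
    pseudo-posterior with 5% branch-length noise.
    """

    n_tips: int = 16
    birth: float = 1.0e-3
    death: float = 0.5e-3
    root_age: float = 4000.0
    clock_mean: float = 2.6e-4
    clock_sigma: float = 0.3
    sample_size: int = 1000
    noise_cv: float = 0.05
    seed: int = 0
    copies: int = 1

    def __post_init__(self) -> None:
        if self.n_tips < 2 or self.root_age <= 0 or self.clock_mean <= 0:
            raise ValueError("tip count, root age and clock mean must be positive")
        if self.noise_cv < 0 or self.clock_sigma < 0:
            raise ValueError("noise CV and clock spread must be >= 0")


def _bd_inverse_cdf(u: np.ndarray, params: BirthDeathParams,
                    t_root: float) -> np.ndarray:
    """Analytic inverse CDF of the conditioned per-age density g(t).

    ``g(t) \\propto p1(t)`` on ``(0, t_root)``; the CDF is invertible in
    closed form, so draws follow the conditioned birth-death law exactly.
    """
    lam, mu = params.birth, params.death
    a = lam - mu
    if mu == 0.0:
        denom = 1.0 - math.exp(-lam * t_root)
        return -np.log(1.0 - u * denom) / lam
    z_total = math.exp(bd_log_normaliser(params, t_root))
    # CDF(t) = (a/mu) * (1/(lam-mu) - 1/(lam - mu e^{-a t})) / z_total
    w = u * z_total * mu / a
    inv = 1.0 / (lam - mu) - w          # = 1/(lam - mu e^{-a t})
    e = (lam - 1.0 / inv) / mu          # = e^{-a t}
    return -np.log(e) / a


def simulate_time_tree(recipe: SimulationRecipe,
                       rng: np.random.Generator | None = None) -> TimeTree:
    """Simulate an ultrametric time tree conditioned on tip count and root age.

    Non-root internal ages are iid draws from the conditioned birth-death
    density on (0, root_age) (analytic inverse CDF); lineages are then
    joined coalescent-style from youngest age upward, which realises a
    uniformly chosen labelled history.  This is exactly the distribution
    the birth-death prior assigns conditional on the root age and the
    number of tips.
    """
    rng = rng if rng is not None else np.random.default_rng(recipe.seed)
    n = recipe.n_tips
    params = BirthDeathParams(birth=recipe.birth, death=recipe.death)
    t_root = recipe.root_age

    for _ in range(100):
        inner = np.sort(_bd_inverse_cdf(rng.random(n - 2), params, t_root))
        if inner.size == 0 or (0 < inner[0] and inner[-1] < t_root
                               and np.all(np.diff(inner) > 0)):
            break
    else:
        raise RuntimeError(
            f"time-tree simulation failed (degenerate ages) with seed "
            f"{recipe.seed}")

    node_ages = np.concatenate([inner, [t_root]])
    labels = [f"t{i+1}" for i in range(n)]
    # join two random lineages at each successive age; clade tip-sets
    # identify nodes exactly across the canonical re-parse
    lineages: list[tuple[str, frozenset[str]]] = [
        (lab, frozenset([lab])) for lab in labels]
    clade_age: dict[frozenset[str], float] = {}
    for age in node_ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        nwk_j, tips_j = lineages.pop(j)
        nwk_i, tips_i = lineages.pop(i)
        merged_tips = tips_i | tips_j
        clade_age[merged_tips] = float(age)
        lineages.append((f"({nwk_i},{nwk_j})", merged_tips))
    newick = lineages[0][0] + ";"
    top, _ = parse_newick(newick)

    ages = np.zeros(top.n_nodes)
    for v in top.internal_nodes:
        ages[v] = clade_age[top.clades[int(v)]]
    return TimeTree(top, ages)


def simulate_ucln_rates(tree: TimeTree, clock_mean: float, clock_sigma: float,
                        seed: int | np.random.Generator = 0) -> ClockState:
    """IID log-normal per-branch rates with mean ``clock_mean``.

    ``clock_sigma = 0`` is the strict-clock degenerate case: every rate
    equals the mean.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = tree.topology.n_branches
    if clock_sigma == 0:
        rates = np.full(n, clock_mean)
    else:
        loc = math.log(clock_mean) - 0.5 * clock_sigma ** 2
        rates = rng.lognormal(mean=loc, sigma=clock_sigma, size=n)
    return ClockState(rates=rates, mu=clock_mean, sigma=clock_sigma)


def simulate_branch_sample(tree: TimeTree, clock: ClockState,
                           sample_size: int = 1000, cv: float = 0.05,
                           seed: int | np.random.Generator = 0,
                           correlated: bool = False) -> PosteriorSample:
    """Pseudo-posterior of branch-length trees around rate x duration.

    Each draw multiplies every true branch length by an independent
    Gamma(shape=1/cv^2, mean=1) factor; ``cv = 0`` yields identical
    trees.  With ``correlated=True`` one shared Gamma factor per tree is
    applied to all branches, mimicking the across-branch correlation of
    real posterior samples.
    """
    if cv < 0 or sample_size < 2:
        raise ValueError("cv must be >= 0 and sample_size >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = clock.rates * branch_durations(tree)
    n_b = x.size
    if cv == 0:
        lengths = np.tile(x, (sample_size, 1))
    else:
        shape = 1.0 / (cv * cv)
        if correlated:
            f = rng.gamma(shape, scale=1.0 / shape, size=(sample_size, 1))
        else:
            f = rng.gamma(shape, scale=1.0 / shape, size=(sample_size, n_b))
        lengths = x[None, :] * f
    return PosteriorSample(tree.topology, lengths, source="<synthetic>")


def make_duplicated_gene_tree(species_tree: TimeTree, copies: int = 2,
                              copy_labels: tuple[str, ...] | None = None,
                              root_age: float | None = None
                              ) -> tuple[TimeTree, CopyMap]:
    """Replicate a dated species tree under a pre-root duplication node.

    The gene tree's root (the duplication, mimicking a pre-divergence
    paralog split) subtends ``copies`` replicas of the species topology,
    tips relabelled ``species_copy``; replica node ages equal the species
    tree ages, providing ground truth for brace tests.  With more than
    two copies the replicas are nested caterpillar-style below the root,
    each duplication slightly older than the next.
    """
    if copies < 2:
        raise ValueError("need at least 2 copies")
    labels = copy_labels or tuple(f"c{i+1}" for i in range(copies))
    if len(labels) != copies:
        raise ValueError("one label per copy required")
    sp_root = species_tree.root_age
    if root_age is None:
        root_age = 1.25 * sp_root
    if root_age <= sp_root:
        raise ValueError("duplication root must predate the species root")

    def subtree_newick(v: int, suffix: str) -> str:
        top = species_tree.topology
        if top.is_tip(v):
            return f"{top.tip_labels[v]}_{suffix}"
        return "(" + ",".join(subtree_newick(c, suffix)
                              for c in top.children[v]) + ")"

    sp_top = species_tree.topology
    replicas = [subtree_newick(sp_top.root, lab) for lab in labels]
    # nest: (((rep_k, rep_{k-1}), ...), rep_1) with increasing dup ages
    nwk = replicas[0]
    dup_ages = np.linspace(root_age, root_age, 1) if copies == 2 else \
        np.linspace(sp_root + (root_age - sp_root) / (copies - 1), root_age,
                    copies - 1)
    for rep in replicas[1:]:
        nwk = f"({nwk},{rep})"
    gene_top, _ = parse_newick(nwk + ";")

    assignment = {f"{sp}_{lab}": (sp, lab)
                  for sp in sp_top.tip_labels for lab in labels}
    copy_map = CopyMap(assignment)

    ages = np.zeros(gene_top.n_nodes)
    dup_iter = iter(dup_ages)
    for v in gene_top.internal_nodes:
        v = int(v)
        clade = gene_top.clades[v]
        copies_here = {copy_map.copy(t) for t in clade}
        if len(copies_here) == 1:
            species = frozenset(copy_map.species(t) for t in clade)
            sp_node = _species_node(sp_top, species)
            ages[v] = species_tree.ages[sp_node]
        else:
            ages[v] = next(dup_iter)
    return TimeTree(gene_top, ages), copy_map


def _species_node(sp_top: RootedTopology, species: frozenset[str]) -> int:
    for v in range(sp_top.n_nodes):
        if sp_top.clades[v] == species:
            return v
    raise ValueError(f"no species-tree node for clade {sorted(species)}")


def calibrations_from_truth(tree: TimeTree, n_internal: int = 3,
                            plateau: float = 0.15,
                            steepness_frac: float = 0.025,
                            root_plateau: float = 0.10) -> list[Calibration]:
    """Root + ``n_internal`` calibrations bracketing the true ages.

    The root gets a plateau of +/- ``root_plateau`` around its true age;
    the ``n_internal`` largest non-root clades get +/- ``plateau``.
    Steepness is ``steepness_frac`` of each boundary age.
    """
    top = tree.topology
    cals = []
    t = tree.root_age
    cals.append(Calibration(
        node=top.root, min_age=(1 - root_plateau) * t,
        max_age=(1 + root_plateau) * t,
        steepness_min=steepness_frac * (1 - root_plateau) * t,
        steepness_max=steepness_frac * (1 + root_plateau) * t,
        name="root"))
    inner = [int(v) for v in top.internal_nodes if int(v) != top.root]
    inner.sort(key=lambda v: -len(top.clades[v]))
    for v in inner[:n_internal]:
        t = float(tree.ages[v])
        cals.append(Calibration(
            node=v, min_age=(1 - plateau) * t, max_age=(1 + plateau) * t,
            steepness_min=steepness_frac * (1 - plateau) * t,
            steepness_max=steepness_frac * (1 + plateau) * t,
            name=f"internal_node{v}"))
    return cals


def write_fixture_bundle(recipe: SimulationRecipe, outdir) -> dict:
    """Simulate and write a complete fixture bundle to a directory.

    Emits: the true dated tree (Newick with ages as branch lengths), a
    pseudo-posterior sample file, a truth table of node ages and branch
    rates (TSV), and a manifest recording the recipe and seed.  Returns
    the manifest dict.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(recipe.seed)
    tree = simulate_time_tree(recipe, rng)
    clock = simulate_ucln_rates(tree, recipe.clock_mean, recipe.clock_sigma,
                                rng)
    sample = simulate_branch_sample(tree, clock, recipe.sample_size,
                                    recipe.noise_cv, rng)

    top = tree.topology
    dur = branch_durations(tree)

    def chronogram(v: int) -> str:
        if top.is_tip(v):
            core = top.tip_labels[v]
        else:
            core = "(" + ",".join(chronogram(c) for c in top.children[v]) + ")"
        p = top.parent[v]
        return f"{core}:{dur[v]:.8g}" if p >= 0 else core

    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(chronogram(top.root) + ";\n")

    with open(os.path.join(outdir, "sample.trees"), "w") as fh:
        for row in sample.lengths:
            def nwk(v: int) -> str:
                if top.is_tip(v):
                    core = top.tip_labels[v]
                else:
                    core = "(" + ",".join(nwk(c) for c in top.children[v]) + ")"
                return f"{core}:{row[v]:.8g}" if top.parent[v] >= 0 else core
            fh.write(nwk(top.root) + ";\n")

    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("kind\tindex\tvalue\n")
        for v in top.internal_nodes:
            fh.write(f"age\t{int(v)}\t{tree.ages[v]:.8g}\n")
        for b in range(top.n_branches):
            fh.write(f"rate\t{b}\t{clock.rates[b]:.8g}\n")

    manifest = {"recipe": asdict(recipe), "seed": recipe.seed,
                "n_nodes": top.n_nodes, "files": ["true_tree.nwk",
                                                  "sample.trees", "truth.tsv"]}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
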