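"""Log-prior and soft-constraint densities for the dating model.

Components: a birth-death prior on internal node ages conditioned on the
root age; an uncorrelated log-normal (UCLN) relaxed clock on branch
rates; calibration densities that are flat between a minimum and a
maximum with Gaussian ("bisected normal") tails beyond each boundary;
brace densities tying equivalent nodes to a common age; relative
node-order penalties; and hyperpriors on the clock and tree-process
parameters.

Calibration, brace and relative densities are unnormalised with the
satisfied region at log density 0, so violations are pure penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .treekit import TimeTree

__all__ = [
    "BirthDeathParams", "ClockState", "Calibration", "Brace",
    "RelativeConstraint", "HyperPriorConfig",
    "log_birth_death", "bd_log_g", "bd_log_normaliser",
    "log_ucln", "log_calibration", "log_brace", "log_relative",
    "log_hyperpriors",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class BirthDeathParams:
    """Reconstructed birth-death process with complete sampling.

    Rates are per-lineage per-Ma; the defaults correspond to 1.0 and 0.5
    events per lineage per Ga.
    """

    birth: float = 1.0e-3
    death: float = 0.5e-3
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if not (0 <= self.death < self.birth):
            raise ValueError("need 0 <= death < birth for the conditioned density")
        if self.rho != 1.0:
            raise ValueError("only complete sampling (rho = 1) is supported")


@dataclass
class ClockState:
    """Per-branch substitution rates plus clock hyperparameters.

    ``sigma`` is the log-scale spread of the UCLN model; ``sigma = 0``
    denotes a strict clock with every branch rate equal to ``mu``.
    Rates are in substitutions/site/Ma.
    """

    rates: np.ndarray
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("all branch rates must be positive")
        if self.mu <= 0:
            raise ValueError("clock mean must be positive")
        if self.sigma < 0:
            raise ValueError("clock spread must be non-negative")

    @property
    def strict(self) -> bool:
        return self.sigma == 0.0


@dataclass
class Calibration:
    """Soft min/max age bounds on one node.

    Log density is 0 on the plateau ``[min_age, max_age]`` and decays as
    a Gaussian tail beyond each present boundary; ``steepness`` values
    are the tail standard deviations in Ma.
    """

    taxa: frozenset[str] = frozenset()
    node: int | None = None
    min_age: float | None = None
    max_age: float | None = None
    steepness_min: float = 1.0
    steepness_max: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.min_age is None and self.max_age is None:
            raise ValueError(f"calibration {self.name!r}: need min and/or max age")
        if (self.min_age is not None and self.max_age is not None
                and not self.min_age < self.max_age):
            raise ValueError(f"calibration {self.name!r}: min must be < max")
        if self.steepness_min <= 0 or self.steepness_max <= 0:
            raise ValueError(f"calibration {self.name!r}: steepness must be > 0")


@dataclass
class Brace:
    """>= 2 nodes constrained toward a common age (anchored to the first)."""

    taxa_groups: tuple[frozenset[str], ...] = ()
    nodes: tuple[int, ...] = ()
    sigma: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"brace {self.name!r}: sigma must be > 0")
        if self.nodes and len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"brace {self.name!r}: duplicate nodes")
        if self.nodes and len(self.nodes) < 2:
            raise ValueError(f"brace {self.name!r}: needs >= 2 nodes")


@dataclass
class RelativeConstraint:
    """Soft requirement that one node be younger than another."""

    younger_taxa: frozenset[str] = frozenset()
    older_taxa: frozenset[str] = frozenset()
    younger: int | None = None
    older: int | None = None
    softness: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.softness <= 0:
            raise ValueError(f"relative constraint {self.name!r}: softness must be > 0")
        if (self.younger is not None and self.younger == self.older):
            raise ValueError(f"relative constraint {self.name!r}: nodes must differ")


# ---------------------------------------------------------------------------
# birth-death node-age prior
# ---------------------------------------------------------------------------


def bd_log_g(t: np.ndarray, params: BirthDeathParams, t_root: float) -> np.ndarray:
    """Log of the normalised per-age density g(t) on (0, t_root).

    Under the reconstructed birth-death process with complete sampling,
    conditional on the root age and the number of tips, the non-root
    internal ages are iid with density proportional to
    ``p1(t) = (lam-mu)^2 exp(-(lam-mu) t) / (lam - mu exp(-(lam-mu) t))^2``.
    """
    t = np.asarray(t, dtype=float)
    lam, mu = params.birth, params.death
    a = lam - mu
    log_p1 = 2.0 * math.log(a) - a * t - 2.0 * np.log(lam - mu * np.exp(-a * t))
    return log_p1 - bd_log_normaliser(params, t_root)


def bd_log_normaliser(params: BirthDeathParams, t_root: float) -> float:
    """log of the analytic integral of p1 over (0, t_root).

    The integral reduces to ``(1 - e^{-a t}) / (lam - mu e^{-a t})`` with
    ``a = lam - mu``, a form that is cancellation-free down to mu = 0.
    """
    lam, mu = params.birth, params.death
    a = lam - mu
    e = math.exp(-a * t_root)
    return math.log(-math.expm1(-a * t_root)) - math.log(lam - mu * e)


def log_birth_death(tree: TimeTree, params: BirthDeathParams) -> float:
    """Birth-death log prior on the non-root internal node ages.

    Conditional on the root age and tip count: each non-root internal age
    is iid g(t) on (0, t_root), times the order-statistics factor
    ``(n_tips - 2)!``.  The root age itself carries no birth-death
    density — it is governed by its calibration.
    """
    top = tree.topology
    t_root = tree.root_age
    nonroot_internal = np.arange(top.n_tips, top.n_nodes - 1)
    k = nonroot_internal.size
    if k == 0:
        return 0.0
    ages = tree.ages[nonroot_internal]
    if np.any(ages >= t_root):
        raise ValueError("internal age at or above the root age")
    return float(np.sum(bd_log_g(ages, params, t_root)) + gammaln(k + 1))


# ---------------------------------------------------------------------------
# relaxed clock
# ---------------------------------------------------------------------------


def log_ucln(clock: ClockState) -> float:
    """UCLN log prior on branch rates, mean-parameterised.

    Each rate is iid log-normal with location ``ln(mu) - sigma^2 / 2``
    and scale ``sigma``, so that ``E[r] = mu``.
    """
    if clock.strict:
        raise ValueError("UCLN prior requires relaxed mode (sigma > 0)")
    r = clock.rates
    s = clock.sigma
    loc = math.log(clock.mu) - 0.5 * s * s
    z = (np.log(r) - loc) / s
    return float(np.sum(-np.log(r * s) - 0.5 * math.log(2.0 * math.pi)
                        - 0.5 * z * z))


# ---------------------------------------------------------------------------
# soft constraints
# ---------------------------------------------------------------------------


def log_calibration(cal: Calibration, age: float) -> float:
    """Plateau-with-Gaussian-tails calibration density (plateau = 0)."""
    if age < 0:
        raise ValueError("negative age")
    if cal.max_age is not None and age > cal.max_age:
        d = age - cal.max_age
        return -0.5 * (d / cal.steepness_max) ** 2
    if cal.min_age is not None and age < cal.min_age:
        d = cal.min_age - age
        return -0.5 * (d / cal.steepness_min) ** 2
    return 0.0


def log_brace(brace: Brace, ages) -> float:
    """Sum of Gaussian penalties tying braced ages to the first-listed node.

    ``ages`` is the sequence of ages of the braced nodes, in brace order.
    Invariant under common translation of all braced ages.
    """
    ages = np.asarray(ages, dtype=float)
    if brace.nodes and ages.shape[0] != len(brace.nodes):
        raise ValueError("one age per braced node required")
    if ages.shape[0] < 2:
        raise ValueError("a brace needs >= 2 ages")
    d = ages[1:] - ages[0]
    return float(np.sum(-0.5 * (d / brace.sigma) ** 2))


def log_relative(con: RelativeConstraint, t_young: float, t_old: float) -> float:
    """0 when the order holds; Gaussian tail penalty on the violation."""
    if t_young < 0 or t_old < 0:
        raise ValueError("negative age")
    if t_young < t_old:
        return 0.0
    d = t_young - t_old
    return -0.5 * (d / con.softness) ** 2


# ---------------------------------------------------------------------------
# hyperpriors
# ---------------------------------------------------------------------------


@dataclass
class HyperPriorConfig:
    """Which hyperparameters are sampled, and their priors.

    Defaults: the clock mean is log-uniform on [1e-6, 1e-1]
    substitutions/site/Ma, the clock spread is Exponential(1), and the
    birth-death rates are fixed.
    """

    sample_clock_mean: bool = True
    clock_mean_bounds: tuple[float, float] = (1e-6, 1e-1)
    sample_clock_sigma: bool = True
    clock_sigma_rate: float = 1.0
    sample_birth_death: bool = False
    bd_log_bounds: tuple[float, float] = (1e-6, 1e-1)


def log_hyperpriors(clock: ClockState, bd: BirthDeathParams,
                    config: HyperPriorConfig | None = None) -> float:
    """Sum of the declared hyperparameter log-priors; -inf outside support."""
    if config is None:
        config = HyperPriorConfig()
    total = 0.0
    if config.sample_clock_mean:
        lo, hi = config.clock_mean_bounds
        if not (lo <= clock.mu <= hi):
            return -math.inf
        total += -math.log(clock.mu) - math.log(math.log(hi / lo))
    if config.sample_clock_sigma and not clock.strict:
        lam = config.clock_sigma_rate
        total += math.log(lam) - lam * clock.sigma
    if config.sample_birth_death:
        lo, hi = config.bd_log_bounds
        for val in (bd.birth, bd.death):
            if val <= 0:
                return -math.inf
            if not (lo <= val <= hi):
                return -math.inf
            total += -math.log(val) - math.log(math.log(hi / lo))
    return total
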