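"""Multivariate-normal approximation of the phylogenetic likelihood.

Instead of recomputing a per-site likelihood at every MCMC step, the
posterior sample of branch-length trees (in substitutions/site) is
summarised once by its mean vector and covariance matrix; the dating run
then evaluates the density of the model-implied branch lengths
``x_b = r_b * dt_b`` (rate times duration) under that Gaussian.

Because reversible substitution models cannot locate the root, the two
branches incident to the root are only identifiable through their sum.
The *observed* branch space therefore merges the root-child pair into a
single entry; the time-tree side contributes
``x_root = r_a * dt_a + r_c * dt_c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .treekit import PosteriorSample, RootedTopology, TimeTree, branch_durations

__all__ = ["MVNApprox", "fit_mvn", "log_density", "log_likelihood_time_tree",
           "observed_branch_map", "to_observed", "save_mvn", "load_mvn"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def observed_branch_map(topology: RootedTopology) -> np.ndarray:
    """Map each branch index to its observed-space index.

    The two root-child branches share one observed index; all other
    branches map one-to-one.  Observed dimension is ``n_branches - 1``.
    """
    root_kids = topology.children[topology.root]
    obs = np.empty(topology.n_branches, dtype=np.intp)
    nxt = 0
    for v in range(topology.n_branches):
        if v in root_kids:
            continue
        obs[v] = nxt
        nxt += 1
    for v in root_kids:
        obs[v] = nxt  # merged entry, last index
    return obs


def to_observed(obs_map: np.ndarray, branch_vec: np.ndarray) -> np.ndarray:
    """Project a per-branch vector into observed space (root pair summed)."""
    out = np.zeros(int(obs_map.max()) + 1)
    np.add.at(out, obs_map, branch_vec)
    return out


@dataclass
class MVNApprox:
    """Fitted Gaussian summary of a branch-length posterior sample."""

    mean: np.ndarray
    cov: np.ndarray
    mode: str  # "full" | "diagonal"
    ridge: float
    obs_map: np.ndarray  # branch index -> observed index
    _cho: tuple = field(default=None, repr=False, compare=False)
    _logdet: float = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(self.mean < 0):
            raise ValueError("mean branch lengths must be non-negative")
        if self._cho is None:
            try:
                c, low = cho_factor(self.cov, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "covariance not positive definite after ridge; "
                    "increase the ridge or use diagonal mode"
                ) from exc
            self._cho = (c, low)
            self._logdet = 2.0 * float(np.sum(np.log(np.diag(c))))

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def fit_mvn(sample: PosteriorSample, mode: str = "full",
            ridge: float | None = None) -> MVNApprox:
    """Fit the Gaussian approximation from a posterior tree sample.

    Parameters
    ----------
    mode
        ``"full"`` keeps the complete sample covariance; ``"diagonal"``
        keeps only per-branch variances (useful for large trees, where
        the full matrix is expensive or rank-deficient).
    ridge
        Diagonal jitter added to the covariance.  ``None`` selects
        ``1e-8 * mean(diag)`` which guarantees a Cholesky factorisation
        with negligible distortion.
    """
    if mode not in ("full", "diagonal"):
        raise ValueError(f"unknown mode {mode!r}")
    obs_map = observed_branch_map(sample.topology)
    X = np.vstack([to_observed(obs_map, row) for row in sample.lengths])
    n, d = X.shape
    if n < 2:
        raise ValueError("sample too small: need at least 2 trees")
    m = X.mean(axis=0)
    if mode == "full":
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if n <= d and (ridge is None or ridge == 0):
            # rank-deficient covariance; the default ridge rescues it but
            # an explicit zero ridge cannot.
            if ridge == 0:
                raise ValueError(
                    f"full covariance needs sample size > dimension "
                    f"({n} <= {d}) or a positive ridge"
                )
    else:
        var = X.var(axis=0, ddof=1)
        cov = np.diag(var)
    if ridge is None:
        base = float(np.mean(np.diag(cov)))
        ridge = 1e-8 * base if base > 0 else 1e-12
    cov = cov + ridge * np.eye(d)
    return MVNApprox(mean=m, cov=cov, mode=mode, ridge=float(ridge),
                     obs_map=obs_map)


def log_density(approx: MVNApprox, x: np.ndarray) -> float:
    """Gaussian log density at an observed-branch-length vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != approx.mean.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {approx.mean.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite entries in x")
    d = x - approx.mean
    quad = float(d @ cho_solve(approx._cho, d))
    return -0.5 * (quad + approx._logdet + approx.dim * _LOG_2PI)


def log_likelihood_time_tree(approx: MVNApprox, tree: TimeTree, clock) -> float:
    """Approximate log likelihood of a time tree under a clock state.

    Builds the model-implied observed vector ``x_b = r_b * dt_b`` (with
    the root pair summed) and evaluates :func:`log_density`.  Exactly
    invariant under the rate-time rescaling (ages * c, rates / c).
    """
    dt = branch_durations(tree)
    x_branch = clock.rates * dt
    if np.any(x_branch < 0):  # defensive; TimeTree invariants forbid this
        raise ValueError("negative implied branch length")
    return log_density(approx, to_observed(approx.obs_map, x_branch))


# ---------------------------------------------------------------------------
# serialization (text) so fitting and dating can run as separate steps
# ---------------------------------------------------------------------------


def save_mvn(approx: MVNApprox, path) -> None:
    payload = {
        "format": "bracedate-mvn-v1",
        "mode": approx.mode,
        "ridge": approx.ridge,
        "mean": approx.mean.tolist(),
        "cov": approx.cov.tolist(),
        "obs_map": approx.obs_map.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_mvn(path) -> MVNApprox:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "bracedate-mvn-v1":
        raise ValueError(f"{path} is not a serialized MVN approximation")
    return MVNApprox(
        mean=np.asarray(payload["mean"]),
        cov=np.asarray(payload["cov"]),
        mode=payload["mode"],
        ridge=float(payload["ridge"]),
        obs_map=np.asarray(payload["obs_map"], dtype=np.intp),
    )
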