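"""Bayesian relaxed molecular clock on a fixed rooted topology.

The model: node ages (Ga) on a fixed topology, per-node log-rates evolving
as Brownian motion along the tree (autocorrelated lognormal clock; the rate
of a branch is exp of the mean of its endpoint log-rates) or i.i.d. gamma
branch rates (uncorrelated clock), an empirical amino-acid matrix with
discrete-gamma site rates for the likelihood, and age calibrations with hard
or soft bounds (soft bounds place 2.5% prior mass beyond each bound of a
two-sided interval, 5% beyond a single bound, with exponential tails matched
continuously to the uniform core).

The node-age prior is "conditional uniform": given the root age, the other
internal ages are i.i.d. uniform below it, so a calibration on the root is
exactly the root-age marginal — convenient for prior-predictive checks.  A
birth–death prior (Rannala–Yang kernel with sampling fraction ρ) is
available as an alternative.

Sampling is Metropolis-within-Gibbs: per-node age slides (reflected within
the parent/child window), Gaussian walks on node log-rates, multiplier moves
on the Brownian variance σ² and the gamma shape, and a whole-tree age scale
move.  The Felsenstein pruning likelihood is evaluated incrementally: each
single-parameter proposal only recomputes the transition matrices and
partial-likelihood arrays on the path from the changed branches to the root,
with double-buffered storage so rejected proposals cost no copying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import Alignment
from .substitution import SubstitutionModel, discrete_gamma_rates
from .trees import TimeTree, NO_PARENT

logger = logging.getLogger(__name__)

AUTOCORRELATED = "autocorrelated-lognormal"
UNCORRELATED = "uncorrelated-gamma"

_LOG_ZERO = -np.inf


class CalibrationError(ValueError):
    """Invalid or mutually infeasible calibrations."""


# --------------------------------------------------------------------------
# Calibrations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Age constraint on the MRCA of ``clade`` (or on the root).

    ``bounds="HARD"`` gives an indicator prior (uniform inside, impossible
    outside).  ``bounds="SOFT"`` keeps 95% of the mass in a uniform core and
    places exactly 2.5% beyond each bound (two-sided) or 5% beyond the single
    bound (one-sided) in an exponential tail whose density is continuous at
    the bound.  One-sided soft calibrations use a uniform core of width
    ``span`` Ga adjacent to the stated bound.
    """

    clade: tuple[str, ...] | str
    min_age: float | None = None
    max_age: float | None = None
    bounds: str = "SOFT"
    span: float = 1.0

    def __post_init__(self):
        if self.min_age is None and self.max_age is None:
            raise CalibrationError("at least one of min_age/max_age is required")
        if (
            self.min_age is not None
            and self.max_age is not None
            and not self.min_age < self.max_age
        ):
            raise CalibrationError(
                f"min_age {self.min_age} must be < max_age {self.max_age}"
            )
        if self.bounds not in ("HARD", "SOFT"):
            raise CalibrationError("bounds must be HARD or SOFT")
        if self.span <= 0:
            raise CalibrationError("span must be > 0")
        if isinstance(self.clade, (list, set)):
            object.__setattr__(self, "clade", tuple(sorted(self.clade)))

    # --- soft-bound geometry -------------------------------------------
    def _core(self) -> tuple[float, float, float]:
        """(core_lo, core_hi, core_density) of the soft density."""
        if self.min_age is not None and self.max_age is not None:
            lo, hi = self.min_age, self.max_age
            h = 0.95 / (hi - lo)
        elif self.min_age is not None:
            lo, hi = self.min_age, self.min_age + self.span
            h = 0.95 / self.span
        else:
            lo, hi = self.max_age - self.span, self.max_age
            h = 0.95 / self.span
        return lo, hi, h

    def _tail_masses(self) -> tuple[float, float]:
        """(lower tail mass, upper tail mass)."""
        if self.min_age is not None and self.max_age is not None:
            return 0.025, 0.025
        if self.min_age is not None:
            return 0.05, 0.0
        return 0.0, 0.05

    def log_density(self, age: float) -> float:
        """Log prior density contribution at ``age``."""
        if self.bounds == "HARD":
            if self.min_age is not None and age < self.min_age:
                return _LOG_ZERO
            if self.max_age is not None and age > self.max_age:
                return _LOG_ZERO
            return 0.0
        lo, hi, h = self._core()
        m_lo, m_hi = self._tail_masses()
        if age < lo:
            if m_lo == 0.0:
                return _LOG_ZERO  # one-sided max: uniform core truncated below
            tau = m_lo / h
            return np.log(h) + (age - lo) / tau
        if age > hi:
            if m_hi == 0.0:
                return _LOG_ZERO
            tau = m_hi / h
            return np.log(h) - (age - hi) / tau
        return float(np.log(h))

    def density(self, age: float) -> float:
        return float(np.exp(self.log_density(age)))

    def cdf(self, age):
        """Analytic CDF of the calibration density (vectorised; HARD bounds
        give the uniform CDF on [min, max])."""
        age = np.asarray(age, dtype=float)
        if self.bounds == "HARD":
            if self.min_age is None or self.max_age is None:
                raise CalibrationError("one-sided HARD bound has no proper CDF")
            x = np.clip(age, self.min_age, self.max_age)
            out = (x - self.min_age) / (self.max_age - self.min_age)
            return out if out.ndim else float(out)
        lo, hi, h = self._core()
        m_lo, m_hi = self._tail_masses()
        below = (
            np.zeros_like(age) if m_lo == 0.0
            else m_lo * np.exp(np.minimum(age - lo, 0.0) * h / max(m_lo, 1e-300))
        )
        core = m_lo + h * (np.clip(age, lo, hi) - lo)
        above = (
            np.ones_like(age) if m_hi == 0.0
            else 1.0 - m_hi * np.exp(-np.maximum(age - hi, 0.0) * h / m_hi)
        )
        out = np.where(age < lo, below, np.where(age <= hi, core, above))
        return out if out.ndim else float(out)


def calibration_logprior(age: float, calibration: Calibration) -> float:
    """Log-density contribution of one calibration at one age."""
    return calibration.log_density(age)


# --------------------------------------------------------------------------
# Rate prior
# --------------------------------------------------------------------------

def rate_logprior(tree: TimeTree, kind: str, sigma2: float | None = None,
                  shape: float | None = None, scale: float | None = None) -> float:
    """Log-density of the branch-rate configuration under the clock model.

    Autocorrelated kind: sum over non-root nodes of
    Normal(log r_child | log r_parent, sigma2 * Δt) evaluated on the stored
    node log-rates.  Uncorrelated kind: sum of Gamma(shape, scale) log-pdfs
    of the branch rates.
    """
    if kind == AUTOCORRELATED:
        if sigma2 is None:
            raise ValueError("sigma2 required for the autocorrelated prior")
        total = 0.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p == NO_PARENT:
                continue
            dt = tree.age[p] - tree.age[v]
            diff = tree.node_log_rate[v] - tree.node_log_rate[p]
            if sigma2 * dt <= 0:
                return _LOG_ZERO if diff != 0.0 else total
            var = sigma2 * dt
            total += -0.5 * (np.log(2 * np.pi * var) + diff * diff / var)
        return float(total)
    if kind == UNCORRELATED:
        from scipy.stats import gamma as gamma_dist

        rates = [
            tree.branch_rate[v]
            for v in range(tree.n_nodes)
            if tree.parent[v] != NO_PARENT
        ]
        return float(gamma_dist.logpdf(rates, a=shape, scale=scale).sum())
    raise ValueError(f"unknown rate model kind {kind!r}")


def _brownian_branch_logpdf(diff: float, var: float) -> float:
    if var <= 0:
        return _LOG_ZERO if diff != 0.0 else 0.0
    return -0.5 * (np.log(2 * np.pi * var) + diff * diff / var)


# --------------------------------------------------------------------------
# Birth-death node-age prior (Rannala-Yang kernel, conditional on the root)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BirthDeathPrior:
    lam: float
    mu: float
    rho: float

    def __post_init__(self):
        if self.lam <= 0 or self.mu < 0 or not 0 < self.rho <= 1:
            raise ValueError("require lam > 0, mu >= 0, 0 < rho <= 1")
        if abs(self.lam - self.mu) < 1e-12:
            raise ValueError("critical case lam == mu is not supported")

    def _p0(self, t: float) -> float:
        lam, mu, rho = self.lam, self.mu, self.rho
        return rho * (lam - mu) / (
            rho * lam + (lam * (1 - rho) - mu) * np.exp((mu - lam) * t)
        )

    def log_kernel(self, t: float, root_age: float) -> float:
        """Log-density of one non-root internal age given the root age."""
        if not 0 < t < root_age:
            return _LOG_ZERO
        lam, mu, rho = self.lam, self.mu, self.rho
        p1 = (1.0 / rho) * self._p0(t) ** 2 * np.exp((mu - lam) * t)
        v = 1.0 - (1.0 / rho) * self._p0(root_age) * np.exp((mu - lam) * root_age)
        if v <= 0:
            return _LOG_ZERO
        return float(np.log(lam * p1 / v))


# --------------------------------------------------------------------------
# Pruning likelihood engine
# --------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning with per-branch caching and double buffering.

    Partial likelihood arrays are indexed [slot][node] with shape
    (K categories, sites, states); a proposal writes the affected nodes into
    the spare slot and either commits (flips the slot index) or abandons the
    proposal at zero cost.
    """

    def __init__(self, alignment: Alignment, tree: TimeTree,
                 model: SubstitutionModel):
        self.tree = tree
        self.model = model
        self.n_nodes = tree.n_nodes
        self.n_sites = alignment.length
        self.k = model.n_categories
        w, u, uinv = model.spectral()
        self._eigvals = w
        self._u = u
        self._uinv = uinv
        self._pi = model.equilibrium_frequencies()
        self.category_rates = model.category_rates()
        if model.n_categories > 1:
            self.gamma_shape = model.gamma_shape
        else:
            self.gamma_shape = None
        n_states = self._pi.size

        lookup = dict(alignment.records)
        leaves = tree.leaves
        codes = np.empty((len(leaves), alignment.length), dtype=np.int8)
        for row, leaf in enumerate(leaves):
            name = tree.names[leaf]
            if name not in lookup:
                raise KeyError(f"leaf {name!r} has no sequence in the alignment")
            codes[row] = model.encode(lookup[name])
        # collapse identical site patterns; likelihoods are weighted sums
        unique, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_inverse = inverse
        self.pattern_weights = counts.astype(float)
        self.n_sites = unique.shape[1]
        self.leaf_partial: dict[int, np.ndarray] = {}
        for row, leaf in enumerate(leaves):
            enc = unique[row]
            part = np.zeros((self.n_sites, n_states))
            missing = enc < 0
            part[np.arange(self.n_sites)[~missing], enc[~missing]] = 1.0
            part[missing, :] = 1.0  # gaps / unknowns are missing data
            self.leaf_partial[leaf] = part

        shape_m = (self.n_nodes, self.k, self.n_sites, n_states)
        # M[v] = (P_v @ partial_v) as a function of the parent state
        self._m = [np.zeros(shape_m), np.zeros(shape_m)]
        self._partial = [np.zeros(shape_m), np.zeros(shape_m)]
        # transition matrices are stored TRANSPOSED so that the pruning
        # matmuls run contiguous-on-contiguous (BLAS fast path)
        self._pt = [
            np.zeros((self.n_nodes, self.k, n_states, n_states)),
            np.zeros((self.n_nodes, self.k, n_states, n_states)),
        ]
        # independent double-buffer slots for partials and branch (P, M)
        # arrays: a proposal may refresh one without the other
        self._slot_part = np.zeros(self.n_nodes, dtype=int)
        self._slot_branch = np.zeros(self.n_nodes, dtype=int)
        self._pending: tuple | None = None
        self._subs = np.zeros(self.n_nodes)
        self._postorder = tree.postorder()
        self._post_index = {v: i for i, v in enumerate(self._postorder)}
        self._loglik = np.nan

    # ----------------------------------------------------------- internals
    def _compute_pt(self, out: np.ndarray, t: float, cat_rates) -> None:
        """Write the K stacked transposed transition matrices for length t."""
        exps = np.exp(np.outer(cat_rates * t, self._eigvals))  # (K, states)
        p = np.matmul(self._u[None, :, :] * exps[:, None, :], self._uinv)
        np.clip(p, 0.0, None, out=p)
        out[...] = p.transpose(0, 2, 1)

    def transition_matrices(self, v: int) -> np.ndarray:
        """Current (K, states, states) transition matrices of branch v."""
        return self._pt[self._slot_branch[v]][v].transpose(0, 2, 1)

    def node_partial(self, v: int) -> np.ndarray:
        """Current inside partial (K, sites, states) of node v."""
        if self.tree.children[v]:
            return self._partial[self._slot_part[v]][v]
        return np.broadcast_to(
            self.leaf_partial[v][None], (self.k, self.n_sites, self._pi.size)
        )

    def branch_m(self, v: int) -> np.ndarray:
        """Current per-parent-state branch factor (K, sites, states) of v."""
        return self._m[self._slot_branch[v]][v]

    def _recompute_branch(self, v: int, t: float, part_of, branch_of,
                          cat_rates) -> None:
        """Fill P^T and M of branch v (reading the partial where current)."""
        s = branch_of[v]
        self._compute_pt(self._pt[s][v], t, cat_rates)
        if self.tree.children[v]:
            np.matmul(
                self._partial[part_of[v]][v], self._pt[s][v], out=self._m[s][v]
            )
        else:
            np.matmul(
                self.leaf_partial[v][None, :, :], self._pt[s][v],
                out=self._m[s][v],
            )

    def _recompute_m_only(self, v: int, part_of, branch_of) -> None:
        """Refresh M of branch v (same P^T) after its subtree partial moved."""
        s = branch_of[v]
        np.copyto(self._pt[s][v], self._pt[1 - s][v])
        np.matmul(
            self._partial[part_of[v]][v], self._pt[s][v], out=self._m[s][v]
        )

    def _recompute_partial(self, u: int, part_of, branch_of) -> None:
        s = part_of[u]
        out = self._partial[s][u]
        children = self.tree.children[u]
        np.copyto(out, self._m[branch_of[children[0]]][children[0]])
        for c in children[1:]:
            out *= self._m[branch_of[c]][c]

    def _root_loglik(self, part_of) -> float:
        part = self._partial[part_of[self.tree.root]][self.tree.root]
        site_lik = np.einsum("ksj,j->s", part, self._pi) / self.k
        logs = np.log(np.maximum(site_lik, 1e-300))
        return float(logs @ self.pattern_weights)

    # ----------------------------------------------------------- public API
    def initialise(self, branch_subs: np.ndarray) -> float:
        """Full pruning pass; ``branch_subs[v]`` is the expected
        substitutions/site on the branch above node v (ignored for the root).
        Returns the log-likelihood."""
        self._subs = np.asarray(branch_subs, dtype=float).copy()
        self._slot_part[:] = 0
        self._slot_branch[:] = 0
        part_of, branch_of = self._slot_part, self._slot_branch
        for v in self._postorder:
            if self.tree.children[v]:
                self._recompute_partial(v, part_of, branch_of)
            if self.tree.parent[v] != NO_PARENT:
                self._recompute_branch(
                    v, self._subs[v], part_of, branch_of, self.category_rates
                )
        self._loglik = self._root_loglik(part_of)
        self._pending = None
        return self._loglik

    def propose(self, changes: dict[int, float],
                new_category_rates=None) -> float:
        """Evaluate the log-likelihood with the given branch-length changes
        written into spare buffers.  Call :meth:`accept` or :meth:`reject`
        before the next proposal."""
        if self._pending is not None:
            raise RuntimeError("previous proposal not resolved")
        cat_rates = (
            self.category_rates if new_category_rates is None else new_category_rates
        )
        if new_category_rates is not None:
            changed = {
                v: changes.get(v, self._subs[v])
                for v in range(self.n_nodes)
                if self.tree.parent[v] != NO_PARENT
            }
        else:
            changed = dict(changes)
        # nodes needing new partials: ancestors of changed branches
        dirty_partial: set[int] = set()
        for v in changed:
            a = self.tree.parent[v]
            while a != NO_PARENT and a not in dirty_partial:
                dirty_partial.add(a)
                a = self.tree.parent[a]
        # branches needing new (P, M): changed lengths, plus unchanged
        # branches whose subtree partial moved
        dirty_branch = set(changed) | {
            v for v in dirty_partial if self.tree.parent[v] != NO_PARENT
        }
        part_of = self._slot_part.copy()
        branch_of = self._slot_branch.copy()
        for v in dirty_partial:
            part_of[v] = 1 - part_of[v]
        for v in dirty_branch:
            branch_of[v] = 1 - branch_of[v]
        for v in sorted(
            dirty_partial | dirty_branch, key=self._post_index.__getitem__
        ):
            if v in dirty_partial:
                self._recompute_partial(v, part_of, branch_of)
            if v in dirty_branch:
                if v in changed or new_category_rates is not None:
                    self._recompute_branch(
                        v, changed.get(v, self._subs[v]), part_of, branch_of,
                        cat_rates,
                    )
                else:
                    self._recompute_m_only(v, part_of, branch_of)
        loglik = self._root_loglik(part_of)
        self._pending = (
            changed, part_of, branch_of, loglik,
            None if new_category_rates is None else np.asarray(cat_rates),
        )
        return loglik

    def accept(self) -> None:
        changed, part_of, branch_of, loglik, cat_rates = self._pending
        self._slot_part = part_of
        self._slot_branch = branch_of
        for v, t in changed.items():
            self._subs[v] = t
        if cat_rates is not None:
            self.category_rates = cat_rates
        self._loglik = loglik
        self._pending = None

    def reject(self) -> None:
        self._pending = None

    @property
    def loglik(self) -> float:
        return self._loglik


def pruning_loglik(alignment: Alignment, topology: TimeTree,
                   branch_subs, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood on a fixed topology.

    ``branch_subs`` maps node index -> expected substitutions/site on the
    branch above that node (dict or array; the root entry is ignored).  Gap
    and unknown characters are treated as missing data.
    """
    subs = np.zeros(topology.n_nodes)
    if isinstance(branch_subs, dict):
        for v, t in branch_subs.items():
            subs[v] = t
    else:
        subs = np.asarray(branch_subs, dtype=float)
    if np.any(subs[np.arange(topology.n_nodes) != topology.root] < 0):
        raise ValueError("branch lengths must be >= 0")
    engine = PruningEngine(alignment, topology, model)
    return engine.initialise(subs)


# --------------------------------------------------------------------------
# Settings / chains containers
# --------------------------------------------------------------------------

@dataclass
class ClockSettings:
    """Tunables of one MCMC run (all randomness flows from ``seed``)."""

    model: SubstitutionModel = field(default_factory=SubstitutionModel)
    rate_model: str = AUTOCORRELATED
    age_prior: str = "uniform"            # or "birth-death"
    birth_death: BirthDeathPrior | None = None
    n_chains: int = 4
    n_iterations: int = 20_000
    burn_in: float = 0.25
    thinning: int = 10
    seed: int = 0
    likelihood: bool = True
    sample_gamma_shape: bool = True
    # hyperpriors
    root_rate_prior_logmean: float = 0.0   # Normal prior on the root log-rate
    root_rate_prior_logsd: float = 1.5
    sigma2_prior_mean: float = 1.0         # exponential prior on sigma2
    gamma_rate_shape: float = 2.0          # uncorrelated clock branch-rate prior
    gamma_rate_scale: float = 0.5
    # initial values
    init_sigma2: float = 0.1
    init_rate: float | None = None
    init_log_rates: np.ndarray | None = None  # per-node, overrides init_rate
    # proposal scales
    age_window_fraction: float = 0.3
    root_age_window: float = 0.2
    rate_walk_sd: float = 0.35
    sigma2_multiplier: float = 0.6
    shape_multiplier: float = 0.3
    tree_scale_log_sd: float = 0.02

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for split-R-hat diagnostics")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.rate_model not in (AUTOCORRELATED, UNCORRELATED):
            raise ValueError(f"unknown rate model {self.rate_model!r}")
        if self.age_prior not in ("uniform", "birth-death"):
            raise ValueError("age_prior must be 'uniform' or 'birth-death'")
        if self.age_prior == "birth-death" and self.birth_death is None:
            raise ValueError("birth-death prior requires birth_death parameters")


@dataclass
class PosteriorChains:
    """Retained MCMC states.

    Arrays are indexed [chain][draw, ...]; ``ages`` and ``log_rates`` cover
    every node in the topology's node order, ``branch_rates`` the branch
    above each non-root node (NaN at the root entry).
    """

    topology: TimeTree
    settings: ClockSettings
    ages: list[np.ndarray]
    log_rates: list[np.ndarray]
    branch_rates: list[np.ndarray]
    sigma2: list[np.ndarray]
    gamma_shape: list[np.ndarray]
    log_posterior: list[np.ndarray]
    log_likelihood: list[np.ndarray]
    acceptance: list[dict[str, float]]

    @property
    def n_chains(self) -> int:
        return len(self.ages)

    @property
    def n_draws(self) -> int:
        return self.ages[0].shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """(chain, draw, ...) array of one stored quantity."""
        return np.stack(getattr(self, name))

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        return np.concatenate(getattr(self, name), axis=0)

    def scalar_summary(self):
        """Split-R-hat and bulk ESS for headline scalars (via ArviZ)."""
        import arviz as az
        import pandas as pd

        root = self.topology.root
        scalars = {
            "root_age": self.stacked("ages")[:, :, root],
            "sigma2": self.stacked("sigma2"),
            "gamma_shape": self.stacked("gamma_shape"),
            "mean_branch_rate": np.nanmean(self.stacked("branch_rates"), axis=2),
            "log_posterior": self.stacked("log_posterior"),
        }
        rows = []
        for name, arr in scalars.items():
            rows.append(
                {
                    "parameter": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)),
                    "rhat": float(az.rhat(az.convert_to_dataset(arr)).x),
                    "ess_bulk": float(az.ess(az.convert_to_dataset(arr)).x),
                }
            )
        df = pd.DataFrame(rows)
        bad = df[df.rhat > 1.1]
        for _, row in bad.iterrows():
            logger.warning(
                "split R-hat %.3f > 1.1 for %s — treat estimates with caution",
                row.rhat, row.parameter,
            )
        return df


@dataclass
class RateProfile:
    """Posterior rate-through-time profile, one row per non-root branch."""

    nodes: np.ndarray            # child node index of each branch
    midpoint_age: np.ndarray     # posterior-mean midpoint age (Ga)
    midpoint_age_se: np.ndarray
    rate: np.ndarray             # posterior-mean branch rate (δ Ga⁻¹)
    rate_se: np.ndarray
    dup_incident: np.ndarray     # bool: branch child of the labelled dup/root

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.nodes,
                "midpoint_age_Ga": self.midpoint_age,
                "midpoint_age_SE": self.midpoint_age_se,
                "rate_subs_per_site_per_Ga": self.rate,
                "rate_SE": self.rate_se,
                "dup_incident": self.dup_incident,
            }
        )


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------

def _resolve_calibrations(tree: TimeTree, calibrations) -> dict[int, Calibration]:
    resolved: dict[int, Calibration] = {}
    for cal in calibrations:
        if cal.clade == "root":
            node = tree.root
        else:
            node = tree.mrca(cal.clade)
        if node in resolved:
            raise CalibrationError(f"multiple calibrations on node {node}")
        resolved[node] = cal
    return resolved


def _feasibility_bounds(tree: TimeTree, node_cals: dict[int, Calibration]):
    """Hard lower/upper age envelopes per node; raises if empty."""
    lower = np.zeros(tree.n_nodes)
    upper = np.full(tree.n_nodes, np.inf)
    for node, cal in node_cals.items():
        # soft bounds are permissive; use them only as initialisation targets
        if cal.bounds == "HARD":
            if cal.min_age is not None:
                lower[node] = max(lower[node], cal.min_age)
            if cal.max_age is not None:
                upper[node] = min(upper[node], cal.max_age)
    for v in tree.postorder():  # propagate minima rootward
        p = tree.parent[v]
        if p != NO_PARENT:
            lower[p] = max(lower[p], lower[v])
    for v in tree.preorder():  # propagate maxima tipward
        p = tree.parent[v]
        if p != NO_PARENT:
            upper[v] = min(upper[v], upper[p])
    for v in tree.internal_nodes:
        if lower[v] >= upper[v]:
            raise CalibrationError(
                f"calibrations leave no feasible age for node {v}: "
                f"[{lower[v]}, {upper[v]}]"
            )
    return lower, upper


def _initial_ages(tree: TimeTree, node_cals, lower, upper) -> np.ndarray:
    """Feasible starting ages: calibration midpoints where available,
    otherwise spread between the structural bounds."""
    target = {}
    for node, cal in node_cals.items():
        if cal.min_age is not None and cal.max_age is not None:
            target[node] = 0.5 * (cal.min_age + cal.max_age)
        elif cal.min_age is not None:
            target[node] = cal.min_age + 0.5 * cal.span
        else:
            target[node] = max(cal.max_age - 0.5 * cal.span, 0.0)
    ages = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if not tree.children[v]:
            continue
        child_max = max(ages[c] for c in tree.children[v])
        lo = max(child_max, lower[v])
        hi = upper[v]
        if v in target:
            ages[v] = min(max(target[v], lo * 1.0001 + 1e-6), hi)
        elif np.isfinite(hi):
            ages[v] = lo + 0.5 * (hi - lo)
        else:
            ages[v] = lo + max(0.3 * max(lo, 1.0), 1e-3)
        if ages[v] <= child_max:
            ages[v] = child_max + 1e-6
    return ages


class _ChainState:
    """One chain's parameter state plus incremental prior bookkeeping."""

    def __init__(self, tree, ages, log_rates, sigma2, gamma_shape, settings):
        self.tree = tree
        self.ages = ages
        self.log_rates = log_rates
        self.sigma2 = sigma2
        self.gamma_shape = gamma_shape
        self.settings = settings

    def branch_rate(self, v: int) -> float:
        if self.settings.rate_model == AUTOCORRELATED:
            p = self.tree.parent[v]
            return float(np.exp(0.5 * (self.log_rates[v] + self.log_rates[p])))
        return float(np.exp(self.log_rates[v]))

    def branch_subs(self, v: int) -> float:
        p = self.tree.parent[v]
        return self.branch_rate(v) * (self.ages[p] - self.ages[v])

    def all_branch_subs(self) -> np.ndarray:
        subs = np.zeros(self.tree.n_nodes)
        for v in range(self.tree.n_nodes):
            if self.tree.parent[v] != NO_PARENT:
                subs[v] = self.branch_subs(v)
        return subs

    def all_branch_rates(self) -> np.ndarray:
        rates = np.full(self.tree.n_nodes, np.nan)
        for v in range(self.tree.n_nodes):
            if self.tree.parent[v] != NO_PARENT:
                rates[v] = self.branch_rate(v)
        return rates


def _log_prior(state: _ChainState, node_cals, settings: ClockSettings) -> float:
    """Full log-prior of a chain state (used at init and for move deltas
    cross-checks; individual moves compute deltas from the same terms)."""
    tree = state.tree
    total = 0.0
    root = tree.root
    # calibrations
    for node, cal in node_cals.items():
        total += cal.log_density(state.ages[node])
        if not np.isfinite(total):
            return _LOG_ZERO
    # conditional node-age prior
    inner = [v for v in tree.internal_nodes if v != root]
    if settings.age_prior == "uniform":
        total += -len(inner) * np.log(state.ages[root])
    else:
        bd = settings.birth_death
        for v in inner:
            total += bd.log_kernel(state.ages[v], state.ages[root])
    # rate prior
    if settings.rate_model == AUTOCORRELATED:
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p == NO_PARENT:
                continue
            dt = state.ages[p] - state.ages[v]
            total += _brownian_branch_logpdf(
                state.log_rates[v] - state.log_rates[p], state.sigma2 * dt
            )
        # root log-rate hyperprior
        z = (state.log_rates[root] - settings.root_rate_prior_logmean) / (
            settings.root_rate_prior_logsd
        )
        total += -0.5 * z * z - np.log(settings.root_rate_prior_logsd)
        # sigma2 hyperprior (exponential)
        total += -state.sigma2 / settings.sigma2_prior_mean
    else:
        from scipy.stats import gamma as gamma_dist

        for v in range(tree.n_nodes):
            if tree.parent[v] == NO_PARENT:
                continue
            # prior on log-rate parameterisation includes the Jacobian r
            r = np.exp(state.log_rates[v])
            total += gamma_dist.logpdf(
                r, a=settings.gamma_rate_shape, scale=settings.gamma_rate_scale
            ) + state.log_rates[v]
    # gamma shape hyperprior: lognormal(0, 1)
    if settings.sample_gamma_shape and settings.model.n_categories > 1:
        ls = np.log(state.gamma_shape)
        total += -0.5 * ls * ls - ls
    return float(total)


def run_mcmc(alignment: Alignment | None, topology: TimeTree, calibrations,
             settings: ClockSettings) -> PosteriorChains:
    """Sample node ages, rates and hyperparameters.

    ``alignment`` may be None when ``settings.likelihood`` is False
    (prior-only run).  The topology's ages, if set, are ignored — starting
    ages are derived from the calibrations.  Chains are deterministic given
    ``settings.seed``.
    """
    node_cals = _resolve_calibrations(topology, calibrations)
    if topology.root not in node_cals and settings.age_prior == "uniform":
        raise CalibrationError(
            "the uniform age prior needs a root calibration to be proper"
        )
    lower, upper = _feasibility_bounds(topology, node_cals)
    if settings.likelihood and alignment is None:
        raise ValueError("likelihood enabled but no alignment given")

    seed_seq = np.random.SeedSequence(settings.seed)
    chain_seeds = seed_seq.spawn(settings.n_chains)

    chains_out = {
        name: [] for name in
        ("ages", "log_rates", "branch_rates", "sigma2", "gamma_shape",
         "log_posterior", "log_likelihood")
    }
    acceptance_out = []
    for ci in range(settings.n_chains):
        result = _run_single_chain(
            alignment, topology, node_cals, lower, upper, settings,
            np.random.default_rng(chain_seeds[ci]),
        )
        for name in chains_out:
            chains_out[name].append(result[name])
        acceptance_out.append(result["acceptance"])
    return PosteriorChains(
        topology=topology,
        settings=settings,
        acceptance=acceptance_out,
        **chains_out,
    )


def _run_single_chain(alignment, tree, node_cals, lower, upper,
                      settings: ClockSettings, rng) -> dict:
    root = tree.root
    inner = [v for v in tree.internal_nodes if v != root]
    non_root = [v for v in range(tree.n_nodes) if v != root]
    ages = _initial_ages(tree, node_cals, lower, upper)

    if settings.init_log_rates is not None:
        log_rates = np.asarray(settings.init_log_rates, dtype=float).copy()
        if log_rates.shape != (tree.n_nodes,):
            raise ValueError("init_log_rates must have one entry per node")
    else:
        if settings.init_rate is not None:
            rate0 = settings.init_rate
        else:
            rate0 = float(np.exp(settings.root_rate_prior_logmean))
        log_rates = np.full(tree.n_nodes, np.log(rate0))
    log_rates += rng.normal(0.0, 0.05, size=tree.n_nodes)  # break symmetry
    state = _ChainState(
        tree, ages, log_rates, settings.init_sigma2,
        settings.model.gamma_shape, settings
    )
    rate_nodes = (
        list(range(tree.n_nodes)) if settings.rate_model == AUTOCORRELATED
        else non_root
    )

    engine = None
    loglik = 0.0
    if settings.likelihood:
        engine = PruningEngine(alignment, tree, settings.model)
        loglik = engine.initialise(state.all_branch_subs())
    logprior = _log_prior(state, node_cals, settings)
    if not np.isfinite(logprior):
        raise CalibrationError("initial state has zero prior probability")

    n_iter = settings.n_iterations
    burn = int(settings.burn_in * n_iter)
    keep = [
        it for it in range(n_iter)
        if it >= burn and (it - burn) % settings.thinning == 0
    ]
    keep_set = set(keep)
    stored = {
        "ages": np.empty((len(keep), tree.n_nodes)),
        "log_rates": np.empty((len(keep), tree.n_nodes)),
        "branch_rates": np.empty((len(keep), tree.n_nodes)),
        "sigma2": np.empty(len(keep)),
        "gamma_shape": np.empty(len(keep)),
        "log_posterior": np.empty(len(keep)),
        "log_likelihood": np.empty(len(keep)),
    }
    accept_count = {"age": 0, "rate": 0, "sigma2": 0, "shape": 0, "scale": 0}
    try_count = {"age": 0, "rate": 0, "sigma2": 0, "shape": 0, "scale": 0}

    def prior_terms_age(v: int, age_v: float) -> float:
        """Prior pieces that depend on the age of node v (rates fixed)."""
        total = 0.0
        if v in node_cals:
            total += node_cals[v].log_density(age_v)
            if not np.isfinite(total):
                return _LOG_ZERO
        if v == root:
            if settings.age_prior == "uniform":
                total += -len(inner) * np.log(age_v)
            else:
                for w in inner:
                    total += settings.birth_death.log_kernel(state.ages[w], age_v)
        elif settings.age_prior == "birth-death":
            total += settings.birth_death.log_kernel(age_v, state.ages[root])
        if settings.rate_model == AUTOCORRELATED:
            p = tree.parent[v]
            if p != NO_PARENT:
                dt = state.ages[p] - age_v
                total += _brownian_branch_logpdf(
                    state.log_rates[v] - state.log_rates[p], state.sigma2 * dt
                )
            for c in tree.children[v]:
                dt = age_v - state.ages[c]
                total += _brownian_branch_logpdf(
                    state.log_rates[c] - state.log_rates[v], state.sigma2 * dt
                )
        return total

    def prior_terms_rate(v: int, lr_v: float) -> float:
        total = 0.0
        if settings.rate_model == AUTOCORRELATED:
            p = tree.parent[v]
            if p != NO_PARENT:
                dt = state.ages[p] - state.ages[v]
                total += _brownian_branch_logpdf(
                    lr_v - state.log_rates[p], state.sigma2 * dt
                )
            for c in tree.children[v]:
                dt = state.ages[v] - state.ages[c]
                total += _brownian_branch_logpdf(
                    state.log_rates[c] - lr_v, state.sigma2 * dt
                )
            if v == root:
                z = (lr_v - settings.root_rate_prior_logmean) / (
                    settings.root_rate_prior_logsd
                )
                total += -0.5 * z * z
        else:
            from scipy.stats import gamma as gamma_dist

            total += float(
                gamma_dist.logpdf(
                    np.exp(lr_v),
                    a=settings.gamma_rate_shape,
                    scale=settings.gamma_rate_scale,
                )
            ) + lr_v
        return total

    def affected_subs_for_age(v: int, new_age: float) -> dict[int, float]:
        changes = {}
        old_age = state.ages[v]
        state.ages[v] = new_age
        if tree.parent[v] != NO_PARENT:
            changes[v] = state.branch_subs(v)
        for c in tree.children[v]:
            changes[c] = state.branch_subs(c)
        state.ages[v] = old_age
        return changes

    def affected_subs_for_rate(v: int, new_lr: float) -> dict[int, float]:
        changes = {}
        old = state.log_rates[v]
        state.log_rates[v] = new_lr
        if tree.parent[v] != NO_PARENT:
            changes[v] = state.branch_subs(v)
        if settings.rate_model == AUTOCORRELATED:
            for c in tree.children[v]:
                changes[c] = state.branch_subs(c)
        state.log_rates[v] = old
        return changes

    def mh_step(kind: str, delta_logprior: float, changes, log_hastings=0.0,
                new_cat_rates=None) -> bool:
        nonlocal loglik, logprior
        try_count[kind] += 1
        if not np.isfinite(delta_logprior):
            return False
        if engine is not None and (changes or new_cat_rates is not None):
            new_loglik = engine.propose(changes, new_cat_rates)
            delta_loglik = new_loglik - loglik
        else:
            new_loglik = loglik
            delta_loglik = 0.0
        log_alpha = delta_logprior + delta_loglik + log_hastings
        if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
            if engine is not None and (changes or new_cat_rates is not None):
                engine.accept()
            loglik = new_loglik
            logprior += delta_logprior
            accept_count[kind] += 1
            return True
        if engine is not None and (changes or new_cat_rates is not None):
            engine.reject()
        return False

    store_row = 0
    for it in range(n_iter):
        # ---- node age moves
        for v in tree.internal_nodes:
            if v == root:
                lo = max(state.ages[c] for c in tree.children[v])
                delta = settings.root_age_window
                y = state.ages[v] + rng.uniform(-delta, delta)
                if y < lo:
                    y = 2 * lo - y  # reflect
            else:
                lo = max(state.ages[c] for c in tree.children[v])
                hi = state.ages[tree.parent[v]]
                delta = settings.age_window_fraction * (hi - lo)
                y = state.ages[v] + rng.uniform(-delta, delta)
                while y < lo or y > hi:  # reflect into the window
                    if y < lo:
                        y = 2 * lo - y
                    if y > hi:
                        y = 2 * hi - y
            old_terms = prior_terms_age(v, state.ages[v])
            new_terms = prior_terms_age(v, y)
            changes = affected_subs_for_age(v, y)
            if mh_step("age", new_terms - old_terms, changes):
                state.ages[v] = y

        # ---- node log-rate moves (leaf rates on alternate sweeps: their
        # conditionals are narrow, so a half-rate scan trades little mixing
        # for a third of the likelihood evaluations)
        for v in rate_nodes:
            if it % 2 and not tree.children[v]:
                continue
            y = state.log_rates[v] + rng.normal(0.0, settings.rate_walk_sd)
            old_terms = prior_terms_rate(v, state.log_rates[v])
            new_terms = prior_terms_rate(v, y)
            changes = affected_subs_for_rate(v, y)
            if mh_step("rate", new_terms - old_terms, changes):
                state.log_rates[v] = y

        # ---- sigma2 multiplier
        if settings.rate_model == AUTOCORRELATED:
            c = np.exp(rng.uniform(-settings.sigma2_multiplier,
                                   settings.sigma2_multiplier))
            new_s2 = state.sigma2 * c
            old_terms = new_terms = 0.0
            for v in non_root:
                p = tree.parent[v]
                dt = state.ages[p] - state.ages[v]
                diff = state.log_rates[v] - state.log_rates[p]
                old_terms += _brownian_branch_logpdf(diff, state.sigma2 * dt)
                new_terms += _brownian_branch_logpdf(diff, new_s2 * dt)
            old_terms += -state.sigma2 / settings.sigma2_prior_mean
            new_terms += -new_s2 / settings.sigma2_prior_mean
            if mh_step("sigma2", new_terms - old_terms, {},
                       log_hastings=np.log(c)):
                state.sigma2 = new_s2

        # ---- gamma shape multiplier (likelihood-wide)
        if (settings.sample_gamma_shape and settings.model.n_categories > 1
                and engine is not None):
            c = np.exp(rng.uniform(-settings.shape_multiplier,
                                   settings.shape_multiplier))
            new_shape = state.gamma_shape * c
            ls_old, ls_new = np.log(state.gamma_shape), np.log(new_shape)
            d_prior = (-0.5 * ls_new * ls_new - ls_new) - (
                -0.5 * ls_old * ls_old - ls_old
            )
            new_rates = discrete_gamma_rates(new_shape,
                                             settings.model.n_categories)
            if mh_step("shape", d_prior, {}, log_hastings=np.log(c),
                       new_cat_rates=new_rates):
                state.gamma_shape = new_shape

        # ---- whole-tree age scale
        c = np.exp(rng.normal(0.0, settings.tree_scale_log_sd))
        new_ages = state.ages * c
        old_terms = _log_prior(state, node_cals, settings)
        saved = state.ages
        state.ages = new_ages
        new_terms = _log_prior(state, node_cals, settings)
        state.ages = saved
        if np.isfinite(new_terms):
            changes = {}
            old_ages = state.ages
            state.ages = new_ages
            for v in non_root:
                changes[v] = state.branch_subs(v)
            state.ages = old_ages
            n_free = len(inner) + 1
            if mh_step("scale", new_terms - old_terms, changes,
                       log_hastings=n_free * np.log(c)):
                state.ages = new_ages
                logprior = new_terms  # replace incremental total exactly
            else:
                logprior = old_terms
        else:
            try_count["scale"] += 1

        if it in keep_set:
            stored["ages"][store_row] = state.ages
            stored["log_rates"][store_row] = state.log_rates
            stored["branch_rates"][store_row] = state.all_branch_rates()
            stored["sigma2"][store_row] = state.sigma2
            stored["gamma_shape"][store_row] = state.gamma_shape
            stored["log_posterior"][store_row] = logprior + loglik
            stored["log_likelihood"][store_row] = loglik
            store_row += 1

    stored["acceptance"] = {
        k: (accept_count[k] / try_count[k] if try_count[k] else np.nan)
        for k in accept_count
    }
    return stored


# --------------------------------------------------------------------------
# Posterior summaries
# --------------------------------------------------------------------------

def extract_rate_profile(chains: PosteriorChains,
                         topology: TimeTree | None = None) -> RateProfile:
    """Posterior-mean branch rates and midpoint ages with standard errors.

    The SE of each quantity is its posterior standard deviation divided by
    the square root of its bulk effective sample size.  Chains with split
    R-hat above 1.1 on headline scalars trigger a warning (never an error).
    """
    import arviz as az

    if chains.n_draws == 0:
        raise ValueError("chains contain no retained draws")
    tree = topology if topology is not None else chains.topology
    chains.scalar_summary()  # emits convergence warnings as a side effect

    root = tree.root
    nodes = np.array([v for v in range(tree.n_nodes) if v != root])
    rates = chains.stacked("branch_rates")[:, :, nodes]      # (C, D, B)
    ages = chains.stacked("ages")                            # (C, D, N)
    parents = tree.parent[nodes]
    midpoints = 0.5 * (ages[:, :, nodes] + ages[:, :, parents])

    def mean_se(arr):
        mean = arr.mean(axis=(0, 1))
        sd = arr.std(axis=(0, 1), ddof=1)
        if arr.shape[0] * arr.shape[1] > 3:
            ess = np.asarray(
                az.ess(az.convert_to_dataset(arr)).x
            )
            ess = np.maximum(ess, 1.0)
        else:
            ess = np.full(arr.shape[2], max(arr.shape[0] * arr.shape[1], 1))
        return mean, sd / np.sqrt(ess)

    rate_mean, rate_se = mean_se(rates)
    age_mean, age_se = mean_se(midpoints)
    dup_node = tree.labels.get("dup", root)
    dup_incident = np.array([tree.parent[v] == dup_node for v in nodes])
    return RateProfile(
        nodes=nodes,
        midpoint_age=age_mean,
        midpoint_age_se=age_se,
        rate=rate_mean,
        rate_se=rate_se,
        dup_incident=dup_incident,
    )
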