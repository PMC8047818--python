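"""Forward simulation of chronograms, branch rates and alignments, and
duplication-anchored paralog datasets.

This module generates the study conditions the downstream analysis assumes:
a species chronogram is mirrored into two paralog subtrees joined at a
duplication node of age ``dup_age``; branch rates follow either an
autocorrelated lognormal process (log-rates doing Brownian motion along the
tree) or a deterministic exponential decay envelope — fast near the ancient
duplication, relaxing to a plateau toward the present — and alignments are
simulated under an empirical amino-acid matrix with discrete-gamma rate
heterogeneity.  Each dataset carries a truth record (ΔT, ν_max, ν_min)
recomputable from the stored tree, so parameter-recovery tests are
self-consistent by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core_io import Alignment
from .substitution import SubstitutionModel, AA_ORDER
from .trees import TimeTree, NO_PARENT

#: Archean/Proterozoic boundary used as the default ν_min window edge (Ga).
DEFAULT_PROTEROZOIC_CUTOFF = 2.5


@dataclass
class RateProcess:
    """Branch-rate process specification.

    kind
        ``"autocorrelated-lognormal"``: node log-rates follow Brownian motion
        with variance ``sigma2`` per Ga, started at ``log(root_rate)``; the
        rate of a branch is ``exp`` of the mean of its two endpoint log-rates.
        ``"uncorrelated-gamma"``: i.i.d. Gamma(shape, scale) branch rates.
    """

    kind: str = "autocorrelated-lognormal"
    root_rate: float = 1.0
    sigma2: float = 0.1
    shape: float = 2.0
    scale: float = 0.5

    def __post_init__(self):
        if self.kind not in ("autocorrelated-lognormal", "uncorrelated-gamma"):
            raise ValueError(f"unknown rate process kind {self.kind!r}")
        if self.root_rate <= 0:
            raise ValueError("root_rate must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape/scale must be > 0")


@dataclass
class DuplicationScenarioTruth:
    """Realised truth of one simulated duplication dataset."""

    delta_t: float
    dup_age: float
    mrca_age: float
    nu_max: float
    nu_min: float
    proterozoic_cutoff: float

    @property
    def ratio(self) -> float:
        return self.nu_max / self.nu_min

    def to_json(self) -> str:
        d = asdict(self)
        d["ratio"] = self.ratio
        return json.dumps(d, indent=2)


def simulate_timetree(
    n_taxa: int,
    root_age: float,
    seed: int | None = None,
    age_distribution: str = "coalescent",
) -> TimeTree:
    """Random rooted chronogram with leaves at age 0 and root at ``root_age``.

    Topology is built by merging uniformly chosen lineage pairs at strictly
    increasing ages.  ``age_distribution`` controls internal node ages:
    ``"coalescent"`` uses rescaled Kingman waiting times (most merges near the
    tips), ``"uniform"`` draws the non-root internal ages i.i.d. uniform on
    (0, root_age) — the latter matches the clock module's uniform-on-ages
    prior, which is convenient for calibration studies.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if root_age <= 0:
        raise ValueError(f"root_age must be > 0, got {root_age}")
    if age_distribution not in ("coalescent", "uniform"):
        raise ValueError("age_distribution must be 'coalescent' or 'uniform'")
    rng = np.random.default_rng(seed)
    if age_distribution == "coalescent":
        times = []
        t = 0.0
        for k in range(n_taxa, 1, -1):
            t += rng.exponential(2.0 / (k * (k - 1)))
            times.append(t)
        ages = np.array(times) * (root_age / times[-1])
    else:
        inner = np.sort(rng.uniform(0.0, root_age, size=n_taxa - 2))
        ages = np.concatenate([inner, [root_age]])
    # guard against exact age ties (probability zero, but be safe)
    ages = np.maximum.accumulate(ages + np.arange(len(ages)) * 1e-12)

    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, NO_PARENT, dtype=int)
    age = np.zeros(n_nodes)
    names: list[str | None] = [f"t{i + 1}" for i in range(n_taxa)] + [None] * (
        n_taxa - 1
    )
    active = list(range(n_taxa))
    nxt = n_taxa
    for merge_age in ages:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        age[nxt] = merge_age
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return TimeTree(parent, age, names)


def simulate_branch_rates(
    tree: TimeTree, process: RateProcess, seed: int | None = None
) -> TimeTree:
    """Fill branch rates on a copy of ``tree`` according to ``process``.

    For the autocorrelated-lognormal kind, node log-rates follow
    log r_child ~ Normal(log r_parent, sigma2 * Δt) and the branch rate is
    exp of the mean of the two endpoint log-rates.  For the uncorrelated
    kind, branch rates are i.i.d. Gamma(shape, scale).
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    if process.kind == "autocorrelated-lognormal":
        out.node_log_rate[out.root] = np.log(process.root_rate)
        for node in out.preorder():
            if node == out.root:
                continue
            p = out.parent[node]
            dt = out.age[p] - out.age[node]
            out.node_log_rate[node] = rng.normal(
                out.node_log_rate[p], np.sqrt(process.sigma2 * dt)
            )
            out.branch_rate[node] = np.exp(
                0.5 * (out.node_log_rate[p] + out.node_log_rate[node])
            )
    else:
        for node in out.postorder():
            if node == out.root:
                continue
            out.branch_rate[node] = rng.gamma(process.shape, process.scale)
    out.validate(require_rates=True)
    return out


def exponential_rate_envelope(
    tree: TimeTree,
    r0: float,
    decay_rate: float,
    plateau: float,
    seed: int | None = None,
    jitter_sd: float = 0.0,
) -> TimeTree:
    """Deterministic decaying rate profile r(t) = plateau + (r0 - plateau) *
    exp(-decay_rate * (t_root - t)), with t the age before present.

    Branch rates are the exact time-average of r(t) over the branch, so the
    realised ν_max/ν_min of a dataset built from this envelope is controlled
    analytically.  Optional multiplicative lognormal jitter (sd ``jitter_sd``
    on the log scale) roughens the profile for noisy recovery tests.
    """
    if r0 <= 0 or plateau <= 0:
        raise ValueError("r0 and plateau must be > 0")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    t_root = out.age[out.root]
    lam = decay_rate
    amp = r0 - plateau
    for node in range(out.n_nodes):
        out.node_log_rate[node] = np.log(
            plateau + amp * np.exp(-lam * (t_root - out.age[node]))
        )
        if node == out.root:
            continue
        a = out.age[node]
        b = out.age[out.parent[node]]
        if lam == 0.0:
            mean_rate = plateau + amp
        else:
            mean_rate = plateau + amp * np.exp(-lam * t_root) * (
                np.exp(lam * b) - np.exp(lam * a)
            ) / (lam * (b - a))
        if jitter_sd > 0:
            mean_rate *= np.exp(rng.normal(0.0, jitter_sd))
        out.branch_rate[node] = mean_rate
    out.validate(require_rates=True)
    return out


def simulate_alignment(
    tree: TimeTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | None = None,
    return_states: bool = False,
):
    """Simulate an ungapped amino-acid alignment down a rate-annotated tree.

    The root sequence is drawn from the model's equilibrium frequencies, each
    site is assigned one of the K discrete-gamma categories, and states evolve
    along each branch with transition matrix P(subs * r_cat).  No indels are
    generated.  With ``return_states`` the full (n_nodes, n_sites) latent
    state matrix is returned alongside the alignment, which is how ancestral
    reconstruction is benchmarked against known ancestors.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tree.validate(require_rates=True)
    rng = np.random.default_rng(seed)
    freqs = model.equilibrium_frequencies()
    cat_rates = model.category_rates()
    k = len(cat_rates)
    site_cat = rng.integers(0, k, size=n_sites)
    states = np.empty((tree.n_nodes, n_sites), dtype=int)
    states[tree.root] = rng.choice(20, size=n_sites, p=freqs)
    for node in tree.preorder():
        if node == tree.root:
            continue
        subs = tree.branch_subs(node)
        parent_states = states[tree.parent[node]]
        child_states = np.empty(n_sites, dtype=int)
        for c in range(k):
            sites = np.nonzero(site_cat == c)[0]
            if sites.size == 0:
                continue
            p = model.transition_matrix(subs, cat_rates[c])
            cum = np.cumsum(p, axis=1)
            u = rng.random(sites.size)
            rows = cum[parent_states[sites]]
            child_states[sites] = (u[:, None] > rows).sum(axis=1)
        states[node] = child_states
    letters = np.array(list(AA_ORDER))
    records = []
    for leaf in tree.leaves:
        records.append((tree.names[leaf], "".join(letters[states[leaf]])))
    alignment = Alignment(records)
    if return_states:
        return alignment, states
    return alignment


def join_paralog_trees(species_tree: TimeTree, dup_age: float) -> TimeTree:
    """Two mirrored copies of ``species_tree`` joined at a duplication root.

    Leaf names get ``_A``/``_B`` suffixes; the new root (age ``dup_age``) is
    labelled ``dup`` and the two species-tree roots ``crown_A``/``crown_B``.
    """
    root_age = species_tree.age[species_tree.root]
    if dup_age <= root_age:
        raise ValueError(
            f"dup_age ({dup_age}) must exceed the species root age ({root_age})"
        )
    n = species_tree.n_nodes
    n_join = 2 * n + 1
    parent = np.full(n_join, NO_PARENT, dtype=int)
    age = np.zeros(n_join)
    names: list[str | None] = [None] * n_join
    dup_node = 2 * n
    for copy_idx, suffix in enumerate(("_A", "_B")):
        off = copy_idx * n
        for i in range(n):
            p = species_tree.parent[i]
            parent[i + off] = dup_node if p == NO_PARENT else p + off
            age[i + off] = species_tree.age[i]
            if species_tree.names[i] is not None:
                names[i + off] = species_tree.names[i] + suffix
    age[dup_node] = dup_age
    labels = {
        "dup": dup_node,
        "crown_A": species_tree.root,
        "crown_B": species_tree.root + n,
    }
    return TimeTree(parent, age, names, labels=labels)


def make_duplication_dataset(
    species_tree: TimeTree,
    dup_age: float,
    process: RateProcess,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | None = None,
    proterozoic_cutoff: float = DEFAULT_PROTEROZOIC_CUTOFF,
    envelope: dict | None = None,
) -> tuple[Alignment, DuplicationScenarioTruth, TimeTree]:
    """Simulate a duplication-anchored paralog alignment plus its truth.

    The species chronogram is duplicated into two paralog subtrees joined at
    a root of age ``dup_age``.  Rates come from the autocorrelated process
    started at ``process.root_rate`` (fast near the duplication, relaxing
    toward the tips) or, when ``envelope`` is given (keys ``r0``,
    ``decay_rate``, ``plateau``, optional ``jitter_sd``), from the
    deterministic exponential decay profile.  The truth record stores the
    realised ΔT, ν_max (mean rate of the two duplication-incident branches)
    and ν_min (mean rate of branches with midpoint age below
    ``proterozoic_cutoff``).

    Returns ``(alignment, truth, rate_tree)``.
    """
    rng = np.random.default_rng(seed)
    joined = join_paralog_trees(species_tree, dup_age)
    if envelope is not None:
        rate_tree = exponential_rate_envelope(
            joined,
            r0=envelope["r0"],
            decay_rate=envelope["decay_rate"],
            plateau=envelope["plateau"],
            seed=int(rng.integers(2**31 - 1)),
            jitter_sd=envelope.get("jitter_sd", 0.0),
        )
    else:
        rate_tree = simulate_branch_rates(
            joined, process, seed=int(rng.integers(2**31 - 1))
        )
    alignment = simulate_alignment(
        rate_tree, model, n_sites, seed=int(rng.integers(2**31 - 1))
    )
    truth = truth_from_tree(rate_tree, proterozoic_cutoff)
    return alignment, truth, rate_tree


def truth_from_tree(
    rate_tree: TimeTree, proterozoic_cutoff: float = DEFAULT_PROTEROZOIC_CUTOFF
) -> DuplicationScenarioTruth:
    """Recompute the ΔT/ν_max/ν_min truth record from a labelled rate tree."""
    dup = rate_tree.labels["dup"]
    crown_a = rate_tree.labels["crown_A"]
    dup_age = float(rate_tree.age[dup])
    mrca_age = float(rate_tree.age[crown_a])
    incident = rate_tree.children[dup]
    nu_max = float(np.mean([rate_tree.branch_rate[c] for c in incident]))
    window = [
        rate_tree.branch_rate[v]
        for v in range(rate_tree.n_nodes)
        if rate_tree.parent[v] != NO_PARENT
        and rate_tree.branch_midpoint_age(v) < proterozoic_cutoff
    ]
    if not window:
        raise ValueError(
            f"no branch midpoint below the {proterozoic_cutoff} Ga cutoff"
        )
    nu_min = float(np.mean(window))
    return DuplicationScenarioTruth(
        delta_t=dup_age - mrca_age,
        dup_age=dup_age,
        mrca_age=mrca_age,
        nu_max=nu_max,
        nu_min=nu_min,
        proterozoic_cutoff=proterozoic_cutoff,
    )


def envelope_r0_for_ratio(
    joined_tree: TimeTree,
    decay_rate: float,
    plateau: float,
    target_ratio: float,
    proterozoic_cutoff: float = DEFAULT_PROTEROZOIC_CUTOFF,
) -> float:
    """Solve for the envelope r0 whose realised ν_max/ν_min equals
    ``target_ratio`` on the given (age-annotated, labelled) joined tree.

    The realised ratio under the deterministic envelope is monotone in r0,
    so a bracketing root search is exact up to tolerance.
    """
    from scipy.optimize import brentq

    if target_ratio <= 1.0:
        raise ValueError("target_ratio must exceed 1")

    def gap(r0: float) -> float:
        rt = exponential_rate_envelope(joined_tree, r0, decay_rate, plateau)
        return truth_from_tree(rt, proterozoic_cutoff).ratio - target_ratio

    lo = plateau * (1.0 + 1e-9)
    hi = plateau * 10.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e9:
            raise RuntimeError("could not bracket the target ratio")
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))


def envelope_r0_for_nu_max(
    nu_max: float,
    delta_t: float,
    decay_rate: float,
    plateau: float,
) -> float:
    """Invert the exponential envelope for the r0 giving a target ν_max.

    ν_max is the time-average of the envelope over the two duplication-
    incident branches (duration ΔT ending at the duplication node), so
    ν_max = plateau + (r0 - plateau) * (1 - exp(-λΔT)) / (λΔT).
    """
    if nu_max <= plateau:
        raise ValueError("target nu_max must exceed the plateau")
    lam = decay_rate
    if lam == 0.0:
        frac = 1.0
    else:
        frac = (1.0 - np.exp(-lam * delta_t)) / (lam * delta_t)
    return plateau + (nu_max - plateau) / frac
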