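"""Amino-acid substitution models with discrete-gamma rate heterogeneity.

A :class:`SubstitutionModel` combines an exchangeability matrix (POISSON,
JTT, WAG or LG), equilibrium frequencies (model-given or observed/empirical)
and a K-category discrete-gamma distribution of among-site rate variation
(Yang's equal-probability discretisation with category means).  The
instantaneous rate matrix is normalised to one expected substitution per
site per unit branch length, so branch lengths are expected
substitutions/site.

Transition probabilities are computed through a single spectral decomposition
of the reversible rate matrix, which makes per-branch, per-category P(t)
evaluation cheap inside likelihood and simulation loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaincc, gammainc
from scipy.stats import gamma as gamma_dist

from . import _aa_models

AA_ORDER = _aa_models.AA_ORDER
N_STATES = 20

_MATRICES = {
    "JTT": (_aa_models.JTT_LOWER_TRIANGLE, _aa_models.JTT_FREQUENCIES),
    "WAG": (_aa_models.WAG_LOWER_TRIANGLE, _aa_models.WAG_FREQUENCIES),
    "LG": (_aa_models.LG_LOWER_TRIANGLE, _aa_models.LG_FREQUENCIES),
}


def _lower_triangle_to_symmetric(values: Sequence[float], n: int) -> np.ndarray:
    s = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = values[k]
            k += 1
    if k != len(values):
        raise ValueError("lower-triangle length mismatch")
    return s


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of K equal-probability categories of Gamma(alpha, alpha).

    The distribution has mean 1; category means are computed from the
    incomplete gamma function so their average is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be > 0, got {alpha}")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X ; X <= b] for Gamma(alpha, rate alpha) = P(alpha+1, alpha*b) (mean 1)
    cum = np.where(np.isinf(bounds), 1.0, gammainc(alpha + 1.0, alpha * bounds))
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Empirical-matrix + discrete-gamma substitution model.

    Parameters
    ----------
    matrix_id : one of "POISSON", "JTT", "WAG", "LG".
    frequencies : optional length-20 equilibrium frequencies over
        :data:`AA_ORDER` (e.g. observed alignment frequencies, "+F");
        defaults to the matrix's own frequencies (uniform for POISSON).
    gamma_shape : shape α of the discrete-gamma among-site rate distribution.
    n_categories : number of discrete rate categories (default 4; use 1 for
        rate homogeneity, in which case ``gamma_shape`` is ignored).
    """

    matrix_id: str = "POISSON"
    frequencies: np.ndarray | None = None
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        self.matrix_id = self.matrix_id.upper()
        if self.matrix_id not in ("POISSON", *_MATRICES):
            raise ValueError(f"unknown matrix_id {self.matrix_id!r}")
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (N_STATES,) or np.any(f < 0):
                raise ValueError("frequencies must be 20 non-negative values")
            if abs(f.sum() - 1.0) > 1e-6:
                raise ValueError("frequencies must sum to 1")
            self.frequencies = f / f.sum()
        if self.n_categories >= 2 and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        self._spectral = None

    # ------------------------------------------------------------- components
    def exchangeabilities(self) -> np.ndarray:
        if self.matrix_id == "POISSON":
            s = np.ones((N_STATES, N_STATES))
            np.fill_diagonal(s, 0.0)
            return s
        return _lower_triangle_to_symmetric(_MATRICES[self.matrix_id][0], N_STATES)

    def equilibrium_frequencies(self) -> np.ndarray:
        if self.frequencies is not None:
            return self.frequencies
        if self.matrix_id == "POISSON":
            return np.full(N_STATES, 1.0 / N_STATES)
        return np.asarray(_MATRICES[self.matrix_id][1], dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix Q normalised to mean rate 1."""
        s = self.exchangeabilities()
        pi = self.equilibrium_frequencies()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        q[np.diag_indices_from(q)] = -q.sum(axis=1)
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def category_rates(self) -> np.ndarray:
        if self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    # --------------------------------------------------------------- spectral
    def spectral(self):
        """(eigenvalues, U, U^-1) of Q with Q = U diag(w) U^-1.

        Computed through the symmetrising similarity transform of the
        reversible chain, cached on the instance.
        """
        if self._spectral is None:
            pi = self.equilibrium_frequencies()
            q = self.rate_matrix()
            sqrt_pi = np.sqrt(pi)
            b = q * sqrt_pi[:, None] / sqrt_pi[None, :]
            b = 0.5 * (b + b.T)  # enforce exact symmetry
            w, v = np.linalg.eigh(b)
            u = v / sqrt_pi[:, None]
            uinv = v.T * sqrt_pi[None, :]
            self._spectral = (w, u, uinv)
        return self._spectral

    def transition_matrix(self, t: float, category_rate: float = 1.0) -> np.ndarray:
        """P(t) for one branch length (expected subs/site) and category rate."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        w, u, uinv = self.spectral()
        p = (u * np.exp(w * t * category_rate)[None, :]) @ uinv
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_k) over the K category rates, shape (K, 20, 20)."""
        return np.stack(
            [self.transition_matrix(t, r) for r in self.category_rates()]
        )

    def encode(self, sequence: str) -> np.ndarray:
        """Map residues to state indices; gaps/unknowns map to -1 (missing)."""
        lookup = {aa: i for i, aa in enumerate(AA_ORDER)}
        return np.array([lookup.get(ch, -1) for ch in sequence], dtype=int)


def observed_frequencies(alignment) -> np.ndarray:
    """Empirical residue frequencies of an Alignment (gaps ignored)."""
    counts = np.zeros(N_STATES)
    lookup = {aa: i for i, aa in enumerate(AA_ORDER)}
    for _, seq in alignment.records:
        for ch in seq:
            idx = lookup.get(ch)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no residues")
    return counts / counts.sum()


def binary_gap_model() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spectral pieces of the symmetric 2-state presence/absence chain.

    Returns (eigenvalues, U, U^-1, frequencies) for Q = [[-1, 1], [1, -1]],
    which has mean rate 1 under its uniform stationary distribution — used
    for maximum-likelihood indel reconstruction.
    """
    q = np.array([[-1.0, 1.0], [1.0, -1.0]])
    w, v = np.linalg.eigh(q)
    return w, v, v.T, np.array([0.5, 0.5])
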