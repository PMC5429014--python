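"""Codon (GY94 branch-model) and nucleotide (GTR+Gamma+I) substitution models.

The codon model follows the Goldman-Yang parameterization used by codeml's
branch models: instantaneous change is allowed only between sense codons
differing at a single nucleotide position, with rate

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

where ``omega`` (dN/dS) may differ between foreground and background branch
classes.  The nucleotide model is the general time-reversible model with
discrete-gamma rate heterogeneity plus a proportion of invariant sites.
Both rate matrices are normalized to one expected substitution per unit
branch length at stationarity, so branch lengths are comparable across fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.special import gammaincinv
from scipy.stats import gamma as gamma_dist

from ._codons import (ADJ_DST, ADJ_IS_NONSYN, ADJ_IS_TRANSITION, ADJ_SRC,
                      N_CODONS)

__all__ = [
    "CodonModelParams", "NucModelParams", "codon_rate_matrix",
    "gtr_rate_matrix", "transition_matrix", "discretize_gamma",
    "SpectralQ",
]


def _check_freqs(pi, n, tol=1e-8):
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (n,):
        raise ValueError(f"frequency vector must have length {n}")
    if np.any(pi < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(pi.sum() - 1.0) > tol:
        raise ValueError("frequencies must sum to 1")
    return pi


@dataclass
class CodonModelParams:
    """Parameters of the GY94-style branch codon model.

    ``omega_by_class`` maps branch class (0 = background, 1 = foreground) to
    its dN/dS ratio; a single-entry map gives the one-ratio (null) model.
    """

    kappa: float = 2.0
    omega_by_class: Dict[int, float] = field(
        default_factory=lambda: {0: 0.2})
    pi: np.ndarray = field(
        default_factory=lambda: np.full(N_CODONS, 1.0 / N_CODONS))
    scaled: bool = True

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for k, w in self.omega_by_class.items():
            if w < 0:
                raise ValueError("omega must be >= 0")
        self.pi = _check_freqs(self.pi, N_CODONS)


@dataclass
class NucModelParams:
    """GTR+Gamma+I nucleotide model parameters.

    ``exchangeabilities`` are the six symmetric GTR rates in the order
    (AC, AG, AT, CG, CT, GT); ``alpha`` is the gamma shape, ``p_inv`` the
    invariant-site proportion, ``n_categories`` the number of discrete
    gamma classes.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        if ex.shape != (6,):
            raise ValueError("need 6 GTR exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if np.any(ex < 0):
            raise ValueError("exchangeabilities must be >= 0")
        if not np.any(ex > 0):
            raise ValueError("at least one exchangeability must be positive")
        self.exchangeabilities = ex
        self.pi = _check_freqs(self.pi, 4)
        if not self.alpha > 0:
            raise ValueError("gamma shape alpha must be > 0")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("need at least one gamma category")


def codon_rate_matrix(params: CodonModelParams, omega: float) -> np.ndarray:
    """61x61 GY94 instantaneous rate matrix for one branch class.

    Only single-nucleotide changes have nonzero rate; the target-codon
    stationary frequency multiplies every rate, transitions are scaled by
    kappa and nonsynonymous changes by ``omega``.  If ``params.scaled``, the
    matrix is normalized to unit expected substitutions per codon.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = _check_freqs(params.pi, N_CODONS)
    rates = pi[ADJ_DST].copy()
    rates[ADJ_IS_TRANSITION] *= params.kappa
    rates[ADJ_IS_NONSYN] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[ADJ_SRC, ADJ_DST] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if params.scaled:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate codon rate matrix (zero total rate)")
        Q /= mean_rate
    return Q


_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def gtr_rate_matrix(params: NucModelParams) -> np.ndarray:
    """4x4 GTR rate matrix, normalized to unit mean substitution rate."""
    pi = _check_freqs(params.pi, 4)
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exchangeabilities, _GTR_PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate GTR rate matrix (zero total rate)")
    return Q / mean_rate


class SpectralQ:
    """Spectral decomposition of a reversible rate matrix.

    Uses the similarity transform ``B = D^(1/2) Q D^(-1/2)`` (D = diag(pi)),
    which is symmetric for any time-reversible Q, so transition matrices
    ``P(t) = exp(Qt)`` can be formed from one symmetric eigendecomposition.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("stationary frequencies must be positive "
                             "for spectral decomposition")
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize numerical noise
        w, V = np.linalg.eigh(B)
        self.eigenvalues = w
        self.left = V / sq[:, None]       # D^{-1/2} V
        self.right = V.T * sq[None, :]    # V^T D^{1/2}
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.left * np.exp(self.eigenvalues * t)) @ self.right
        np.clip(P, 0.0, 1.0, out=P)
        return P


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix ``P = exp(Qt)``.

    Small negative entries from round-off are clamped to zero.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    from scipy.linalg import expm

    P = expm(np.asarray(Q, dtype=float) * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability segments of Gamma(alpha, alpha).

    This is the standard discrete-gamma construction: the unit-mean gamma
    density is cut at its 1/k quantiles and each category's rate is the
    conditional mean of its segment, so the category mean is exactly 1.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    # segment boundaries of Gamma(alpha, rate=alpha)
    probs = np.arange(1, k) / k
    cuts = gammaincinv(alpha, probs) / alpha
    bounds = np.concatenate(([0.0], cuts, [np.inf]))
    # mean over a segment: alpha/alpha * [F_{a+1}(b) - F_{a+1}(a)] * k where
    # F_{a+1} is the CDF of Gamma(alpha+1, rate=alpha)
    upper = gamma_dist.cdf(bounds[1:], alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(bounds[:-1], alpha + 1, scale=1.0 / alpha)
    rates = (upper - lower) * k
    return rates / rates.mean()
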