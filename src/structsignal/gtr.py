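"""GTR + discrete-gamma substitution model utilities.

The general time-reversible rate matrix is parameterized by six
exchangeabilities (AC, AG, AT, CG, CT, GT) and stationary base frequencies,
normalized to one expected substitution per unit branch length.  Rate
heterogeneity across sites uses the standard equal-probability discrete
gamma approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import BASES, GAP, IUPAC

#: leaf partial-likelihood vectors for every observed character.
LEAF_PARTIALS = {c: np.array([1.0 if b in IUPAC[c] else 0.0 for b in BASES]) for c in IUPAC}
LEAF_PARTIALS[GAP] = np.ones(4)


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma(alpha, alpha) categories.

    Uses the incomplete-gamma identity so each category mean is exact; the
    rates average to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a<X<b] * P = alpha/alpha * (F_{a+1}(b) - F_{a+1}(a)) for gamma(alpha, 1/alpha)
    upper = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = ncat * (upper - lower)
    return rates / rates.mean()


@dataclass
class GTRModel:
    """Time-reversible nucleotide model with precomputed eigensystem."""

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )  # AC, AG, AT, CG, CT, GT
    frequencies: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (6,) or np.any(s < 0):
            raise ValueError("need 6 non-negative exchangeabilities")
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()
        R = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), sij in zip(pairs, s):
            R[i, j] = R[j, i] = sij
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        self.frequencies = pi
        self.Q = Q
        # symmetrize for a stable eigensystem: B = D^{1/2} Q D^{-1/2}
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        # Q = D^{-1/2} B D^{1/2}  =>  exp(Qt) = D^{-1/2} V e^{wt} V' D^{1/2}
        self._eigval = w
        self._right = V / d[:, None]
        self._left = V.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        return np.clip(P, 0.0, None)


def jc_model() -> GTRModel:
    return GTRModel()
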