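"""Multinomial log-likelihoods of counted family data.

Each family type contributes ``sum_i count_i * log(P_i)`` with the cell
probabilities of :mod:`famlrt.model`.  Because every cell probability is a
monomial over ``R``, the log-likelihood collapses to

    ap*log p + aq*log q + a1*log psi1 + a2*log psi2 + const - n_fam*log R

with the integer coefficients of :func:`famlrt.counts.sufficient_stats`.  The
multinomial coefficient (constant in both data and parameters) is omitted
throughout, so absolute log-likelihood values are comparable only within this
convention; differences (and hence likelihood-ratio statistics) are
unaffected.

Conventions: ``0 * log 0 := 0``, and a strictly positive count on a
zero-probability cell (a relative risk at the zero boundary) yields ``-inf``
rather than an exception, so that optimisers can reject the point.
"""

from __future__ import annotations

import numpy as np

from .counts import (
    DyadCounts,
    FamilyDataset,
    MonadCounts,
    SufficientStats,
    TriadCounts,
    sufficient_stats,
)
from .model import RiskModelParams, normalizer

__all__ = [
    "loglik_triads",
    "loglik_dyads",
    "loglik_monads",
    "loglik_combined",
    "loglik_from_stats",
]


def _xlogy(coeff, value):
    """``coeff * log(value)`` with ``0 * log 0 = 0`` and ``+k * log 0 = -inf``."""
    coeff = np.asarray(coeff, dtype=float)
    value = np.asarray(value, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(coeff == 0.0, 0.0, coeff * np.log(value))
    return out


def loglik_from_stats(stats: SufficientStats, p, psi1, psi2):
    """Log-likelihood evaluated from sufficient statistics (vectorised).

    ``p``, ``psi1``, ``psi2`` may be scalars or arrays broadcastable against
    the statistics arrays.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    r = p * p * psi2 + 2.0 * p * q * psi1 + q * q
    return (
        _xlogy(stats.ap, p)
        + _xlogy(stats.aq, q)
        + _xlogy(stats.a1, psi1)
        + _xlogy(stats.a2, psi2)
        + stats.const
        - stats.n_fam * np.log(r)
    )


def _component_loglik(cells10, cells7, cells3, params: RiskModelParams) -> float:
    from .counts import sufficient_stats_arrays

    stats = sufficient_stats_arrays(cells10, cells7, cells3)
    return float(loglik_from_stats(stats, params.p, params.psi1, params.psi2))


def loglik_triads(counts: TriadCounts, params: RiskModelParams) -> float:
    """Log-likelihood of triad cell counts ``n1..n10``."""
    return _component_loglik(counts.cells, np.zeros(7), np.zeros(3), params)


def loglik_dyads(counts: DyadCounts, params: RiskModelParams) -> float:
    """Log-likelihood of parent-child dyad cell counts ``m1..m7``."""
    return _component_loglik(np.zeros(10), counts.cells, np.zeros(3), params)


def loglik_monads(counts: MonadCounts, params: RiskModelParams) -> float:
    """Log-likelihood of affected-singleton counts ``(s2, s1, s0)``."""
    return _component_loglik(np.zeros(10), np.zeros(7), counts.cells, params)


def loglik_combined(data: FamilyDataset, params: RiskModelParams) -> float:
    """Joint log-likelihood of triads, dyads and monads (their sum)."""
    return float(loglik_from_stats(sufficient_stats(data), params.p, params.psi1, params.psi2))
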