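"""Association tests: five likelihood-ratio tests, the TDT and the combined score test.

The LRT compares the maximised log-likelihood under one of the five
constrained risk models against the null ``psi1 = psi2 = 1``; the statistic
``2*(logL_alt - logL_null)`` is referred to a chi-square distribution with
2 df (Unr) or 1 df (Dom, Rec, Mult, Add).

The transmission disequilibrium test uses only the heterozygous-parent
transmissions counted from triads, ``TDT = (b - c)^2 / (b + c)`` with

    b = n2 + 2*n5 + n6 + n8   (risk alleles transmitted)
    c = n3 + n6 + 2*n7 + n9   (risk alleles untransmitted)

and the combined score test adds the dyad analogues ``b1 = m2 + m5`` and
``c1 = m3 + m6``:

    z_com = (W - A_com) / sqrt(V_com),
    W = b + b1,  A_com = (b+c)/2 + (b1+c1)/2,  V_com = (b+c)/4 + (b1+c1)/4,

referred two-sided to the standard normal.  With no dyads, ``z_com**2``
equals the TDT statistic exactly, so the two-sided z decision reduces to the
TDT chi-square decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .counts import DyadCounts, FamilyDataset, TriadCounts
from .estimate import FitResult, RiskModel, mle_alternative, mle_null

__all__ = [
    "TestResult",
    "TransmissionCounts",
    "UndefinedTestError",
    "lrt",
    "tdt",
    "zcom",
    "transmission_counts",
]

# A negative LRT larger than this (in magnitude) indicates optimiser failure
# rather than roundoff, and is raised instead of clamped.
_LRT_CLAMP_TOL = 1e-8


class UndefinedTestError(ValueError):
    """The test statistic is undefined (no informative transmissions)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test."""

    test: str
    statistic: float
    df: "int | None"  # None marks a standard-normal reference (z_com)
    p_value: float
    null_fit: "FitResult | None" = None
    alt_fit: "FitResult | None" = None


@dataclass(frozen=True)
class TransmissionCounts:
    """Transmitted/untransmitted risk-allele counts and score components."""

    b: int
    c: int
    b1: int
    c1: int

    @property
    def w(self) -> float:
        return float(self.b + self.b1)

    @property
    def a_com(self) -> float:
        return (self.b + self.c) / 2.0 + (self.b1 + self.c1) / 2.0

    @property
    def v_com(self) -> float:
        return (self.b + self.c) / 4.0 + (self.b1 + self.c1) / 4.0


def transmission_counts(triads: TriadCounts, dyads: DyadCounts | None = None) -> TransmissionCounts:
    """Tabulate heterozygous-parent transmissions from triad and dyad cells."""
    b, c = _triad_bc(triads.cells)
    if dyads is None:
        b1 = c1 = 0
    else:
        b1, c1 = _dyad_bc(dyads.cells)
    return TransmissionCounts(b=int(b), c=int(c), b1=int(b1), c1=int(c1))


def _triad_bc(cells):
    cells = np.asarray(cells)
    n = cells.T  # allow stacked (B, 10) input
    b = n[1] + 2 * n[4] + n[5] + n[7]
    c = n[2] + n[5] + 2 * n[6] + n[8]
    return b, c


def _dyad_bc(cells):
    cells = np.asarray(cells)
    m = cells.T
    return m[1] + m[4], m[2] + m[5]


def lrt(data: FamilyDataset, model: "RiskModel | str") -> TestResult:
    """Likelihood-ratio test of association under one constrained risk model."""
    model = RiskModel.parse(model)
    null_fit = mle_null(data)
    alt_fit = mle_alternative(data, model)
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -_LRT_CLAMP_TOL:
        raise RuntimeError(
            f"{model.value} LRT is negative ({stat:.3g}): the constrained "
            "optimiser failed to reach the null's likelihood"
        )
    stat = max(stat, 0.0)
    return TestResult(
        test=model.value,
        statistic=stat,
        df=model.df,
        p_value=float(sps.chi2.sf(stat, model.df)),
        null_fit=null_fit,
        alt_fit=alt_fit,
    )


def tdt(counts: TriadCounts) -> TestResult:
    """Transmission disequilibrium test from triad counts."""
    b, c = _triad_bc(counts.cells)
    if b + c == 0:
        raise UndefinedTestError("TDT undefined: no informative transmissions (b + c = 0)")
    stat = float((b - c) ** 2 / (b + c))
    return TestResult(test="TDT", statistic=stat, df=1, p_value=float(sps.chi2.sf(stat, 1)))


def zcom(triads: TriadCounts, dyads: DyadCounts) -> TestResult:
    """Combined score test of triad plus dyad transmissions (two-sided normal)."""
    tc = transmission_counts(triads, dyads)
    if tc.v_com <= 0:
        raise UndefinedTestError("z_com undefined: no informative transmissions (V_com = 0)")
    z = (tc.w - tc.a_com) / np.sqrt(tc.v_com)
    return TestResult(
        test="zcom",
        statistic=float(z),
        df=None,
        p_value=float(2.0 * sps.norm.sf(abs(z))),
    )
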