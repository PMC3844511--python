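"""Conditional genotype probabilities for case-ascertained nuclear families.

The sampling unit is a family ascertained through an affected child at a
di-allelic locus with risk allele ``A`` (frequency ``p``) and alternative
allele ``a`` (frequency ``q = 1 - p``).  Penetrances enter only through the
genotype relative risks ``psi1 = f1/f0`` and ``psi2 = f2/f0`` for one and two
copies of ``A``.  Assuming Hardy-Weinberg equilibrium and random mating in the
parental generation, conditioning on the child's affection status yields
closed-form cell probabilities for

* **triads** (both parents genotyped): 10 cells indexed by the unordered
  parental mating type and the child genotype,
* **parent-child dyads** (one parent genotyped, either sex): 7 cells,
* **monads** (affected singletons): the 3 child genotypes,

each normalised by ``R = p^2 psi2 + 2 p q psi1 + q^2``, the marginal
disease-probability factor induced by the ascertainment.

Every cell probability has the monomial form
``k * p^a * q^b * psi1^c * psi2^d / R``; the exponent tables below are shared
with the log-likelihood and estimation code, where the same integers appear as
the coefficients of ``log p``, ``log q``, ``log psi1`` and ``log psi2``.

Cell order is part of the public contract:

* triad cells 1..10: (AAxAA, AA), (AAxAa, AA), (AAxAa, Aa), (AAxaa, Aa),
  (AaxAa, AA), (AaxAa, Aa), (AaxAa, aa), (Aaxaa, Aa), (Aaxaa, aa),
  (aaxaa, aa);
* dyad cells 1..7: parent AA with child AA, Aa; parent Aa with child AA, Aa,
  aa; parent aa with child Aa, aa;
* monad cells: child AA, Aa, aa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RiskModelParams",
    "ParameterDomainError",
    "normalizer",
    "triad_probabilities",
    "dyad_probabilities",
    "dyad_probabilities_complex",
    "monad_probabilities",
    "schaid_sommer_unordered_probability",
]


class ParameterDomainError(ValueError):
    """Raised when (p, psi1, psi2) lies outside the admissible domain."""


@dataclass(frozen=True)
class RiskModelParams:
    """Allele frequency and genotype relative risks.

    Parameters
    ----------
    p : float
        Frequency of the risk allele ``A``; must lie strictly in (0, 1).
    psi1, psi2 : float
        Relative risks ``f1/f0`` and ``f2/f0``; must be >= 0.  Zero is an
        admissible boundary (it arises during constrained optimisation).
    """

    p: float
    psi1: float
    psi2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0) or not np.isfinite(self.p):
            raise ParameterDomainError(f"allele frequency p={self.p} must be in (0, 1)")
        for name, value in (("psi1", self.psi1), ("psi2", self.psi2)):
            if value < 0.0 or not np.isfinite(value):
                raise ParameterDomainError(f"relative risk {name}={value} must be >= 0 and finite")

    @property
    def q(self) -> float:
        """Frequency of the non-risk allele, ``1 - p``."""
        return 1.0 - self.p


# Exponents of p, q, psi1, psi2 and the leading integer multiplicity for each
# cell probability k * p^a q^b psi1^c psi2^d / R, in the fixed cell order.
TRIAD_P_EXP = np.array([4, 3, 3, 2, 2, 2, 2, 1, 1, 0])
TRIAD_Q_EXP = np.array([0, 1, 1, 2, 2, 2, 2, 3, 3, 4])
TRIAD_PSI1_EXP = np.array([0, 0, 1, 1, 0, 1, 0, 1, 0, 0])
TRIAD_PSI2_EXP = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0, 0])
TRIAD_MULT = np.array([1, 2, 2, 2, 1, 2, 1, 2, 2, 1])

DYAD_P_EXP = np.array([3, 2, 2, 1, 1, 1, 0])
DYAD_Q_EXP = np.array([0, 1, 1, 1, 2, 2, 3])
DYAD_PSI1_EXP = np.array([0, 1, 0, 1, 0, 1, 0])
DYAD_PSI2_EXP = np.array([1, 0, 1, 0, 0, 0, 0])
DYAD_MULT = np.array([1, 1, 1, 1, 1, 1, 1])

MONAD_P_EXP = np.array([2, 1, 0])
MONAD_Q_EXP = np.array([0, 1, 2])
MONAD_PSI1_EXP = np.array([0, 1, 0])
MONAD_PSI2_EXP = np.array([1, 0, 0])
MONAD_MULT = np.array([1, 2, 1])


def normalizer(params: RiskModelParams) -> float:
    """Return ``R = p^2 psi2 + 2 p q psi1 + q^2``.

    ``R`` is proportional to the marginal probability of disease and is
    strictly positive on the admissible domain (``q > 0`` guarantees the
    ``q^2`` term).
    """
    p, q = params.p, params.q
    return p * p * params.psi2 + 2.0 * p * q * params.psi1 + q * q


def _cell_probs(params, p_exp, q_exp, c1_exp, c2_exp, mult):
    p, q = params.p, params.q
    num = (
        mult
        * p**p_exp
        * q**q_exp
        * float(params.psi1) ** c1_exp
        * float(params.psi2) ** c2_exp
    )
    return num / normalizer(params)


def triad_probabilities(params: RiskModelParams) -> np.ndarray:
    """Probabilities of the 10 (mating type, child genotype) triad cells.

    The vector sums to one: the cells partition the triad sample space under
    ascertainment through the affected child.
    """
    return _cell_probs(params, TRIAD_P_EXP, TRIAD_Q_EXP, TRIAD_PSI1_EXP, TRIAD_PSI2_EXP, TRIAD_MULT)


def dyad_probabilities(params: RiskModelParams) -> np.ndarray:
    """Probabilities of the 7 (parent genotype, child genotype) dyad cells.

    The dyad model is parent-sex-agnostic: the genotyped parent may be either
    the mother or the father.  The simplified monomial form used here is
    algebraically identical to summing the ordered triad probabilities over
    the missing parent (see :func:`dyad_probabilities_complex`).
    """
    return _cell_probs(params, DYAD_P_EXP, DYAD_Q_EXP, DYAD_PSI1_EXP, DYAD_PSI2_EXP, DYAD_MULT)


def dyad_probabilities_complex(params: RiskModelParams) -> np.ndarray:
    """Dyad cell probabilities obtained by summing over the missing parent.

    Each cell is assembled term by term from the ordered triad probabilities
    (an unordered mating-type probability is halved when the two parental
    genotypes differ, because exactly one of the two orderings matches the
    observed parent).  Kept as an independent route for cross-checking the
    simplified closed form; the two agree to machine precision.
    """
    t = triad_probabilities(params)
    return np.array(
        [
            t[0] + t[1] / 2.0,          # parent AA, child AA: partner AA or Aa
            t[2] / 2.0 + t[3] / 2.0,    # parent AA, child Aa: partner Aa or aa
            t[1] / 2.0 + t[4],          # parent Aa, child AA
            t[2] / 2.0 + t[5] + t[7] / 2.0,  # parent Aa, child Aa
            t[6] + t[8] / 2.0,          # parent Aa, child aa
            t[3] / 2.0 + t[7] / 2.0,    # parent aa, child Aa
            t[8] / 2.0 + t[9],          # parent aa, child aa
        ]
    )


def monad_probabilities(params: RiskModelParams) -> np.ndarray:
    """Probabilities of the affected-singleton genotypes (AA, Aa, aa).

    ``(p^2 psi2, 2 p q psi1, q^2) / R`` — Hardy-Weinberg frequencies tilted by
    the relative risks and renormalised.
    """
    return _cell_probs(params, MONAD_P_EXP, MONAD_Q_EXP, MONAD_PSI1_EXP, MONAD_PSI2_EXP, MONAD_MULT)


def schaid_sommer_unordered_probability(params: RiskModelParams) -> float:
    """Unordered probability that "a case is AA and one parent is Aa, the other missing".

    Classical case-parent computation that does not specify *which* parent is
    observed; it exceeds the ordered dyad cell (parent Aa, child AA) by
    exactly ``p^3 q psi2 / R``.  Provided as a documented cross-check only —
    the dyad likelihood in this package uses the ordered form, since real
    dyad records always identify the genotyped parent.
    """
    p, q = params.p, params.q
    return (p * p * q + p**3 * q) * params.psi2 / normalizer(params)
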