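"""Observed multinomial cell counts for triads, dyads and monads."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import model

__all__ = ["TriadCounts", "DyadCounts", "MonadCounts", "FamilyDataset", "SufficientStats"]


def _as_count_array(values: Iterable[int], size: int, what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=np.int64)
    if arr.shape != (size,):
        raise ValueError(f"{what} requires exactly {size} cells, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"{what} cells must be nonnegative, got {arr.tolist()}")
    return arr


@dataclass(frozen=True)
class TriadCounts:
    """Counts ``n1..n10`` of the 10 triad cells (fixed cell order).

    ``n1..n10`` index the (unordered mating type, child genotype) combinations
    in the order documented in :mod:`famlrt.model`.
    """

    cells: np.ndarray

    def __init__(self, cells: Iterable[int] = (0,) * 10):
        object.__setattr__(self, "cells", _as_count_array(cells, 10, "TriadCounts"))

    @property
    def n(self) -> int:
        return int(self.cells.sum())

    @classmethod
    def zeros(cls) -> "TriadCounts":
        return cls()


@dataclass(frozen=True)
class DyadCounts:
    """Counts ``m1..m7`` of the 7 parent-child dyad cells (fixed cell order)."""

    cells: np.ndarray

    def __init__(self, cells: Iterable[int] = (0,) * 7):
        object.__setattr__(self, "cells", _as_count_array(cells, 7, "DyadCounts"))

    @property
    def m(self) -> int:
        return int(self.cells.sum())

    @classmethod
    def zeros(cls) -> "DyadCounts":
        return cls()


@dataclass(frozen=True)
class MonadCounts:
    """Counts of affected singletons by genotype: ``s2`` (AA), ``s1`` (Aa), ``s0`` (aa)."""

    cells: np.ndarray

    def __init__(self, s2: int = 0, s1: int = 0, s0: int = 0):
        object.__setattr__(self, "cells", _as_count_array((s2, s1, s0), 3, "MonadCounts"))

    @property
    def s2(self) -> int:
        return int(self.cells[0])

    @property
    def s1(self) -> int:
        return int(self.cells[1])

    @property
    def s0(self) -> int:
        return int(self.cells[2])

    @property
    def s(self) -> int:
        return int(self.cells.sum())

    @classmethod
    def zeros(cls) -> "MonadCounts":
        return cls()


@dataclass(frozen=True)
class FamilyDataset:
    """A combined sample of triads, parent-child dyads and affected monads."""

    triads: TriadCounts = field(default_factory=TriadCounts.zeros)
    dyads: DyadCounts = field(default_factory=DyadCounts.zeros)
    monads: MonadCounts = field(default_factory=MonadCounts.zeros)

    @property
    def n_families(self) -> int:
        return self.triads.n + self.dyads.m + self.monads.s

    def subset(self, data_used: str) -> "FamilyDataset":
        """Restrict to ``"FT"`` (full triads), ``"FT+PD"`` or ``"FT+PD+AM"``."""
        key = data_used.upper().replace(" ", "")
        if key == "FT":
            return FamilyDataset(triads=self.triads)
        if key == "FT+PD":
            return FamilyDataset(triads=self.triads, dyads=self.dyads)
        if key == "FT+PD+AM":
            return self
        raise ValueError(f"unknown data subset {data_used!r}; expected FT, FT+PD or FT+PD+AM")


@dataclass(frozen=True)
class SufficientStats:
    """Linear summaries of counts that the log-likelihood depends on.

    The combined log-likelihood is
    ``ap*log p + aq*log q + a1*log psi1 + a2*log psi2 + const - n_fam*log R``,
    so each coefficient is the corresponding exponent summed over all counted
    cells.  ``const`` collects the parameter-free ``count * log(multiplicity)``
    terms, and ``n_fam`` is the total number of families.  Arrays are allowed
    so that many replicate datasets can be summarised and fitted at once.
    """

    ap: np.ndarray
    aq: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    n_fam: np.ndarray
    const: np.ndarray


_LOG_TRIAD_MULT = np.log(model.TRIAD_MULT.astype(float))
_LOG_DYAD_MULT = np.log(model.DYAD_MULT.astype(float))
_LOG_MONAD_MULT = np.log(model.MONAD_MULT.astype(float))


def sufficient_stats_arrays(
    triads: np.ndarray, dyads: np.ndarray, monads: np.ndarray
) -> SufficientStats:
    """Sufficient statistics for stacked count arrays.

    Parameters are arrays whose last axis has length 10, 7 and 3 respectively;
    leading axes index replicate datasets.
    """
    t = np.asarray(triads, dtype=float)
    d = np.asarray(dyads, dtype=float)
    mo = np.asarray(monads, dtype=float)
    return SufficientStats(
        ap=t @ model.TRIAD_P_EXP + d @ model.DYAD_P_EXP + mo @ model.MONAD_P_EXP,
        aq=t @ model.TRIAD_Q_EXP + d @ model.DYAD_Q_EXP + mo @ model.MONAD_Q_EXP,
        a1=t @ model.TRIAD_PSI1_EXP + d @ model.DYAD_PSI1_EXP + mo @ model.MONAD_PSI1_EXP,
        a2=t @ model.TRIAD_PSI2_EXP + d @ model.DYAD_PSI2_EXP + mo @ model.MONAD_PSI2_EXP,
        n_fam=t.sum(axis=-1) + d.sum(axis=-1) + mo.sum(axis=-1),
        const=t @ _LOG_TRIAD_MULT + d @ _LOG_DYAD_MULT + mo @ _LOG_MONAD_MULT,
    )


def sufficient_stats(data: FamilyDataset) -> SufficientStats:
    """Sufficient statistics of a single :class:`FamilyDataset`."""
    return sufficient_stats_arrays(data.triads.cells, data.dyads.cells, data.monads.cells)
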