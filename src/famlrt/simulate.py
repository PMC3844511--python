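"""Multinomial replicate engine for type-I-error and power studies.

A study configuration fixes the generating parameters ``(p, psi1, psi2)`` and
the family-type sample sizes ``n`` (triads), ``m`` (dyads) and ``s``
(monads).  Each replicate draws the three count vectors from independent
multinomials with the cell probabilities of :mod:`famlrt.model`, evaluates the
requested test statistics, and compares them with their reference-distribution
critical values at each nominal level.  Rejection proportions over replicates
estimate the type I error rate (under ``psi1 = psi2 = 1``) or the power.

Replicates whose statistic is undefined or whose optimiser fails are counted
and reported separately; they enter neither the numerator nor the denominator
of a rejection proportion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import _dyad_bc, _triad_bc
from .counts import DyadCounts, FamilyDataset, MonadCounts, TriadCounts, sufficient_stats_arrays
from .estimate import RiskModel, fit_many, null_fit_many
from .model import (
    RiskModelParams,
    dyad_probabilities,
    monad_probabilities,
    triad_probabilities,
)

__all__ = ["SimConfig", "StudyResult", "simulate_dataset", "run_study", "DEFAULT_STATISTICS"]

DEFAULT_STATISTICS = ("Unr", "Dom", "Rec", "Mult", "Add", "TDT", "zcom")


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters and sample sizes for one simulation study."""

    params: RiskModelParams
    n: int = 0
    m: int = 0
    s: int = 0
    replicates: int = 10_000
    seed: int = 0
    alpha_levels: tuple = (0.05, 0.01)

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.s) < 0 or self.n + self.m + self.s <= 0:
            raise ValueError("sample sizes n, m, s must be nonnegative with n + m + s > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build from a flat key-value mapping (p, psi1, psi2, n, m, s, ...)."""
        d = dict(d)
        params = RiskModelParams(
            p=float(d.pop("p")), psi1=float(d.pop("psi1")), psi2=float(d.pop("psi2"))
        )
        if "alpha_levels" in d:
            d["alpha_levels"] = tuple(float(a) for a in d["alpha_levels"])
        return cls(params=params, **{k: int(v) if k != "alpha_levels" else v for k, v in d.items()})


@dataclass(frozen=True)
class StudyResult:
    """Rejection proportions per (statistic, nominal level) with MC errors."""

    config: SimConfig
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per statistic x nominal level."""
        frame = pd.DataFrame(self.rows)
        cfg = self.config
        frame.insert(0, "p", cfg.params.p)
        frame.insert(1, "psi1", cfg.params.psi1)
        frame.insert(2, "psi2", cfg.params.psi2)
        frame.insert(3, "n", cfg.n)
        frame.insert(4, "m", cfg.m)
        frame.insert(5, "s", cfg.s)
        frame.insert(6, "replicates", cfg.replicates)
        frame.insert(7, "seed", cfg.seed)
        return frame

    def proportion(self, statistic: str, alpha: float) -> float:
        """Rejection proportion of one statistic at one nominal level."""
        for row in self.rows:
            if row["statistic"].lower() == statistic.lower() and row["alpha"] == alpha:
                return row["proportion"]
        raise KeyError(f"no result for statistic={statistic!r} at alpha={alpha}")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_frame().to_dict(orient="records"), handle, indent=1)


def _simulate_count_arrays(config: SimConfig, rng: np.random.Generator, size: int):
    """Draw ``size`` independent (triad, dyad, monad) count-vector replicates."""
    params = config.params
    triads = rng.multinomial(config.n, triad_probabilities(params), size=size)
    dyads = rng.multinomial(config.m, dyad_probabilities(params), size=size)
    monads = rng.multinomial(config.s, monad_probabilities(params), size=size)
    return triads, dyads, monads


def simulate_dataset(config: SimConfig, rng: "np.random.Generator | int | None" = None) -> FamilyDataset:
    """Draw one FamilyDataset; totals are exactly (n, m, s).

    ``rng`` may be a Generator (for a shared stream), an integer seed, or
    None to seed from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    t, d, m = _simulate_count_arrays(config, rng, size=1)
    return FamilyDataset(
        triads=TriadCounts(t[0]),
        dyads=DyadCounts(d[0]),
        monads=MonadCounts(*m[0]),
    )


def _evaluate_statistic(name, stats, l0, valid, triads, dyads):
    """Per-replicate statistic values, validity mask and reference critical values."""
    key = name.strip().lower()
    if key == "tdt":
        b, c = _triad_bc(triads)
        ok = (b + c) > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(ok, (b - c) ** 2 / np.maximum(b + c, 1), np.nan)
        return stat.astype(float), ok, ("chi2", 1)
    if key == "zcom":
        b, c = _triad_bc(triads)
        b1, c1 = _dyad_bc(dyads)
        v = (b + c) / 4.0 + (b1 + c1) / 4.0
        ok = v > 0
        w = b + b1
        a_com = (b + c) / 2.0 + (b1 + c1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(ok, (w - a_com) / np.sqrt(np.maximum(v, 1e-300)), np.nan)
        return stat.astype(float), ok, ("normal", None)
    model = RiskModel.parse(name)
    fit = fit_many(stats, model)
    stat = 2.0 * (fit["loglik"] - l0)
    # Boundary solutions (a risk parameter estimable only in the limit
    # psi -> 0 or inf) are counted as estimation failures: the prescribed
    # Newton-Raphson has no interior optimum there and the chi-square
    # reference does not apply.
    ok = valid & fit["converged"] & ~fit["boundary"] & (stat > -1e-8)
    stat = np.clip(stat, 0.0, None)
    return stat, ok, ("chi2", model.df)


def run_study(
    config: SimConfig,
    statistics=DEFAULT_STATISTICS,
    strict: bool = False,
) -> StudyResult:
    """Simulate ``config.replicates`` datasets and tabulate rejection proportions.

    Parameters
    ----------
    statistics : iterable of str
        Any of ``Unr, Dom, Rec, Mult, Add`` (LRTs), ``TDT`` and ``zcom``.
    strict : bool
        Escalate the >1% failure-rate warning to an error.

    Identical ``config`` (including seed) always yields an identical result.
    """
    rng = np.random.default_rng(config.seed)
    triads, dyads, monads = _simulate_count_arrays(config, rng, config.replicates)
    stats = sufficient_stats_arrays(triads, dyads, monads)
    _, l0, valid = null_fit_many(stats)

    rows = []
    for name in statistics:
        stat, ok, (ref, df) = _evaluate_statistic(name, stats, l0, valid, triads, dyads)
        n_failed = int((~ok).sum())
        n_eff = int(ok.sum())
        if n_failed > 0.01 * config.replicates:
            message = (
                f"{name}: {n_failed}/{config.replicates} replicates failed "
                "(degenerate data or non-convergence)"
            )
            if strict:
                raise RuntimeError(message)
            warnings.warn(message, stacklevel=2)
        for alpha in config.alpha_levels:
            if ref == "chi2":
                reject = ok & (stat >= sps.chi2.isf(alpha, df))
            else:  # two-sided standard normal
                reject = ok & (np.abs(stat) >= sps.norm.isf(alpha / 2.0))
            n_reject = int(reject.sum())
            prop = n_reject / n_eff if n_eff else np.nan
            rows.append(
                {
                    "statistic": name if name.lower() != "zcom" else "zcom",
                    "alpha": alpha,
                    "n_reject": n_reject,
                    "n_failed": n_failed,
                    "n_effective": n_eff,
                    "proportion": prop,
                    "mc_se": float(np.sqrt(prop * (1.0 - prop) / n_eff)) if n_eff else np.nan,
                }
            )
    return StudyResult(config=config, rows=rows)
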