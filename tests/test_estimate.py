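"""MLE correctness: closed-form null, constrained fits vs brute-force grids, nesting."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from famlrt import (
    DegenerateDataError,
    FamilyDataset,
    MonadCounts,
    RiskModelParams,
    TriadCounts,
    loglik_combined,
    mle_alternative,
    mle_null,
)
from famlrt.counts import sufficient_stats
from famlrt.likelihood import loglik_from_stats

from conftest import random_dataset

ALL_MODELS = ["Unr", "Dom", "Rec", "Mult", "Add"]

# grid coordinate -> (psi1, psi2) for the oracle; Add uses log(psi1 - 1/2) so
# the narrow basin above its admissibility bound is resolvable on a grid
_CONSTRAINTS = {
    "Dom": lambda v: (np.exp(v), np.exp(v)),
    "Rec": lambda v: (np.ones_like(v), np.exp(v)),
    "Mult": lambda v: (np.exp(v), np.exp(2 * v)),
    "Add": lambda v: (0.5 + np.exp(v), 2.0 * np.exp(v)),
}


def _grid_best_loglik(data, model, rounds=6, pts=25):
    """Coarse-to-fine grid maximisation of the combined log-likelihood."""
    stats = sufficient_stats(data)

    def ll(p, psi1, psi2):
        return loglik_from_stats(stats, p, psi1, psi2)

    if model == "Unr":
        centers = np.array([0.0, 0.0, 0.0])  # (logit p, log psi1, log psi2)
        spans = np.array([5.0, 5.0, 5.0])
        pts = 13
        for _ in range(rounds + 2):
            axes = [c + np.linspace(-s, s, pts) for c, s in zip(centers, spans)]
            g = np.meshgrid(*axes, indexing="ij")
            vals = ll(1 / (1 + np.exp(-g[0])), np.exp(g[1]), np.exp(g[2]))
            best = np.unravel_index(np.argmax(vals), vals.shape)
            centers = np.array([axes[d][best[d]] for d in range(3)])
            spans = spans * (2.0 / (pts - 1)) * 2
        return float(vals[best])

    to_psi = _CONSTRAINTS[model]
    centers = np.array([0.0, -3.0 if model == "Add" else 0.0])
    spans = np.array([5.0, 9.0 if model == "Add" else 5.0])
    for _ in range(rounds):
        ax_a = centers[0] + np.linspace(-spans[0], spans[0], pts)
        ax_v = centers[1] + np.linspace(-spans[1], spans[1], pts)
        psi1, psi2 = to_psi(ax_v)
        vals = ll(1 / (1 + np.exp(-ax_a))[:, None], psi1[None, :], psi2[None, :])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        centers = np.array([ax_a[i], ax_v[j]])
        spans = spans * (2.0 / (pts - 1)) * 2
    return float(vals[i, j])


def test_null_mle_closed_form_on_symmetric_fixture(null_dataset):
    fit = mle_null(null_dataset)
    assert fit.p_hat == pytest.approx(0.5, abs=1e-15)  # 32 A / 64 alleles
    assert fit.loglik == pytest.approx(
        loglik_combined(null_dataset, RiskModelParams(0.5, 1, 1)), abs=1e-12
    )


def test_null_mle_degenerate_data_raises():
    with pytest.raises(DegenerateDataError):
        mle_null(FamilyDataset(monads=MonadCounts(4, 0, 0)))  # no 'a' alleles
    with pytest.raises(DegenerateDataError):
        mle_null(FamilyDataset(monads=MonadCounts(0, 0, 7)))  # no 'A' alleles


def test_null_mle_matches_numeric_1d_maximiser():
    rng = np.random.default_rng(42)
    for _ in range(10):
        data = random_dataset(rng)
        fit = mle_null(data)
        res = minimize_scalar(
            lambda p: -loglik_combined(data, RiskModelParams(p, 1, 1)),
            bounds=(1e-6, 1 - 1e-6),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.p_hat == pytest.approx(res.x, abs=1e-8)
        assert fit.loglik >= -res.fun - 1e-10


@pytest.mark.parametrize("model", ALL_MODELS)
def test_exact_null_data_fit_at_null(null_dataset, model):
    """Counts exactly proportional to null probabilities => MLE is the null point."""
    fit = mle_alternative(null_dataset, model)
    null = mle_null(null_dataset)
    assert fit.p_hat == pytest.approx(0.5, abs=1e-7)
    assert fit.psi1_hat == pytest.approx(1.0, abs=1e-6)
    assert fit.psi2_hat == pytest.approx(1.0, abs=1e-6)
    assert fit.loglik == pytest.approx(null.loglik, abs=1e-10)


@pytest.mark.parametrize("model", ALL_MODELS)
def test_constraints_hold_exactly(model):
    rng = np.random.default_rng(5)
    for _ in range(5):
        data = random_dataset(rng)
        fit = mle_alternative(data, model)
        if model == "Dom":
            assert fit.psi2_hat == fit.psi1_hat
        elif model == "Rec":
            assert fit.psi1_hat == 1.0
        elif model == "Mult":
            assert fit.psi2_hat == fit.psi1_hat**2
        elif model == "Add":
            assert fit.psi2_hat == 2 * fit.psi1_hat - 1
        # attained value never below the null's
        assert fit.loglik >= mle_null(data).loglik - 1e-9


def test_nesting_of_maximised_likelihoods():
    rng = np.random.default_rng(6)
    for _ in range(8):
        data = random_dataset(rng, n=40, m=20, s=10)
        null = mle_null(data)
        fits = {m: mle_alternative(data, m) for m in ALL_MODELS}
        for m in ["Dom", "Rec", "Mult", "Add"]:
            assert fits["Unr"].loglik >= fits[m].loglik - 1e-9
            assert fits[m].loglik >= null.loglik - 1e-9


@pytest.mark.parametrize("model", ALL_MODELS)
def test_newton_fit_matches_grid_oracle(model):
    rng = np.random.default_rng(17)
    for _ in range(4):
        data = random_dataset(rng, n=30, m=15, s=10)
        fit = mle_alternative(data, model)
        grid = _grid_best_loglik(data, model)
        assert fit.loglik >= grid - 1e-6
        if not fit.boundary:  # a bounded grid cannot follow a boundary supremum
            assert abs(fit.loglik - grid) < 1e-4


def test_boundary_flag_when_risk_class_unobserved():
    """No AA case anywhere => psi2 is maximised only in the limit psi2 -> 0."""
    data = FamilyDataset(
        triads=TriadCounts([0, 0, 3, 2, 0, 4, 2, 3, 4, 6]),
        monads=MonadCounts(0, 5, 9),
    )
    fit = mle_alternative(data, "Rec")
    assert fit.boundary
    assert fit.psi2_hat < 1e-5
    assert np.isfinite(fit.loglik)


def test_fit_result_diagnostics_populated():
    rng = np.random.default_rng(23)
    data = random_dataset(rng)
    fit = mle_alternative(data, "Unr")
    assert fit.converged
    assert fit.iterations >= 1
    assert 0.0 < fit.p_hat < 1.0
    assert fit.model == "Unr"
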