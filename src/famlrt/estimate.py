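"""Maximum-likelihood estimation of (p, psi1, psi2) under constrained risk models.

Five alternatives to the no-association null ``psi1 = psi2 = 1`` are
supported, each named for the mode of inheritance it encodes:

=========  ======================  ==============
model      constraint              free risk df
=========  ======================  ==============
Unr        psi1, psi2 free         2
Dom        psi2 = psi1             1
Rec        psi1 = 1, psi2 free     1
Mult       psi2 = psi1**2          1
Add        psi2 = 2*psi1 - 1       1
=========  ======================  ==============

The log-likelihood depends on the data only through the sufficient statistics
``(ap, aq, a1, a2, n_fam)`` of :mod:`famlrt.counts`, so estimation over many
replicate datasets is vectorised: a damped Newton ascent with analytic
gradient and Hessian runs simultaneously on whole arrays of statistics
(:func:`fit_many`), which is what makes 100,000-replicate simulation studies
cheap.

Parameterisation.  The ascent runs over ``a = logit(p)`` and a log-scale risk
parameter, which enforces ``0 < p < 1`` and ``psi > 0`` without explicit
bounds.  For the additive model the induced admissibility bound
``psi1 >= 1/2`` (so that ``psi2 = 2*psi1 - 1 >= 0``) is enforced via
``psi1 = 1/2 + exp(theta)``.  Writing ``w = (q^2, 2pq*psi1, p^2*psi2)`` for
the unnormalised case-genotype weights and ``u = w / R``, the derivatives of
``log R`` take a multinomial-logistic form (``u`` is a softmax over the log
weights), which gives the compact expressions used below.

Under the null, ``R = 1`` and the likelihood is Binomial in the allele counts,
so ``p_hat = ap / (ap + aq)`` in closed form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .counts import FamilyDataset, SufficientStats, sufficient_stats
from .likelihood import loglik_combined

__all__ = [
    "RiskModel",
    "FitResult",
    "DegenerateDataError",
    "NonConvergenceError",
    "mle_null",
    "mle_alternative",
    "fit_many",
    "null_fit_many",
]

_T_MAX = 25.0  # clamp on log-scale risk parameters; exp(+-25) spans any realistic psi
_A_MAX = 16.0  # clamp on logit(p)
# A free risk parameter beyond exp(+-12) marks a boundary solution: when a
# risk-carrying cell class is unobserved the likelihood is maximised only in
# the limit psi -> 0 (or infinity), where a Newton-Raphson ascent has no
# interior stationary point.  Interior MLEs never come close to this range at
# realistic sample sizes (with at least one observation in the class,
# psi_hat >= R / (n_fam * p^2) up to small factors).
_B_THRESH = 12.0


class DegenerateDataError(ValueError):
    """The data contain no copies of one allele; p would be estimated at 0 or 1."""


class NonConvergenceError(RuntimeError):
    """Optimiser failed to converge; carries the best point found."""

    def __init__(self, message: str, best: "FitResult"):
        super().__init__(message)
        self.best = best


class RiskModel(enum.Enum):
    """The five alternative hypotheses about (psi1, psi2)."""

    UNR = "Unr"
    DOM = "Dom"
    REC = "Rec"
    MULT = "Mult"
    ADD = "Add"

    @property
    def df(self) -> int:
        """Degrees of freedom of the LRT against the null."""
        return 2 if self is RiskModel.UNR else 1

    @property
    def n_risk_params(self) -> int:
        return 2 if self is RiskModel.UNR else 1

    @classmethod
    def parse(cls, name: "str | RiskModel") -> "RiskModel":
        if isinstance(name, cls):
            return name
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown risk model {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class FitResult:
    """Constrained MLE with convergence diagnostics."""

    model: str
    p_hat: float
    psi1_hat: float
    psi2_hat: float
    loglik: float
    converged: bool
    iterations: int
    boundary: bool


# --- model maps: theta (free risk params) -> (t1, t2) = (log psi1, log psi2) ---
# Each entry: (k, theta_at_null, to_t, jacobian, hessian_correction).
# For all but Add the map is linear, so the correction vanishes.


def _map_t(model: RiskModel, theta: np.ndarray):
    """Map free parameters to (t1, t2); theta has shape (B, k)."""
    if model is RiskModel.UNR:
        return theta[:, 0], theta[:, 1]
    th = theta[:, 0]
    if model is RiskModel.DOM:
        return th, th
    if model is RiskModel.REC:
        return np.zeros_like(th), th
    if model is RiskModel.MULT:
        return th, 2.0 * th
    # Add: psi1 = 1/2 + exp(theta), psi2 = 2*exp(theta)
    psi1 = 0.5 + np.exp(th)
    return np.log(psi1), np.log(2.0) + th


def _map_jacobian(model: RiskModel, theta: np.ndarray) -> np.ndarray:
    """d(t1, t2)/d(theta), shape (B, 2, k)."""
    b = theta.shape[0]
    if model is RiskModel.UNR:
        return np.broadcast_to(np.eye(2), (b, 2, 2)).copy()
    jac = np.empty((b, 2, 1))
    if model is RiskModel.DOM:
        jac[:, 0, 0] = 1.0
        jac[:, 1, 0] = 1.0
    elif model is RiskModel.REC:
        jac[:, 0, 0] = 0.0
        jac[:, 1, 0] = 1.0
    elif model is RiskModel.MULT:
        jac[:, 0, 0] = 1.0
        jac[:, 1, 0] = 2.0
    else:  # Add: dt1/dtheta = exp(th)/(1/2 + exp(th)), dt2/dtheta = 1
        r = 1.0 / (1.0 + 0.5 * np.exp(-theta[:, 0]))
        jac[:, 0, 0] = r
        jac[:, 1, 0] = 1.0
    return jac


def _hess_correction(model: RiskModel, theta: np.ndarray, g_t1: np.ndarray) -> np.ndarray:
    """sum_i g_ti * d^2 t_i / dtheta^2 — nonzero only for the Add map."""
    k = 2 if model is RiskModel.UNR else 1
    corr = np.zeros((theta.shape[0], k, k))
    if model is RiskModel.ADD:
        r = 1.0 / (1.0 + 0.5 * np.exp(-theta[:, 0]))
        corr[:, 0, 0] = g_t1 * r * (1.0 - r)
    return corr


def _psis_from_theta(model: RiskModel, theta: np.ndarray):
    """(psi1, psi2) with the model's constraint satisfied exactly, not in floats-of-logs."""
    if model is RiskModel.UNR:
        return np.exp(theta[:, 0]), np.exp(theta[:, 1])
    th = theta[:, 0]
    if model is RiskModel.DOM:
        psi1 = np.exp(th)
        return psi1, psi1
    if model is RiskModel.REC:
        return np.ones_like(th), np.exp(th)
    if model is RiskModel.MULT:
        psi1 = np.exp(th)
        return psi1, psi1**2
    psi1 = 0.5 + np.exp(th)  # Add
    return psi1, 2.0 * psi1 - 1.0


def _theta_null(model: RiskModel, b: int) -> np.ndarray:
    """Free-parameter value at psi1 = psi2 = 1 (the ascent's starting point)."""
    if model is RiskModel.UNR:
        return np.zeros((b, 2))
    if model is RiskModel.ADD:
        return np.full((b, 1), np.log(0.5))
    return np.zeros((b, 1))


def _objective(stats: SufficientStats, a, t1, t2):
    """Log-likelihood up to the parameter-free constant, on the working scale."""
    p = expit(a)
    q = expit(-a)
    r = q * q + 2.0 * p * q * np.exp(t1) + p * p * np.exp(t2)
    return (
        stats.ap * np.log(p)
        + stats.aq * np.log(q)
        + stats.a1 * t1
        + stats.a2 * t2
        - stats.n_fam * np.log(r)
    )


def _grad_hess(stats: SufficientStats, a, t1, t2):
    """Analytic gradient and Hessian in (a, t1, t2) coordinates."""
    p = expit(a)
    q = expit(-a)
    pq = p * q
    w0 = q * q
    w1 = 2.0 * pq * np.exp(t1)
    w2 = p * p * np.exp(t2)
    r = w0 + w1 + w2
    u1 = w1 / r
    u2 = w2 / r
    ubar = u1 + 2.0 * u2                 # expected risk-allele dosage of a case
    usq = u1 + 4.0 * u2                  # E[dosage^2]
    nf = stats.n_fam

    g_a = stats.ap * q - stats.aq * p - nf * (ubar - 2.0 * p)
    g_t1 = stats.a1 - nf * u1
    g_t2 = stats.a2 - nf * u2

    h_aa = -(stats.ap + stats.aq) * pq - nf * (usq - ubar * ubar - 2.0 * pq)
    h_a1 = -nf * u1 * (1.0 - ubar)
    h_a2 = -nf * u2 * (2.0 - ubar)
    h_11 = -nf * u1 * (1.0 - u1)
    h_12 = nf * u1 * u2
    h_22 = -nf * u2 * (1.0 - u2)
    return (g_a, g_t1, g_t2), (h_aa, h_a1, h_a2, h_11, h_12, h_22)


def _assemble(model, theta, grads, hessians):
    """Project the (a, t1, t2) gradient/Hessian onto (a, theta) coordinates."""
    g_a, g_t1, g_t2 = grads
    h_aa, h_a1, h_a2, h_11, h_12, h_22 = hessians
    b = theta.shape[0]
    k = theta.shape[1]
    jac = _map_jacobian(model, theta)  # (B, 2, k)
    g_t = np.stack([g_t1, g_t2], axis=1)  # (B, 2)
    h_tt = np.empty((b, 2, 2))
    h_tt[:, 0, 0] = h_11
    h_tt[:, 0, 1] = h_12
    h_tt[:, 1, 0] = h_12
    h_tt[:, 1, 1] = h_22
    h_at = np.stack([h_a1, h_a2], axis=1)  # (B, 2)

    grad = np.empty((b, 1 + k))
    grad[:, 0] = g_a
    grad[:, 1:] = np.einsum("bij,bi->bj", jac, g_t)

    hess = np.empty((b, 1 + k, 1 + k))
    hess[:, 0, 0] = h_aa
    cross = np.einsum("bij,bi->bj", jac, h_at)
    hess[:, 0, 1:] = cross
    hess[:, 1:, 0] = cross
    hess[:, 1:, 1:] = (
        np.einsum("bij,bil,blm->bjm", jac, h_tt, jac)
        + _hess_correction(model, theta, g_t1)
    )
    return grad, hess


def null_fit_many(stats: SufficientStats):
    """Closed-form null MLE and maximised log-likelihood (vectorised).

    Returns ``(p_hat, loglik, valid)``; ``valid`` is False where the data are
    degenerate (all risk or all non-risk alleles, or no families).
    """
    ap = np.asarray(stats.ap, dtype=float)
    aq = np.asarray(stats.aq, dtype=float)
    total = ap + aq
    valid = (ap > 0) & (aq > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(valid, ap / np.where(total > 0, total, 1.0), np.nan)
        l0 = np.where(
            valid,
            ap * np.log(np.where(valid, p0, 0.5))
            + aq * np.log(np.where(valid, 1.0 - p0, 0.5))
            + stats.const,
            np.nan,
        )
    return p0, l0, valid


def fit_many(
    stats: SufficientStats,
    model: "RiskModel | str",
    theta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """Constrained MLE for a batch of datasets summarised by sufficient stats.

    Runs a damped Newton ascent (halving line search, ridge fallback) from the
    null point — or from ``theta0`` — simultaneously for all datasets.
    Returns a dict of arrays: ``p``, ``psi1``, ``psi2``, ``loglik`` (same
    constant convention as :func:`famlrt.likelihood.loglik_combined`),
    ``converged``, ``iterations``, ``boundary`` and ``valid``.
    """
    model = RiskModel.parse(model)
    ap = np.atleast_1d(np.asarray(stats.ap, dtype=float))
    squeeze = np.ndim(stats.ap) == 0
    stats = SufficientStats(
        ap=ap,
        aq=np.atleast_1d(np.asarray(stats.aq, dtype=float)),
        a1=np.atleast_1d(np.asarray(stats.a1, dtype=float)),
        a2=np.atleast_1d(np.asarray(stats.a2, dtype=float)),
        n_fam=np.atleast_1d(np.asarray(stats.n_fam, dtype=float)),
        const=np.atleast_1d(np.asarray(stats.const, dtype=float)),
    )
    b = stats.ap.shape[0]
    k = model.n_risk_params

    p0, _, valid = null_fit_many(stats)
    a = logit(np.clip(np.where(valid, p0, 0.5), expit(-_A_MAX), expit(_A_MAX)))
    theta = _theta_null(model, b) if theta0 is None else np.array(theta0, dtype=float)
    if theta.shape != (b, k):
        theta = np.broadcast_to(np.asarray(theta, dtype=float).reshape(1, k), (b, k)).copy()

    t1, t2 = _map_t(model, theta)
    l_cur = _objective(stats, a, t1, t2)
    active = valid.copy()
    iterations = np.zeros(b, dtype=np.int64)
    converged = np.zeros(b, dtype=bool)

    eye = np.eye(1 + k)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        sub = SufficientStats(*(getattr(stats, f)[idx] for f in
                                ("ap", "aq", "a1", "a2", "n_fam", "const")))
        a_s, th_s = a[idx], theta[idx]
        t1_s, t2_s = _map_t(model, th_s)
        grad, hess = _assemble(model, th_s, *_grad_hess(sub, a_s, t1_s, t2_s))

        # Newton direction with a tiny ridge; fall back to scaled gradient
        # where the system is singular or not an ascent direction.
        diag_scale = np.abs(np.diagonal(hess, axis1=1, axis2=2)).max(axis=1)
        ridge = (1e-9 * (1.0 + diag_scale))[:, None, None] * eye
        try:
            step = np.linalg.solve(-hess + ridge, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = grad / (diag_scale + 1.0)[:, None]
        bad = ~np.isfinite(step).all(axis=1) | (np.einsum("bi,bi->b", step, grad) <= 0)
        if bad.any():
            step[bad] = grad[bad] / (diag_scale[bad] + 1.0)[:, None]

        # Backtracking line search (vectorised): halve until no worse.
        scale = np.ones(len(idx))
        l_old = l_cur[idx]
        accepted = np.zeros(len(idx), dtype=bool)
        a_new = a_s.copy()
        th_new = th_s.copy()
        l_new = l_old.copy()
        for _ls in range(40):
            trial_a = np.clip(a_s + scale * step[:, 0], -_A_MAX, _A_MAX)
            trial_th = np.clip(th_s + scale[:, None] * step[:, 1:], -_T_MAX, _T_MAX)
            tt1, tt2 = _map_t(model, trial_th)
            sub_l = _objective(sub, trial_a, tt1, tt2)
            improve = sub_l >= l_old
            newly = improve & ~accepted
            a_new[newly] = trial_a[newly]
            th_new[newly] = trial_th[newly]
            l_new[newly] = sub_l[newly]
            accepted |= improve
            if accepted.all():
                break
            scale = np.where(accepted, scale, scale * 0.5)

        a[idx] = a_new
        theta[idx] = th_new
        l_cur[idx] = l_new
        iterations[idx] += 1

        gain = l_new - l_old
        done = gain < tol * (1.0 + np.abs(l_new))
        converged[idx[done]] = True
        active[idx[done]] = False

    t1, t2 = _map_t(model, theta)
    psi1, psi2 = _psis_from_theta(model, theta)
    boundary = (np.abs(theta) >= _B_THRESH).any(axis=1) | (np.abs(a) >= _A_MAX - 1e-9)
    loglik = _objective(stats, a, t1, t2) + stats.const
    out = {
        "p": expit(a),
        "psi1": psi1,
        "psi2": psi2,
        "loglik": np.where(valid, loglik, np.nan),
        "converged": converged & valid,
        "iterations": iterations,
        "boundary": boundary,
        "valid": valid,
    }
    if squeeze:
        out = {key: val[0] for key, val in out.items()}
    return out


def mle_null(data: FamilyDataset) -> FitResult:
    """Null-hypothesis MLE: psi1 = psi2 = 1, closed-form allele frequency.

    Under the null the normaliser ``R`` is 1 and the likelihood reduces to a
    Binomial in the coefficient sums of ``log p`` and ``log q``, so
    ``p_hat = ap / (ap + aq)`` exactly.
    """
    stats = sufficient_stats(data)
    p0, l0, valid = null_fit_many(
        SufficientStats(*(np.atleast_1d(getattr(stats, f)) for f in
                          ("ap", "aq", "a1", "a2", "n_fam", "const")))
    )
    if not valid[0]:
        raise DegenerateDataError(
            "cannot estimate the allele frequency: the data carry copies of "
            "only one allele (p_hat would be 0 or 1)"
        )
    return FitResult(
        model="Null",
        p_hat=float(p0[0]),
        psi1_hat=1.0,
        psi2_hat=1.0,
        loglik=float(l0[0]),
        converged=True,
        iterations=0,
        boundary=False,
    )


_EXTRA_STARTS = {
    1: [np.array([0.7]), np.array([-0.7])],
    2: [np.array([0.7, 0.7]), np.array([-0.7, -0.7]),
        np.array([0.7, -0.7]), np.array([-0.7, 0.7])],
}


def mle_alternative(data: FamilyDataset, model: "RiskModel | str") -> FitResult:
    """Constrained MLE of (p, psi1, psi2) under one alternative risk model.

    The ascent starts at the null MLE (so the attained log-likelihood can
    never fall below the null's) and is repeated from a few deterministic
    over- and under-dispersed starting points, keeping the best optimum.
    """
    model = RiskModel.parse(model)
    stats = sufficient_stats(data)
    mle_null(data)  # raises DegenerateDataError on degenerate data

    k = model.n_risk_params
    starts = [None]
    shift = np.log(0.5) if model is RiskModel.ADD else 0.0
    starts += [s[:k] + shift for s in _EXTRA_STARTS[k]]

    best = None
    for theta0 in starts:
        res = fit_many(stats, model, theta0=None if theta0 is None else theta0.reshape(1, k))
        if best is None or res["loglik"] > best["loglik"] + 1e-12:
            best = res
    assert best is not None
    result = FitResult(
        model=model.value,
        p_hat=float(best["p"]),
        psi1_hat=float(best["psi1"]),
        psi2_hat=float(best["psi2"]),
        loglik=float(best["loglik"]),
        converged=bool(best["converged"]),
        iterations=int(best["iterations"]),
        boundary=bool(best["boundary"]),
    )
    if not result.converged:
        raise NonConvergenceError(
            f"{model.value} fit did not converge after restarts", best=result
        )
    return result
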