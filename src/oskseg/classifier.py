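"""Kernel low-rank + sparse representation (KLRR-SR) solved by ADMM.

Given a dictionary kernel V = K(D, D) and a cross kernel U = K(D, X), the
representation coefficients A (one column per test sample) minimise

    (1/2) tr(AᵀVA) − tr(AᵀU) + lambda ‖A‖_* + alpha ‖A‖_1 ,

the kernelised form of a least-squares fit in the RKHS jointly penalised by
the nuclear norm (global low-rank structure) and the elementwise l1 norm
(local sparsity; alpha = 0 recovers the pure kernel low-rank model).  The
problem is split with auxiliary variables E = A (low-rank block) and F = A
(sparse block) and solved by ADMM: singular-value thresholding for E, soft
thresholding for F, and a positive-definite linear solve for A.

Each test sample is then assigned the class whose dictionary atoms best
reconstruct it, measured by the kernel residual
delta_c(a)ᵀ V delta_c(a) − 2 delta_c(a)ᵀ u, where delta_c zeroes the
coefficients of every other class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RepresentationProblem",
    "AdmmResult",
    "soft_threshold",
    "svt",
    "update_A",
    "admm_solve",
    "classify",
    "stabilise_psd",
]

logger = logging.getLogger(__name__)


def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage sign(x)·max(|x|−tau, 0): the l1 prox."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def svt(x: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: the nuclear-norm prox.

    Soft-thresholds the singular values, leaving singular vectors intact.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x = np.asarray(x, dtype=float)
    if tau == 0:
        return x.copy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def stabilise_psd(v: np.ndarray, floor: float = -1e-8) -> np.ndarray:
    """Symmetrise and clip eigenvalues below ``floor``·(max eig, 1).

    Absorbs tiny indefiniteness that mixed-sign MKL weights can introduce,
    so that V + 2 mu I stays positive definite for every mu > 0.
    """
    v = (np.asarray(v, dtype=float) + np.asarray(v).T) / 2.0
    evals, evecs = np.linalg.eigh(v)
    lo = floor * max(evals[-1], 1.0)
    if evals[0] >= lo:
        return v
    clipped = np.maximum(evals, 0.0)
    logger.warning("V clipped: min eigenvalue %.3e below tolerance", evals[0])
    return (evecs * clipped) @ evecs.T


def update_A(
    E: np.ndarray,
    F: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    V: np.ndarray,
    U: np.ndarray,
    mu: float,
    factor=None,
) -> np.ndarray:
    """Exact minimiser of the quadratic A-subproblem.

    Stationarity gives (V + 2 mu I) A = U + mu (E + F) − Y1 − Y2, solved by
    a Cholesky factorisation (reusable across iterations at fixed mu via
    ``factor``).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rhs = U + mu * (E + F) - Y1 - Y2
    if factor is None:
        H = V + 2.0 * mu * np.eye(V.shape[0])
        try:
            factor = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            cond = np.linalg.cond(H)
            raise np.linalg.LinAlgError(
                f"V + 2*mu*I not positive definite (cond={cond:.3e}); "
                "V may be far from PSD"
            ) from err
    return cho_solve(factor, rhs)


@dataclass
class RepresentationProblem:
    """KLRR-SR instance plus ADMM hyper-parameters.

    lambda_lr weighs the nuclear norm, alpha_sp the l1 penalty (alpha_sp = 0
    is the pure kernel low-rank model).  mu follows the standard increasing
    penalty schedule mu <- min(rho*mu, mu_max).
    """

    V: np.ndarray
    U: np.ndarray
    lambda_lr: float = 0.005
    alpha_sp: float = 0.002
    mu0: float = 0.1
    rho: float = 1.1
    mu_max: float = 1e6
    tol: float = 1e-6
    dual_tol: float = 1e-5
    max_iter: int = 1000

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        t = self.V.shape[0]
        if self.V.shape != (t, t) or self.U.shape[0] != t:
            raise ValueError("V must be T×T and U T×N")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("V must be symmetric")
        if self.lambda_lr < 0 or self.alpha_sp < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.mu0 <= 0 or self.rho < 1 or self.tol <= 0:
            raise ValueError("invalid ADMM parameters")

    def objective(self, A: np.ndarray) -> float:
        """Model objective at A (the constant (1/2)tr(K_XX) term omitted)."""
        quad = 0.5 * np.sum(A * (self.V @ A)) - np.sum(A * self.U)
        nuc = np.linalg.svd(A, compute_uv=False).sum()
        return float(quad + self.lambda_lr * nuc
                     + self.alpha_sp * np.abs(A).sum())


@dataclass
class AdmmResult:
    """Solution with convergence diagnostics."""

    A: np.ndarray
    converged: bool
    n_iter: int
    history: pd.DataFrame = field(repr=False)

    @property
    def final_residual(self) -> float:
        return float(self.history[["res_E", "res_F"]].iloc[-1].max())


def admm_solve(problem: RepresentationProblem) -> AdmmResult:
    """Run ADMM on a :class:`RepresentationProblem`.

    Per sweep: E <- SVT_{lambda/mu}(A + Y1/mu); F <- shrink_{alpha/mu}(A + Y2/mu);
    A <- (V + 2 mu I)^{-1} (U + mu (E+F) − Y1 − Y2); dual ascent on Y1, Y2.

    The penalty grows geometrically, mu <- min(rho mu, mu_max), but only once
    the normalised dual change mu·max(‖E−E_prev‖, ‖F−F_prev‖)/‖U‖ falls below
    ``dual_tol`` (the usual inexact-ALM rule): growing mu unconditionally
    enforces the split constraints faster than the subproblems are solved and
    freezes the iterates short of optimality.  Convergence requires both
    infinity-norm split residuals below ``tol`` and the dual criterion below
    ``dual_tol``.  Non-convergence returns the last iterate with
    ``converged=False`` and a logged warning, never silently.
    """
    V = stabilise_psd(problem.V)
    U = problem.U
    t, n = U.shape
    A = np.zeros((t, n))
    E = np.zeros((t, n))
    F = np.zeros((t, n))
    Y1 = np.zeros((t, n))
    Y2 = np.zeros((t, n))
    mu = problem.mu0

    rows = []
    converged = False
    factor = None
    factor_mu = None
    it = 0
    e_prev = E
    f_prev = F
    u_norm = max(float(np.linalg.norm(U)), 1.0)
    for it in range(1, problem.max_iter + 1):
        E = svt(A + Y1 / mu, problem.lambda_lr / mu)
        F = soft_threshold(A + Y2 / mu, problem.alpha_sp / mu)
        if factor is None or factor_mu != mu:
            factor = cho_factor(V + 2.0 * mu * np.eye(t), lower=True)
            factor_mu = mu
        A = update_A(E, F, Y1, Y2, V, U, mu, factor=factor)
        Y1 = Y1 + mu * (A - E)
        Y2 = Y2 + mu * (A - F)
        res_e = float(np.abs(A - E).max(initial=0.0))
        res_f = float(np.abs(A - F).max(initial=0.0))
        dual = mu * max(float(np.linalg.norm(E - e_prev)),
                        float(np.linalg.norm(F - f_prev))) / u_norm
        rows.append(
            {
                "iteration": it,
                "objective": problem.objective(A),
                "res_E": res_e,
                "res_F": res_f,
                "dual": dual,
                "mu": mu,
            }
        )
        if max(res_e, res_f) < problem.tol and dual < problem.dual_tol:
            converged = True
            break
        if dual < problem.dual_tol:
            mu = min(problem.rho * mu, problem.mu_max)
        e_prev, f_prev = E, F

    if not converged:
        logger.warning(
            "ADMM did not reach tol=%.1e in %d iterations "
            "(final residual %.3e)", problem.tol, problem.max_iter,
            max(res_e, res_f),
        )
    history = pd.DataFrame(rows)
    return AdmmResult(A=A, converged=converged, n_iter=it, history=history)


def classify(
    A: np.ndarray,
    V: np.ndarray,
    U: np.ndarray,
    atom_labels: np.ndarray,
) -> np.ndarray:
    """Class-wise kernel-residual decision for every test column.

    For each column a and class c the score is
    delta_c(a)ᵀ V delta_c(a) − 2 delta_c(a)ᵀ u  (u the matching column of U);
    the predicted class minimises the score, ties going to the smallest
    class label.
    """
    A = np.asarray(A, dtype=float)
    atom_labels = np.asarray(atom_labels)
    if atom_labels.shape != (A.shape[0],):
        raise ValueError("need one label per dictionary atom")
    classes = np.unique(atom_labels)
    scores = np.empty((classes.size, A.shape[1]))
    for k, c in enumerate(classes):
        sel = atom_labels == c
        Ac = np.where(sel[:, None], A, 0.0)
        scores[k] = np.sum(Ac * (V @ Ac), axis=0) - 2.0 * np.sum(Ac * U, axis=0)
    return classes[np.argmin(scores, axis=0)]
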