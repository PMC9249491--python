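"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: brute-force double
sums for the superpixel kernel, a dense SVD of the materialised stacked
Gram matrix for the MKL weights, grid search for the scalar prox, and a
Davis–Yin three-operator splitting solver (no multipliers, no penalty
schedule) for the low-rank + sparse representation objective.
"""

from __future__ import annotations

import numpy as np


def brute_superpixel_kernel(features: np.ndarray, sp_labels: np.ndarray,
                            kernel) -> np.ndarray:
    """Superpixel kernel by the literal double sum over member pixels."""
    n = features.shape[0]
    out = np.empty((n, n))
    members = {p: np.flatnonzero(sp_labels == p) for p in np.unique(sp_labels)}
    for k in range(n):
        for s in range(n):
            mi = members[sp_labels[k]]
            mj = members[sp_labels[s]]
            acc = 0.0
            for a in mi:
                for b in mj:
                    acc += kernel(features[a], features[b])
            out[k, s] = acc / (len(mi) * len(mj))
    return out


def averaging_operator(sp_labels: np.ndarray) -> np.ndarray:
    """Explicit N×N operator E with E G Eᵀ the superpixel-mean Gram."""
    n = sp_labels.size
    E = np.zeros((n, n))
    for p in np.unique(sp_labels):
        idx = np.flatnonzero(sp_labels == p)
        E[np.ix_(idx, idx)] = 1.0 / idx.size
    return E


def dense_mkl_weights(pixel_grams: list[np.ndarray]) -> np.ndarray:
    """Top left-singular vector of the explicitly materialised M×N² stack."""
    stack = np.stack([g.ravel(order="F") for g in pixel_grams])  # (M, N²)
    u, _, _ = np.linalg.svd(stack, full_matrices=False)
    w = u[:, 0]
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def scalar_prox_grid(x: float, tau: float, grid: int = 40001,
                     span: float = 4.0) -> float:
    """argmin_z 0.5 (z-x)^2 + tau |z| by two-stage brute grid search."""
    z = np.linspace(-span, span, grid)
    obj = 0.5 * (z - x) ** 2 + tau * np.abs(z)
    best = z[np.argmin(obj)]
    step = z[1] - z[0]
    z = np.linspace(best - 2 * step, best + 2 * step, grid)
    obj = 0.5 * (z - x) ** 2 + tau * np.abs(z)
    return float(z[np.argmin(obj)])


def lowrank_sparse_objective(A, V, U, lam, alpha):
    quad = 0.5 * np.sum(A * (V @ A)) - np.sum(A * U)
    return float(quad + lam * np.linalg.svd(A, compute_uv=False).sum()
                 + alpha * np.abs(A).sum())


def davis_yin_solve(V, U, lam, alpha, n_iter=20000, tol=1e-12):
    """Three-operator splitting for 0.5 tr(AᵀVA) − tr(AᵀU) + lam‖A‖_* + alpha‖A‖₁.

    Smooth part f(A) with gradient VA − U (Lipschitz ‖V‖₂); g the nuclear
    norm, h the l1 norm.  Iteration: x = prox_{γg}(z);
    y = prox_{γh}(2x − z − γ∇f(x)); z ← z + y − x.  Returns the g-point x.
    """
    V = np.asarray(V, float)
    U = np.asarray(U, float)
    L = max(np.linalg.eigvalsh((V + V.T) / 2)[-1], 1e-12)
    gamma = 1.0 / L

    def prox_nuc(X, t):
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        s = np.maximum(s - t, 0.0)
        return (u * s) @ vt

    def prox_l1(X, t):
        return np.sign(X) * np.maximum(np.abs(X) - t, 0.0)

    z = np.zeros_like(U)
    x = z
    for _ in range(n_iter):
        x = prox_nuc(z, gamma * lam)
        grad = V @ x - U
        y = prox_l1(2 * x - z - gamma * grad, gamma * alpha)
        step = y - x
        z = z + step
        if np.max(np.abs(step)) < tol:
            break
    return x


def nearest_centroid(test: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1-based nearest-centroid labels (independent of any package code)."""
    d = np.linalg.norm(test[:, None] - centroids[None], axis=-1)
    return d.argmin(axis=1) + 1
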