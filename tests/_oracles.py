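"""Independent reference implementations used only to check the package.

These deliberately share no code with ftilt's solver: the lasso oracle is
a dense ADMM iteration with a closed-form ridge step, and optimality is
certified by the subgradient (KKT) residual of the l1 problem.
"""

from __future__ import annotations

import numpy as np


def admm_lasso(A: np.ndarray, b: np.ndarray, tau: float,
               rho: float = 0.5, n_iter: int = 200_000, kkt_tol: float = 1e-9):
    """Minimize ||A x - b||_2^2 + tau * ||x||_1 over complex x by ADMM.

    Scaled-form ADMM with cached factorization of (2 A^H A + rho I); stops
    when the l1 subgradient (KKT) residual drops below ``kkt_tol``.
    Returns the final z iterate, which is exactly sparse.
    """
    m, n = A.shape
    AHA = A.conj().T @ A
    AHb = A.conj().T @ b
    # x-step solves (2 A^H A + rho I) x = 2 A^H b + rho (z - u)
    M = 2.0 * AHA + rho * np.eye(n)
    import scipy.linalg as sla

    cho = sla.cho_factor(M)
    x = np.zeros(n, dtype=complex)
    z = np.zeros(n, dtype=complex)
    u = np.zeros(n, dtype=complex)
    for it in range(n_iter):
        x = sla.cho_solve(cho, 2.0 * AHb + rho * (z - u))
        w = x + u
        mag = np.abs(w)
        z = w * np.maximum(1.0 - (tau / rho) / np.maximum(mag, 1e-300), 0.0)
        u = u + x - z
        if it % 200 == 199 and kkt_residual(A, b, z, tau) < kkt_tol:
            break
    return z


def lasso_objective(A: np.ndarray, b: np.ndarray, x: np.ndarray, tau: float) -> float:
    r = A @ x - b
    return float(np.vdot(r, r).real + tau * np.abs(x).sum())


def kkt_residual(A: np.ndarray, b: np.ndarray, x: np.ndarray, tau: float) -> float:
    """Max violation of the l1 subgradient optimality conditions.

    At an optimum, g = 2 A^H (A x - b) satisfies g_i = -tau * x_i/|x_i|
    where x_i != 0 and |g_i| <= tau elsewhere.
    """
    g = 2.0 * A.conj().T @ (A @ x - b)
    viol = 0.0
    scale = max(np.abs(x).max(initial=0.0), 1.0)
    for i in range(x.size):
        if abs(x[i]) > 1e-10 * scale:
            viol = max(viol, abs(g[i] + tau * x[i] / abs(x[i])))
        else:
            viol = max(viol, max(abs(g[i]) - tau, 0.0))
    return viol


def dense_dft_spectrum(x: np.ndarray, freqs: np.ndarray, sw: float) -> np.ndarray:
    """Direct O(n^2) analysis DFT of a t1 FID onto arbitrary frequencies."""
    n = x.size
    t = np.arange(n) / sw
    return np.exp(-2j * np.pi * freqs[:, None] * t[None, :]) @ x
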