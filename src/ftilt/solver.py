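"""FISTA with complex soft thresholding for the l1-regularized joint inversion.

Solves

    min_Q  || P Q - q ||_2^2  +  tau * || Q ||_1

where P is the sampled joint Fourier-Laplace operator, q the measured
sample vector and ||Q||_1 the sum of complex magnitudes.  The proximal
step is magnitude shrinkage (phase preserved), the standard choice for
complex NMR spectra.  The gradient of the fidelity term is
``2 P^H (P Q - q)`` with Lipschitz constant ``L = 2 lambda_max(P^H P)``;
the fixed step 1/L (power-iteration estimate times a 1.02 safety margin)
keeps the iteration deterministic — no backtracking.  Plain FISTA
momentum by default, with an optional monotone safeguard that never lets
the objective increase.

A useful exact property of this scaling: the solution is identically zero
iff ``tau >= 2 ||P^H q||_inf``.  Since the data scaling of any given
experiment is arbitrary, ``tau_mode="relative"`` specifies tau as a
fraction of that critical value — the scale-free way to set the penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import JointOperator

__all__ = [
    "SolverConfig",
    "SolverResult",
    "soft_threshold",
    "lipschitz_estimate",
    "critical_tau",
    "fista_solve",
    "fista_solve_batch",
]


@dataclass(frozen=True)
class SolverConfig:
    """FISTA settings.

    ``tau`` is the l1 weight; with ``tau_mode="relative"`` it is the
    fraction of the critical value ``2 ||P^H q||_inf`` above which the
    solution is exactly zero (recommended: scale-free).  ``n_iter`` fixed
    iteration budget; ``tolerance`` optional early stop on the relative
    objective change; ``monotone`` enables the monotone-FISTA safeguard.
    """

    tau: float = 0.01
    tau_mode: str = "relative"       # "relative" | "absolute"
    n_iter: int = 500
    tolerance: float | None = None
    monotone: bool = False
    restart: bool = False            # gradient-based adaptive momentum restart
    precision: str = "double"        # "double" | "single" (batch path only)
    lipschitz_safety: float = 1.02
    n_power_iter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.tau_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown tau_mode {self.tau_mode!r}")
        if self.precision not in ("double", "single"):
            raise ValueError(f"unknown precision {self.precision!r}")


@dataclass
class SolverResult:
    """Reconstructed plane plus convergence diagnostics."""

    Q: np.ndarray
    objective_trace: np.ndarray
    n_iter_used: int
    tau_effective: float
    diverged: bool = False

    def trace_to_tsv(self, path) -> None:
        """Write the per-iteration objective values as a two-column TSV
        (iteration, objective) for convergence plots."""
        with open(path, "w") as fh:
            fh.write("iteration\tobjective\n")
            for i, v in enumerate(self.objective_trace, start=1):
                fh.write(f"{i}\t{v:.12g}\n")


def soft_threshold(x, theta: float):
    """Complex soft thresholding: shrink the magnitude by ``theta``,
    preserve the phase; values with ``|x| <= theta`` go to zero."""
    if theta < 0:
        raise ValueError(f"threshold must be >= 0, got {theta}")
    x = np.asarray(x)
    mag = np.abs(x)
    scale = np.maximum(1.0 - theta / np.maximum(mag, 1e-300), 0.0)
    out = x * scale
    return out[()] if out.ndim == 0 else out


def lipschitz_estimate(
    operator: JointOperator, n_power_iter: int = 30, seed: int = 0
) -> float:
    """Largest eigenvalue of P^H P by power iteration on the plane space."""
    if n_power_iter < 1:
        raise ValueError("n_power_iter must be >= 1")
    rng = np.random.default_rng(seed)
    shape = operator.plane_shape
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    nrm = np.linalg.norm(x)
    x = x / nrm
    lam = 0.0
    for _ in range(n_power_iter):
        z = operator.adjoint(operator.forward(x))
        nz = np.linalg.norm(z)
        if nz == 0:
            raise ValueError("operator maps the start vector to zero (zero operator?)")
        lam = float(np.real(np.vdot(x, z)))
        x = z / nz
    return lam


def critical_tau(operator: JointOperator, q: np.ndarray) -> float:
    """Smallest tau for which the minimizer is exactly zero: ``2 ||P^H q||_inf``."""
    return 2.0 * float(np.max(np.abs(operator.adjoint(q))))


def _objective(operator: JointOperator, q: np.ndarray, Q: np.ndarray, tau: float) -> float:
    resid = operator.forward(Q) - q
    return float(np.vdot(resid, resid).real + tau * np.abs(Q).sum())


def fista_solve(
    operator: JointOperator, q: np.ndarray, config: SolverConfig
) -> SolverResult:
    """Minimize ``||P Q - q||^2 + tau ||Q||_1`` by FISTA.

    Deterministic given the config.  Raises on non-finite data; flags
    divergence (objective exceeding 10x the initial value) in the result
    instead of raising.
    """
    q = np.asarray(q, dtype=complex)
    if q.shape != (operator.n_samples,):
        raise ValueError(f"data length {q.shape} != ({operator.n_samples},)")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite values in data vector")

    tau = config.tau
    if config.tau_mode == "relative":
        tau = config.tau * critical_tau(operator, q)
    if tau == 0.0:         # q == 0 in relative mode: minimizer is 0 for any tau > 0
        Q0 = np.zeros(operator.plane_shape, dtype=complex)
        return SolverResult(Q=Q0, objective_trace=np.zeros(1), n_iter_used=0,
                            tau_effective=0.0)

    L = 2.0 * lipschitz_estimate(operator, config.n_power_iter, config.seed)
    L *= config.lipschitz_safety

    x = np.zeros(operator.plane_shape, dtype=complex)
    y = x
    t = 1.0
    obj_x = _objective(operator, q, x, tau)
    obj0 = obj_x
    trace = []
    n_used = 0
    diverged = False
    for _ in range(config.n_iter):
        grad = 2.0 * operator.adjoint(operator.forward(y) - q)
        x_new = soft_threshold(y - grad / L, tau / L)
        obj_new = _objective(operator, q, x_new, tau)
        if config.monotone and obj_new > obj_x:
            # monotone FISTA: keep the best iterate, momentum still uses x_new
            z = x_new
            x_new, obj_new = x, obj_x
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            y = x_new + (t / t_new) * (z - x_new) + ((t - 1.0) / t_new) * (x_new - x)
        else:
            if config.restart and np.real(np.vdot(y - x_new, x_new - x)) > 0:
                t = 1.0   # momentum restart: the generalized gradient
                          # opposes progress, so drop the accumulated inertia
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        rel_change = abs(obj_x - obj_new) / max(obj_x, 1e-300)
        x, obj_x, t = x_new, obj_new, t_new
        trace.append(obj_x)
        n_used += 1
        if obj_x > 10.0 * max(obj0, 1e-300):
            diverged = True
            break
        if config.tolerance is not None and rel_change < config.tolerance:
            break
    return SolverResult(
        Q=x,
        objective_trace=np.array(trace),
        n_iter_used=n_used,
        tau_effective=tau,
        diverged=diverged,
    )


def fista_solve_batch(
    operator: JointOperator, qs: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """Solve the l1 problem for many data columns sharing one operator.

    Mathematically identical to calling :func:`fista_solve` per column
    (same step size, same momentum schedule, per-column effective tau in
    relative mode) but the per-iteration contractions are fused into two
    large matrix products across all columns, which is substantially
    faster on a single CPU.  No objective traces are tracked.  With
    ``config.precision == "single"`` the iteration runs in complex64
    (about 2x faster; the iterate differs from the double run by
    O(1e-5) relative, far below the method's rate-estimation error).
    Returns the stacked planes, shape ``(n_columns, n_freq, n_rate)``.
    """
    qs = np.atleast_2d(np.asarray(qs, dtype=complex))
    C, M = qs.shape
    if M != operator.n_samples:
        raise ValueError(f"data length {M} != {operator.n_samples}")
    if not np.all(np.isfinite(qs)):
        raise ValueError("non-finite values in data")
    K, J = operator.plane_shape

    taus = np.empty(C)
    for c in range(C):
        taus[c] = (
            config.tau * critical_tau(operator, qs[c])
            if config.tau_mode == "relative"
            else config.tau
        )
    L = 2.0 * lipschitz_estimate(operator, config.n_power_iter, config.seed)
    L *= config.lipschitz_safety
    A, B = operator._A, operator._B          # (M, K), (M, J)
    cdtype = np.complex128
    if config.precision == "single":
        cdtype = np.complex64
        A, B, qs = A.astype(cdtype), B.astype(np.float32), qs.astype(cdtype)
    AH = A.conj().T
    thr = taus / L                            # per-column threshold

    x = np.zeros((C, K, J), dtype=cdtype)
    y = x.copy()
    t = 1.0
    for _ in range(config.n_iter):
        # residual r[c] = P y[c] - q[c], all columns in one GEMM
        T = (A @ y.transpose(1, 0, 2).reshape(K, C * J)).reshape(M, C, J)
        resid = np.einsum("mcj,mj->cm", T, B, optimize=True) - qs
        W = (resid.T[:, :, None] * B[:, None, :]).reshape(M, C * J)
        grad = (AH @ W).reshape(K, C, J).transpose(1, 0, 2)
        z = y - cdtype(2.0 / L) * grad
        mag = np.abs(z)
        x_new = z * np.maximum(1.0 - thr[:, None, None] / np.maximum(mag, 1e-30), 0.0).astype(mag.dtype)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = x_new + cdtype((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
    return x.astype(np.complex128)
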