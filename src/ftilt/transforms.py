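"""The joint Fourier-Laplace dictionary and its sampled linear operator.

The reconstruction plane Q lives on a frequency grid (indirect dimension)
times a decay-rate grid.  A scheduled sample at ``(t1, t_relax)`` sees

    q_m = sum_{k,j}  exp(+i 2 pi f_k t1_m) / K  *  exp(-r_j t_relax_m)  * Q[k, j]

i.e. the row of an inverse-DFT synthesis matrix (positive exponent, 1/K
scaling) Kronecker-multiplied with a row of the Laplace kernel.  The
operator is applied separably — the full Kronecker matrix is never
materialized — but agrees with it exactly on small grids (tested).

Laplace columns are *not* normalized by default: the raw ``exp(-R t)``
kernels keep a single regularization weight meaningful across the plane.
Because l1 shrinkage then biases against fast-decaying components (their
columns carry less energy over the delay range), a ``normalize_columns``
switch is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AcquisitionGeometry
from .sampling import JointSchedule

__all__ = [
    "FrequencyGrid",
    "RateGrid",
    "fourier_row",
    "laplace_entry",
    "JointOperator",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """``n`` uniformly spaced frequencies covering ``(-SW/2, +SW/2]``."""

    values: np.ndarray

    @classmethod
    def from_geometry(cls, geometry: AcquisitionGeometry) -> "FrequencyGrid":
        n, sw = geometry.n_f1_recon, geometry.sw_indirect
        vals = -sw / 2 + (np.arange(n) + 1) * sw / n
        return cls(values=vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0]) if self.n > 1 else 0.0

    def nearest_index(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.values - freq)))


@dataclass(frozen=True)
class RateGrid:
    """``n`` decay rates spanning ``[r_min, r_max]``, linear by default.

    The band endpoints are included exactly; a logarithmic option exists
    for wide bands but is not the default.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("rate grid must be a 1-D array")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("rate grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_geometry(cls, geometry: AcquisitionGeometry, spacing: str = "linear") -> "RateGrid":
        if spacing == "linear":
            vals = np.linspace(geometry.r_min, geometry.r_max, geometry.n_r_recon)
        elif spacing == "log":
            vals = np.geomspace(geometry.r_min, geometry.r_max, geometry.n_r_recon)
        else:
            raise ValueError(f"unknown rate-grid spacing {spacing!r}")
        return cls(values=vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0]) if self.n > 1 else 0.0

    def nearest_index(self, rate: float) -> int:
        return int(np.argmin(np.abs(self.values - rate)))


def fourier_row(t1: float, fgrid: FrequencyGrid) -> np.ndarray:
    """Row of the synthesis (inverse-DFT) matrix at evolution time ``t1``:
    entry k is ``exp(+i 2 pi f_k t1) / n``."""
    return np.exp(2j * np.pi * fgrid.values * t1) / fgrid.n


def laplace_entry(trelax: float, rate) -> np.ndarray | float:
    """Laplace kernel ``exp(-rate * trelax)``; ``rate`` may be an array."""
    if trelax < 0:
        raise ValueError(f"negative relaxation delay {trelax}")
    r = np.asarray(rate, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rates must be > 0")
    out = np.exp(-r * trelax)
    return float(out) if out.ndim == 0 else out


class JointOperator:
    """Sampled joint Fourier-Laplace operator P = F (x) L restricted to a schedule.

    ``forward`` maps a complex plane Q of shape (n_freq, n_rate) to the
    length-M sample vector; ``adjoint`` is its exact algebraic adjoint.
    Both are separable contractions (two BLAS matmuls), never the dense
    Kronecker product, but ``dense_matrix`` assembles the explicit
    M x (n_freq*n_rate) matrix for validation on small grids.
    """

    def __init__(
        self,
        geometry: AcquisitionGeometry,
        schedule: JointSchedule,
        fgrid: FrequencyGrid | None = None,
        rgrid: RateGrid | None = None,
        normalize_columns: bool = False,
    ):
        schedule.validate_against(geometry)
        self.geometry = geometry
        self.schedule = schedule
        self.fgrid = fgrid if fgrid is not None else FrequencyGrid.from_geometry(geometry)
        self.rgrid = rgrid if rgrid is not None else RateGrid.from_geometry(geometry)
        self.normalize_columns = normalize_columns
        t1 = schedule.t1_indices / geometry.sw_indirect
        # A: (M, K) Fourier synthesis rows; B: (M, J) Laplace kernel
        self._A = np.exp(2j * np.pi * t1[:, None] * self.fgrid.values[None, :]) / self.fgrid.n
        self._B = np.exp(-schedule.delays[:, None] * self.rgrid.values[None, :])
        if normalize_columns:
            # |A[m,k]| = 1/K for all m, so the (k,j) column norm separates:
            # ||P[:, kj]|| = (1/K) * ||B[:, j]||; dividing B columns by their
            # 2-norm times 1/K... keep the Fourier 1/K scale, normalize B only.
            norms = np.linalg.norm(self._B, axis=0)
            norms[norms == 0] = 1.0
            self._B = self._B / norms[None, :]

    @property
    def n_samples(self) -> int:
        return self.schedule.n_points

    @property
    def plane_shape(self) -> tuple[int, int]:
        return (self.fgrid.n, self.rgrid.n)

    def forward(self, Q: np.ndarray) -> np.ndarray:
        """Sample vector ``q_m = sum_kj A[m,k] B[m,j] Q[k,j]``."""
        Q = np.asarray(Q)
        if Q.shape != self.plane_shape:
            raise ValueError(f"plane shape {Q.shape} != expected {self.plane_shape}")
        return np.einsum("mj,mj->m", self._A @ Q, self._B, optimize=True)

    def adjoint(self, q: np.ndarray) -> np.ndarray:
        """Exact adjoint: plane ``[k,j] = sum_m conj(A[m,k]) B[m,j] q_m``."""
        q = np.asarray(q)
        if q.shape != (self.n_samples,):
            raise ValueError(f"sample vector length {q.shape} != ({self.n_samples},)")
        return self._A.conj().T @ (q[:, None] * self._B)

    def dense_matrix(self) -> np.ndarray:
        """Explicit sampled Kronecker matrix, row m = A[m,:] (x) B[m,:].

        For validation only; O(M * K * J) memory.
        """
        M = self.n_samples
        return (self._A[:, :, None] * self._B[:, None, :]).reshape(M, -1)
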