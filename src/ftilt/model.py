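"""Signal model and synthetic data for joint t1/t_relax relaxation experiments.

The time-domain signal of an amide resonance in a 2D heteronuclear
relaxation series is modelled as a damped complex exponential in the
indirect evolution time ``t1`` multiplied by a mono-exponential decay in
the relaxation delay ``t_relax``::

    s(t1, t_relax) = sum_i  a_i * exp(+i 2 pi f_i t1) * exp(-pi lw_i t1)
                            * exp(-R_i t_relax)

with amplitude ``a_i``, indirect offset frequency ``f_i`` (Hz), Lorentzian
linewidth ``lw_i`` (Hz) and longitudinal decay rate ``R_i`` (1/s).  The
indirect dimension is treated as an analytic (complex) signal, standing in
for States-type quadrature detection.  Additive noise is i.i.d. circular
complex Gaussian, the simplest model consistent with thermal NMR noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PeakModel",
    "AcquisitionGeometry",
    "NoiseModel",
    "simulate_joint_fid",
    "simulate_full_grid",
    "protein_fixture",
    "read_peak_table",
    "write_peak_table",
]


@dataclass(frozen=True)
class PeakModel:
    """One resonance of the synthetic spectrum.

    Parameters
    ----------
    freq_indirect : float
        Offset frequency in the indirect dimension, Hz.  Must lie within
        ``(-sw/2, +sw/2]`` of the geometry it is simulated against.
    linewidth : float
        Lorentzian linewidth in t1, Hz (exponential damping
        ``exp(-pi * linewidth * t1)``).
    amplitude : float
        Peak amplitude, arbitrary intensity units, non-negative.
    rate : float
        Longitudinal decay rate R in 1/s; strictly positive.
    freq_direct : float, optional
        Direct-dimension frequency, Hz.  Only used when a direct dimension
        is simulated; the reconstruction operates per direct column.
    """

    freq_indirect: float
    linewidth: float
    amplitude: float
    rate: float
    freq_direct: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.linewidth < 0:
            raise ValueError(f"linewidth must be >= 0, got {self.linewidth}")
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Sampling grids and reconstruction grids of a joint NUS experiment.

    The indirect evolution time is gridded as ``t1 = k / sw_indirect`` for
    ``k = 0 .. n_t1 - 1``.  The relaxation delay lives on a finite universe
    ``{trelax_min + j * trelax_mesh} ∩ [trelax_min, trelax_max]`` (delays
    themselves need no reconstruction grid: the Laplace kernel is evaluated
    at the exact delay in seconds).  The reconstruction plane is
    ``n_f1_recon`` frequency bins covering the indirect spectral width by
    ``n_r_recon`` decay-rate bins covering ``[r_min, r_max]``.
    """

    n_t1: int = 128
    sw_indirect: float = 3000.0          # Hz
    trelax_min: float = 0.01             # s
    trelax_max: float = 0.8              # s
    trelax_mesh: float = 0.01            # s
    n_f1_recon: int = 256
    n_r_recon: int = 256
    r_min: float = 0.5                   # 1/s
    r_max: float = 5.0                   # 1/s

    def __post_init__(self) -> None:
        if self.n_t1 < 1:
            raise ValueError("n_t1 must be >= 1")
        if self.sw_indirect <= 0:
            raise ValueError("sw_indirect must be > 0")
        if self.trelax_mesh <= 0:
            raise ValueError("trelax_mesh must be > 0")
        if not 0 <= self.trelax_min <= self.trelax_max:
            raise ValueError("need 0 <= trelax_min <= trelax_max")
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")
        if self.n_f1_recon < 1 or self.n_r_recon < 1:
            raise ValueError("reconstruction grid sizes must be >= 1")

    @property
    def t1_times(self) -> np.ndarray:
        """Indirect evolution times in seconds, ``k / sw_indirect``."""
        return np.arange(self.n_t1) / self.sw_indirect

    @property
    def delay_universe(self) -> np.ndarray:
        """All admissible relaxation delays, rounded to 1 microsecond.

        Rounding keeps delays exactly representable in the 6-decimal text
        schedule format, so schedules round-trip bit-exactly.
        """
        n = int(math.floor((self.trelax_max - self.trelax_min) / self.trelax_mesh + 1e-9)) + 1
        return np.round(self.trelax_min + np.arange(n) * self.trelax_mesh, 6)

    def contains_delay(self, trelax: float, tol: float = 1e-9) -> bool:
        return bool(np.any(np.abs(self.delay_universe - trelax) <= tol))

    def contains_frequency(self, freq: float) -> bool:
        return -self.sw_indirect / 2 < freq <= self.sw_indirect / 2


@dataclass(frozen=True)
class NoiseModel:
    """Additive circular complex Gaussian noise.

    ``sigma`` is the standard deviation of the real part and of the
    imaginary part of each sample (so ``E|z|^2 = 2 sigma^2``).  The same
    seed reproduces the same realization bit for bit.
    """

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def sample(self, n: int) -> np.ndarray:
        if self.sigma == 0:
            return np.zeros(n, dtype=complex)
        rng = np.random.default_rng(self.seed)
        return self.sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))


def _peak_arrays(peaks: list[PeakModel]):
    f = np.array([p.freq_indirect for p in peaks], dtype=float)
    lw = np.array([p.linewidth for p in peaks], dtype=float)
    a = np.array([p.amplitude for p in peaks], dtype=float)
    r = np.array([p.rate for p in peaks], dtype=float)
    return f, lw, a, r


def simulate_joint_fid(
    peaks: list[PeakModel],
    geometry: AcquisitionGeometry,
    schedule,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Simulate the complex sample vector for a joint t1/t_relax schedule.

    Entry ``m`` is the superposition over peaks of
    ``a * exp(i 2 pi f t1_m - pi lw t1_m - R trelax_m)`` plus noise, where
    ``t1_m = schedule.t1_indices[m] / sw`` and ``trelax_m`` the scheduled
    delay.  Deterministic given the noise seed.

    Raises
    ------
    ValueError
        If any schedule row lies outside the geometry (the message names
        the offending row).
    """
    schedule.validate_against(geometry)
    t1 = schedule.t1_indices / geometry.sw_indirect
    trel = schedule.delays
    out = np.zeros(schedule.n_points, dtype=complex)
    if peaks:
        f, lw, a, r = _peak_arrays(peaks)
        for p in peaks:
            if not geometry.contains_frequency(p.freq_indirect):
                raise ValueError(
                    f"peak frequency {p.freq_indirect} Hz outside "
                    f"(-{geometry.sw_indirect / 2}, {geometry.sw_indirect / 2}]"
                )
        # (M, N) phase/damping, summed over peaks
        phase = np.exp(
            (2j * np.pi * f[None, :] - np.pi * lw[None, :]) * t1[:, None]
            - r[None, :] * trel[:, None]
        )
        out = phase @ a.astype(complex)
    if noise is not None:
        out = out + noise.sample(schedule.n_points)
    return out


def simulate_full_grid(
    peaks: list[PeakModel],
    geometry: AcquisitionGeometry,
    delays: np.ndarray,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Simulate a fully sampled t1 grid at each given relaxation delay.

    Returns a complex array of shape ``(len(delays), n_t1)`` — the input of
    the conventional (Fourier transform + exponential fit) processing path.
    """
    delays = np.asarray(delays, dtype=float)
    t1 = geometry.t1_times
    out = np.zeros((delays.size, geometry.n_t1), dtype=complex)
    if peaks:
        f, lw, a, r = _peak_arrays(peaks)
        osc = a[:, None] * np.exp((2j * np.pi * f[:, None] - np.pi * lw[:, None]) * t1[None, :])
        dec = np.exp(-r[:, None] * delays[None, :])          # (N, D)
        out = np.einsum("nd,nk->dk", dec, osc)
    if noise is not None:
        flat = noise.sample(out.size)
        out = out + flat.reshape(out.shape)
    return out


def protein_fixture(
    n_peaks: int,
    geometry: AcquisitionGeometry,
    seed: int,
    linewidth_range: tuple[float, float] = (10.0, 30.0),
    rate_margin_frac: float = 0.1,
    max_tries: int = 10_000,
    n_columns: int = 1,
) -> list[PeakModel]:
    """Draw a protein-like peak table: well-separated frequencies, decay
    rates safely inside the reconstruction band, amplitudes within one
    order of magnitude.

    Frequencies are drawn uniformly over the spectral width subject to a
    minimum pairwise separation of two reconstruction bins
    (``2 * sw / n_f1_recon``); rates uniformly in
    ``[r_min + m, r_max - m]`` with margin ``m = rate_margin_frac * band``;
    amplitudes log-uniformly in ``[1, 10]``; linewidths uniformly in
    ``linewidth_range`` (Hz, typical amide 15N values).  Reproducible by
    seed.

    With ``n_columns > 1`` the peaks are tiled round-robin over that many
    direct-dimension columns (``freq_direct`` holds the column index):
    reconstruction is per direct column, and in a real protein HSQC each
    amide 1H column carries only a few 15N peaks.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    sw = geometry.sw_indirect
    min_sep = 2 * sw / geometry.n_f1_recon
    if n_peaks * min_sep >= sw:
        raise ValueError(
            f"cannot place {n_peaks} peaks with separation >= {min_sep:.3g} Hz "
            f"inside a {sw:.3g} Hz window"
        )
    rng = np.random.default_rng(seed)
    freqs: list[float] = []
    tries = 0
    while len(freqs) < n_peaks:
        if tries >= max_tries:
            raise ValueError(
                f"failed to draw {n_peaks} frequencies with separation "
                f">= {min_sep:.3g} Hz after {max_tries} tries"
            )
        cand = float(rng.uniform(-sw / 2, sw / 2))
        if cand <= -sw / 2:
            tries += 1
            continue
        if all(abs(cand - f0) >= min_sep for f0 in freqs):
            freqs.append(cand)
        tries += 1
    band = geometry.r_max - geometry.r_min
    margin = rate_margin_frac * band
    rates = rng.uniform(geometry.r_min + margin, geometry.r_max - margin, n_peaks)
    amps = 10.0 ** rng.uniform(0.0, 1.0, n_peaks)
    lws = rng.uniform(*linewidth_range, n_peaks)
    return [
        PeakModel(freq_indirect=freqs[i], linewidth=float(lws[i]),
                  amplitude=float(amps[i]), rate=float(rates[i]),
                  freq_direct=float(i % n_columns) if n_columns > 1 else None)
        for i in range(n_peaks)
    ]


_PEAK_COLUMNS = ["freq_hz", "linewidth_hz", "amplitude", "rate_hz"]


def write_peak_table(peaks: list[PeakModel], path) -> None:
    """Write a peak table as TSV with header (freq_hz, linewidth_hz, amplitude, rate_hz)."""
    df = pd.DataFrame(
        {
            "freq_hz": [p.freq_indirect for p in peaks],
            "linewidth_hz": [p.linewidth for p in peaks],
            "amplitude": [p.amplitude for p in peaks],
            "rate_hz": [p.rate for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peak_table(path) -> list[PeakModel]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    return [
        PeakModel(
            freq_indirect=float(row.freq_hz),
            linewidth=float(row.linewidth_hz),
            amplitude=float(row.amplitude),
            rate=float(row.rate_hz),
        )
        for row in df.itertuples()
    ]
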