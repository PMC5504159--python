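"""Joint t1/t_relax non-uniform sampling schedules.

A schedule is an ordered list of unique ``(t1 grid index, relaxation
delay)`` pairs drawn from the joint grid ``{0..n_t1-1} x delay_universe``.
Generation is uniform random without replacement — the acquisition
randomizes both the evolution-time index and the relaxation delay on a
fine mesh, so the relaxation decay is sampled extensively even at low
total point counts.  No decay-matched weighting is applied by default
(``t1_weighting`` is a hook for users who want it).

Subsampling uses per-row priorities keyed on ``(seed, t1_index, delay)``:
every row gets a deterministic uniform priority and the ``n`` smallest
survive, original order preserved.  Because priorities depend only on the
seed and the row itself, subsampling is *nested*: taking 200 points and
then 100 from those equals taking 100 directly with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AcquisitionGeometry

__all__ = [
    "JointSchedule",
    "generate_schedule",
    "subsample_schedule",
    "write_schedule",
    "read_schedule",
]


@dataclass(frozen=True)
class JointSchedule:
    """Ordered list of sampled (t1 index, relaxation delay) pairs."""

    t1_indices: np.ndarray   # int, shape (n_points,)
    delays: np.ndarray       # float seconds, shape (n_points,)

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1_indices, dtype=int)
        tr = np.round(np.asarray(self.delays, dtype=float), 6)
        if t1.shape != tr.shape or t1.ndim != 1:
            raise ValueError("t1_indices and delays must be 1-D arrays of equal length")
        object.__setattr__(self, "t1_indices", t1)
        object.__setattr__(self, "delays", tr)
        pairs = set(zip(t1.tolist(), tr.tolist()))
        if len(pairs) != t1.size:
            raise ValueError("duplicate (t1_index, delay) pairs in schedule")

    @property
    def n_points(self) -> int:
        return int(self.t1_indices.size)

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other) -> bool:
        if not isinstance(other, JointSchedule):
            return NotImplemented
        return (
            self.t1_indices.shape == other.t1_indices.shape
            and np.array_equal(self.t1_indices, other.t1_indices)
            and np.array_equal(self.delays, other.delays)
        )

    def validate_against(self, geometry: AcquisitionGeometry) -> None:
        """Reject any row outside the geometry, naming the offending row."""
        universe = geometry.delay_universe
        for m in range(self.n_points):
            k = self.t1_indices[m]
            if not 0 <= k < geometry.n_t1:
                raise ValueError(
                    f"schedule row {m}: t1 index {k} outside 0..{geometry.n_t1 - 1}"
                )
            if not np.any(np.abs(universe - self.delays[m]) <= 1e-9):
                raise ValueError(
                    f"schedule row {m}: delay {self.delays[m]!r} s not in the "
                    f"delay universe [{geometry.trelax_min}, {geometry.trelax_max}] "
                    f"mesh {geometry.trelax_mesh}"
                )


def generate_schedule(
    geometry: AcquisitionGeometry,
    n_points: int,
    seed: int,
    force_anchor: bool = False,
    t1_weighting=None,
) -> JointSchedule:
    """Draw ``n_points`` unique pairs uniformly without replacement from the
    full t1 x delay-universe grid; rows sorted by (t1, delay).

    ``force_anchor=True`` guarantees the (t1=0, smallest delay) point is
    included.  ``t1_weighting`` optionally maps t1 index -> relative weight
    (e.g. exponential decay matching); default is flat.
    """
    universe = geometry.delay_universe
    total = geometry.n_t1 * universe.size
    if n_points > total:
        raise ValueError(f"n_points={n_points} exceeds grid cardinality {total}")
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    rng = np.random.default_rng(seed)
    if t1_weighting is None:
        flat = rng.choice(total, size=n_points, replace=False)
    else:
        w_t1 = np.asarray([t1_weighting(k) for k in range(geometry.n_t1)], dtype=float)
        p = np.repeat(w_t1, universe.size)
        p = p / p.sum()
        flat = rng.choice(total, size=n_points, replace=False, p=p)
    t1_idx = flat // universe.size
    d_idx = flat % universe.size
    if force_anchor and n_points > 0:
        if not np.any((t1_idx == 0) & (d_idx == 0)):
            t1_idx[0], d_idx[0] = 0, 0
    order = np.lexsort((universe[d_idx], t1_idx))
    return JointSchedule(t1_indices=t1_idx[order], delays=universe[d_idx][order])


def _row_priority(seed: int, t1_index: int, delay: float) -> float:
    key = np.random.SeedSequence(entropy=[int(seed), int(t1_index), int(round(delay * 1e6))])
    return float(np.random.default_rng(key).random())


def subsample_schedule(schedule: JointSchedule, n_points: int, seed: int) -> JointSchedule:
    """Uniform random subset of ``n_points`` rows, original order preserved.

    Each row's priority is a deterministic uniform variate keyed on
    ``(seed, t1_index, delay)``; the ``n_points`` lowest-priority rows
    survive.  This makes subsampling chains nested for a fixed seed.
    """
    if n_points > schedule.n_points:
        raise ValueError(
            f"n_points={n_points} exceeds schedule size {schedule.n_points}"
        )
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    prio = np.array(
        [
            _row_priority(seed, schedule.t1_indices[m], schedule.delays[m])
            for m in range(schedule.n_points)
        ]
    )
    keep = np.sort(np.argsort(prio, kind="stable")[:n_points])
    return JointSchedule(
        t1_indices=schedule.t1_indices[keep], delays=schedule.delays[keep]
    )


def write_schedule(schedule: JointSchedule, path) -> None:
    """Write a two-column text schedule: t1 index, delay in seconds (6 decimals)."""
    with open(path, "w") as fh:
        fh.write("# t1_index trelax_s\n")
        for m in range(schedule.n_points):
            fh.write(f"{schedule.t1_indices[m]} {schedule.delays[m]:.6f}\n")


def read_schedule(path) -> JointSchedule:
    """Read a two-column schedule file; '#'-prefixed comment lines permitted.

    Raises ``ValueError`` naming the line number for malformed lines, and
    rejects duplicate pairs.
    """
    t1_idx: list[int] = []
    delays: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                k = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if k < 0:
                raise ValueError(f"line {lineno}: negative t1 index {k}")
            if t < 0:
                raise ValueError(f"line {lineno}: negative delay {t}")
            t1_idx.append(k)
            delays.append(t)
    return JointSchedule(
        t1_indices=np.array(t1_idx, dtype=int), delays=np.array(delays, dtype=float)
    )
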