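"""Portable serialization of sample vectors and spectrum cubes.

NumPy ``.npz`` containers with the axis coordinates embedded, so a file
is self-describing: a cube carries its frequency (Hz) and rate (1/s)
axes, a sample file carries its schedule.
"""

from __future__ import annotations

import numpy as np

from .pipeline import SpectrumCube
from .sampling import JointSchedule

__all__ = ["save_samples", "load_samples", "save_cube", "load_cube"]


def save_samples(path, samples: np.ndarray, schedule: JointSchedule) -> None:
    np.savez(
        path,
        samples=np.asarray(samples, dtype=complex),
        t1_indices=schedule.t1_indices,
        delays=schedule.delays,
    )


def load_samples(path):
    with np.load(path) as z:
        schedule = JointSchedule(t1_indices=z["t1_indices"], delays=z["delays"])
        return z["samples"], schedule


def save_cube(path, cube: SpectrumCube) -> None:
    payload = {
        "data": cube.data,
        "freq_axis": cube.freq_axis,
        "rate_axis": cube.rate_axis,
    }
    if cube.direct_axis is not None:
        payload["direct_axis"] = cube.direct_axis
    np.savez(path, **payload)


def load_cube(path) -> SpectrumCube:
    with np.load(path) as z:
        return SpectrumCube(
            data=z["data"],
            freq_axis=z["freq_axis"],
            rate_axis=z["rate_axis"],
            direct_axis=z["direct_axis"] if "direct_axis" in z.files else None,
        )
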