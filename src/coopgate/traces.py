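"""Time-series containers shared across the package.

All traces carry their sampling interval ``dt`` in seconds. Current is in pA
(inward negative), intracellular calcium in nM, fluorescence in arbitrary
camera units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalciumTrace", "CurrentTrace", "SweepSet", "BleachTrace"]


def _as_1d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D trace, got shape {arr.shape}")
    return arr


@dataclass
class CalciumTrace:
    """[Ca2+]i time course at one sparklet site, in nM."""

    values: np.ndarray
    dt: float
    site_id: str = ""
    origin: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = _as_1d(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass
class CurrentTrace:
    """Membrane current in pA; depolarization onset at t = 0."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = _as_1d(self.values)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass
class SweepSet:
    """Repeated single-channel sweeps at one test potential.

    ``sweeps`` is an (n_sweeps, n_frames) array of currents in pA.
    """

    sweeps: np.ndarray
    dt: float
    voltage: float = float("nan")

    def __post_init__(self):
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_frames(self) -> int:
        return self.sweeps.shape[1]


@dataclass
class BleachTrace:
    """Summed ROI intensity versus frame for one photobleaching spot."""

    values: np.ndarray
    dt: float = 1.0
    roi_center: tuple[int, int] | None = None

    def __post_init__(self):
        self.values = _as_1d(self.values)

    def __len__(self) -> int:
        return self.values.size
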