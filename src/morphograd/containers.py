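"""In-memory containers for concentration profiles and space-time fields."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ModelParameters

__all__ = ["ConcentrationProfile", "SpaceTimeField"]


@dataclass
class ConcentrationProfile:
    """One spatial concentration profile c(x) at time t on [0, L]."""

    t: float
    L: float
    x: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.c.shape:
            raise ValueError("x and c must be 1D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.x[0] < 0 or self.x[-1] > self.L * (1 + 1e-12):
            raise ValueError("x must lie within [0, L]")

    def interp(self, xq) -> np.ndarray:
        """Piecewise-linear interpolation of c at query positions."""
        return np.interp(xq, self.x, self.c)


@dataclass
class SpaceTimeField:
    """Stack of profiles on a common (strictly increasing) time grid."""

    times: np.ndarray
    profiles: Sequence[ConcentrationProfile]
    params: Optional[ModelParameters] = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.profiles) != self.times.size:
            raise ValueError("need one profile per time")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for t, p in zip(self.times, self.profiles):
            if not np.isclose(p.t, t, rtol=1e-12, atol=1e-12):
                raise ValueError("profile times must match the time grid")
        lengths = [p.L for p in self.profiles]
        if np.any(np.diff(lengths) < -1e-12):
            raise ValueError("domain lengths must be nondecreasing in time")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self):
        return iter(self.profiles)
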