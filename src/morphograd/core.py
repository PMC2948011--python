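"""Model parameters and growth kinematics for a 1D tissue elongating by cell
proliferation.

The tissue occupies [0, L(t)].  A morphogen-encoding gene is transcribed in a
fixed zone [0, w) at the left end with source strength ``S``; transcripts
degrade at rate ``k``.  Cell proliferation (local relative growth rate ``d``)
drives both advection and dilution of the per-length transcript concentration.
Two proliferation modes are supported:

* ``localized`` — divisions confined to the transcription zone.  Material is
  pushed out of the zone at speed ``d*w`` and the tissue grows linearly,
  ``L(t) = L0 + d*w*t``.
* ``uniform`` — divisions everywhere, giving ``v = d*x`` and exponential
  growth, ``L(t) = L0 * exp(d*t)``.

The zone predicate is half-open: source and localized dilution act for
``x < w`` and are off for ``x >= w``; the single boundary point is measure
zero and closed-form branch values at ``x = w`` are one-sided limits.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

__all__ = [
    "Mode",
    "ModelParameters",
    "tissue_length",
    "velocity",
    "dilution_rate",
    "nondimensional_preset",
    "somitogenesis_preset",
]


class Mode(str, enum.Enum):
    """Spatial distribution of cell proliferation."""

    LOCALIZED = "localized"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the growth/transcription model.

    Parameters
    ----------
    S : float
        Transcription source strength inside the zone, concentration/time.
    d : float
        Local relative proliferation rate, 1/time.  Must be positive: with
        no proliferation there is no advection or dilution and the mechanism
        modelled here is absent.
    k : float
        First-order mRNA degradation rate, 1/time.
    w : float
        Transcription-zone length.
    L0 : float
        Initial tissue length; must satisfy ``L0 >= w``.
    C0 : float
        Uniform initial transcript concentration.
    mode : Mode
        Proliferation mode, localized or uniform.
    """

    S: float
    d: float
    k: float
    w: float
    L0: float
    C0: float
    mode: Mode

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not self.S >= 0:
            raise ValueError(f"S must be >= 0, got {self.S}")
        if not self.d > 0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if not self.k >= 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not self.w > 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if not self.L0 >= self.w:
            raise ValueError(f"L0 must be >= w, got L0={self.L0}, w={self.w}")
        if not self.C0 >= 0:
            raise ValueError(f"C0 must be >= 0, got {self.C0}")

    @property
    def equilibrium(self) -> float:
        """In-zone equilibrium concentration C_E = S/(d+k)."""
        return self.S / (self.d + self.k)

    def to_dict(self) -> dict:
        rec = asdict(self)
        rec["mode"] = self.mode.value
        return rec

    @classmethod
    def from_dict(cls, rec: dict) -> "ModelParameters":
        required = {"mode", "S", "d", "k", "w", "L0", "C0"}
        missing = required - rec.keys()
        if missing:
            raise ValueError(
                "missing required field(s): " + ", ".join(sorted(missing))
            )
        extra = rec.keys() - required
        if extra:
            raise ValueError("unknown field(s): " + ", ".join(sorted(extra)))
        return cls(
            S=float(rec["S"]),
            d=float(rec["d"]),
            k=float(rec["k"]),
            w=float(rec["w"]),
            L0=float(rec["L0"]),
            C0=float(rec["C0"]),
            mode=Mode(rec["mode"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def nondimensional_preset(
    mode: Union[Mode, str] = Mode.LOCALIZED, *, k: float = 0.0, C0: float = 0.0
) -> ModelParameters:
    """Reference nondimensional parameter set: S = d = w = L0 = 1.

    Time is measured in units of 1/d and length in units of w; the qualitative
    regime is then fixed entirely by C0 (relative to C_E and S/d) and by k/d,
    which are left as knobs.
    """
    return ModelParameters(S=1.0, d=1.0, k=k, w=1.0, L0=1.0, C0=C0, mode=Mode(mode))


def somitogenesis_preset(mode: Union[Mode, str] = Mode.LOCALIZED) -> ModelParameters:
    """Dimensional parameter set for the vertebrate somitogenesis FGF8 gradient.

    Lengths in micrometres, time in minutes, concentration in arbitrary units.
    Axis elongation speed d*w is set to 125/90 um/min (one mid-range somite of
    ~125 um laid down per ~90 min period, consistent with chick, zebrafish,
    snake and mouse rates of ~1-1.4 um/min); the transcription/progenitor zone
    is taken as w = 200 um, of the order of the tail-bud region, giving
    d ~ 6.9e-3 per min.  Transcript half-life of 2 h gives k = ln2/120 per min.
    The source strength sets the concentration scale and is arbitrary.
    """
    w = 200.0
    d = (125.0 / 90.0) / w
    return ModelParameters(
        S=1.0,
        d=d,
        k=math.log(2.0) / 120.0,
        w=w,
        L0=w,
        C0=0.0,
        mode=Mode(mode),
    )


def tissue_length(params: ModelParameters, t):
    """Tissue length L(t).

    Linear growth ``L0 + d*w*t`` for localized proliferation, exponential
    growth ``L0*exp(d*t)`` for uniform proliferation.  Accepts scalar or
    array ``t >= 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.mode is Mode.LOCALIZED:
        out = params.L0 + params.d * params.w * t
    else:
        out = params.L0 * np.exp(params.d * t)
    return out if out.ndim else float(out)


def velocity(params: ModelParameters, x, t=None):
    """Tissue velocity field v(x) induced by proliferation.

    Localized mode: ``v = d*x`` inside the zone, constant ``d*w`` beyond it
    (material is pushed out of the zone at the elongation speed).  Uniform
    mode: ``v = d*x`` everywhere.  v(0) = 0 and v(L(t)) = dL/dt, so the
    domain edge is a material point and no-flux boundaries hold automatically.

    ``t`` is only used to validate that x lies within the current domain;
    pass ``t=None`` to skip the upper-bound check.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if t is not None:
        L = tissue_length(params, t)
        if np.any(x > L * (1 + 1e-12)):
            raise ValueError(f"x outside the domain [0, L(t)={L}]")
    if params.mode is Mode.LOCALIZED:
        out = params.d * np.minimum(x, params.w)
    else:
        out = params.d * x
    return out if out.ndim else float(out)


def dilution_rate(params: ModelParameters, x):
    """Local dilution rate dv/dx at position x.

    This is the reaction-like sink produced by cell division splitting
    transcripts between daughters: ``d`` inside the proliferative region,
    zero outside it (localized mode), ``d`` everywhere (uniform mode).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if params.mode is Mode.LOCALIZED:
        out = np.where(x < params.w, params.d, 0.0)
    else:
        out = np.full_like(x, params.d)
    return out if out.ndim else float(out)
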