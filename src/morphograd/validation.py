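"""Regime grid and closed-form-vs-characteristics certification.

The closed forms in :mod:`morphograd.analytic` were derived by hand, so the
package treats them as untrusted until they match the independent Lagrangian
solver on a grid of parameter sets spanning every qualitative regime: both
proliferation modes, no/moderate/strong degradation (k/d = 0, 1/2, 2), the
full range of initial conditions relative to C_E and S/d, and a partial-zone
(w < L0) case per mode.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from . import analytic
from .characteristics import SolverSettings, solve
from .core import Mode, ModelParameters

__all__ = ["regime_grid", "oracle_max_error", "validate_grid"]

DEFAULT_TIMES = (0.25, 1.0, 4.0)


def regime_grid() -> List[ModelParameters]:
    """Parameter sets spanning the model's qualitative regimes (S = d = 1,
    w = L0 = 1 except the two partial-zone cases; time in 1/d, length in w)."""
    out = []
    for mode in (Mode.LOCALIZED, Mode.UNIFORM):
        for k in (0.0, 0.5, 2.0):
            CE = 1.0 / (1.0 + k)  # S/(d+k)
            c0s = {0.0, CE, (CE + 1.0) / 2.0, 2.0}  # 2 = 2*S/d; set dedups
            for C0 in sorted(c0s):
                out.append(
                    ModelParameters(S=1.0, d=1.0, k=k, w=1.0, L0=1.0, C0=C0, mode=mode)
                )
    # partial transcription zone: part of the tissue never transcribes
    out.append(
        ModelParameters(S=1.0, d=1.0, k=0.5, w=0.5, L0=1.0, C0=0.5, mode=Mode.LOCALIZED)
    )
    out.append(
        ModelParameters(S=1.0, d=1.0, k=0.5, w=0.5, L0=1.0, C0=0.5, mode=Mode.UNIFORM)
    )
    return out


def oracle_max_error(
    params: ModelParameters,
    times: Sequence[float] = DEFAULT_TIMES,
    n_particles: int = 128,
) -> float:
    """Max scale-relative deviation between the closed form and the
    characteristics solver at particle positions.

    The deviation at each particle is normalised by the profile's
    concentration scale rather than pointwise: at the moving fronts the
    closed form evaluates to zero through cancellation of exponentials, so a
    pointwise quotient would compare rounding residue against zero.
    """
    solve_times = np.unique(np.concatenate([[0.0], np.asarray(times, dtype=float)]))
    fld = solve(params, SolverSettings(n_particles=n_particles), solve_times)
    worst = 0.0
    for p in fld.profiles:
        exact = analytic.concentration(params, p.x, p.t)
        scale = max(float(np.max(np.abs(exact))), params.C0, params.equilibrium, 1e-300)
        worst = max(worst, float(np.max(np.abs(exact - p.c))) / scale)
    return worst


def validate_grid(
    times: Sequence[float] = DEFAULT_TIMES,
    n_particles: int = 128,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Run the certification over the full regime grid.

    Returns one row per parameter set with its max deviation and pass flag.
    """
    rows = []
    for params in regime_grid():
        err = oracle_max_error(params, times, n_particles)
        rows.append(
            {
                "mode": params.mode.value,
                "k": params.k,
                "C0": params.C0,
                "w": params.w,
                "L0": params.L0,
                "max_rel_error": err,
                "passed": err <= tol,
            }
        )
    return pd.DataFrame(rows)
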