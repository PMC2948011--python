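"""Closed-form solutions of the transcript conservation law and derived
profile features.

The per-length transcript concentration c(x, t) on the growing domain obeys

    dc/dt + d(v c)/dx = S * 1[x < w] - k * c,      c(x, 0) = C0,

with the proliferation-induced velocity v from :mod:`morphograd.core`.  Both
proliferation modes admit exact solutions by integrating along characteristics
(material trajectories dx/dt = v), because v is piecewise linear in x with
constant coefficients in each region.

Localized proliferation (elongation speed d*w, linear growth):

* in zone, x < w:                 c = C_E + (C0 - C_E) e^{-(d+k) t}
* zone-derived, w <= x <= w+dwt:  with s = (x - w)/(d w) the time since the
  material left the zone,
                                  c = C_E e^{-k s} + (C0 - C_E) e^{-(d+k) t} e^{d s}
* never-transcribing material, x > w + dwt (exists only when w < L0):
                                  c = C0 e^{-k t}

Uniform proliferation (exponential growth):

* in zone, x < w:                 c = C_E + (C0 - C_E) e^{-(d+k) t}
* zone-derived, w <= x <= w e^{dt}:
                                  c = C_E (w/x)^{(d+k)/d} + (C0 - C_E) e^{-(d+k) t}
* beyond, x > w e^{dt} (w < L0): c = C0 e^{-(d+k) t}

with the in-zone equilibrium C_E = S/(d+k).  All branches join continuously.

Shape diagnostics in the localized case (zone-derived region, as functions of
the exit-age coordinate s):

* interior minimum: for k > 0 and C0 > S/d the profile develops a local
  minimum after the critical time
      t_c = ln[ d (C0 - C_E) / (k C_E) ] / (d + k),
  located at x_min = w (1 + d (t - t_c)) and advancing at speed d*w.
* inflection: for k > 0 and d^2 (C_E - C0) > k^2 C_E the initially
  concave-down profile develops a concave-up region at the zone edge after
      t_i = ln[ d^2 (C_E - C0) / (k^2 C_E) ] / (d + k),
  the inflection sitting at x_i = w (1 + d (t - t_i)).
* endpoint curvatures (w = L0): second x-derivative equals
  [k^2 C_E + d^2 (C0 - C_E) e^{-(d+k) t}] / (d w)^2 at the zone edge and
  e^{-k t} [k^2 C_E + d^2 (C0 - C_E)] / (d w)^2 at the tissue edge; the
  tissue-edge sign is time-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .containers import ConcentrationProfile, SpaceTimeField
from .core import Mode, ModelParameters, tissue_length

__all__ = [
    "CriticalFeatures",
    "equilibrium_concentration",
    "concentration",
    "concentration_localized",
    "concentration_uniform",
    "critical_min_features",
    "inflection_features",
    "endpoint_curvature",
    "evaluate_profile",
    "evaluate_field",
    "total_transcripts",
]


def equilibrium_concentration(params: ModelParameters) -> float:
    """In-zone equilibrium concentration C_E = S/(d+k), either mode."""
    return params.equilibrium


def _check_domain(params: ModelParameters, x: np.ndarray, t: float) -> float:
    L = float(tissue_length(params, t))
    if np.any(x < 0) or np.any(x > L * (1 + 1e-12)):
        raise ValueError(f"x outside the current domain [0, {L}]")
    return L


def concentration_localized(params: ModelParameters, x, t: float):
    """Exact concentration for localized proliferation; scalar or array x."""
    if params.mode is not Mode.LOCALIZED:
        raise ValueError("params.mode must be localized")
    x = np.asarray(x, dtype=float)
    _check_domain(params, x, t)
    S, d, k, w, C0 = params.S, params.d, params.k, params.w, params.C0
    CE = params.equilibrium
    transient = (C0 - CE) * np.exp(-(d + k) * t)

    s = (x - w) / (d * w)  # time since leaving the zone (x >= w)
    front = w + d * w * t  # trajectory of material initially at x = w
    out = np.where(
        x < w,
        CE + transient,
        np.where(
            x <= front * (1 + 1e-12),
            CE * np.exp(-k * np.maximum(s, 0.0))
            + transient * np.exp(d * np.maximum(s, 0.0)),
            C0 * np.exp(-k * t),
        ),
    )
    return out if out.ndim else float(out)


def concentration_uniform(params: ModelParameters, x, t: float):
    """Exact concentration for uniformly distributed proliferation."""
    if params.mode is not Mode.UNIFORM:
        raise ValueError("params.mode must be uniform")
    x = np.asarray(x, dtype=float)
    _check_domain(params, x, t)
    d, k, w, C0 = params.d, params.k, params.w, params.C0
    CE = params.equilibrium
    transient = (C0 - CE) * np.exp(-(d + k) * t)

    front = w * np.exp(d * t)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, w / np.maximum(x, 1e-300), np.inf)
    out = np.where(
        x < w,
        CE + transient,
        np.where(
            x <= front * (1 + 1e-12),
            CE * np.minimum(ratio, 1.0) ** ((d + k) / d) + transient,
            C0 * np.exp(-(d + k) * t),
        ),
    )
    return out if out.ndim else float(out)


def concentration(params: ModelParameters, x, t: float):
    """Mode-dispatching exact concentration."""
    if params.mode is Mode.LOCALIZED:
        return concentration_localized(params, x, t)
    return concentration_uniform(params, x, t)


@dataclass(frozen=True)
class CriticalFeatures:
    """Interior-minimum and inflection diagnostics of a localized profile.

    ``t_c``/``t_i`` are onset times; ``x_min``/``x_i`` are positions at the
    query time and are ``None`` before onset (or where a feature's regime
    condition fails, flagged by ``exists_min``/``exists_inflection``).
    """

    exists_min: bool
    t_c: Optional[float] = None
    x_min: Optional[float] = None
    exists_inflection: bool = False
    t_i: Optional[float] = None
    x_i: Optional[float] = None


def _feature_position(params: ModelParameters, t: float, t_onset: float) -> Optional[float]:
    if t <= t_onset:
        return None
    pos = params.w * (1.0 + params.d * (t - t_onset))
    L = float(tissue_length(params, t))
    if pos > L:  # formula landed beyond the tissue: not yet inside the domain
        return None
    return pos


def critical_min_features(params: ModelParameters, t: float) -> CriticalFeatures:
    """Interior-minimum regime test and location (localized mode).

    A local minimum exists (for t > t_c) iff k > 0 and C0 > S/d, i.e. the
    initial concentration exceeds what the source can sustain against
    dilution alone.
    """
    if params.mode is not Mode.LOCALIZED:
        raise ValueError("critical-minimum analysis applies to localized mode")
    S, d, k, C0 = params.S, params.d, params.k, params.C0
    CE = params.equilibrium
    if k <= 0 or not d * (C0 - CE) > k * CE:  # d(C0-CE) > k CE  <=>  C0 > S/d
        return CriticalFeatures(exists_min=False)
    t_c = np.log(d * (C0 - CE) / (k * CE)) / (d + k)
    return CriticalFeatures(
        exists_min=True, t_c=float(t_c), x_min=_feature_position(params, t, t_c)
    )


def inflection_features(params: ModelParameters, t: float) -> CriticalFeatures:
    """Inflection regime test and location (localized mode).

    The concavity change exists (for t > t_i) iff k > 0 and
    d^2 (C_E - C0) > k^2 C_E; before t_i the exterior profile is concave
    down throughout, after t_i it is concave up at the zone edge and concave
    down beyond x_i.
    """
    if params.mode is not Mode.LOCALIZED:
        raise ValueError("inflection analysis applies to localized mode")
    d, k, C0 = params.d, params.k, params.C0
    CE = params.equilibrium
    if k <= 0 or not d * d * (CE - C0) > k * k * CE:
        return CriticalFeatures(exists_min=False, exists_inflection=False)
    t_i = np.log(d * d * (CE - C0) / (k * k * CE)) / (d + k)
    return CriticalFeatures(
        exists_min=False,
        exists_inflection=True,
        t_i=float(t_i),
        x_i=_feature_position(params, t, t_i),
    )


def endpoint_curvature(params: ModelParameters, t: float) -> Tuple[float, float]:
    """Second x-derivative of the localized solution at both exterior endpoints.

    Returns ``(curvature at x = w+, curvature at x = L(t))``.  Requires
    w == L0 so the whole exterior is zone-derived material.  The sign pair
    determines the concavity regime; the tissue-edge sign never changes with
    time.
    """
    if params.mode is not Mode.LOCALIZED:
        raise ValueError("endpoint curvature applies to localized mode")
    if not np.isclose(params.w, params.L0):
        raise ValueError("endpoint curvature requires w == L0")
    d, k, w, C0 = params.d, params.k, params.w, params.C0
    CE = params.equilibrium
    inv = 1.0 / (d * w) ** 2
    zone_edge = inv * (k * k * CE + d * d * (C0 - CE) * np.exp(-(d + k) * t))
    tissue_edge = inv * np.exp(-k * t) * (k * k * CE + d * d * (C0 - CE))
    return float(zone_edge), float(tissue_edge)


def evaluate_profile(
    params: ModelParameters, t: float, n_points: int = 201
) -> ConcentrationProfile:
    """Sample the exact solution on an n-point grid spanning [0, L(t)]."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    L = float(tissue_length(params, t))
    x = np.linspace(0.0, L, n_points)
    return ConcentrationProfile(t=float(t), L=L, x=x, c=concentration(params, x, t))


def evaluate_field(
    params: ModelParameters, times: Sequence[float], n_points: int = 201
) -> SpaceTimeField:
    """Sample the exact solution at several times (one growing grid per time)."""
    times = np.asarray(times, dtype=float)
    profiles = [evaluate_profile(params, float(t), n_points) for t in times]
    return SpaceTimeField(times=times, profiles=profiles, params=params)


def total_transcripts(params: ModelParameters, t: float) -> float:
    """Total transcript amount M(t) = integral of c over [0, L(t)].

    Advection and dilution conserve mass, so M obeys dM/dt = S w - k M with
    M(0) = C0 L0, independent of proliferation mode.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    Sw = params.S * params.w
    M0 = params.C0 * params.L0
    if params.k == 0:
        return M0 + Sw * t
    Minf = Sw / params.k
    return float(Minf + (M0 - Minf) * np.exp(-params.k * t))
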