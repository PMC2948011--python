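"""Inference of the proliferation mode from concentration profiles.

Given one or more transcript concentration profiles on the region outside the
transcription zone, the qualitative shape of the profiles constrains where
cell division occurs:

* localized proliferation if the concentration increases away from the zone
  (rule L1, which also covers the interior-minimum regime), or decreases but
  is concave down sufficiently far from the zone (L2), or is steady in time
  and decays exponentially with distance (L3);
* uniformly distributed proliferation if the concentration decreases away
  from the zone, is concave up, and grows in time at fixed position with a
  spatially uniform increment (U1), or is steady and decays as a negative
  power of distance (U2);
* indeterminate when the profile decreases, is concave up and decays in time
  (I1) — localized and uniform proliferation both produce this pattern.

Rule U1 carries one refinement over a purely qualitative reading: localized
proliferation with strong degradation (k^2 C_E >= d^2 (C_E - C0), C0 < C_E)
also yields decreasing, concave-up profiles that grow in time.  The two cases
separate through the spatial structure of the inter-time increment
c(x, t2) - c(x, t1): under uniform proliferation the transient is spatially
constant outside the zone, so the increment is flat in x, whereas under
localized proliferation the transient is amplified by e^{d s} toward the
tissue edge.  An increment growing with distance therefore fires the
localized rule L4; U1 requires a flat increment.

All shape calls are invariant to rescaling the concentration axis: every
threshold is relative to the profile maximum (dead-band fraction ``tol``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import analytic
from .containers import ConcentrationProfile, SpaceTimeField
from .core import ModelParameters

__all__ = [
    "Monotonicity",
    "Concavity",
    "TimeTrend",
    "DecayLaw",
    "ShapeSummary",
    "ClassificationResult",
    "summarize_shape",
    "infer_proliferation_mode",
    "generate_noisy_fixture",
]

DEFAULT_TOL = 1e-3  # dead-band fraction for noiseless model output


class Monotonicity(str, enum.Enum):
    DECREASING = "decreasing"
    INCREASING = "increasing"
    LOCAL_MINIMUM = "local_minimum"
    FLAT = "flat"


class Concavity(str, enum.Enum):
    UP_THROUGHOUT = "up_throughout"
    DOWN_THROUGHOUT = "down_throughout"
    UP_THEN_DOWN = "up_then_down"
    DOWN_THEN_UP = "down_then_up_equiv_min"


class TimeTrend(str, enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    CONSTANT = "constant"
    UNKNOWN = "unknown"


class DecayLaw(str, enum.Enum):
    EXPONENTIAL = "exponential"
    POWER = "power"
    NEITHER = "neither"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class ShapeSummary:
    """Qualitative shape of one exterior profile (x > zone length)."""

    t: float
    monotonicity: Monotonicity
    concavity: Concavity
    time_trend: TimeTrend
    decay_law: DecayLaw
    decay_rate: Optional[float] = None       # exponential: c ~ e^{-rate * x}
    decay_exponent: Optional[float] = None   # power: c ~ x^{exponent}
    residual_exponential: Optional[float] = None
    residual_power: Optional[float] = None
    far_field_sign: int = 0                  # sign of curvature near tissue edge

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "monotonicity": self.monotonicity.value,
            "concavity": self.concavity.value,
            "time_trend": self.time_trend.value,
            "decay_law": self.decay_law.value,
            "decay_rate": self.decay_rate,
            "decay_exponent": self.decay_exponent,
            "residual_exponential": self.residual_exponential,
            "residual_power": self.residual_power,
            "far_field_sign": self.far_field_sign,
        }


@dataclass
class ClassificationResult:
    mode_inferred: str                     # localized | uniform | indeterminate
    rule_fired: str                        # L1 L2 L3 L4 U1 U2 I1
    features: List[ShapeSummary] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode_inferred": self.mode_inferred,
            "rule_fired": self.rule_fired,
            "features": [s.to_dict() for s in self.features],
        }


# ---------------------------------------------------------------------------
# shape primitives


def _exterior(profile: ConcentrationProfile, zone_length: float):
    mask = profile.x > zone_length * (1 + 1e-9)
    x, c = profile.x[mask], profile.c[mask]
    if x.size < 8:
        raise ValueError(
            f"need >= 8 exterior points beyond x = {zone_length}, got {x.size}"
        )
    return x, c


def _bin_means(x: np.ndarray, c: np.ndarray, m: int):
    idx = np.array_split(np.arange(x.size), m)
    bx = np.array([x[i].mean() for i in idx])
    bc = np.array([c[i].mean() for i in idx])
    return bx, bc


def _monotonicity(x, c, tol: float, cmax: float) -> Monotonicity:
    """Monotonicity pattern from binned means and cumulative drop/rise.

    The decision uses the total descent to, and ascent from, the smallest
    binned value rather than bin-to-bin differences: a shallow interior dip
    spreads over many bins, so cumulative changes carry the signal while
    per-bin differences drown in the dead-band.
    """
    m = int(np.clip(x.size // 8, 8, 24))
    m = min(m, x.size)
    _, bc = _bin_means(x, c, m)
    band = tol * cmax
    if np.max(bc) - np.min(bc) < band:
        return Monotonicity.FLAT
    imin = int(np.argmin(bc))
    lead_drop = bc[0] - bc[imin]
    tail_rise = bc[-1] - bc[imin]
    if 0 < imin < m - 1 and lead_drop > band and tail_rise > band:
        return Monotonicity.LOCAL_MINIMUM
    net = bc[-1] - bc[0]
    if net < -band and tail_rise <= band:
        return Monotonicity.DECREASING
    if net > band and lead_drop <= band:
        return Monotonicity.INCREASING
    if net < -band:
        return Monotonicity.DECREASING
    if net > band:
        return Monotonicity.INCREASING
    return Monotonicity.FLAT


def _curvature_sign(x, c, tol: float) -> int:
    """Sign of profile curvature over a window, via a quadratic fit.

    Decided (+/-1) when the parabola's sagitta — its maximum deviation from
    the chord, |a| W^2 / 4 for fitted curvature 2a over width W — exceeds the
    dead-band ``tol`` times the window's own concentration scale; 0 otherwise.
    Scaling the band with the local maximum keeps the test meaningful in the
    far field where the absolute concentration is small, and matches the
    multiplicative character of measurement noise.
    """
    if x.size < 5:
        return 0
    coeffs = np.polyfit(x, c, 2)
    width = x[-1] - x[0]
    sagitta = abs(coeffs[0]) * width**2 / 4.0
    scale = np.max(np.abs(c))
    if scale <= 0 or sagitta <= tol * scale:
        return 0
    return 1 if coeffs[0] > 0 else -1


def _concavity(x, c, tol: float) -> tuple:
    """(pattern, far-field sign): halves give the pattern, the outer quarter
    the far-field sign used by rule L2."""
    half = x.size // 2
    inner = _curvature_sign(x[:half], c[:half], tol)
    outer = _curvature_sign(x[half:], c[half:], tol)
    quarter = max(5, x.size // 4)
    far = _curvature_sign(x[-quarter:], c[-quarter:], tol)
    if inner >= 0 and outer >= 0 and (inner > 0 or outer > 0):
        pattern = Concavity.UP_THROUGHOUT
    elif inner <= 0 and outer <= 0 and (inner < 0 or outer < 0):
        pattern = Concavity.DOWN_THROUGHOUT
    elif inner > 0 and outer < 0:
        pattern = Concavity.UP_THEN_DOWN
    elif inner < 0 and outer > 0:
        pattern = Concavity.DOWN_THEN_UP
    else:
        pattern = Concavity.UP_THROUGHOUT  # undecided; flat profiles land here
    return pattern, far


def _decay_fit(x, c, tol: float) -> dict:
    """Straight-line fits of log c vs x (exponential) and log c vs log x
    (power) on the exterior; the smaller RMS residual picks the law."""
    pos = c > 0
    x, c = x[pos], c[pos]
    out = {
        "law": DecayLaw.NEITHER,
        "rate": None,
        "exponent": None,
        "res_exp": None,
        "res_pow": None,
    }
    if x.size < 8:
        return out
    logc = np.log(c)
    be = np.polyfit(x, logc, 1)
    res_e = float(np.sqrt(np.mean((np.polyval(be, x) - logc) ** 2)))
    bp = np.polyfit(np.log(x), logc, 1)
    res_p = float(np.sqrt(np.mean((np.polyval(bp, np.log(x)) - logc) ** 2)))
    out.update(rate=float(-be[0]), exponent=float(bp[0]),
               res_exp=res_e, res_pow=res_p)
    if min(res_e, res_p) > max(0.05, 3 * tol):
        out["law"] = DecayLaw.NEITHER
    elif res_e <= res_p:
        out["law"] = DecayLaw.EXPONENTIAL
    else:
        out["law"] = DecayLaw.POWER
    return out


# ---------------------------------------------------------------------------
# field-level helpers


def _field_scale(field: SpaceTimeField, zone_length: float) -> float:
    return max(
        float(np.max(np.abs(_exterior(p, zone_length)[1]))) for p in field.profiles
    )


def _pair_increment(p_early: ConcentrationProfile, p_late: ConcentrationProfile,
                    zone_length: float):
    """c(x, t_late) - c(x, t_early) on their common exterior (w, L(t_early)].

    Query positions are taken from the later profile's own grid, where its
    values are exact; only the earlier profile — whose grid is finer there,
    since its domain is shorter — is interpolated.  Interpolating the coarse
    late-time grid instead would bias the increment upward on concave-up
    profiles (chords of a convex curve lie above it).
    """
    lo = zone_length * (1 + 1e-9)
    hi = p_early.L * (1 + 1e-12)
    xg = p_late.x[(p_late.x > lo) & (p_late.x <= hi)]
    if xg.size < 6:
        xg = _exterior(p_early, zone_length)[0]
    return xg, p_late.interp(xg) - p_early.interp(xg)


def _increments(field: SpaceTimeField, zone_length: float):
    """Consecutive-pair increments, each on its own common exterior grid."""
    pairs = zip(field.profiles[:-1], field.profiles[1:])
    return [_pair_increment(a, b, zone_length) for a, b in pairs]


def _time_trend(field: SpaceTimeField, zone_length: float, tol: float) -> TimeTrend:
    if len(field) < 2:
        return TimeTrend.UNKNOWN
    cmax = _field_scale(field, zone_length)
    band = tol * cmax
    trends = []
    for _, dlt in _increments(field, zone_length):
        # average in thirds to suppress pointwise noise
        parts = [seg.mean() for seg in np.array_split(dlt, 3)]
        if max(abs(p) for p in parts) < band:
            trends.append(TimeTrend.CONSTANT)
        elif float(np.mean(dlt)) > 0:
            trends.append(TimeTrend.INCREASING)
        else:
            trends.append(TimeTrend.DECREASING)
    if all(tr is TimeTrend.CONSTANT for tr in trends):
        return TimeTrend.CONSTANT
    moving = [tr for tr in trends if tr is not TimeTrend.CONSTANT]
    if all(tr is TimeTrend.INCREASING for tr in moving):
        return TimeTrend.INCREASING
    if all(tr is TimeTrend.DECREASING for tr in moving):
        return TimeTrend.DECREASING
    return TimeTrend.UNKNOWN


def summarize_shape(
    fld: SpaceTimeField,
    zone_length: float,
    tol: float = DEFAULT_TOL,
    assume_steady: bool = False,
) -> List[ShapeSummary]:
    """Qualitative shape summary of each profile's exterior region.

    ``tol`` is the dead-band fraction: differences smaller than
    ``tol * max|c|`` count as zero.  Use ~3x the measurement coefficient of
    variation for noisy data.  The decay-law fit is only attempted when the
    field is steady in time (or ``assume_steady`` is set): a transient
    profile follows neither pure law.
    """
    if not 0 < tol <= 0.1:
        raise ValueError("tol must be in (0, 0.1]")
    if len(fld) == 0:
        raise ValueError("field has no profiles")
    trend = _time_trend(fld, zone_length, tol)
    cmax = _field_scale(fld, zone_length)
    steady = assume_steady or trend is TimeTrend.CONSTANT
    out = []
    for p in fld.profiles:
        x, c = _exterior(p, zone_length)
        mono = _monotonicity(x, c, tol, cmax)
        conc, far = _concavity(x, c, tol)
        summary = ShapeSummary(
            t=p.t,
            monotonicity=mono,
            concavity=conc,
            time_trend=trend,
            decay_law=DecayLaw.NOT_APPLICABLE,
            far_field_sign=far,
        )
        if steady and mono is not Monotonicity.FLAT:
            fit = _decay_fit(x, c, tol)
            summary.decay_law = fit["law"]
            summary.decay_rate = fit["rate"]
            summary.decay_exponent = fit["exponent"]
            summary.residual_exponential = fit["res_exp"]
            summary.residual_power = fit["res_pow"]
        out.append(summary)
    return out


# ---------------------------------------------------------------------------
# classification


def _increment_shape(field: SpaceTimeField, zone_length: float, tol: float) -> str:
    """'flat', 'amplified' or 'unclear': spatial structure of the largest
    inter-time increment (see module docstring, rules U1 vs L4)."""
    deltas = [dlt for _, dlt in _increments(field, zone_length)]
    best = max(deltas, key=lambda dlt: float(np.mean(np.abs(dlt))))
    thirds = np.array_split(np.abs(best), 3)
    near, farv = float(thirds[0].mean()), float(thirds[-1].mean())
    floor = tol * _field_scale(field, zone_length)
    if near < floor or farv < floor:
        return "unclear"
    ratio = farv / near
    gamma = max(0.10, 5 * tol)
    if ratio > 1 + gamma:
        return "amplified"
    if 1 / (1 + gamma / 2) <= ratio <= 1 + gamma / 2:
        return "flat"
    return "unclear"


def _majority(values, targets) -> bool:
    hits = sum(1 for v in values if v in targets)
    return hits * 2 > len(values)


def infer_proliferation_mode(
    fld: SpaceTimeField,
    zone_length: float,
    tol: float = DEFAULT_TOL,
    assume_steady: bool = False,
) -> ClassificationResult:
    """Classify the proliferation mode from profile shape, first-match rules
    L1, L2, L3, U1, U2, L4, then I1 (indeterminate).

    Single-profile input can fire L1/L2; the steady-profile rules L3/U2
    additionally require either several times showing no change or an
    explicit ``assume_steady`` from the caller.  Rules U1/L4 need at least
    two times.
    """
    summaries = summarize_shape(fld, zone_length, tol, assume_steady=assume_steady)
    monos = [s.monotonicity for s in summaries]
    trend = summaries[0].time_trend
    steady = assume_steady or trend is TimeTrend.CONSTANT

    def result(mode: str, rule: str) -> ClassificationResult:
        return ClassificationResult(mode_inferred=mode, rule_fired=rule,
                                    features=summaries)

    # L1: concentration increases away from the zone (or dips to an interior
    # minimum then increases) -- only localized proliferation does this, so a
    # single clean observation at any one time decides.  The interior minimum
    # flattens toward the tissue edge as degradation removes the transient,
    # so late snapshots may read as plainly decreasing; any-time semantics
    # keeps the early diagnostic observation decisive.
    if any(m in (Monotonicity.INCREASING, Monotonicity.LOCAL_MINIMUM) for m in monos):
        return result("localized", "L1")

    decreasing = _majority(monos, {Monotonicity.DECREASING})

    # L2: decreasing but concave down in the far field.
    if decreasing and _majority([s.far_field_sign for s in summaries], {-1}):
        return result("localized", "L2")

    # L3: steady exponential decay.
    if steady and decreasing and summaries[-1].decay_law is DecayLaw.EXPONENTIAL:
        return result("localized", "L3")

    increment = (
        _increment_shape(fld, zone_length, tol) if len(fld) >= 2 else "unclear"
    )
    concave_up = _majority([s.far_field_sign for s in summaries], {1})

    # U1: decreasing, concave up, growing in time with a spatially flat
    # increment (the uniform-mode transient signature).
    if (
        decreasing
        and concave_up
        and trend is TimeTrend.INCREASING
        and increment == "flat"
    ):
        return result("uniform", "U1")

    # U2: steady power-law decay.
    if steady and decreasing and summaries[-1].decay_law is DecayLaw.POWER:
        return result("uniform", "U2")

    # L4: growing in time with an increment amplified toward the tissue edge
    # (the localized-mode transient signature e^{d s}).
    if decreasing and trend is TimeTrend.INCREASING and increment == "amplified":
        return result("localized", "L4")

    return result("indeterminate", "I1")


# ---------------------------------------------------------------------------
# validation fixtures


def generate_noisy_fixture(
    params: ModelParameters,
    times: Sequence[float],
    n_points: int = 128,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> SpaceTimeField:
    """Exact field with multiplicative lognormal measurement noise.

    The perturbation has unit mean and coefficient of variation ``noise_cv``,
    independent across grid points; ``noise_cv = 0`` returns the exact field.
    """
    if not 0 <= noise_cv <= 0.2:
        raise ValueError("noise_cv must be in [0, 0.2]")
    fld = analytic.evaluate_field(params, times, n_points)
    if noise_cv == 0:
        return fld
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noisy = []
    for p in fld.profiles:
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=p.c.size)
        noisy.append(
            ConcentrationProfile(t=p.t, L=p.L, x=p.x, c=p.c * factors)
        )
    return SpaceTimeField(times=fld.times, profiles=noisy, params=params)
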