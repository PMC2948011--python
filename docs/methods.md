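# Methods

## Model

The per-length morphogen mRNA concentration `c(x, t)` on a growing 1D domain
`[0, L(t)]` satisfies mass conservation

    ∂c/∂t + ∂(v c)/∂x = S·1[x < w] − k·c,     c(x, 0) = C0  (uniform),

where transcription happens only in the fixed-length zone `[0, w)` and the
velocity `v(x)` is generated by cell proliferation at relative rate `d`.
Expanding the flux splits proliferation's two effects: advection `v ∂c/∂x`
(cells carried outward) and dilution `c ∂v/∂x` (divisions splitting a fixed
transcript pool over more length). Because the domain edge is a material
point (`v(L) = dL/dt`), no-flux boundaries hold automatically and the total
transcript amount obeys `dM/dt = S·w − k·M` exactly, in both modes.

Assumptions worth stating explicitly: morphogen protein level is
proportional to local mRNA (no protein transport), the initial concentration
is spatially uniform, `S` and `d` are spatially constant within their
regions, the zone length `w` is constant in time, and `d > 0` (with no
proliferation the entire mechanism is absent; parameter validation rejects
`d = 0` rather than silently producing pure-decay dynamics).

### Closed forms

Both velocity fields are piecewise linear with constant coefficients, so the
PDE integrates exactly along characteristics; the branches are listed in
`morphograd/analytic.py`. The structure is identical in both modes: a
spatially uniform in-zone value relaxing to the equilibrium `C_E = S/(d+k)`
at rate `d+k`; a zone-derived exterior region between `x = w` and the moving
front traced by the material initially at `w`; and — only when `w < L0` — a
beyond-front region of material that never transcribed, which keeps a
spatially flat, exponentially decaying value forever (the "partial
gradient" behaviour).

Shape diagnostics for the localized case come from differentiating the
exterior branch in the exit-age coordinate `s = (x−w)/(dw)`:

* interior minimum: exists iff `k > 0` and `C0 > S/d`; onset
  `t_c = ln[d(C0−C_E)/(kC_E)]/(d+k)`, position `x_min = w(1 + d(t−t_c))`.
* inflection: exists iff `k > 0` and `d²(C_E−C0) > k²C_E`; onset
  `t_i = ln[d²(C_E−C0)/(k²C_E)]/(d+k)`, position `x_i = w(1 + d(t−t_i))`.
* endpoint curvatures (for `w = L0`):
  `c''(w⁺) = [k²C_E + d²(C0−C_E)e^{−(d+k)t}]/(dw)²` and
  `c''(L⁻) = e^{−kt}[k²C_E + d²(C0−C_E)]/(dw)²`; the tissue-edge sign is
  time-independent.

Both features, when present, travel at exactly the elongation speed `d·w`.
The regime conditions are equivalent to the onset-time logarithms exceeding
one; a non-positive logarithm means the feature never forms (not that it
formed before `t = 0`), and the feature accessors report it absent.
Positions landing beyond `L(t)` are reported as not yet inside the domain.

### Independent certification

The closed forms were derived by hand, so the package treats them as
untrusted until certified. `morphograd.characteristics` solves the same PDE
by Lagrangian particle tracking with *exact* per-region updates: within each
region both the trajectory and the concentration ODE have constant
coefficients, and the zone-exit time comes from the closed-form trajectory,
so the solver's only error is floating-point rounding of crossing times. It
is independent of the analytic module in the operative sense: it never
eliminates the exit time algebraically, which is the step that produces the
closed-form branches.

`morphograd.validation.regime_grid()` spans `{localized, uniform} ×
{k/d = 0, 1/2, 2} × C0 ∈ {0, C_E, (C_E+S/d)/2, 2S/d}` (duplicates dropped)
plus one `w < L0` case per mode — 24 parameter sets covering every
qualitative regime. Agreement is measured at particle positions at
`t ∈ {0.25, 1, 4}/d`, normalised by the profile's concentration scale
rather than pointwise: at the moving fronts the closed form evaluates to
exact zeros through cancellation of exponentials, and a pointwise quotient
there would compare rounding residue against zero. Measured maximum
deviation: ~6e−16; the acceptance bound is 1e−9.

Particles are seeded uniformly on `[0, L0]` with particles pinned exactly at
`0`, `w` and `L0`, so both solution interfaces (zone-exit front,
initial-material front) are tracked without smearing. Uniform seeding
leaves a widening particle gap just outside the zone edge at late times
(in-zone particles exit at logarithmically spaced times), which only affects
*interpolated* queries between particles — values at particles are exact,
and all certification compares at particle positions.

## Classifier

`infer_proliferation_mode` applies first-match rules to the exterior region
of one or more profiles:

* **L1** (localized): concentration increases away from the zone, or dips to
  an interior minimum. Any-time semantics: a single clean observation
  decides, because no uniform-proliferation profile ever produces these
  shapes, and with strong degradation the minimum's trailing rise decays
  like `e^{−k s}` and is measurable only in early snapshots.
* **L2** (localized): decreasing but concave *down* in the far field,
  operationalised as the outer quarter of the exterior. The inflection
  point trails the domain edge at the fixed distance `d·w·t_i`, so the
  concave-down band is a boundary layer at the front: testing the outer
  half would dilute it at late times.
* **L3** (localized): steady in time and exponentially decaying — fitted
  rate `k/(dw)`.
* **U1** (uniform): decreasing, concave up, growing in time *with a
  spatially flat inter-time increment*.
* **U2** (uniform): steady and power-law decaying — fitted exponent
  `−(1+k/d)`.
* **L4** (localized): as U1 but the increment is amplified toward the
  tissue edge.
* **I1**: indeterminate.

The U1/L4 split is this package's refinement of the purely qualitative
criteria. The triad (decreasing, concave up, increasing in time) does *not*
identify uniform proliferation: localized growth with `C0 < C_E` and
`k²C_E ≥ d²(C_E−C0)` (e.g. `k = 2d`, `C0 = 0`) produces exactly the same
triad. The two cases separate through the transient's spatial structure,
read directly off the closed forms: outside the zone the uniform-mode
transient `(C0−C_E)e^{−(d+k)t}` is independent of `x`, so the increment
`c(x, t₂) − c(x, t₁)` is flat, whereas the localized transient carries the
factor `e^{d s}` and the increment grows toward the front. The increment is
evaluated on the later profile's own grid (exact there, interpolating only
the finer early profile — interpolating a coarse grid of a convex profile
would bias the increment upward), and its far/near ratio is compared
against `1 ± max(0.1, 5·tol)`.

Two patterns remain genuinely unresolvable and return indeterminate: the
(decreasing, concave-up, time-*decreasing*) triad, produced by both modes
whenever `C0 > C_E` (and, for localized, `C0 ≤ S/d`), and the flat
no-gradient special case (localized, `k = 0`, `C0 = S/d`), where the
profile carries no shape information at all.

### Numerical shape decisions

All thresholds are relative to the profile maximum through the dead-band
fraction `tol` (default `1e−3` for noiseless model output; use ≈3× the
measurement coefficient of variation for noisy data), making every decision
invariant to concentration units:

* monotonicity: equal-count bin means (8–24 bins); the pattern is decided
  from the cumulative descent to and ascent from the minimum bin, not from
  bin-to-bin signs — a shallow dip spreads over many bins and per-bin
  differences drown in the dead-band;
* concavity: quadratic fits over the inner/outer halves (pattern) and the
  outer quarter (far field); a sign is decided when the fitted parabola's
  sagitta exceeds `tol` times the *window's own* maximum, matching the
  multiplicative noise model where absolute levels are small;
* steadiness: all consecutive increments below `tol` times the field scale,
  averaged in thirds; with a single profile the caller must assert
  steadiness explicitly (one snapshot cannot show it);
* decay law: least-squares lines to `log c` vs `x` and vs `log x` on the
  positive exterior values; the smaller RMS residual picks the law, `neither`
  if both exceed `max(0.05, 3·tol)` in log units.

## Synthetic data

`generate_noisy_fixture` perturbs the exact field with independent,
multiplicative lognormal noise of unit mean and chosen coefficient of
variation — emulating proportional measurement error in imaging-based
quantification (e.g. FISH intensity). It does not emulate spatially
correlated noise, background offsets, limited optical resolution, cell-level
granularity, or embryo-to-embryo parameter variability; robustness results
therefore show tolerance to uncorrelated intensity noise only, not a full
measurement model. The default study condition used in tests is 1 % noise
on 256-point profiles at `t ∈ {0.5, 1.5, 3}/d`, 50 seeds per regime, with
classification tolerance `tol = 3 × 0.01`.

## Parameter choices and problem sizes

The nondimensional preset `S = d = w = L0 = 1` (time in `1/d`, length in
`w`) is used throughout tests and figures: all qualitative regimes are fixed
by `C0` relative to `C_E` and `S/d`, and by `k/d`, which the regime grid
varies. The dimensional `somitogenesis` preset (micrometres/minutes) uses
the vertebrate axis-elongation range — one ~125 µm somite per ~90 min
period, so `d·w = 125/90 µm/min` with a `w = 200 µm` progenitor zone — and
`k = ln 2 / 120 min⁻¹` from a 2 h transcript half-life; the source `S` only
sets the concentration scale.

Problem sizes in tests and the acceptance script: 128 particles for
certification (values at particles are exact; the count only sets sampling
density), 10⁵-point grids for brute-force feature location (one grid spacing
≈ 2–5×10⁻⁵ `w`), 10⁴ points for trapezoidal mass checks (quadrature error
~10⁻⁹ relative, bound 10⁻⁶), 256-point profiles for classification.

## Known limitations

* Spatially varying `S(x)`, `d(x)`, a time-dependent zone length, non-uniform
  initial conditions, 2D/3D geometry and stochastic cell-level effects are
  out of scope.
* The classifier's far-field window (outer quarter) assumes the inflection
  boundary layer occupies at least a quarter of the exterior; for
  `t ≫ 4 t_i` in the inflection regime, rule L2 can lose the concave-down
  band. The travelling-feature accessors, not the classifier, are the right
  tool at very late times.
* Linear interpolation between particles (for plotting or off-particle
  queries) degrades near the zone-edge kink at late times because exited
  particles thin out there; certification avoids interpolation entirely.
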