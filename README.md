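# morphograd

Morphogen gradients without diffusion: exact solvers and shape-based
inference for transcript gradients built purely by cell proliferation in an
axially elongating 1D tissue.

## The problem

In many developing tissues (vertebrate somitogenesis and its FGF8 gradient,
annelid/arthropod axial elongation), positional information comes from a
morphogen gradient. The textbook mechanism is protein diffusion from a
localized source — but in large, highly cellularised tissues diffusion may be
impossible. An alternative is purely kinematic: the morphogen-encoding gene
is transcribed only in a zone `[0, w)` at one end of the tissue, the mRNA
stays inside cells, and tissue growth by cell proliferation both carries
cells away from the zone (advection) and dilutes their transcript load as
divisions split transcripts between daughters. Since the protein level
tracks its mRNA, a transcript gradient is a morphogen gradient.

`morphograd` implements this model: the per-length transcript concentration
`c(x, t)` on the growing domain `[0, L(t)]` obeys the conservation law

```
∂c/∂t + ∂(v c)/∂x = S·1[x < w] − k·c,        c(x, 0) = C0,
```

with source strength `S`, degradation rate `k`, and a proliferation-induced
velocity `v` that depends on where divisions happen (relative rate `d`):

* **localized** — divisions only in the transcription zone:
  `v = d·x` for `x < w`, `v = d·w` beyond; linear growth `L = L0 + d·w·t`;
* **uniform** — divisions everywhere: `v = d·x`; exponential growth
  `L = L0·e^{d·t}`.

Both cases solve exactly along characteristics. With the in-zone equilibrium
`C_E = S/(d+k)`, the steady exterior gradient is exponential,
`C_E·e^{−k(x−w)/(dw)}`, under localized proliferation and a power law,
`C_E·(w/x)^{1+k/d}`, under uniform proliferation. Transients add an
interior minimum (localized, `k > 0`, `C0 > S/d`, appearing at the critical
time `t_c = ln[d(C0−C_E)/(kC_E)]/(d+k)` and travelling at speed `d·w`) and a
moving inflection point (localized, `d²(C_E−C0) > k²C_E`). These shape
features are measurable, so the package can also run the inference in
reverse: given concentration profiles, decide whether proliferation was
localized or uniformly distributed — or prove the question unresolvable.

The package provides:

* `morphograd.core` — parameters, growth kinematics, velocity/dilution fields;
* `morphograd.analytic` — exact concentration fields, critical features
  (`t_c`, `x_min`, `t_i`, `x_i`), endpoint curvatures, total transcript mass;
* `morphograd.characteristics` — an independent Lagrangian particle solver
  (exact per-region updates, no discretisation error) used to certify every
  closed form;
* `morphograd.classify` — profile-shape summaries and the proliferation-mode
  classifier, with a noisy-fixture generator for robustness studies;
* `morphograd.cli` — `simulate`, `features`, `classify`, `validate`
  subcommands with CSV/JSON output and optional plots.

## Worked example

A localized-proliferation tissue loaded well above what the source sustains
(`C0 = 4 > S/d = 2`) first builds an *inverted* gradient, then develops a
travelling interior minimum after `t_c`:

```sh
$ morphograd features -S 2 -k 1 -c 4 --times 1.0
{
  "params": {"S": 2.0, "d": 1.0, "k": 1.0, "w": 1.0, "L0": 1.0, "C0": 4.0,
             "mode": "localized"},
  "features": [
    {
      "t": 1.0,
      "exists_min": true,
      "t_c": 0.5493061443340549,
      "x_min": 1.450693855665945,
      "exists_inflection": false,
      "t_i": null,
      "x_i": null
    }
  ]
}
```

Here `t_c = ln 3 / 2 ≈ 0.549` (in units of `1/d`) is when the minimum
detaches from the zone edge, and by `t = 1` it sits at
`x_min = w(1 + d(t − t_c)) ≈ 1.451` (in units of `w`). Evaluating the
closed form at `t = 1` confirms the dip: `c = 1.406` at the zone edge,
`1.274` at `x_min`, `1.472` at the tissue edge — a non-monotone gradient
that only localized proliferation can produce (the classifier's rule L1).

Simulating with both solvers cross-checks the closed form against the
characteristics solver on the fly:

```sh
$ morphograd simulate --mode uniform -k 0.5 -c 0 --times 0.5,1.5 \
      --solver both --out-csv field.csv
[morphograd] params S=1.0 d=1.0 k=0.5 w=1.0 L0=1.0 C0=0.0 mode=uniform
[morphograd] comparison max_rel_error=3.331e-16
[morphograd] done solver=both outputs=field.csv
```

and `morphograd classify field.csv -w 1.0` infers `"mode_inferred":
"uniform"` back from the profiles alone.

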