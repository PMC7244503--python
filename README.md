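# tmsd — mismatch-elimination strand displacement

`tmsd` models toehold-mediated strand displacement (TMSD) reactions in
which the invading strand eliminates an internal base-pairing mismatch
from the substrate duplex.  A mismatch placed deep inside the incumbent
duplex contributes several kcal/mol of extra thermodynamic drive to the
reaction while barely changing its forward rate — *hidden thermodynamic
driving* — whereas a mismatch eliminated early (but not immediately)
during branch migration accelerates displacement by orders of magnitude.
The package is aimed at designers of dynamic DNA circuits who want to
tune reaction thermodynamics and kinetics independently.

## What it computes

**Nearest-neighbour thermodynamics** (`tmsd.nn_thermo`).  Duplex free
energies ΔG°(T) = ΔH° − TΔS° from the unified Watson–Crick parameter set
plus the published internal single-mismatch stacks (tables taken from
Biopython's `Bio.SeqUtils.MeltingTemp`), with a monovalent-equivalent
salt correction.  `displacement_profile` builds the free-energy profile
G(n) of displacement intermediates over macrostates labelled by the
number of invader–target base pairs *n*, with each macrostate a partition
sum over up to `f_max` frayed incumbent base pairs ahead of the branch
point.  Fraying is what makes a mismatch at domain position 2 cheaper to
carry — and hence less accelerating — than one at position 3.

**Landscape kinetics** (`tmsd.landscape`).  The profile becomes a
continuous-time Markov chain (detached ← toehold-bound ↔ branch states →
displaced) with Metropolis rates satisfying detailed balance.  In the
second-order limit the rate constant factorises as

    k = k_toehold · p(disp | toehold)

and the splitting probability decomposes at any reference position *x*:

    p(disp | toehold) = p(bp x reached | toehold) · p(disp | bp x reached)

Both factors are exact absorption solves; `relative_rate` gives k/k₀
versus mismatch position (k_toehold cancels for a shared toehold), and
`mean_first_passage_time` covers the first-order, high-concentration
limit.  `kmc_splitting` (Gillespie) and `tmsd.ffs` (direct forward flux
sampling on the same reaction coordinate) are stochastic estimators
validated against the exact solves.

**Circuit kinetics** (`tmsd.kinetics`).  Mass-action ODE models of the
three assay motifs — the reporter rate assay, the catalytic toehold
exchange A + B·D ⇌ B + A·D, C + A·D ⇌ A + C·D (with optional direct leak
channel), and the two-toehold pulse generator — plus trace normalisation
(F − F_min)/(F_max − F_min) and nonlinear least-squares fitting of
second-order rate constants.

**Synthetic data** (`tmsd.synthetic`).  Spectrofluorimeter-like traces
(60-s sampling, baseline segments, affine signal map, seeded Gaussian
noise) and the mismatch-position sequence series built by sliding a 3-bp
mismatch motif along the displacement domain (point mutations where the
domain doubles as the reporter toehold).

## Worked example

```python
from tmsd import mismatch_ddg
from tmsd.landscape import relative_rate
from tmsd.synthetic import (MismatchSeriesSpec, generate_mismatch_series,
                            reference_design)

spec = MismatchSeriesSpec(positions=(2, 3, 7, 13))   # C–C motif series
series = generate_mismatch_series(spec)
ref = reference_design(spec).as_system(4)            # mismatch-free k0 design
for x, entry in series.items():
    system = entry.as_system(4)
    res = relative_rate(system, ref)
    print(f"x={x:2d}  k/k0 = {res.ratio:7.2f}   "
          f"ddG37 = {mismatch_ddg(system, temperature=37.0):+.2f} kcal/mol")
```

prints

```
x= 2  k/k0 =   46.19   ddG37 = -5.97 kcal/mol
x= 3  k/k0 =   64.28   ddG37 = -5.97 kcal/mol
x= 7  k/k0 =    4.49   ddG37 = -5.97 kcal/mol
x=13  k/k0 =    1.82   ddG37 = -5.97 kcal/mol
```

Every design gains the same ≈6 kcal/mol of thermodynamic drive from the
eliminated C–C mismatch, but only early positions convert it into a rate
acceleration: the non-monotonic maximum sits at position 3 (position 2 is
blunted by duplex-end fraying), and by position 13 the rate has relaxed
back to within a factor of two of the mismatch-free k₀ — the drive is
kinetically hidden.

Fitting a synthetic rate-assay trace (1% noise) recovers its generating
constant:

```python
from tmsd.kinetics import build_rate_assay_model, fit_rate_constant
from tmsd.synthetic import NoiseModel, generate_trace, simple_protocol

net = build_rate_assay_model(k_disp=2.6e3)          # 12.5 nM I and O·T
trace = generate_trace(net, simple_protocol(500 * 60),
                       NoiseModel(sigma_abs=0.01, seed=7))
fit = fit_rate_constant(trace, build_rate_assay_model,
                        ["k_disp"], {"k_disp": 1e4})
print(f"fitted k = {fit['k_disp']:.3g} +/- {fit.se['k_disp']:.2g} M^-1 s^-1")
# fitted k = 2.59e+03 +/- 5.3 M^-1 s^-1
```

A command-line interface mirrors the library:

```bash
tmsd profile  --config system.yaml --out profile.csv
tmsd rates    --config system.yaml --positions 2..13 --out rates.csv
tmsd ffs      --config system.yaml --trials 1000 --seed 7 --out ffs.json
tmsd synth    --model rate_assay --k 2600 --out trace.csv
tmsd fit      --model rate_assay --trace trace.csv --out fit.json
```

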