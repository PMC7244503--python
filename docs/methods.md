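# Methods

## Scope and model hierarchy

The package treats a mismatch-elimination TMSD reaction at three levels:

1. **Equilibrium thermodynamics** — nearest-neighbour (NN) duplex free
   energies and free-energy profiles of displacement intermediates.
2. **Landscape kinetics** — a one-dimensional continuous-time Markov
   chain over those intermediates, solved exactly (splitting
   probabilities, conditional decompositions, mean first-passage times)
   and stochastically (kinetic Monte Carlo, forward flux sampling).
3. **Circuit kinetics** — deterministic mass-action ODEs for the
   fluorescence assays, with least-squares fitting of second-order rate
   constants.

A synthetic-data generator emulates the spectrofluorimeter protocol so
that every stage can be exercised without laboratory data.

## Nearest-neighbour thermodynamics

Duplex stability is the unified Watson–Crick NN parameter set with
published internal single-mismatch stacks, both read from Biopython's
`Bio.SeqUtils.MeltingTemp` tables (`DNA_NN4`, `DNA_IMM1`); ΔG°(T) is
reconstructed as ΔH° − TΔS°, with duplex initiation and terminal A·T
penalties.  The tables' reference temperature is 37 °C; the working
temperature defaults to 25 °C (the assay temperature).  Statements about
the *magnitude* of the mismatch contribution (the ≈6 kcal/mol bound) are
evaluated at 37 °C, the scale on which NN predictions are conventionally
quoted; at 25 °C the same C–C stacks are up to ~0.6 kcal/mol more
destabilising.

**Salt.**  A monovalent-equivalent correction adds
0.368·ln[Na⁺]_eq cal/(mol·K) per stack, with magnesium folded in through
[Na⁺]_eq = [Na⁺] + 0.120·√([Mg²⁺]/mM) M.  The default describes the
fluorometry buffer (50 mM NaCl + 10 mM MgCl₂, [Na⁺]_eq ≈ 0.43 M).  The
correction is configurable and cancels exactly in mismatch ΔΔG values
(equal-length duplexes).

**Mismatch attribution.**  `mismatch_ddg` compares a design against its
*own* mismatch-free variant (same target, fully complementary
incumbent).  Comparing different positional designs against a single
canonical reference instead mixes in terminal-context differences of up
to ~0.8 kcal/mol that are artefacts of the sequence construction, not of
the mismatch.

**Profiles.**  Macrostate *n* = number of invader–target base pairs
(toehold pairs included), n = 1..n_max, G(1) = 0, with
n_max = h + N for a mismatch-free system and h + N − 1 with a mismatch
(the incumbent's final base pair is taken to dissociate spontaneously).
Each macrostate is a Boltzmann sum (log-sum-exp) over microstates with
f = 0..f_max incumbent base pairs frayed ahead of the branch point
(default f_max = 3).  The mismatch position never holds a base pair; its
two flanking stacks take internal-mismatch values while it is enclosed,
and vanish once the incumbent region reaches it.  Consequently the
elimination drop begins at n = h + x − 1 without fraying and strictly
earlier with fraying — fraying "anticipates enclosure", and for x = 2 it
lets the duplex trade the enclosed-mismatch cost for the loss of one or
two terminal pairs, which is why a position-2 mismatch yields a smaller
overall bias and a smaller acceleration than position 3.  A
`plateau_penalty` (default 2 k_BT, the cost of initiating the
three-stranded branch-migration junction) is added to every intermediate
h < n < n_max; a per-step sawtooth barrier ΔG_s is carried on the
profile and attenuates the hop rate rather than entering G.

## Landscape Markov chain

States: DETACHED (absorbing), TOEHOLD_BOUND (coordinate h), BRANCH(n)
for h < n ≤ n_max, DISPLACED (absorbing).  Branch-migration transitions
use Metropolis rates k_bm·min(1, e^{G_i−G_j}), which satisfy detailed
balance on the profile.  Toehold binding is a single bimolecular step
with constant k_toehold; detachment follows by detailed balance at a 1 M
reference, k_off = k_toehold·(1 M)·e^{ΔG_toehold/k_BT}.  BRANCH(n_max)
commits irreversibly, making p(disp | bp n_max reached) exactly 1.

Defaults (`LandscapeParams`): k_bm = 10⁴ s⁻¹ (effective branch-migration
hop rate, sawtooth absorbed), k_toehold = 3×10⁶ M⁻¹s⁻¹
(literature-typical; a pure scale factor that cancels in every ratio),
plateau penalty 2 k_BT, f_max = 3, and the **sequence-averaged** NN set:
every WC stack takes the mean of the ten unique WC stacks, every
mismatch stack the mean of the C–C stacks, terminal penalties zeroed.
Rate-versus-position studies therefore respond to mismatch position and
type only, not to incidental sequence wiggles; the toehold binding free
energy is still computed from the design's actual toehold sequence.
Under these defaults the mismatch-free model gives k₀ ≈ 9.6×10³ M⁻¹s⁻¹
and a maximal acceleration of ≈64× at position 3 — the package targets
the *shape* of the position dependence (non-monotonic rise to x = 3,
near-exponential decay back to k₀ by x ≳ 13, suppression of all
acceleration in the long-toehold limit), not the absolute constants.

Exact quantities are linear absorption solves on the generator matrix
(≤25 states; `numpy.linalg.solve`).  Because the chain is one
dimensional, p(disp|toehold) = p(reach x)·p(disp|reach x) holds exactly
for every x; tests pin the identity at 1e−10.  The mean first-passage
time switches off detachment (first-order, high-concentration limit:
a detached invader is replaced instantly) and solves Q·t = −1.

**Stochastic estimators.**  `kmc_splitting` runs Gillespie trajectories
with one RNG stream per trajectory index (reproducible under any
execution order).  `run_ffs` is direct forward flux sampling on the
branch coordinate: interfaces default to every 2 coordinate units from
h+1, with the final interface at the DISPLACED coordinate, so the flux
product estimates exactly the quantity the absorption solve computes;
stored configurations are state labels (the chain is memoryless, so
restarts are exact in distribution).  Standard errors are binomial,
propagated in quadrature across interfaces.

## Circuit ODE models

Networks are explicit species lists with at-most-bimolecular mass-action
reactions, integrated with LSODA after non-dimensionalising by the
largest initial concentration (rtol 1e−8); strand-conservation totals
are preserved to ~1e−9 relative and audited in tests.  Concentration
presets derive from the stated assay volumes (2.4 µl of 10 µM into
1.92 ml → 12.5 nM substrate and invader; 25 nM reporter; catalytic motif
40 nM B·D, 200 nM C, 5 nM A, 250 nM reporter; pulse 4:2:1
I₅:I₃:O·T on the 12.5 nM scale).  Injection dilution (~0.13% per
addition) is neglected.

The rate-assay reporter is instantaneous by default (signal ≡ cumulative
released output); an explicit reporter with k_rep ≥ 100× the
displacement timescale agrees within 2% and is available for protocol
simulations with baseline segments.  The catalytic model's optional leak
channel C + B·D ⇌ B + C·D defaults to a cycle-consistent reverse rate
(K_leak = K₁K₂); supplying an inconsistent value warns with the log
residual, as does an inconsistent pulse-model cycle.  The pulse defaults
give I₃ a ~20× kinetic advantage with equal overall driving (both
invaders eliminate the same mismatch, K₃ = K₅), reproducing the
rise–peak–decay of the kinetically favoured product and an equilibrium
biased to the excess invader; the inferred O channel is the sum of the
two product duplexes.

**Catalysis neutrality.**  Catalysis cannot move the B·D ⇌ C·D
equilibrium, but the catalyst itself sequesters part of the target
strand in the A·D intermediate (~2 nM of 40 nM at the presets), so raw
equilibrium concentrations shift by ~2%.  The invariant quantity is the
conversion yield [C·D]/([B·D]+[C·D]), which is catalyst-independent to
solver precision; tests assert it at 0.1%.

**Fitting.**  Trust-region least squares on the fractional-fluorescence
residuals, optimising rate constants in log₁₀ space (positivity by
construction) with five decade-spaced multistarts; optional affine
nuisance parameters (`scale`, `baseline`).  Standard errors come from
the Gauss–Newton covariance at the optimum; non-convergence is flagged
on the result, never raised.  Fits are deterministic given the trace and
initial guess.

## Synthetic data

`generate_trace` integrates a network piecewise across reagent
injections (baseline → substrate → invader), samples every 60 s, applies
an affine signal map with optional exponential photobleaching, and adds
seeded Gaussian noise (default σ = 1% of full scale; the instrument's
true noise level is not published).  What it does **not** emulate:
instrument drift, lamp flicker, inner-filter effects, cross-talk, or
pipetting variability — so round-trip tests demonstrate estimator
correctness on the stated noise model, not robustness to real-instrument
systematics.

The mismatch series uses a synthetic stand-in for the unpublished
experimental sequences: toehold `ATGT`, a 17-nt domain background, and
target motif window `GCG` whose central C opposes the incumbent's C
(C–C, the most destabilising pairing; its NN drive is 5.97 kcal/mol at
37 °C, the largest of the sixteen C–C contexts).  The background was
chosen once so that positions 15 and 17 of the reference design satisfy
the point-mutation context constraint (an incumbent C flanked by the
motif environment), mirroring the constraint that forces point mutations
in the reporter-toehold region.  Slide construction: the domain for
position x is background[:x−2] + motif + background[x−2:], so deleting
the window yields the same string for every position and base content is
conserved; the motif-internal stacks are identical across positions,
which is why the reaction ΔΔG is position independent to well under
0.5 kcal/mol.  All series code is parameterised so real assay sequences
can be substituted directly.

## Numerical choices and degenerate inputs

- One kcal/mol ↔ k_BT conversion constant for the whole package
  (`tmsd.constants`), 1 kcal/mol = 1.688 k_BT at 25 °C.
- Terminal mismatches are rejected by `duplex_free_energy` (end effects
  belong to the fraying model); a mismatched pair at the edge of a
  retained incumbent region contributes no stack (it is effectively
  frayed).  A mismatch at x = 1 or x = N is therefore dominated by
  terminal-fraying microstates — an extrapolation, as no assayed design
  places one there.
- Two adjacent mismatches, unsupported steps and non-ACGT symbols raise
  errors naming the offending dinucleotide.
- Domains shorter than 2 bp and chains with non-finite G are rejected;
  x = None builds the mismatch-free system everywhere.
- Seeds: every stochastic component takes a single integer seed and
  spawns independent `numpy` SeedSequence streams (per trajectory, per
  FFS stage, per fixture), so results are bit-reproducible.

## Problem sizes used in the shipped checks

Exact solves operate on ≤25-state chains.  The stochastic validations
use 10⁴ KMC trajectories and 10³ FFS trials per interface (agreement
with exact solves within 3 SE); the fit-bias check uses 50 noisy
replicates at 2% noise.  The acceptance script fits three 501-point
noiseless traces (500 min at 60-s sampling).

## Known limitations

- The landscape chain is a surrogate at the resolution of base-pair
  macrostates: no nucleotide-level structure, no per-base toehold
  zipping, no double-joined three-way intermediates beyond the single
  branch point, and no sequence-resolved branch-migration barriers under
  the sequence-averaged defaults.  Absolute rate constants are set by
  the k_toehold/ΔG_toehold calibration and are only order-of-magnitude;
  ratios are the meaningful output.
- NN parameters ignore dangling ends, coaxial stacking and fluorophore/
  quencher contributions, which are known to shift duplex stabilities by
  a few k_BT in these assays.
- The catalytic and pulse models use lumped second-order constants per
  exchange step; they do not resolve the toehold-exchange intermediates.
- Reporter systems are modelled as fast or instantaneous sinks; reporter
  leak pathways are out of scope.
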