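"""Synthetic spectrofluorimeter traces and mismatch-series sequence design.

Two jobs live here.  First, emulating the acquisition protocol of the
displacement assays: piecewise ODE integration across reagent injections
(baseline -> substrate -> invader), sampling every 60 s, an affine map
from concentration to signal, optional photobleaching, and additive
Gaussian noise — all seeded and reproducible.  Second, constructing the
mismatch-position sequence series: the 3-bp mismatch motif is slid along
the displacement domain by moving the base pair immediately after it to
the position immediately before it, so that all targets are identical
once the motif window is deleted and base content is preserved; positions
inside the reporter-toehold region are instead reached by a single point
mutation of the target.

The experimental motif sequence is not public; fixtures use a documented
synthetic stand-in (target window ``GCG`` with a central C-C mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import (
    CATALYTIC_CONCENTRATIONS,
    PULSE_CONCENTRATIONS,
    RATE_ASSAY_CONCENTRATIONS,
    ReactionNetwork,
    Trace,
    build_catalytic_model,
    build_pulse_model,
    build_rate_assay_model,
    simulate_network,
)
from .nn_thermo import DisplacementSystem, complement, revcomp

__all__ = [
    "NoiseModel",
    "Injection",
    "Protocol",
    "SeriesError",
    "MismatchSeriesSpec",
    "SeriesEntry",
    "generate_trace",
    "generate_mismatch_series",
    "rate_assay_protocol",
    "simple_protocol",
    "Fixture",
    "FIXTURE_NAMES",
    "trace_fixture_suite",
    "STANDIN_TOEHOLD",
    "STANDIN_BACKGROUND",
    "STANDIN_MOTIF",
]

SAMPLE_INTERVAL_S = 60.0

# synthetic stand-in design (the experimental sequences are not
# published; drop the real strands in via MismatchSeriesSpec)
STANDIN_TOEHOLD = "ATGT"
STANDIN_BACKGROUND = "ACTTCACTACGGGGGTA"  # domain with the motif excised
STANDIN_MOTIF = "GCG"  # target-side window; centre C pairs the C-C mismatch


class SeriesError(ValueError):
    """Invalid mismatch-series construction."""


@dataclass(frozen=True)
class NoiseModel:
    """Affine signal map plus additive Gaussian noise.

    ``sigma_abs`` is the absolute noise SD in signal units (default 1% of
    a unit-scaled trace); ``scale`` converts fractional conversion to
    arbitrary fluorescence units and ``baseline`` offsets it;
    ``bleach_rate`` optionally applies exponential photobleaching to the
    scaled signal.
    """

    sigma_abs: float = 0.01
    scale: float = 1.0
    baseline: float = 0.0
    bleach_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma_abs < 0:
            raise ValueError("sigma_abs must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class Injection:
    time: float
    additions: Mapping[str, float]
    label: str = ""


@dataclass(frozen=True)
class Protocol:
    """Segment schedule: injections at boundaries, then sampling to t_end."""

    injections: tuple
    t_end: float
    sample_interval: float = SAMPLE_INTERVAL_S

    def __post_init__(self):
        times = [inj.time for inj in self.injections]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SeriesError("injection times must be strictly increasing")
        if not self.injections:
            raise SeriesError("protocol needs at least one injection")
        if self.t_end <= times[-1]:
            raise SeriesError("t_end must lie beyond the last injection")


def simple_protocol(duration_s: float = 500 * 60.0,
                    sample_interval: float = SAMPLE_INTERVAL_S) -> Protocol:
    """Everything mixed at t = 0; sample for ``duration_s``."""
    return Protocol(injections=(Injection(0.0, {}, "reaction"),),
                    t_end=duration_s, sample_interval=sample_interval)


def rate_assay_protocol(duration_s: float = 500 * 60.0,
                        baseline_s: float = 600.0,
                        concentrations: Mapping[str, float] | None = None
                        ) -> Protocol:
    """Reporter baseline, substrate baseline, then invader at t = 0."""
    conc = dict(RATE_ASSAY_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    return Protocol(
        injections=(
            Injection(-2 * baseline_s, {"Rep": conc["Rep"]}, "baseline"),
            Injection(-baseline_s, {"OT": conc["OT"]}, "post-substrate"),
            Injection(0.0, {"I": conc["I"]}, "post-invader"),
        ),
        t_end=duration_s,
    )


def generate_trace(network: ReactionNetwork,
                   protocol: Protocol | None = None,
                   noise: NoiseModel | None = None) -> Trace:
    """Fluorimeter-like trace for a reaction network.

    Species named in any injection start at zero and receive their
    concentration at the injection time (injection dilution is neglected:
    2.4 ul into 1.92 ml changes the volume by ~0.13%); all other species
    start at the network's initial concentrations.  The ODE system is
    solved piecewise across injections, sampled on the 60-s grid, mapped
    through the affine noise model and given seeded Gaussian noise.
    """
    protocol = protocol or simple_protocol()
    noise = noise or NoiseModel(sigma_abs=0.0)
    injected = {sp for inj in protocol.injections for sp in inj.additions}
    conc = dict(network.species)
    for sp in injected:
        if sp not in conc:
            raise SeriesError(f"injected species {sp!r} not in network")
        conc[sp] = 0.0
    t0 = protocol.injections[0].time
    times = np.arange(t0, protocol.t_end + 1e-9, protocol.sample_interval)
    signal = np.zeros_like(times)
    boundaries = [inj.time for inj in protocol.injections] + [protocol.t_end]
    segments = {}
    for i, inj in enumerate(protocol.injections):
        for sp, amount in inj.additions.items():
            conc[sp] = conc[sp] + amount
        seg_lo, seg_hi = boundaries[i], boundaries[i + 1]
        if inj.label:
            segments[inj.label] = (seg_lo, seg_hi)
        mask = (times >= seg_lo - 1e-9) & (times <= seg_hi + 1e-9)
        seg_times = times[mask]
        grid = np.unique(np.concatenate([[seg_lo], seg_times, [seg_hi]]))
        if len(grid) < 2:
            continue
        sim = simulate_network(network, grid, initial=conc)
        sig = sim.observable(network.signal_species)
        if network.signal_scale:
            sig = sig / network.signal_scale
        signal[mask] = np.interp(seg_times, grid, sig)
        conc = {sp: float(sim[sp][-1]) for sp in network.species_names}
    scaled = noise.baseline + noise.scale * signal
    if noise.bleach_rate:
        scaled = noise.baseline + noise.scale * signal * np.exp(
            -noise.bleach_rate * (times - t0))
    rng = np.random.default_rng(noise.seed)
    noisy = scaled + rng.normal(0.0, noise.sigma_abs, size=len(times)) \
        if noise.sigma_abs > 0 else scaled
    return Trace(time=times, signal=noisy, segments=segments)


# -- mismatch-position sequence series ------------------------------------

@dataclass(frozen=True)
class MismatchSeriesSpec:
    """Recipe for the mismatch-position sequence series.

    ``background`` is the displacement domain with the 3-nt motif window
    excised; the full domain for mismatch position x restores the motif
    at target positions x-1..x+1.  ``mismatch`` names the O.T pair (the
    motif centre is the target-side base).  ``construction`` is ``slide``
    (motif translated along the domain; sequences identical with the
    window deleted) or ``point_mutation`` (single target base change,
    required where the domain doubles as the reporter toehold).
    """

    toehold: str = STANDIN_TOEHOLD
    background: str = STANDIN_BACKGROUND
    motif: str = STANDIN_MOTIF
    mismatch: str = "C-C"
    positions: tuple = (2, 3, 4, 5, 7, 9, 11, 13)
    construction: str = "slide"
    canonical_position: int = 7
    temperature: float = 25.0

    def __post_init__(self):
        if len(self.motif) != 3:
            raise SeriesError("motif must be exactly 3 bases")
        o_base, t_base = self.mismatch.split("-")
        if self.motif[1] != t_base:
            raise SeriesError(
                f"motif centre {self.motif[1]!r} must be the target-side "
                f"base of the {self.mismatch} mismatch")
        if o_base == complement(t_base):
            raise SeriesError(f"{self.mismatch} is a Watson-Crick pair, "
                              f"not a mismatch")
        if self.construction not in ("slide", "point_mutation"):
            raise SeriesError("construction must be 'slide' or "
                              "'point_mutation'")

    @property
    def domain_length(self) -> int:
        return len(self.background) + 3

    @property
    def o_base(self) -> str:
        return self.mismatch.split("-")[0]


@dataclass(frozen=True)
class SeriesEntry:
    position: int
    target: str
    incumbent: str
    invader: str
    construction: str

    def as_system(self, toehold_length: int,
                  temperature: float = 25.0) -> DisplacementSystem:
        return DisplacementSystem(
            target=self.target, incumbent=self.incumbent,
            invader=self.invader, toehold_length=toehold_length,
            temperature=temperature)


def _slide_domain(spec: MismatchSeriesSpec, x: int) -> str:
    N = spec.domain_length
    if x < 2 or x > N - 2:
        raise SeriesError(
            f"slide construction places the motif at positions "
            f"{x - 1}..{x + 1}; position {x} would overlap the toehold or "
            f"run off the domain (valid range 2..{N - 2})")
    bg = spec.background
    return bg[:x - 2] + spec.motif + bg[x - 2:]


def _entry_from_domain(spec: MismatchSeriesSpec, domain: str, x: int,
                       construction: str) -> SeriesEntry:
    N = len(domain)
    target = spec.toehold + domain
    incumbent = list(revcomp(domain))
    incumbent[N - x] = spec.o_base
    return SeriesEntry(position=x, target=target,
                       incumbent="".join(incumbent),
                       invader=revcomp(target), construction=construction)


def reference_design(spec: MismatchSeriesSpec) -> SeriesEntry:
    """The mismatch-free system: canonical-position target, WC incumbent."""
    domain = _slide_domain(spec, spec.canonical_position)
    target = spec.toehold + domain
    return SeriesEntry(position=0, target=target, incumbent=revcomp(domain),
                       invader=revcomp(target), construction="reference")


def generate_mismatch_series(spec: MismatchSeriesSpec) -> dict:
    """(O, T, I) triples per mismatch position, keyed by position.

    Slide entries share a common background (deleting the 3-nt motif
    window yields identical targets) and base composition.  Point
    mutations start from the reference design and change exactly one
    target base, which requires the reference to already present the
    mismatch environment (an incumbent ``o_base`` flanked by the motif
    flanks) at that position.
    """
    entries = {}
    ref = reference_design(spec)
    for x in spec.positions:
        if spec.construction == "slide":
            domain = _slide_domain(spec, x)
            entries[x] = _entry_from_domain(spec, domain, x, "slide")
        else:
            entries[x] = _point_mutation_entry(spec, ref, x)
    return entries


def _point_mutation_entry(spec: MismatchSeriesSpec, ref: SeriesEntry,
                          x: int) -> SeriesEntry:
    domain = ref.target[len(spec.toehold):]
    N = len(domain)
    if not 2 <= x <= N - 1:
        raise SeriesError(f"point mutation position {x} outside 2..{N - 1}")
    o_base, t_base = spec.mismatch.split("-")
    incumbent_base = revcomp(domain)[N - x]
    flanks_ok = (domain[x - 2] == spec.motif[0]
                 and domain[x] == spec.motif[2])
    if incumbent_base != o_base or not flanks_ok:
        raise SeriesError(
            f"point mutation at position {x} impossible: the mismatch "
            f"motif requires an output-strand {o_base!r} (target "
            f"{complement(o_base)!r}) flanked by "
            f"{spec.motif[0]!r}..{spec.motif[2]!r} on the target; found "
            f"target window "
            f"{domain[x - 2]}{domain[x - 1]}{domain[x]!s}")
    new_domain = domain[:x - 1] + t_base + domain[x:]
    target = spec.toehold + new_domain
    return SeriesEntry(position=x, target=target,
                       incumbent=revcomp(domain),
                       invader=revcomp(target),
                       construction="point_mutation")


# -- fixture suite --------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    name: str
    network: ReactionNetwork
    trace: Trace
    truth: dict


FIXTURE_NAMES = (
    "rate_assay_k0",
    "rate_assay_x3",
    "rate_assay_x15",
    "catalytic_triggered",
    "catalytic_untriggered",
    "pulse",
)

# experimentally fitted rate constants reproduced by the fixtures
RATE_CONSTANTS = {"rate_assay_k0": 2.6e3, "rate_assay_x3": 1.8e5,
                  "rate_assay_x15": 1.7e3}


def trace_fixture_suite(seed: int = 0) -> dict:
    """Named (network, trace, truth) bundles for the assay presets.

    Rate-assay fixtures reproduce the three fitted rate constants
    (mismatch-free, position 3, position 15); the catalytic pair differs
    only in the presence of the 5 nM catalyst; the pulse fixture runs the
    4:2:1 two-invader competition.  Traces carry 1% Gaussian noise by
    default; truth dictionaries record the generating constants.
    """
    streams = np.random.SeedSequence(seed).spawn(len(FIXTURE_NAMES))
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(FIXTURE_NAMES, streams)}
    fixtures = {}
    for name in ("rate_assay_k0", "rate_assay_x3", "rate_assay_x15"):
        k = RATE_CONSTANTS[name]
        net = build_rate_assay_model(k_disp=k)
        trace = generate_trace(
            net, simple_protocol(duration_s=500 * 60.0),
            NoiseModel(sigma_abs=0.01, seed=seeds[name]))
        fixtures[name] = Fixture(name, net, trace, {"k_disp": k})
    kcat = dict(k1=5e5, k1r=5e5, k2=5e5, k2r=5e5, k_rep=1e6, k_leak=10.0)
    for name, a0 in (("catalytic_triggered", CATALYTIC_CONCENTRATIONS["A"]),
                     ("catalytic_untriggered", 0.0)):
        net = build_catalytic_model(**kcat, concentrations={"A": a0})
        trace = generate_trace(
            net, simple_protocol(duration_s=500 * 60.0),
            NoiseModel(sigma_abs=0.01, seed=seeds[name]))
        fixtures[name] = Fixture(name, net, trace, {**kcat, "A0": a0})
    kpulse = dict(k3=1e5, k3r=50.0, k5=5e3, k5r=2.5, k_ex=5e3, k_exr=5e3)
    net = build_pulse_model(**kpulse)
    trace = generate_trace(net, simple_protocol(duration_s=500 * 60.0),
                           NoiseModel(sigma_abs=0.01, seed=seeds["pulse"]))
    fixtures["pulse"] = Fixture("pulse", net, trace, dict(kpulse))
    return fixtures
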