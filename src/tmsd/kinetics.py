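"""Mass-action ODE models of the fluorescence assays.

Three circuit motifs are modelled:

* **rate assay** — a single mismatch-elimination displacement
  ``I + O.T -> I.T + O`` read out by a reporter that consumes released
  output strand.  The reporter toehold is much longer than the reaction
  toehold, so by default it is treated as instantaneous and the signal is
  the cumulative released output.
* **catalytic toehold exchange** — ``A + B.D <=> B + A.D`` and
  ``C + A.D <=> A + C.D``: strand A catalyses the interconversion of B.D
  and C.D, with an optional direct (uncatalysed) leak channel
  ``C + B.D <=> B + C.D`` and an irreversible reporter sink for B.
* **pulse generator** — two invaders attack a two-toehold substrate from
  opposite ends and exchange with each other, producing a transient excess
  of the kinetically favoured product.

Concentration presets come from the stated assay volumes (2.4 ul of 10 uM
stock into 1.92 ml gives 12.5 nM, etc.).  All concentrations are molar and
times are seconds.  Rate constants are second order (M^-1 s^-1) for
bimolecular steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trace",
    "FitResult",
    "SimulationResult",
    "KineticsError",
    "DegenerateTraceError",
    "simulate_network",
    "strand_conservation",
    "build_rate_assay_model",
    "build_catalytic_model",
    "build_pulse_model",
    "fit_rate_constant",
    "normalize_trace",
    "dilution",
    "RATE_ASSAY_CONCENTRATIONS",
    "CATALYTIC_CONCENTRATIONS",
    "PULSE_CONCENTRATIONS",
]


class KineticsError(ValueError):
    """Invalid network, trace, or fitting input."""


class DegenerateTraceError(KineticsError):
    """Normalization attempted with Fmax equal to Fmin."""


def dilution(volume_added_l: float, stock_m: float,
             volume_total_l: float = 1.92e-3) -> float:
    """Final concentration after injecting a stock into a cuvette."""
    return volume_added_l * stock_m / volume_total_l


# assay presets derived from the stated volumes: 2.4 ul of 10 uM
# substrate/invader and 2.4 ul of 20 uM reporter into 1.92 ml
RATE_ASSAY_CONCENTRATIONS = {
    "I": dilution(2.4e-6, 10e-6),
    "OT": dilution(2.4e-6, 10e-6),
    "Rep": dilution(2.4e-6, 20e-6),
}

CATALYTIC_CONCENTRATIONS = {"BD": 40e-9, "C": 200e-9, "A": 5e-9,
                            "Rep": 250e-9}

# [I5]:[I3]:[O.T] = 4:2:1 on the 12.5 nM substrate scale
PULSE_CONCENTRATIONS = {"OT": dilution(2.4e-6, 10e-6),
                        "I3": 2 * dilution(2.4e-6, 10e-6),
                        "I5": 4 * dilution(2.4e-6, 10e-6)}


@dataclass(frozen=True)
class Reaction:
    reactants: tuple
    products: tuple
    rate_constant: float

    def __post_init__(self):
        if self.rate_constant < 0:
            raise KineticsError("rate constants must be >= 0")
        if len(self.reactants) > 2:
            raise KineticsError("at most bimolecular reactions are supported")


@dataclass
class ReactionNetwork:
    """Named species with initial concentrations plus mass-action reactions.

    ``composition`` maps each complex to its strand content so strand
    conservation can be audited; ``signal_species`` and ``signal_scale``
    define the fractional-fluorescence observable (sum of the signal
    species divided by the completion concentration); ``channels`` holds
    extra named observables (used by the two-channel pulse model).
    """

    species: dict
    reactions: list
    composition: dict = field(default_factory=dict)
    signal_species: tuple = ()
    signal_scale: float | None = None
    channels: dict = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self):
        for rxn in self.reactions:
            for sp in rxn.reactants + rxn.products:
                if sp not in self.species:
                    raise KineticsError(
                        f"reaction references undeclared species {sp!r}")
        for sp, conc in self.species.items():
            if conc < 0:
                raise KineticsError(f"negative initial concentration for {sp}")

    @property
    def species_names(self) -> list:
        return list(self.species)

    def with_concentrations(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        sp = dict(self.species)
        unknown = set(updates) - set(sp)
        if unknown:
            raise KineticsError(f"unknown species {sorted(unknown)}")
        sp.update(updates)
        return replace(self, species=sp)


@dataclass(frozen=True)
class SimulationResult:
    time: np.ndarray
    frame: pd.DataFrame  # columns = species, molar

    def __getitem__(self, species: str) -> np.ndarray:
        return self.frame[species].to_numpy()

    def observable(self, species: Sequence[str]) -> np.ndarray:
        return self.frame[list(species)].sum(axis=1).to_numpy()


def _rhs_factory(network: ReactionNetwork, order: list):
    idx = {sp: i for i, sp in enumerate(order)}
    terms = []
    for rxn in network.reactions:
        r = [idx[s] for s in rxn.reactants]
        p = [idx[s] for s in rxn.products]
        terms.append((r, p, rxn.rate_constant))

    def rhs(t, y):
        dy = np.zeros_like(y)
        for r, p, k in terms:
            flux = k
            for i in r:
                flux *= y[i]
            for i in r:
                dy[i] -= flux
            for i in p:
                dy[i] += flux
        return dy

    return rhs


def simulate_network(network: ReactionNetwork,
                     time_grid: np.ndarray,
                     rtol: float = 1e-8,
                     atol_scale: float = 1e-12,
                     initial: Mapping[str, float] | None = None
                     ) -> SimulationResult:
    """Integrate the mass-action ODEs on ``time_grid`` (seconds).

    Concentrations are non-dimensionalised by the largest initial
    concentration so the solver tolerances behave sensibly at nanomolar
    scales.  Strand-conservation totals are preserved to solver accuracy.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise KineticsError("time_grid must be a strictly increasing vector")
    order = network.species_names
    conc0 = dict(network.species)
    if initial is not None:
        conc0.update(initial)
    y0 = np.array([conc0[s] for s in order], dtype=float)
    scale = y0.max() if y0.max() > 0 else 1.0
    scaled = replace(
        network,
        species={s: conc0[s] / scale for s in order},
        reactions=[replace(r, rate_constant=r.rate_constant *
                           (scale if len(r.reactants) == 2 else 1.0))
                   for r in network.reactions],
    )
    rhs = _rhs_factory(scaled, order)
    sol = solve_ivp(rhs, (t[0], t[-1]), y0 / scale, t_eval=t,
                    method="LSODA", rtol=rtol, atol=atol_scale)
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed for network {network.name!r}: {sol.message}")
    frame = pd.DataFrame(sol.y.T * scale, columns=order)
    return SimulationResult(time=t, frame=frame)


def strand_conservation(network: ReactionNetwork,
                        result: SimulationResult) -> pd.DataFrame:
    """Total concentration of each named strand over time."""
    strands = sorted({s for comp in network.composition.values()
                      for s in comp})
    data = {}
    for strand in strands:
        total = np.zeros(len(result.time))
        for sp in network.species_names:
            count = network.composition.get(sp, {}).get(strand, 0)
            if count:
                total += count * result[sp]
        data[strand] = total
    return pd.DataFrame(data)


# -- model builders -------------------------------------------------------

def build_rate_assay_model(k_disp: float,
                           reporter: str = "instantaneous",
                           k_rep: float | None = None,
                           concentrations: Mapping[str, float] | None = None
                           ) -> ReactionNetwork:
    """Single-displacement rate assay with reporter readout.

    ``reporter='instantaneous'`` maps the signal to the cumulative
    released output (the reporter is treated as an immediate sink);
    ``reporter='explicit'`` adds ``O + Rep -> OR + F`` with rate ``k_rep``
    and reads the released fluorophore strand F.
    """
    if k_disp <= 0:
        raise KineticsError("k_disp must be > 0")
    conc = dict(RATE_ASSAY_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    species = {"I": conc["I"], "OT": conc["OT"], "IT": 0.0, "O": 0.0}
    composition = {"I": {"I": 1}, "OT": {"O": 1, "T": 1},
                   "IT": {"I": 1, "T": 1}, "O": {"O": 1}}
    reactions = [Reaction(("I", "OT"), ("IT", "O"), k_disp)]
    if reporter == "instantaneous":
        signal = ("IT",)
    elif reporter == "explicit":
        if k_rep is None or k_rep <= 0:
            raise KineticsError("explicit reporter requires k_rep > 0")
        species.update({"Rep": conc["Rep"], "OR": 0.0, "F": 0.0})
        composition.update({"Rep": {"RF": 1, "RQ": 1},
                            "OR": {"O": 1, "RQ": 1}, "F": {"RF": 1}})
        reactions.append(Reaction(("O", "Rep"), ("OR", "F"), k_rep))
        signal = ("F",)
    else:
        raise KineticsError("reporter must be 'instantaneous' or 'explicit'")
    return ReactionNetwork(species=species, reactions=reactions,
                           composition=composition, signal_species=signal,
                           signal_scale=conc["OT"], name="rate_assay")


def build_catalytic_model(k1: float = 5e5, k1r: float = 5e5,
                          k2: float = 5e5, k2r: float = 5e5,
                          k_rep: float = 1e6,
                          k_leak: float = 0.0,
                          k_leakr: float | None = None,
                          reporter: bool = True,
                          concentrations: Mapping[str, float] | None = None
                          ) -> ReactionNetwork:
    """Catalytic toehold-exchange motif with optional leak channel.

    A catalyses B.D -> C.D via the exchanges ``A + B.D <=> B + A.D`` and
    ``C + A.D <=> A + C.D``.  ``k_leak`` enables the direct
    ``C + B.D <=> B + C.D`` channel (strong for the extended-fuel C2
    variant, weak otherwise); its reverse rate defaults to the
    thermodynamically consistent value ``k_leak * k1r*k2r/(k1*k2)`` so the
    reaction cycle has zero net driving.
    """
    for k in (k1, k1r, k2, k2r, k_rep, k_leak):
        if k < 0:
            raise KineticsError("rate constants must be >= 0")
    conc = dict(CATALYTIC_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    species = {"A": conc["A"], "BD": conc["BD"], "C": conc["C"],
               "B": 0.0, "AD": 0.0, "CD": 0.0}
    composition = {"A": {"A": 1}, "B": {"B": 1}, "C": {"C": 1},
                   "BD": {"B": 1, "D": 1}, "AD": {"A": 1, "D": 1},
                   "CD": {"C": 1, "D": 1}}
    reactions = [
        Reaction(("A", "BD"), ("B", "AD"), k1),
        Reaction(("B", "AD"), ("A", "BD"), k1r),
        Reaction(("C", "AD"), ("A", "CD"), k2),
        Reaction(("A", "CD"), ("C", "AD"), k2r),
    ]
    if k_leak > 0:
        consistent = (k_leak * k1r * k2r / (k1 * k2)
                      if k1 > 0 and k2 > 0 else 0.0)
        if k_leakr is None:
            k_leakr = consistent
        elif consistent > 0 and k_leakr > 0:
            residual = math.log(k_leakr / consistent)
            if abs(residual) > 1e-6:
                warnings.warn(
                    f"leak reverse rate violates thermodynamic cycle "
                    f"closure (log residual {residual:+.3f})")
        reactions.append(Reaction(("C", "BD"), ("B", "CD"), k_leak))
        if k_leakr and k_leakr > 0:
            reactions.append(Reaction(("B", "CD"), ("C", "BD"), k_leakr))
    signal = ()
    if reporter:
        species.update({"Rep": conc["Rep"], "BF": 0.0, "Q": 0.0})
        composition.update({"Rep": {"RF": 1, "RQ": 1},
                            "BF": {"B": 1, "RF": 1}, "Q": {"RQ": 1}})
        reactions.append(Reaction(("B", "Rep"), ("BF", "Q"), k_rep))
        signal = ("BF",)
    return ReactionNetwork(species=species, reactions=reactions,
                           composition=composition, signal_species=signal,
                           signal_scale=conc["BD"], name="catalytic")


def build_pulse_model(k3: float = 1e5, k3r: float = 50.0,
                      k5: float = 5e3, k5r: float = 2.5,
                      k_ex: float = 5e3, k_exr: float = 5e3,
                      concentrations: Mapping[str, float] | None = None
                      ) -> ReactionNetwork:
    """Two-toehold competitive displacement pulse generator.

    Invaders I3 (kinetically favoured: it eliminates the mismatch early)
    and I5 attack the substrate O.T from opposite toeholds, and I5
    displaces I3 from I3.T by toehold exchange.  The defaults encode a
    ~20x kinetic advantage for I3 with equal overall driving (both
    invaders eliminate the same mismatch), and the 4:2:1 concentration
    preset biases the final equilibrium toward I5.T.  A warning is issued
    if the three equilibrium constants violate the thermodynamic cycle
    I3.T + I5 <=> O.T + ... closure.
    """
    for k in (k3, k3r, k5, k5r, k_ex, k_exr):
        if k < 0:
            raise KineticsError("rate constants must be >= 0")
    if min(k3r, k5r, k_exr) > 0:
        residual = math.log((k3 / k3r) * (k_ex / k_exr) * (k5r / k5))
        if abs(residual) > 1e-6:
            warnings.warn(
                f"pulse rate constants violate thermodynamic cycle closure "
                f"(log residual {residual:+.3f})")
    conc = dict(PULSE_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    species = {"I3": conc["I3"], "I5": conc["I5"], "OT": conc["OT"],
               "I3T": 0.0, "I5T": 0.0, "O": 0.0}
    composition = {"I3": {"I3": 1}, "I5": {"I5": 1}, "O": {"O": 1},
                   "OT": {"O": 1, "T": 1}, "I3T": {"I3": 1, "T": 1},
                   "I5T": {"I5": 1, "T": 1}}
    reactions = [
        Reaction(("I3", "OT"), ("I3T", "O"), k3),
        Reaction(("I3T", "O"), ("I3", "OT"), k3r),
        Reaction(("I5", "OT"), ("I5T", "O"), k5),
        Reaction(("I5T", "O"), ("I5", "OT"), k5r),
        Reaction(("I5", "I3T"), ("I5T", "I3"), k_ex),
        Reaction(("I5T", "I3"), ("I5", "I3T"), k_exr),
    ]
    return ReactionNetwork(
        species=species, reactions=reactions, composition=composition,
        signal_species=("I3T",), signal_scale=conc["OT"],
        channels={"cy3": ("I3T",), "cy5": ("I5T",),
                  "O_inferred": ("I3T", "I5T")},
        name="pulse")


# -- traces and fitting ---------------------------------------------------

@dataclass(frozen=True)
class Trace:
    """Fluorescence time series (seconds, arbitrary units)."""

    time: np.ndarray
    signal: np.ndarray
    segments: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise KineticsError("time and signal must be equal-length vectors")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("trace time must be strictly increasing")
        if np.isnan(t).any() or np.isnan(s).any():
            raise KineticsError("trace contains NaN values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)

    def crop(self, t_lo: float, t_hi: float = np.inf) -> "Trace":
        mask = (self.time >= t_lo) & (self.time <= t_hi)
        return Trace(self.time[mask], self.signal[mask], dict(self.segments))

    def shifted(self, origin: float) -> "Trace":
        return Trace(self.time - origin, self.signal.copy(),
                     {k: (a - origin, b - origin)
                      for k, (a, b) in self.segments.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "signal": self.signal})


def normalize_trace(trace: Trace,
                    baseline_window: tuple,
                    max_window: tuple) -> Trace:
    """Fractional fluorescence recovery (F - Fmin) / (Fmax - Fmin).

    Fmin and Fmax are window means (windows given as (t_lo, t_hi) in
    seconds).  Invariant under affine transforms of the raw signal.
    """
    def window_mean(lo, hi):
        mask = (trace.time >= lo) & (trace.time <= hi)
        if not mask.any():
            raise KineticsError(f"empty normalization window ({lo}, {hi})")
        return float(trace.signal[mask].mean())

    fmin = window_mean(*baseline_window)
    fmax = window_mean(*max_window)
    span = fmax - fmin
    if abs(span) < 1e-12 * max(abs(fmax), abs(fmin), 1e-30):
        raise DegenerateTraceError("degenerate trace: Fmax equals Fmin")
    return Trace(trace.time, (trace.signal - fmin) / span,
                 dict(trace.segments))


@dataclass(frozen=True)
class FitResult:
    """Fitted rate constants with standard errors."""

    params: dict
    se: dict
    rss: float
    converged: bool
    model: str
    n_points: int
    n_starts: int

    def __getitem__(self, name: str) -> float:
        return self.params[name]


_AFFINE = ("scale", "baseline")


def _model_signal(builder: Callable, known: Mapping, values: Mapping,
                  time: np.ndarray) -> np.ndarray:
    kin = {k: v for k, v in values.items() if k not in _AFFINE}
    net = builder(**{**dict(known or {}), **kin})
    t = time
    prepend = t[0] > 0
    if prepend:
        t = np.concatenate([[0.0], t])
    sim = simulate_network(net, t)
    sig = sim.observable(net.signal_species)
    if net.signal_scale:
        sig = sig / net.signal_scale
    if prepend:
        sig = sig[1:]
    scale = values.get("scale", 1.0)
    baseline = values.get("baseline", 0.0)
    return baseline + scale * sig


def fit_rate_constant(trace: Trace,
                      model_builder: Callable[..., ReactionNetwork],
                      free_parameters: Sequence[str],
                      init_guess: Mapping[str, float],
                      bounds: Mapping[str, tuple] | None = None,
                      known: Mapping | None = None,
                      n_starts: int = 5) -> FitResult:
    """Nonlinear least squares of an ODE model against a fractional trace.

    Rate constants are optimised in log10 space (which enforces
    positivity); the reserved names ``scale`` and ``baseline`` fit an
    affine signal map linearly.  ``n_starts`` log-spaced multi-starts
    (decade offsets applied to every free rate constant) guard against
    local minima; the fit is deterministic for a given ``init_guess``.
    Non-convergence is flagged on the result rather than raised.
    """
    free = list(free_parameters)
    if len(trace.time) < len(free) + 2:
        raise KineticsError("need at least n_free + 2 data points")
    missing = [p for p in free if p not in init_guess]
    if missing:
        raise KineticsError(f"init_guess missing {missing}")
    bounds = dict(bounds or {})
    log_names = [p for p in free if p not in _AFFINE]
    lin_names = [p for p in free if p in _AFFINE]

    def pack(values):
        return np.array([math.log10(values[p]) for p in log_names]
                        + [values[p] for p in lin_names])

    def unpack(theta):
        vals = {p: 10.0 ** theta[i] for i, p in enumerate(log_names)}
        vals.update({p: theta[len(log_names) + i]
                     for i, p in enumerate(lin_names)})
        return vals

    lo, hi = [], []
    for p in log_names:
        b = bounds.get(p, (1e-1, 1e8))
        lo.append(math.log10(b[0]))
        hi.append(math.log10(b[1]))
    for p in lin_names:
        b = bounds.get(p, (0.1, 10.0) if p == "scale" else (-1.0, 1.0))
        lo.append(b[0])
        hi.append(b[1])

    def residuals(theta):
        try:
            pred = _model_signal(model_builder, known, unpack(theta),
                                 trace.time)
        except RuntimeError:
            return np.full(len(trace.time), 1e3)
        return pred - trace.signal

    offsets = np.linspace(-2, 2, n_starts) if n_starts > 1 else [0.0]
    best = None
    for off in offsets:
        theta0 = pack(init_guess).copy()
        theta0[:len(log_names)] += off
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult(params=dict(init_guess), se={}, rss=float("nan"),
                         converged=False, model=getattr(
                             model_builder, "__name__", "model"),
                         n_points=len(trace.time), n_starts=n_starts)
    values = unpack(best.x)
    rss = float(2 * best.cost)
    n, p = len(trace.time), len(best.x)
    se = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (rss / max(n - p, 1))
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        for i, name in enumerate(log_names):
            se[name] = values[name] * math.log(10.0) * sd[i]
        for i, name in enumerate(lin_names):
            se[name] = sd[len(log_names) + i]
        se_ok = all(np.isfinite(list(se.values())))
    except np.linalg.LinAlgError:
        se_ok = False
    converged = bool(best.status > 0 and np.isfinite(rss))
    return FitResult(params=values, se=se, rss=rss, converged=converged,
                     model=getattr(model_builder, "__name__", "model"),
                     n_points=n, n_starts=n_starts)
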