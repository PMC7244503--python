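"""Discrete-state Markov chain of toehold binding and branch migration.

The displacement free-energy profile is turned into a continuous-time
Markov chain with states

    DETACHED  <-  TOEHOLD_BOUND  <->  BRANCH(h+1) ... BRANCH(n_max)  ->  DISPLACED

Branch-migration transitions use Metropolis rates on the profile free
energies, so detailed balance holds between all reversible transient
pairs.  Toehold binding is a single bimolecular step whose second-order
constant ``k_toehold`` is recorded separately; the detachment rate follows
from the toehold binding free energy by detailed balance at a 1 M
reference concentration.  Reaching BRANCH(n_max) commits the reaction:
the last branch state feeds DISPLACED irreversibly.

Exact splitting probabilities, the conditional decomposition
p(disp|toehold) = p(bp x reached|toehold) * p(disp|bp x reached), relative
rates versus mismatch position, kinetic Monte Carlo, and first-order-limit
mean first-passage times are all computed on this chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import kcal_to_kbt
from .nn_thermo import (
    DisplacementSystem,
    FreeEnergyProfile,
    NNParameterSet,
    displacement_profile,
    duplex_free_energy,
    revcomp,
)

__all__ = [
    "ChainError",
    "MarkovChain",
    "LandscapeParams",
    "DecompositionResult",
    "RateResult",
    "KMCResult",
    "build_chain",
    "chain_for_system",
    "splitting_probability_exact",
    "conditional_probabilities",
    "relative_rate",
    "kmc_splitting",
    "mean_first_passage_time",
]

DETACHED = "DETACHED"
TOEHOLD_BOUND = "TOEHOLD_BOUND"
DISPLACED = "DISPLACED"


class ChainError(ValueError):
    """Invalid chain construction or query."""


@dataclass(frozen=True)
class MarkovChain:
    """Labelled CTMC with two absorbing fates.

    ``rates[i, j]`` is the transition rate i -> j in 1/s; ``G`` holds the
    free energy of each transient state in kB*T (NaN for absorbing
    states); ``coordinate`` is the reaction coordinate (number of
    invader-target base pairs; DETACHED sits below all interfaces and
    DISPLACED above).  ``k_toehold`` (M^-1 s^-1) is the bimolecular
    binding constant of the DETACHED -> TOEHOLD_BOUND step, recorded
    separately from the unimolecular rate matrix.
    """

    labels: tuple
    G: np.ndarray
    rates: np.ndarray
    coordinate: np.ndarray
    k_toehold: float = 3.0e6

    def __post_init__(self):
        object.__setattr__(self, "_index",
                           {lab: i for i, lab in enumerate(self.labels)})

    def index(self, label: str) -> int:
        return self._index[label]

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def absorbing(self) -> tuple:
        return tuple(lab for lab in (DETACHED, DISPLACED) if lab in self._index)

    def transient_indices(self) -> np.ndarray:
        absorbing = {self.index(a) for a in self.absorbing}
        return np.array([i for i in range(self.n_states) if i not in absorbing])

    def validate(self, tol: float = 1e-9) -> None:
        for a in self.absorbing:
            if self.rates[self.index(a)].any():
                raise ChainError(f"absorbing state {a} has outgoing rate")
        if not np.isfinite(self.G[self.transient_indices()]).all():
            raise ChainError("non-finite free energy on a transient state")
        tr = self.transient_indices()
        for i in tr:
            for j in tr:
                if i < j and self.rates[i, j] > 0 and self.rates[j, i] > 0:
                    lhs = self.rates[i, j] / self.rates[j, i]
                    rhs = np.exp(self.G[i] - self.G[j])
                    if abs(lhs - rhs) > tol * max(1.0, rhs):
                        raise ChainError(
                            f"detailed balance violated between "
                            f"{self.labels[i]} and {self.labels[j]}"
                        )

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"state_from": self.labels[i], "state_to": self.labels[j],
             "rate_s_inv": self.rates[i, j]}
            for i in range(self.n_states)
            for j in range(self.n_states)
            if self.rates[i, j] > 0
        ]
        return pd.DataFrame(rows)


def build_chain(profile: FreeEnergyProfile,
                k_bm: float = 1.0e4,
                k_toehold: float = 3.0e6,
                toehold_dg: float = -5.0) -> MarkovChain:
    """Assemble the displacement chain from a free-energy profile.

    ``k_bm`` is the branch-migration attempt rate (1/s); the profile's
    sawtooth barrier attenuates it as ``k_bm * exp(-sawtooth)``.
    ``toehold_dg`` (kB*T, negative = stable) sets the detachment rate via
    detailed balance with the bimolecular binding step at a 1 M reference
    concentration: ``k_off = k_toehold * (1 M) * exp(toehold_dg)``.
    """
    if k_bm <= 0:
        raise ChainError("k_bm must be > 0")
    if not np.isfinite(profile.G).all():
        raise ChainError("profile free energies must be finite")
    h = profile.toehold_length
    n_max = profile.n_max
    labels = [DETACHED, TOEHOLD_BOUND]
    coords = [h - 1, h]
    for n in range(h + 1, n_max + 1):
        labels.append(f"BRANCH({n})")
        coords.append(n)
    labels.append(DISPLACED)
    coords.append(n_max + 1)
    S = len(labels)
    G = np.full(S, np.nan)
    for i, lab in enumerate(labels):
        if lab == TOEHOLD_BOUND:
            G[i] = profile.g_at(h)
        elif lab.startswith("BRANCH"):
            G[i] = profile.g_at(coords[i])
    rates = np.zeros((S, S))
    k_eff = k_bm * np.exp(-profile.sawtooth)

    def metropolis(gi: float, gj: float) -> float:
        return k_eff * min(1.0, np.exp(gi - gj))

    # toehold detachment
    rates[1, 0] = k_toehold * 1.0 * np.exp(toehold_dg)
    # branch-migration ladder (TOEHOLD_BOUND acts as coordinate n = h)
    for i in range(1, S - 2):
        rates[i, i + 1] = metropolis(G[i], G[i + 1])
        if i > 1:
            rates[i, i - 1] = metropolis(G[i], G[i - 1])
    # the last branch state commits irreversibly
    rates[S - 2, S - 3] = 0.0
    rates[S - 2, S - 1] = k_eff
    chain = MarkovChain(labels=tuple(labels), G=G, rates=rates,
                        coordinate=np.array(coords), k_toehold=k_toehold)
    chain.validate()
    return chain


@dataclass(frozen=True)
class LandscapeParams:
    """Calibrated landscape defaults for rate studies.

    ``nn_params=None`` selects the sequence-averaged (uniform) parameter
    set, so relative rates depend on mismatch position and type only.
    ``toehold_dg=None`` derives the toehold binding free energy from the
    system's toehold sequence with the same parameter set.
    """

    k_bm: float = 1.0e4
    k_toehold: float = 3.0e6
    f_max: int = 3
    sawtooth: float = 0.0
    plateau_penalty: float = 2.0
    nn_params: NNParameterSet | None = None
    toehold_dg: float | None = None

    def resolve_params(self) -> NNParameterSet:
        return self.nn_params if self.nn_params is not None \
            else NNParameterSet.uniform()


def chain_for_system(system: DisplacementSystem,
                     rate_params: LandscapeParams | None = None
                     ) -> tuple[FreeEnergyProfile, MarkovChain]:
    """Profile + chain for a displacement system under landscape defaults."""
    lp = rate_params or LandscapeParams()
    params = lp.resolve_params()
    profile = displacement_profile(system, params=params, f_max=lp.f_max,
                                   sawtooth=lp.sawtooth,
                                   plateau_penalty=lp.plateau_penalty)
    if lp.toehold_dg is not None:
        toehold_dg = lp.toehold_dg
    else:
        dg_kcal = duplex_free_energy(system.toehold, revcomp(system.toehold),
                                     params=params,
                                     temperature=system.temperature)
        toehold_dg = kcal_to_kbt(dg_kcal, system.temperature)
    chain = build_chain(profile, k_bm=lp.k_bm, k_toehold=lp.k_toehold,
                        toehold_dg=toehold_dg)
    return profile, chain


# -- exact absorption solves ---------------------------------------------

def _generator_submatrix(chain: MarkovChain,
                         transient: np.ndarray) -> np.ndarray:
    Q = chain.rates[np.ix_(transient, transient)].astype(float).copy()
    total_out = chain.rates[transient].sum(axis=1)
    np.fill_diagonal(Q, Q.diagonal() - total_out)
    return Q


def _absorption_probabilities(chain: MarkovChain) -> dict[str, float]:
    """p(DISPLACED before DETACHED) for every transient state."""
    transient = chain.transient_indices()
    Q = _generator_submatrix(chain, transient)
    b = -chain.rates[transient, chain.index(DISPLACED)]
    try:
        p = np.linalg.solve(Q, b)
    except np.linalg.LinAlgError as exc:
        raise ChainError(f"singular absorption system: {exc}") from exc
    return {chain.labels[s]: float(p[i]) for i, s in enumerate(transient)}


def splitting_probability_exact(chain: MarkovChain,
                                start: str = TOEHOLD_BOUND) -> float:
    """Probability of absorption in DISPLACED before DETACHED from ``start``.

    If the chain has no detachment pathway the probability is exactly 1.
    """
    if chain.rates[:, chain.index(DETACHED)].sum() == 0:
        return 1.0
    return _absorption_probabilities(chain)[start]


@dataclass(frozen=True)
class DecompositionResult:
    """Per-position conditional decomposition of p(disp|toehold)."""

    x: np.ndarray
    p_reach: np.ndarray
    p_disp_given_reach: np.ndarray
    p_disp_given_toehold: float

    @property
    def product(self) -> np.ndarray:
        return self.p_reach * self.p_disp_given_reach

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x,
            "p_reach": self.p_reach,
            "p_disp_given_reach": self.p_disp_given_reach,
            "product": self.product,
        })


def conditional_probabilities(chain: MarkovChain,
                              x_values: Iterable[int]) -> DecompositionResult:
    """Split p(disp|toehold) at reference branch positions ``x``.

    ``p_reach(x)`` is the probability of hitting BRANCH(h+x) before
    DETACHED starting toehold-bound; ``p_disp_given_reach(x)`` the
    probability of displacement from BRANCH(h+x).  Both are exact
    absorption solves; because the chain is one dimensional their product
    equals the overall splitting probability for every x.
    """
    h = int(chain.coordinate[chain.index(TOEHOLD_BOUND)])
    branch_coords = [int(c) for lab, c in zip(chain.labels, chain.coordinate)
                     if lab.startswith("BRANCH")]
    n_max = max(branch_coords)
    x_values = list(x_values)
    for x in x_values:
        if not 1 <= x <= n_max - h:
            raise ChainError(
                f"x={x} outside the branch-migration range 1..{n_max - h}")
    absorb_full = _absorption_probabilities(chain)
    p_overall = absorb_full[TOEHOLD_BOUND]
    p_reach = np.empty(len(x_values))
    p_dgr = np.empty(len(x_values))
    det = chain.index(DETACHED)
    for k, x in enumerate(x_values):
        target = chain.index(f"BRANCH({h + x})")
        sub = np.array([i for i in chain.transient_indices()
                        if chain.coordinate[i] < h + x])
        Q = _generator_submatrix(chain, sub)
        b = -chain.rates[sub, target]
        try:
            p = np.linalg.solve(Q, b)
        except np.linalg.LinAlgError as exc:
            raise ChainError(f"singular reach system at x={x}") from exc
        p_reach[k] = p[list(sub).index(chain.index(TOEHOLD_BOUND))]
        p_dgr[k] = absorb_full[f"BRANCH({h + x})"]
    return DecompositionResult(
        x=np.array(x_values), p_reach=p_reach, p_disp_given_reach=p_dgr,
        p_disp_given_toehold=p_overall)


@dataclass(frozen=True)
class RateResult:
    """Effective second-order rate constant relative to a reference."""

    k: float
    k0: float
    ratio: float
    regime: str = "second-order"
    p: float = float("nan")
    p0: float = float("nan")


def relative_rate(system: DisplacementSystem,
                  reference: DisplacementSystem,
                  rate_params: LandscapeParams | None = None) -> RateResult:
    """Rate constant of ``system`` relative to ``reference``.

    In the second-order limit k = k_toehold * p(disp|toehold); with a
    shared toehold the binding constant cancels, so the ratio is the ratio
    of exact splitting probabilities.
    """
    if (system.toehold_length != reference.toehold_length
            or system.toehold != reference.toehold):
        raise ChainError(
            "relative_rate requires identical toeholds; the k_toehold "
            "cancellation is invalid otherwise"
        )
    lp = rate_params or LandscapeParams()
    _, chain = chain_for_system(system, lp)
    _, chain0 = chain_for_system(reference, lp)
    p = splitting_probability_exact(chain)
    p0 = splitting_probability_exact(chain0)
    if p0 <= 0:
        raise ChainError("reference splitting probability is zero")
    return RateResult(k=lp.k_toehold * p, k0=lp.k_toehold * p0,
                      ratio=p / p0, p=p, p0=p0)


# -- stochastic simulation -----------------------------------------------

def _jump_tables(chain: MarkovChain):
    """Per-state outgoing targets, cumulative probabilities, total rates."""
    targets, cumprobs, totals = [], [], []
    for i in range(chain.n_states):
        row = chain.rates[i]
        nz = np.nonzero(row)[0]
        tot = row[nz].sum()
        targets.append(nz)
        totals.append(tot)
        cumprobs.append(np.cumsum(row[nz]) / tot if tot > 0 else np.array([]))
    return targets, cumprobs, np.array(totals)


@dataclass(frozen=True)
class KMCResult:
    estimate: float
    se: float
    n_displaced: int
    n_traj: int
    mean_time: float


def kmc_splitting(chain: MarkovChain, n_traj: int, seed: int) -> KMCResult:
    """Gillespie trajectories from TOEHOLD_BOUND until absorption.

    Each trajectory index gets its own RNG stream spawned from ``seed``,
    so results are bit-identical for a given seed regardless of execution
    order.  Returns the displaced fraction with its binomial standard
    error.
    """
    if n_traj < 1:
        raise ChainError("n_traj must be >= 1")
    targets, cumprobs, totals = _jump_tables(chain)
    start = chain.index(TOEHOLD_BOUND)
    disp = chain.index(DISPLACED)
    det = chain.index(DETACHED)
    streams = np.random.SeedSequence(seed).spawn(n_traj)
    n_disp = 0
    t_sum = 0.0
    for child in streams:
        rng = np.random.default_rng(child)
        state = start
        t = 0.0
        while state != disp and state != det:
            tot = totals[state]
            t += rng.exponential(1.0 / tot)
            u = rng.random()
            state = targets[state][np.searchsorted(cumprobs[state], u)]
        if state == disp:
            n_disp += 1
        t_sum += t
    p = n_disp / n_traj
    se = float(np.sqrt(p * (1.0 - p) / n_traj))
    return KMCResult(estimate=p, se=se, n_displaced=n_disp, n_traj=n_traj,
                     mean_time=t_sum / n_traj)


def mean_first_passage_time(chain: MarkovChain) -> float:
    """Exact MFPT (seconds) from TOEHOLD_BOUND to DISPLACED.

    First-order, high-concentration limit: detachment is switched off
    (a detached invader is instantly replaced), making DETACHED
    reflecting, and the expected absorption time into DISPLACED is
    obtained from the linear system Q t = -1.
    """
    rates = chain.rates.copy()
    rates[:, chain.index(DETACHED)] = 0.0
    mod = MarkovChain(labels=chain.labels, G=chain.G, rates=rates,
                      coordinate=chain.coordinate, k_toehold=chain.k_toehold)
    transient = np.array([i for i in range(mod.n_states)
                          if i != mod.index(DISPLACED)
                          and i != mod.index(DETACHED)])
    Q = _generator_submatrix(mod, transient)
    try:
        t = np.linalg.solve(Q, -np.ones(len(transient)))
    except np.linalg.LinAlgError as exc:
        raise ChainError("DISPLACED unreachable: singular MFPT system") from exc
    if (t < 0).any() or not np.isfinite(t).all():
        raise ChainError("DISPLACED unreachable from some transient state")
    return float(t[list(transient).index(chain.index(TOEHOLD_BOUND))])
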