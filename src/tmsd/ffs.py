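"""Direct forward flux sampling over the displacement Markov chain.

FFS estimates the small splitting probability p(disp|toehold) as a product
of interface-crossing probabilities on the reaction coordinate (number of
invader-target base pairs).  Trials start toehold-bound, are propagated by
kinetic Monte Carlo until they either cross the next interface (success;
the crossing state is stored as a restart configuration) or fall back to
the failure boundary DETACHED.  Because the chain is memoryless, storing
the state label makes restarts exact in distribution.

The final interface is the displacement-committed coordinate (absorption
into DISPLACED), so the product of crossing probabilities estimates the
same quantity as the exact absorption solve, against which it is
validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape import (
    DETACHED,
    DISPLACED,
    TOEHOLD_BOUND,
    ChainError,
    LandscapeParams,
    MarkovChain,
    _jump_tables,
    chain_for_system,
)
from .nn_thermo import DisplacementSystem

__all__ = [
    "FFSConfig",
    "FFSResult",
    "FFSRatio",
    "InterfaceStarvedError",
    "default_interfaces",
    "run_ffs",
    "relative_rate_ffs",
]


class InterfaceStarvedError(RuntimeError):
    """No trial crossed an interface; the estimate cannot continue."""

    def __init__(self, stage: int, value: float):
        self.stage = stage
        self.value = value
        super().__init__(
            f"interface starved: 0 of the trials launched toward interface "
            f"#{stage} (coordinate {value}) crossed it"
        )


@dataclass(frozen=True)
class FFSConfig:
    """Interface set and sampling effort.

    ``interfaces=None`` selects the default placement for the chain at
    hand (every 2 branch-coordinate units, ending at the committed
    coordinate).
    """

    interfaces: tuple | None = None
    trials_per_interface: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_interface < 1:
            raise ValueError("trials_per_interface must be >= 1")
        if self.interfaces is not None:
            ifs = tuple(self.interfaces)
            if any(b <= a for a, b in zip(ifs, ifs[1:])):
                raise ValueError("interfaces must be strictly increasing")
            object.__setattr__(self, "interfaces", ifs)


def default_interfaces(chain: MarkovChain) -> tuple:
    """Every 2 branch-coordinate units from h+1 up to the committed state."""
    h = int(chain.coordinate[chain.index(TOEHOLD_BOUND)])
    committed = int(chain.coordinate[chain.index(DISPLACED)])
    ifs = list(range(h + 1, committed, 2))
    ifs.append(committed)
    return tuple(ifs)


@dataclass(frozen=True)
class FFSResult:
    interfaces: tuple
    p_interface: np.ndarray
    n_success: np.ndarray
    n_trials: np.ndarray
    p_total: float
    se_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interface": list(self.interfaces),
            "p_interface": self.p_interface,
            "n_success": self.n_success,
            "n_trials": self.n_trials,
        })

    def to_dict(self) -> dict:
        return {
            "p_total": self.p_total,
            "se_total": self.se_total,
            "interfaces": [
                {"coordinate": float(c), "p": float(p),
                 "n_success": int(s), "n_trials": int(t)}
                for c, p, s, t in zip(self.interfaces, self.p_interface,
                                      self.n_success, self.n_trials)
            ],
        }


def _propagate(state, lam, threshold, targets, cumprobs, det, rng):
    """KMC until the coordinate reaches ``threshold`` or DETACHED."""
    while True:
        if lam[state] >= threshold:
            return state
        if state == det:
            return None
        u = rng.random()
        state = targets[state][np.searchsorted(cumprobs[state], u)]


def run_ffs(chain: MarkovChain, config: FFSConfig) -> FFSResult:
    """Direct FFS estimate of p(disp|toehold) on ``chain``.

    Raises :class:`InterfaceStarvedError` when an interface collects no
    successful crossings.  Reproducible: each stage draws from its own
    RNG stream spawned from ``config.seed``.
    """
    lam = chain.coordinate.astype(float)
    interfaces = config.interfaces or default_interfaces(chain)
    h = lam[chain.index(TOEHOLD_BOUND)]
    if interfaces[0] < h:
        raise ChainError("first interface must be at or above the "
                         "toehold-bound coordinate")
    targets, cumprobs, _ = _jump_tables(chain)
    det = chain.index(DETACHED)
    start = chain.index(TOEHOLD_BOUND)
    streams = np.random.SeedSequence(config.seed).spawn(len(interfaces))
    n_trials = config.trials_per_interface
    pool = [start]
    p_list, s_list = [], []
    for stage, threshold in enumerate(interfaces):
        rng = np.random.default_rng(streams[stage])
        successes = []
        for _ in range(n_trials):
            s0 = pool[rng.integers(len(pool))] if stage else start
            end = _propagate(s0, lam, threshold, targets, cumprobs, det, rng)
            if end is not None:
                successes.append(end)
        if not successes:
            raise InterfaceStarvedError(stage, threshold)
        p_list.append(len(successes) / n_trials)
        s_list.append(len(successes))
        pool = successes
    p = np.array(p_list)
    n = np.full(len(interfaces), n_trials)
    p_total = float(np.prod(p))
    rel_var = np.sum((1.0 - p) / (p * n))
    se_total = p_total * float(np.sqrt(rel_var))
    return FFSResult(interfaces=tuple(interfaces), p_interface=p,
                     n_success=np.array(s_list), n_trials=n,
                     p_total=p_total, se_total=se_total)


@dataclass(frozen=True)
class FFSRatio:
    ratio: float
    se: float
    system: FFSResult
    reference: FFSResult


def relative_rate_ffs(system: DisplacementSystem,
                      reference: DisplacementSystem,
                      config: FFSConfig,
                      rate_params: LandscapeParams | None = None) -> FFSRatio:
    """Relative rate constant from the ratio of FFS flux products.

    Both systems are sampled with the same configuration (and therefore
    the same seed policy), so an identical system and reference give a
    ratio of exactly 1.  Interfaces default to each chain's own placement
    because the committed coordinate differs between mismatch and
    mismatch-free systems.
    """
    if (system.toehold_length != reference.toehold_length
            or system.toehold != reference.toehold):
        raise ChainError("relative_rate_ffs requires identical toeholds")
    _, chain_s = chain_for_system(system, rate_params)
    _, chain_r = chain_for_system(reference, rate_params)
    res_s = run_ffs(chain_s, config)
    res_r = run_ffs(chain_r, config)
    ratio = res_s.p_total / res_r.p_total
    se = ratio * float(np.sqrt((res_s.se_total / res_s.p_total) ** 2
                               + (res_r.se_total / res_r.p_total) ** 2))
    return FFSRatio(ratio=ratio, se=se, system=res_s, reference=res_r)
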