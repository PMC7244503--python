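"""Nearest-neighbour duplex thermodynamics for strand-displacement design.

This module scores DNA duplexes with the unified nearest-neighbour (NN)
model (SantaLucia & Hicks parameter set, as distributed with Biopython's
``Bio.SeqUtils.MeltingTemp`` tables) extended with the published internal
single-mismatch stacks (Allawi & SantaLucia; Peyret et al.).  On top of the
plain duplex score it builds free-energy profiles of strand-displacement
intermediates: macrostates are labelled by the number of invader-target
base pairs ``n``, and each macrostate is a partition sum over microstates
in which up to ``f_max`` incumbent-target base pairs ahead of the branch
point have frayed open.  Fraying is what makes a mismatch at domain
position 2 cheaper to carry than a deeper mismatch: the terminal base pair
of the incumbent duplex can open, converting an enclosed (expensive)
mismatch into a terminal (cheap) one.

Conventions
-----------
* All sequences are written 5'->3'.
* The target strand is ``toehold + displacement domain``; domain position 1
  is the base adjacent to the toehold (the toehold-proximal end), and the
  mismatch position ``x`` is 1-based in that coordinate.
* Duplex free energies are in kcal/mol; profile free energies are in kB*T
  at the system temperature, with G(n=1) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import logsumexp
from Bio.SeqUtils import MeltingTemp as _mt

from .constants import GAS_CONSTANT_KCAL, kelvin, kcal_to_kbt

__all__ = [
    "COMPLEMENT",
    "complement",
    "revcomp",
    "SaltModel",
    "NNParameterSet",
    "DisplacementSystem",
    "FreeEnergyProfile",
    "ThermodynamicsError",
    "UnsupportedStepError",
    "duplex_free_energy",
    "reaction_delta_g",
    "displacement_profile",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class ThermodynamicsError(ValueError):
    """Invalid sequence or unsupported pairing context."""


class UnsupportedStepError(ThermodynamicsError):
    """A dinucleotide step with no parameter table entry."""


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ThermodynamicsError(f"unsupported base symbol {base!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement of a 5'->3' sequence (result also 5'->3')."""
    return "".join(complement(b) for b in reversed(seq))


def _check_sequence(seq: str, name: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ThermodynamicsError(
            f"unsupported base symbol(s) {sorted(bad)} in {name} sequence"
        )


def _is_wc(top: str, bottom: str) -> bool:
    return COMPLEMENT.get(top) == bottom


@dataclass(frozen=True)
class SaltModel:
    """Monovalent-equivalent salt correction.

    The entropy of each dinucleotide stack is adjusted by
    ``0.368 * ln([Na+]_eq)`` cal/(mol K), with divalent magnesium folded
    into a sodium equivalent through the common square-root heuristic
    ``[Na+]_eq = [Na+] + 0.120 * sqrt([Mg2+]/1 mM) M``.  Defaults describe
    the fluorometry buffer used for the displacement assays
    (50 mM NaCl + 10 mM MgCl2).
    """

    monovalent_m: float = 0.050
    magnesium_m: float = 0.010
    name: str = "monovalent-equivalent"

    @property
    def sodium_equivalent_m(self) -> float:
        # 120 mM per sqrt(mM) of Mg2+, expressed in molar units
        return self.monovalent_m + 0.120 * math.sqrt(self.magnesium_m * 1000.0)

    def entropy_per_stack(self) -> float:
        """cal/(mol K) added to each stack's entropy."""
        return 0.368 * math.log(self.sodium_equivalent_m)


def _invert_key(key: str) -> str:
    # Read the same dinucleotide duplex step from the opposite strand.
    return key[4] + key[3] + "/" + key[1] + key[0]


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbour parameter tables.

    ``watson_crick`` and ``internal_mismatch`` map dinucleotide step keys
    ``"XY/WZ"`` (top strand 5'->3' over bottom strand 3'->5') to
    ``(dH kcal/mol, dS cal/(mol K))`` pairs.  Free energies at temperature
    ``T`` are reconstructed as ``dH - T*dS``.
    """

    watson_crick: Mapping[str, tuple]
    internal_mismatch: Mapping[str, tuple]
    initiation: tuple
    terminal_at: tuple
    salt: SaltModel | None = None
    temperature_reference: float = 37.0

    # -- constructors -----------------------------------------------------
    @classmethod
    def default(cls, salt: SaltModel | None = SaltModel()) -> "NNParameterSet":
        """Unified WC table plus published internal-mismatch stacks."""
        wc = {k: v for k, v in _mt.DNA_NN4.items()
              if "/" in k and not k.startswith("init") and k != "sym"}
        imm = {k: v for k, v in _mt.DNA_IMM1.items() if "/" in k}
        return cls(
            watson_crick=wc,
            internal_mismatch=imm,
            initiation=_mt.DNA_NN4["init"],
            terminal_at=_mt.DNA_NN4["init_A/T"],
            salt=salt,
        )

    @classmethod
    def uniform(cls, mismatch_pair: str = "CC",
                salt: SaltModel | None = SaltModel()) -> "NNParameterSet":
        """Sequence-averaged parameter set.

        Every WC stack takes the mean (dH, dS) of the ten unique WC stacks;
        every mismatch stack takes the mean over the stacks whose central
        pair is ``mismatch_pair`` (C-C by default, the pairing used in the
        mismatch-elimination series).  Terminal penalties are zeroed so
        profiles built from this set are strictly sequence independent.
        Used for calibrated landscape studies where only the position of a
        mismatch, not the sequence, should matter.
        """
        base = cls.default(salt=salt)
        wc_vals = list(base.watson_crick.values())
        wc_mean = (float(np.mean([v[0] for v in wc_vals])),
                   float(np.mean([v[1] for v in wc_vals])))
        a, b = mismatch_pair[0], mismatch_pair[1]
        mm_vals = [v for k, v in base.internal_mismatch.items()
                   if (k[1], k[4]) == (a, b) or (k[0], k[3]) == (a, b)
                   or (k[1], k[4]) == (b, a) or (k[0], k[3]) == (b, a)]
        mm_mean = (float(np.mean([v[0] for v in mm_vals])),
                   float(np.mean([v[1] for v in mm_vals])))
        return cls(
            watson_crick={k: wc_mean for k in base.watson_crick},
            internal_mismatch={k: mm_mean for k in base.internal_mismatch},
            initiation=base.initiation,
            terminal_at=(0.0, 0.0),
            salt=salt,
        )

    # -- lookups ----------------------------------------------------------
    def wc_stack(self, key: str) -> tuple:
        if key in self.watson_crick:
            return self.watson_crick[key]
        inv = _invert_key(key)
        if inv in self.watson_crick:
            return self.watson_crick[inv]
        raise UnsupportedStepError(f"no Watson-Crick entry for step {key!r}")

    def mismatch_stack(self, key: str) -> tuple:
        if key in self.internal_mismatch:
            return self.internal_mismatch[key]
        inv = _invert_key(key)
        if inv in self.internal_mismatch:
            return self.internal_mismatch[inv]
        raise UnsupportedStepError(
            f"unsupported mismatch context: no table entry for dinucleotide "
            f"step {key!r} (or its strand-swapped form {inv!r})"
        )


def _step_params(params: NNParameterSet, top2: str, bot2: str,
                 wc_flags: tuple[bool, bool]) -> tuple:
    key = top2 + "/" + bot2
    if all(wc_flags):
        return params.wc_stack(key)
    if sum(wc_flags) == 1:
        return params.mismatch_stack(key)
    raise UnsupportedStepError(
        f"two adjacent non-Watson-Crick pairs in step {key!r} are not "
        f"supported by the internal-mismatch tables"
    )


def _duplex_dh_ds(top: str, bottom_aligned: str, params: NNParameterSet,
                  allow_edge_mismatch: bool = False) -> tuple[float, float]:
    """(dH, dS) of a duplex given the bottom strand aligned 3'->5' under top.

    With ``allow_edge_mismatch`` a mismatched pair sitting at a duplex end
    contributes no stack and no terminal penalty: it is treated as an
    unstacked, effectively frayed terminal pair.
    """
    L = len(top)
    wc = [_is_wc(a, b) for a, b in zip(top, bottom_aligned)]
    if not allow_edge_mismatch and L and (not wc[0] or not wc[-1]):
        raise ThermodynamicsError(
            "terminal mismatches are not supported here; model duplex-end "
            "fraying through displacement_profile instead"
        )
    dh = ds = 0.0
    n_stacks = 0
    for i in range(L - 1):
        edge_mm = (i == 0 and not wc[0]) or (i == L - 2 and not wc[-1])
        if edge_mm and allow_edge_mismatch:
            continue
        h, s = _step_params(params, top[i:i + 2], bottom_aligned[i:i + 2],
                            (wc[i], wc[i + 1]))
        dh += h
        ds += s
        n_stacks += 1
    if L:
        h0, s0 = params.initiation
        dh += h0
        ds += s0
        for end in (0, L - 1):
            if wc[end] and top[end] in "AT":
                h1, s1 = params.terminal_at
                dh += h1
                ds += s1
    if params.salt is not None and L > 1:
        ds += params.salt.entropy_per_stack() * (L - 1)
    return dh, ds


def duplex_free_energy(top: str, bottom: str,
                       params: NNParameterSet | None = None,
                       temperature: float = 25.0) -> float:
    """Standard free energy (kcal/mol) of a duplex of two 5'->3' strands.

    The two strands must have equal length and pair antiparallel; every
    opposed pair must be Watson-Crick or a supported internal mismatch, and
    terminal mismatches are rejected (end effects are handled by the
    fraying microstates of :func:`displacement_profile`).  More negative
    values mean a more stable duplex.
    """
    if params is None:
        params = NNParameterSet.default()
    _check_sequence(top, "top")
    _check_sequence(bottom, "bottom")
    if len(top) != len(bottom):
        raise ThermodynamicsError("duplex strands must have equal length")
    if not top:
        raise ThermodynamicsError("empty duplex")
    dh, ds = _duplex_dh_ds(top, bottom[::-1], params)
    return dh - kelvin(temperature) * ds / 1000.0


@dataclass(frozen=True)
class DisplacementSystem:
    """A designed mismatch-elimination displacement reaction.

    ``target`` is toehold + displacement domain (5'->3'); ``incumbent``
    pairs the domain (with at most one declared mismatch) and ``invader``
    is the full complement of the target.  The mismatch position and type
    are inferred from the sequences.
    """

    target: str
    incumbent: str
    invader: str
    toehold_length: int = 4
    temperature: float = 25.0

    def __post_init__(self):
        for name in ("target", "incumbent", "invader"):
            _check_sequence(getattr(self, name), name)
        h, N = self.toehold_length, self.domain_length
        if h < 0 or N < 2:
            raise ThermodynamicsError(
                "degenerate system: need toehold_length >= 0 and a "
                "displacement domain of at least 2 bp"
            )
        if len(self.incumbent) != N:
            raise ThermodynamicsError(
                f"incumbent length {len(self.incumbent)} != domain length {N}"
            )
        if self.invader != revcomp(self.target):
            raise ThermodynamicsError(
                "invader must be the full reverse complement of the target "
                "(toehold + displacement domain)"
            )
        mism = self._mismatch_positions()
        if len(mism) > 1:
            raise ThermodynamicsError(
                f"incumbent differs from the domain complement at positions "
                f"{mism}; at most one mismatch is supported"
            )

    # -- derived geometry -------------------------------------------------
    @property
    def domain(self) -> str:
        return self.target[self.toehold_length:]

    @property
    def toehold(self) -> str:
        return self.target[:self.toehold_length]

    @property
    def domain_length(self) -> int:
        return len(self.target) - self.toehold_length

    def _mismatch_positions(self) -> list[int]:
        dom = self.domain
        # incumbent is 5'->3'; the base pairing domain position p (1-based)
        # is incumbent[N - p]
        return [p for p in range(1, len(dom) + 1)
                if self.incumbent[len(dom) - p] != complement(dom[p - 1])]

    @property
    def mismatch_position(self) -> int | None:
        """1-based position from the toehold-proximal end, or None."""
        pos = self._mismatch_positions()
        return pos[0] if pos else None

    @property
    def mismatch_type(self) -> str | None:
        """'O-T' bases of the mismatched pair, e.g. 'C-C'."""
        x = self.mismatch_position
        if x is None:
            return None
        o = self.incumbent[self.domain_length - x]
        t = self.domain[x - 1]
        return f"{o}-{t}"

    @property
    def eliminated_pair(self) -> str | None:
        """Base pair formed by the invader at the mismatch site, e.g. 'G-C'."""
        x = self.mismatch_position
        if x is None:
            return None
        t = self.domain[x - 1]
        return f"{complement(t)}-{t}"

    @property
    def n_max(self) -> int:
        """Largest invader-target base-pair coordinate on the profile."""
        n = self.toehold_length + self.domain_length
        return n - 1 if self.mismatch_position is not None else n

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_strands(cls, target: str, incumbent: str, invader: str,
                     toehold_length: int = 4,
                     temperature: float = 25.0) -> "DisplacementSystem":
        return cls(target=target, incumbent=incumbent, invader=invader,
                   toehold_length=toehold_length, temperature=temperature)

    @classmethod
    def mismatch_free(cls, target: str, toehold_length: int = 4,
                      temperature: float = 25.0) -> "DisplacementSystem":
        dom = target[toehold_length:]
        return cls(target=target, incumbent=revcomp(dom),
                   invader=revcomp(target), toehold_length=toehold_length,
                   temperature=temperature)


def reaction_delta_g(system: DisplacementSystem,
                     params: NNParameterSet | None = None,
                     temperature: float | None = None) -> float:
    """Standard free energy of displacement, kcal/mol.

    ``dG(products I.T + O) - dG(reactants O.T + I)`` with single strands
    assigned zero structure free energy.  For a mismatch-free system this
    reduces to the toehold hybridisation free energy (the displacement
    domain cancels); a mismatch in O.T makes the reaction more negative by
    the NN destabilisation it contributes.
    """
    if params is None:
        params = NNParameterSet.default()
    if temperature is None:
        temperature = system.temperature
    T = kelvin(temperature)
    dh_it, ds_it = _duplex_dh_ds(
        system.target, "".join(complement(b) for b in system.target), params)
    dom = system.domain
    bottom_aligned = system.incumbent[::-1]
    dh_ot, ds_ot = _duplex_dh_ds(dom, bottom_aligned, params,
                                 allow_edge_mismatch=True)
    dg_it = dh_it - T * ds_it / 1000.0
    dg_ot = dh_ot - T * ds_ot / 1000.0
    return dg_it - dg_ot


def mismatch_ddg(system: DisplacementSystem,
                 params: NNParameterSet | None = None,
                 temperature: float | None = None) -> float:
    """Reaction free energy attributable to mismatch elimination, kcal/mol.

    Difference between the displacement reaction free energy of ``system``
    and that of its own mismatch-free variant (same target, fully
    complementary incumbent).  Comparing each design against its own
    reference isolates the mismatch contribution from sequence-context
    differences between designs.  Negative: the mismatch makes
    displacement more favourable.
    """
    reference = DisplacementSystem.mismatch_free(
        system.target, system.toehold_length, system.temperature)
    return (reaction_delta_g(system, params, temperature)
            - reaction_delta_g(reference, params, temperature))


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy per displacement macrostate, in kB*T.

    ``n`` counts invader-target base pairs (toehold pairs included),
    running from 1 to ``n_max``; ``G`` is zeroed at n = 1.
    """

    n: np.ndarray
    G: np.ndarray
    f_max: int
    sawtooth: float
    plateau_penalty: float
    toehold_length: int
    enclosure_n: int | None
    temperature: float

    @property
    def n_max(self) -> int:
        return int(self.n[-1])

    def g_at(self, n: int) -> float:
        return float(self.G[int(n) - 1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.n, "G_kBT": self.G})


def displacement_profile(system: DisplacementSystem,
                         params: NNParameterSet | None = None,
                         f_max: int = 3,
                         sawtooth: float = 0.0,
                         plateau_penalty: float = 2.0) -> FreeEnergyProfile:
    """Free-energy profile G(n) of displacement intermediates.

    For each macrostate n the invader pairs the first n target bases;
    the incumbent retains the domain bases beyond the branch point except
    for 0..f_max frayed pairs, and G(n) is -ln of the Boltzmann sum over
    those microstates.  A mismatch contributes its NN penalty only in
    microstates where it is enclosed in the incumbent duplex, so with
    fraying enabled the free-energy drop of mismatch elimination begins
    slightly before the enclosure coordinate.  ``plateau_penalty`` (kB*T)
    is added to every three-stranded branch-migration intermediate
    (h < n < n_max); ``sawtooth`` (kB*T) is the per-step migration barrier,
    recorded for the rate model rather than entering G.
    """
    if f_max < 0:
        raise ValueError("f_max must be >= 0")
    if params is None:
        params = NNParameterSet.default()
    h = system.toehold_length
    N = system.domain_length
    x = system.mismatch_position
    n_max = system.n_max
    if n_max < 2:
        raise ThermodynamicsError("degenerate system: n_max < 2")
    T = kelvin(system.temperature)
    dom = system.domain
    target = system.target

    def dg(top: str, bottom_aligned: str, edge_ok: bool = False) -> float:
        if not top:
            return 0.0
        dh, ds = _duplex_dh_ds(top, bottom_aligned, params,
                               allow_edge_mismatch=edge_ok)
        return dh - T * ds / 1000.0

    # invader-target subduplex energies, kcal/mol, for prefix length n
    e_it = np.empty(n_max + 1)
    e_it[0] = 0.0
    for n in range(1, n_max + 1):
        top = target[:n]
        e_it[n] = dg(top, "".join(complement(b) for b in top))

    # incumbent-target energy for a retained region s..N (domain coords)
    def e_ot(s: int) -> float:
        if s > N:
            return 0.0
        top = dom[s - 1:]
        bottom = []
        for p in range(s, N + 1):
            if p == x:
                bottom.append(system.incumbent[N - p])
            else:
                bottom.append(complement(dom[p - 1]))
        return dg(top, "".join(bottom), edge_ok=True)

    G_raw = np.empty(n_max)
    for n in range(1, n_max + 1):
        m = max(n - h, 0)
        energies = []
        for f in range(0, f_max + 1):
            s = m + f + 1
            if s > N + 1:
                break
            energies.append(e_it[n] + e_ot(s))
        if not energies:
            energies = [e_it[n]]
        e_kbt = np.array([kcal_to_kbt(e, system.temperature)
                          for e in energies])
        g = -logsumexp(-e_kbt)
        if h < n < n_max:
            g += plateau_penalty
        G_raw[n - 1] = g
    G = G_raw - G_raw[0]
    return FreeEnergyProfile(
        n=np.arange(1, n_max + 1),
        G=G,
        f_max=f_max,
        sawtooth=sawtooth,
        plateau_penalty=plateau_penalty,
        toehold_length=h,
        enclosure_n=(h + x) if x is not None else None,
        temperature=system.temperature,
    )
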