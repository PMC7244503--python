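"""Configuration, sequence and trace I/O.

Configs are YAML (or JSON, a YAML subset) with per-command blocks;
unknown keys are rejected so typos fail loudly.  Traces are CSV with a
``time_s,signal`` header (or ``time_s,cy3,cy5`` for two-channel pulse
data); a ``time_min`` header is accepted and converted to seconds.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kinetics import KineticsError, Trace
from .nn_thermo import DisplacementSystem
from .synthetic import MismatchSeriesSpec, SeriesEntry, generate_mismatch_series, reference_design

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "system_from_config",
    "read_trace",
    "write_trace",
    "read_fasta",
    "write_fasta",
]


class ConfigError(ValueError):
    """Malformed or incomplete configuration."""


_SYSTEM_KEYS = {
    "target", "incumbent", "invader", "toehold_length", "temperature",
    "toehold", "background", "motif", "mismatch", "position",
    "construction", "canonical_position",
}
_RATES_KEYS = {"positions", "k_bm", "k_toehold", "f_max", "sawtooth",
               "plateau_penalty", "toehold_dg"}
_FFS_KEYS = {"interfaces", "trials_per_interface"}
_FIT_KEYS = {"model", "trace", "free_parameters", "init_guess", "known",
             "bounds"}
_SYNTH_KEYS = {"preset", "noise_sigma", "duration_min"}


@dataclass
class RunConfig:
    """Validated run configuration with defaults applied."""

    system: dict | None = None
    rates: dict = field(default_factory=dict)
    ffs: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"
    temperature: float = 25.0


_BLOCK_KEYS = {"system": _SYSTEM_KEYS, "rates": _RATES_KEYS,
               "ffs": _FFS_KEYS, "fit": _FIT_KEYS, "synth": _SYNTH_KEYS}
_GLOBAL_KEYS = {"seed", "outdir", "log_level", "temperature"}
_REQUIRED_ANY = ("system", "fit", "synth")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON config file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None or not isinstance(raw, dict) or not raw:
        raise ConfigError(
            f"{path}: empty or non-mapping config; expected at least one of "
            f"the blocks {sorted(_BLOCK_KEYS)} (plus optional globals "
            f"{sorted(_GLOBAL_KEYS)})")
    unknown = set(raw) - set(_BLOCK_KEYS) - _GLOBAL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) "
                          f"{sorted(unknown)}")
    for block, allowed in _BLOCK_KEYS.items():
        if block in raw and raw[block] is not None:
            if not isinstance(raw[block], dict):
                raise ConfigError(f"{path}: block {block!r} must be a "
                                  f"mapping, got {type(raw[block]).__name__}")
            bad = set(raw[block]) - allowed
            if bad:
                raise ConfigError(
                    f"{path}: unknown key(s) {sorted(bad)} in block "
                    f"{block!r}; allowed: {sorted(allowed)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if v is not None})
    if not isinstance(cfg.seed, int):
        raise ConfigError(f"{path}: 'seed' must be an integer")
    if not isinstance(cfg.temperature, (int, float)):
        raise ConfigError(f"{path}: 'temperature' must be a number")
    if cfg.system is not None:
        cfg.system.setdefault("toehold_length", 4)
        cfg.system.setdefault("temperature", cfg.temperature)
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    data = {k: v for k, v in dataclasses.asdict(cfg).items()
            if v not in (None, {}, [])}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def system_from_config(block: dict) -> DisplacementSystem:
    """Build a displacement system from a config ``system`` block.

    Either explicit strands (``target``/``incumbent``/``invader``) or a
    series design (``toehold``/``background``/``motif``/``mismatch`` with
    ``position``; position null means the mismatch-free reference).
    """
    block = dict(block)
    toehold_length = block.pop("toehold_length", 4)
    temperature = block.pop("temperature", 25.0)
    if {"target", "incumbent", "invader"} <= set(block):
        return DisplacementSystem(
            target=block["target"], incumbent=block["incumbent"],
            invader=block["invader"], toehold_length=toehold_length,
            temperature=temperature)
    spec_kwargs = {k: block[k] for k in
                   ("toehold", "background", "motif", "mismatch",
                    "construction", "canonical_position") if k in block}
    position = block.get("position")
    spec = MismatchSeriesSpec(
        positions=(position,) if position else (),
        temperature=temperature, **spec_kwargs)
    if position:
        entry = generate_mismatch_series(spec)[position]
    else:
        entry = reference_design(spec)
    return entry.as_system(len(spec.toehold), temperature)


# -- traces ----------------------------------------------------------------

def write_trace(trace: Trace, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "signal"])
        for t, s in zip(trace.time, trace.signal):
            writer.writerow([repr(float(t)), repr(float(s))])


def read_trace(path) -> Trace:
    """Read a ``time_s,signal`` CSV; ``time_min`` headers convert to s."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise KineticsError(f"{path}: empty trace file") from None
        header = [h.strip() for h in header]
        if header[0] == "time_s":
            factor = 1.0
        elif header[0] == "time_min":
            factor = 60.0
        else:
            raise KineticsError(
                f"{path}: first column must be 'time_s' or 'time_min', "
                f"got {header[0]!r}")
        if len(header) != 2:
            raise KineticsError(
                f"{path}: expected exactly one signal column, got header "
                f"{header}")
        times, signals = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t, s = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise KineticsError(
                    f"{path}: malformed row at line {lineno}: {row}"
                    ) from None
            times.append(t * factor)
            signals.append(s)
    return Trace(np.array(times), np.array(signals))


# -- sequences --------------------------------------------------------------

def read_fasta(path) -> dict:
    """Name -> sequence for a (single-line or wrapped) FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
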