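"""Cycle-by-cycle simulator for solid-phase enzymatic oligonucleotide synthesis.

Each synthesis cycle attempts one controlled incorporation. The cycle's
outcome is drawn from three mutually exclusive events: with probability
``p_del`` no base is incorporated (deletion), otherwise with conditional
probability ``p_sub / (1 - p_del)`` a wrong base is incorporated
(substitution), otherwise the target base is incorporated. Independently
of that outcome, with probability ``p_ins`` one extra uncontrolled base is
appended after the cycle (insertion). Under this model the per-cycle
deletion and substitution probabilities are estimated directly by the
classification rate ``N_error / (reads x rounds)``, which is what makes
simulation-based recovery checks meaningful.

Reads are emitted in sequencing orientation as
``initiator-anchor + payload + polyA tail``, optionally with uniform
post-synthesis sequencing substitutions. The simulator is a statistical
channel only: it does not model enzyme kinetics, surface crowding or
scaffold geometry.

Ground truth is written into each read's header as a per-cycle event
string so that downstream classification can be scored exactly; see
:func:`replay_events`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .targets import INITIATOR_ANCHOR

__all__ = [
    "ErrorModel",
    "ReadLayout",
    "SimulationRun",
    "SimulatedRead",
    "simulate_read",
    "simulate_run",
    "replay_events",
    "write_reads",
    "read_sequences",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Per-cycle error probabilities of the synthesis channel.

    Parameters
    ----------
    p_del, p_sub, p_ins
        Per-cycle probabilities of deletion (no incorporation),
        substitution (wrong base incorporated) and insertion (one extra
        uncontrolled incorporation after the cycle). Deletion and
        substitution are exclusive outcomes of one cycle, so
        ``p_del + p_sub <= 1``; insertion is independent.
    sub_base_dist
        Distribution over the three wrong bases, in alphabetical order of
        the candidates; default uniform.
    ins_base_dist
        Distribution over A, C, G, T for inserted bases; default uniform.
    seq_error_rate
        Optional per-base substitution rate applied uniformly over the
        finished read, emulating sequencing errors.
    """

    p_del: float = 0.0
    p_sub: float = 0.0
    p_ins: float = 0.0
    sub_base_dist: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ins_base_dist: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_del", "p_sub", "p_ins", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_del + self.p_sub > 1.0 + 1e-12:
            raise ValueError("p_del + p_sub must not exceed 1 (exclusive outcomes)")
        for name, n in (("sub_base_dist", 3), ("ins_base_dist", 4)):
            d = getattr(self, name)
            if len(d) != n or any(p < 0 for p in d) or abs(sum(d) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be {n} non-negative weights summing to 1")


@dataclass(frozen=True)
class ReadLayout:
    """Constant read context: 5' initiator anchor and 3' polyA tail.

    The tail must be at least 10 nt so the downstream extraction pattern
    (ten consecutive A) can fire. ``tail_law`` is either ``"fixed"``
    (length exactly ``tail_length``) or ``"geometric"`` (``tail_length``
    plus a geometric excess with success probability ``tail_geom_p``).
    """

    anchor5: str = INITIATOR_ANCHOR
    tail_base: str = "A"
    tail_law: str = "fixed"
    tail_length: int = 20
    tail_geom_p: float = 0.25

    def __post_init__(self) -> None:
        if not self.anchor5:
            raise ValueError("anchor5 must be non-empty")
        if self.tail_length < 10:
            raise ValueError("tail_length must be >= 10 (extraction needs ten A)")
        if self.tail_law not in ("fixed", "geometric"):
            raise ValueError(f"unknown tail_law {self.tail_law!r}")

    def draw_tail_length(self, rng: np.random.Generator) -> int:
        if self.tail_law == "fixed":
            return self.tail_length
        return self.tail_length + int(rng.geometric(self.tail_geom_p)) - 1


@dataclass(frozen=True)
class SimulationRun:
    """Full configuration of one reproducible simulation."""

    target: str
    n_reads: int
    seed: int
    model: ErrorModel = field(default_factory=ErrorModel)
    layout: ReadLayout = field(default_factory=ReadLayout)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not self.target:
            raise ValueError("target must be non-empty")
        if set(self.target) - set(_BASES):
            raise ValueError("target must be over A,C,G,T")


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read with its ground-truth event log.

    ``events`` holds one token per synthesis cycle: ``M`` (correct base),
    ``D`` (deletion), ``S>x`` (substitution emitting base x), each
    optionally followed by ``+I>x`` (insertion of base x after the
    cycle). ``payload`` is the synthesized segment before sequencing
    noise; ``sequence`` is the full read after it.
    """

    read_id: str
    sequence: str
    payload: str
    events: tuple[str, ...]

    @property
    def header_description(self) -> str:
        return f"events={','.join(self.events)}"


_EVENT_RE = re.compile(r"^(M|D|S>[ACGT])(\+I>[ACGT])?$")


def replay_events(target: str, events: Sequence[str]) -> str:
    """Reconstruct the synthesized payload from a per-cycle event log."""
    if len(events) != len(target):
        raise ValueError(f"{len(events)} events for a {len(target)}-cycle target")
    out: list[str] = []
    for base, ev in zip(target, events):
        m = _EVENT_RE.match(ev)
        if m is None:
            raise ValueError(f"malformed event token {ev!r}")
        op, ins = m.groups()
        if op == "M":
            out.append(base)
        elif op.startswith("S>"):
            out.append(op[2:])
        # 'D' emits nothing
        if ins:
            out.append(ins[3:])
    return "".join(out)


def _wrong_bases(base: str) -> str:
    return _BASES.replace(base, "")


def simulate_read(
    target: str,
    model: ErrorModel,
    layout: ReadLayout,
    rng: np.random.Generator,
    read_id: str = "read",
) -> SimulatedRead:
    """Simulate one read: draw per-cycle events, assemble anchor+payload+tail."""
    n = len(target)
    u_cycle = rng.random(n)
    u_ins = rng.random(n)
    p_sub_given_not_del = model.p_sub / (1.0 - model.p_del) if model.p_del < 1.0 else 0.0

    payload: list[str] = []
    events: list[str] = []
    for i, base in enumerate(target):
        if u_cycle[i] < model.p_del:
            tok = "D"
        elif model.p_sub > 0 and rng.random() < p_sub_given_not_del:
            wrong = rng.choice(list(_wrong_bases(base)), p=model.sub_base_dist)
            payload.append(wrong)
            tok = f"S>{wrong}"
        else:
            payload.append(base)
            tok = "M"
        if u_ins[i] < model.p_ins:
            extra = rng.choice(list(_BASES), p=model.ins_base_dist)
            payload.append(extra)
            tok += f"+I>{extra}"
        events.append(tok)

    payload_s = "".join(payload)
    tail = layout.tail_base * layout.draw_tail_length(rng)
    read = layout.anchor5 + payload_s + tail
    if model.seq_error_rate > 0:
        chars = list(read)
        hits = np.nonzero(rng.random(len(chars)) < model.seq_error_rate)[0]
        for pos in hits:
            chars[pos] = rng.choice(list(_wrong_bases(chars[pos])))
        read = "".join(chars)
    return SimulatedRead(read_id, read, payload_s, tuple(events))


def simulate_run(run: SimulationRun) -> list[SimulatedRead]:
    """Simulate ``run.n_reads`` reads; identical runs are bit-identical."""
    rng = np.random.default_rng(run.seed)
    width = len(str(run.n_reads))
    return [
        simulate_read(run.target, run.model, run.layout, rng, f"read_{i:0{width}d}")
        for i in range(1, run.n_reads + 1)
    ]


def write_reads(
    reads: Iterable[SimulatedRead],
    path: str | Path,
    fmt: str = "fasta",
    quality_char: str = "I",
) -> None:
    """Write simulated reads as FASTA or FASTQ (constant quality string)."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {fmt!r}")
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=r.header_description)
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(
                r.sequence
            )
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA/FASTQ records; format inferred from the extension if omitted."""
    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in (".fq", ".fastq") else "fasta"
    return list(SeqIO.parse(str(p), fmt))
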