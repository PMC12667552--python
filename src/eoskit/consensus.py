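"""Majority-vote recovery of the dominant synthesized sequence.

Two procedures are provided. :func:`global_majority` returns the modal
full payload string — the "dominant sequence" of a read population.
:func:`conditional_consensus` walks the synthesis positions in order:
at each position it tallies the base among reads that agreed with the
consensus at every earlier position, calls the plurality base, and keeps
only the agreeing reads as survivors for the next position. The screen
can alternatively be referenced to a known target, which is the
convention used for position-by-position error profiling when the ground
truth is available.

Ties are broken lexicographically (A < C < G < T) and flagged rather than
randomized, for reproducibility. Reads shorter than the current position
leave the tally (and, necessarily, the survivor set) from that position
onward but keep their contributions to earlier positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import storage_codec
from .read_processing import ExtractedPayload
from .storage_codec import BaseMap, DEFAULT_MAP

__all__ = ["ConsensusResult", "global_majority", "conditional_consensus", "decode_information"]

_BASES = "ACGT"


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of a majority vote.

    ``per_position_counts`` is a position x base count DataFrame (1-based
    positions; for the global vote it tallies all reads covering each
    position of the modal string). ``surviving_reads`` gives, for the
    conditional procedure, the post-screen survivor count at each position
    (non-increasing); for the global vote, each position's read coverage.
    ``tie_flags`` lists 1-based positions where the vote
    was tied (or, for the global vote, is [0] when the modal string itself
    was tied).
    """

    consensus: str
    per_position_counts: pd.DataFrame
    surviving_reads: tuple[int, ...]
    tie_flags: tuple[int, ...]
    method: str


def _payload_strings(payloads: Sequence[str | ExtractedPayload]) -> list[str]:
    out = [p.payload if isinstance(p, ExtractedPayload) else p for p in payloads]
    if not out:
        raise ValueError("empty payload collection")
    return out


def _position_counts(strings: Sequence[str], length: int) -> pd.DataFrame:
    tally = np.zeros((length, 4), dtype=np.int64)
    idx = {b: i for i, b in enumerate(_BASES)}
    for s in strings:
        for k in range(min(len(s), length)):
            tally[k, idx[s[k]]] += 1
    return pd.DataFrame(
        tally, columns=list(_BASES), index=pd.RangeIndex(1, length + 1, name="position")
    )


def global_majority(payloads: Sequence[str | ExtractedPayload]) -> ConsensusResult:
    """Return the most frequent payload string as the consensus.

    A tie between distinct modal strings is resolved lexicographically and
    flagged. The per-position count matrix tallies every read over the
    modal string's positions (reads shorter than a position drop out of
    that position's count).
    """
    strings = _payload_strings(payloads)
    freq = Counter(strings)
    top = max(freq.values())
    modal = sorted(s for s, c in freq.items() if c == top)
    consensus = modal[0]
    ties = (0,) if len(modal) > 1 else ()
    counts = _position_counts(strings, len(consensus))
    survivors = tuple(int(x) for x in counts.sum(axis=1))
    return ConsensusResult(consensus, counts, survivors, ties, "global")


def conditional_consensus(
    payloads: Sequence[str | ExtractedPayload],
    length: int,
    reference: str | None = None,
) -> ConsensusResult:
    """Position-by-position plurality vote over screened reads.

    At position k (1-based) the vote is taken among reads that survived
    the screen through k-1 and are at least k long. Survivors at k are
    those matching the called base — the evolving consensus by default, or
    ``reference`` when given (target-referenced error profiling).

    Raises ``ValueError`` if the survivor set empties before ``length``,
    reporting the position reached.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if reference is not None and len(reference) < length:
        raise ValueError("reference shorter than requested length")
    strings = _payload_strings(payloads)
    survivors = strings
    consensus: list[str] = []
    counts = np.zeros((length, 4), dtype=np.int64)
    n_surv: list[int] = []
    ties: list[int] = []
    idx = {b: i for i, b in enumerate(_BASES)}
    for k in range(length):
        eligible = [s for s in survivors if len(s) > k]
        if not eligible:
            raise ValueError(
                f"survivor set empty at position {k + 1} of {length}; "
                f"consensus reached {''.join(consensus)!r}"
            )
        tally = Counter(s[k] for s in eligible)
        for b, c in tally.items():
            counts[k, idx[b]] = c
        top = max(tally.values())
        modal = sorted(b for b, c in tally.items() if c == top)
        if len(modal) > 1:
            ties.append(k + 1)
        called = modal[0]
        consensus.append(called)
        screen_base = reference[k] if reference is not None else called
        survivors = [s for s in eligible if s[k] == screen_base]
        n_surv.append(len(survivors))
    df = pd.DataFrame(
        counts, columns=list(_BASES), index=pd.RangeIndex(1, length + 1, name="position")
    )
    return ConsensusResult(
        "".join(consensus), df, tuple(n_surv), tuple(ties), "conditional"
    )


def decode_information(
    consensus: ConsensusResult | str, base_map: BaseMap = DEFAULT_MAP
) -> bytes:
    """Decode a consensus sequence to its stored byte message."""
    seq = consensus.consensus if isinstance(consensus, ConsensusResult) else consensus
    return storage_codec.decode_message(seq, base_map)
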