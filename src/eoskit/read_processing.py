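"""Payload extraction, alignment, error classification and yield statistics.

The synthesized segment of each read is extracted by pattern matching
``anchor5 (.*?) AAAAAAAAAA`` — the constant initiator context, a
non-greedy payload, then the first run of ten adenines from the polyA
tail. Extracted payloads are globally aligned to the target under unit
edit costs (match 0, substitution 1, gap 1) and each target position is
classified as correct, deletion or substitution; insertions are tallied
against the target position they follow. From the classified population
the per-class error rates, correct-base proportion, full-length yield
``Y_total = S_right / S_all`` and average stepwise yield
``Y_total^(1/r)`` are computed, where ``r`` is the number of synthesis
rounds (the target length), ``S_right`` counts payloads exactly equal to
the target and ``S_all`` counts all extracted payloads.

Tie-breaking among co-optimal alignments is deterministic: the traceback
prefers a diagonal step (match/substitution) over gaps and otherwise
consumes target gaps late in the backward pass, which places deletions
leftmost in homopolymer runs. Class totals are unaffected by the choice —
under unit costs the three counts are pinned by the edit distance and the
length difference — only per-position tallies depend on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ReadLayout

__all__ = [
    "ExtractedPayload",
    "AlignmentResult",
    "ErrorCounts",
    "SynthesisMetrics",
    "extract_payload",
    "extract_payloads",
    "align_to_target",
    "classify_errors",
    "compute_metrics",
    "stepwise_yield",
    "per_position_profile",
    "analyze_reads",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExtractedPayload:
    """A read's synthesized segment and the strand it was found on."""

    read_id: str
    payload: str
    strand: str  # "forward" | "reverse"


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment of a payload to the target.

    ``ops`` is an ordered tuple of ``(op, target_pos, read_pos)`` with op in
    {"match", "substitution", "deletion", "insertion"}; positions are
    0-based indices of the consumed base (insertions carry the 0-based
    target position they follow, -1 for an insertion before the first
    target base). ``score`` is the unit-cost edit distance.
    """

    ops: tuple[tuple[str, int, int], ...]
    score: int


def _compile_pattern(layout: ReadLayout) -> re.Pattern[str]:
    return re.compile(re.escape(layout.anchor5) + r"(.*?)" + layout.tail_base * 10)


def extract_payload(
    read: str, layout: ReadLayout | None = None, read_id: str = "read"
) -> ExtractedPayload | None:
    """Extract the synthesized payload from one read, or return None.

    The leftmost, non-greedy match between the anchor and the first run of
    ten tail bases is taken; anchors must match exactly. If the forward
    strand has no match the reverse complement is searched. A zero-length
    payload is a valid observation (a fully failed synthesis).
    """
    layout = layout or ReadLayout()
    pat = _compile_pattern(layout)
    m = pat.search(read)
    if m is not None:
        return ExtractedPayload(read_id, m.group(1), "forward")
    m = pat.search(reverse_complement(read))
    if m is not None:
        return ExtractedPayload(read_id, m.group(1), "reverse")
    return None


def extract_payloads(
    reads: Iterable, layout: ReadLayout | None = None
) -> tuple[list[ExtractedPayload], int]:
    """Extract payloads from records or (id, sequence) pairs.

    Accepts Bio.SeqRecord objects, plain strings or (id, seq) tuples.
    Returns the extracted payloads and the count of reads with no match.
    """
    out: list[ExtractedPayload] = []
    n_absent = 0
    for i, rec in enumerate(reads):
        if isinstance(rec, str):
            rid, seq = f"read_{i + 1}", rec
        elif isinstance(rec, tuple):
            rid, seq = rec
        else:  # SeqRecord-like
            rid, seq = rec.id, str(rec.seq)
        hit = extract_payload(seq.upper(), layout, rid)
        if hit is None:
            n_absent += 1
        else:
            out.append(hit)
    return out, n_absent


def align_to_target(payload: str, target: str) -> AlignmentResult:
    """Optimal global alignment of payload to target under unit edit costs.

    Deterministic traceback: diagonal first, then target gap (deletion),
    then read gap (insertion). An empty payload yields one deletion per
    target position.
    """
    if not target:
        raise ValueError("target must be non-empty")
    n, m = len(target), len(payload)
    # dp[i, j]: edit distance between target[:i] and payload[:j]
    dp = np.empty((n + 1, m + 1), dtype=np.int32)
    dp[0, :] = np.arange(m + 1)
    dp[:, 0] = np.arange(n + 1)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    p = np.frombuffer(payload.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = dp[i - 1, :-1] + (p != t[i - 1])
        row = dp[i]
        prev = dp[i - 1]
        row[1:] = np.minimum(sub, prev[1:] + 1)
        # horizontal dependency: resolve sequentially
        r = row
        for j in range(1, m + 1):
            if r[j - 1] + 1 < r[j]:
                r[j] = r[j - 1] + 1

    ops: list[tuple[str, int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (target[i - 1] != payload[j - 1]):
            op = "match" if target[i - 1] == payload[j - 1] else "substitution"
            ops.append((op, i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            ops.append(("deletion", i - 1, -1))
            i -= 1
        else:
            ops.append(("insertion", i - 1, j - 1))
            j -= 1
    ops.reverse()
    return AlignmentResult(tuple(ops), int(dp[n, m]))


@dataclass(frozen=True)
class ErrorCounts:
    """Per-read classification: one outcome per target position.

    ``outcomes[k]`` is the aligned observation at target position k: the
    read base (for match or substitution) or ``"-"`` (deletion).
    ``insertions[k]`` counts inserted bases following target position k
    (index 0 means before the first base, so entry k+1 follows base k).
    """

    n_correct: int
    n_del: int
    n_sub: int
    n_ins: int
    outcomes: tuple[str, ...]
    insertions: tuple[int, ...]


def classify_errors(aln: AlignmentResult, target: str, payload: str) -> ErrorCounts:
    """Classify one alignment into per-position outcomes and class counts."""
    outcomes = ["-"] * len(target)
    insertions = [0] * (len(target) + 1)
    n_corr = n_del = n_sub = n_ins = 0
    for op, ti, pi in aln.ops:
        if op == "match":
            outcomes[ti] = payload[pi]
            n_corr += 1
        elif op == "substitution":
            outcomes[ti] = payload[pi]
            n_sub += 1
        elif op == "deletion":
            n_del += 1
        else:  # insertion following target position ti
            insertions[ti + 1] += 1
            n_ins += 1
    return ErrorCounts(n_corr, n_del, n_sub, n_ins, tuple(outcomes), tuple(insertions))


@dataclass(frozen=True)
class SynthesisMetrics:
    """Population-level error and yield statistics for one target.

    Rates are fractions in [0, 1]; multiply by 100 for percentages.
    ``N_all = n_reads_extracted * r`` is the denominator of the per-class
    error rates and of the correct-base proportion.
    """

    target: str
    r: int
    n_reads_extracted: int
    n_full_length: int
    N_right: int
    N_del: int
    N_ins: int
    N_sub: int

    @property
    def N_all(self) -> int:
        return self.n_reads_extracted * self.r

    @property
    def error_rate_del(self) -> float:
        return self.N_del / self.N_all

    @property
    def error_rate_ins(self) -> float:
        return self.N_ins / self.N_all

    @property
    def error_rate_sub(self) -> float:
        return self.N_sub / self.N_all

    @property
    def correct_proportion(self) -> float:
        return self.N_right / self.N_all

    @property
    def full_length_yield(self) -> float:
        return self.n_full_length / self.n_reads_extracted

    @property
    def stepwise_yield(self) -> float:
        return stepwise_yield(self.full_length_yield, self.r)

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "target": self.target,
            "r": self.r,
            "n_reads_extracted": self.n_reads_extracted,
            "n_full_length": self.n_full_length,
            "N_right": self.N_right,
            "N_del": self.N_del,
            "N_ins": self.N_ins,
            "N_sub": self.N_sub,
            "error_rate_del": self.error_rate_del,
            "error_rate_ins": self.error_rate_ins,
            "error_rate_sub": self.error_rate_sub,
            "correct_proportion": self.correct_proportion,
            "full_length_yield": self.full_length_yield,
            "stepwise_yield": self.stepwise_yield,
        }


def stepwise_yield(full_length_yield: float, r: int) -> float:
    """Average per-cycle success probability: the r-th root of the yield."""
    if not 0.0 <= full_length_yield <= 1.0:
        raise ValueError("full_length_yield must be in [0, 1]")
    if r < 1:
        raise ValueError("r must be >= 1")
    return full_length_yield ** (1.0 / r)


def _classified_by_payload(
    payloads: Sequence[str], target: str, length_cap_factor: float | None = 2.0
) -> tuple[dict[str, ErrorCounts], dict[str, int], int]:
    """Align and classify unique payload strings (identical reads share work).

    Payloads longer than ``length_cap_factor * len(target)`` are still
    classified (insertions dominate) unless the factor is exceeded tenfold,
    which guards pathological anchor matches; those are dropped and counted.
    """
    counts: dict[str, int] = {}
    for s in payloads:
        counts[s] = counts.get(s, 0) + 1
    hard_cap = None
    if length_cap_factor is not None:
        hard_cap = int(10 * length_cap_factor * len(target))
    classified: dict[str, ErrorCounts] = {}
    n_capped = 0
    for s in counts:
        if hard_cap is not None and len(s) > hard_cap:
            n_capped += counts[s]
            continue
        classified[s] = classify_errors(align_to_target(s, target), target, s)
    return classified, counts, n_capped


def compute_metrics(
    payloads: Sequence[str | ExtractedPayload], target: str, r: int | None = None
) -> SynthesisMetrics:
    """Compute per-class error rates and yields for an extracted population.

    ``r`` defaults to the target length (one synthesis round per base).
    Raises on an empty population: every denominator is undefined.
    """
    strings = [p.payload if isinstance(p, ExtractedPayload) else p for p in payloads]
    if not strings:
        raise ValueError("no extracted payloads: metrics denominators undefined")
    if r is None:
        r = len(target)
    classified, counts, n_capped = _classified_by_payload(strings, target)
    N_right = N_del = N_sub = N_ins = 0
    n_extracted = 0
    for s, ec in classified.items():
        w = counts[s]
        n_extracted += w
        N_right += w * ec.n_correct
        N_del += w * ec.n_del
        N_sub += w * ec.n_sub
        N_ins += w * ec.n_ins
    if n_extracted == 0:
        raise ValueError("all payloads exceeded the length cap")
    n_full = counts.get(target, 0)
    return SynthesisMetrics(
        target=target,
        r=r,
        n_reads_extracted=n_extracted,
        n_full_length=n_full,
        N_right=N_right,
        N_del=N_del,
        N_ins=N_ins,
        N_sub=N_sub,
    )


def per_position_profile(
    payloads: Sequence[str | ExtractedPayload],
    target: str,
    conditional: bool = True,
) -> pd.DataFrame:
    """Position-by-position outcome frequencies across the read population.

    For each target position the frequencies of observing A, C, G, T or a
    deletion are tallied from the alignments. With ``conditional=True``
    (the heatmap convention) a read contributes at position k only if all
    its outcomes at positions < k were correct; its first error is tallied
    and the read is then dropped, so the deletion fraction at each
    position estimates the per-cycle deletion probability. Without the
    screen all positions are tallied, except that trailing deletions
    beyond a read's last aligned base are excluded.

    Returns a DataFrame indexed by 1-based position with columns
    A, C, G, T, deleted, n (the position's denominator); frequency rows
    sum to 1.
    """
    strings = [p.payload if isinstance(p, ExtractedPayload) else p for p in payloads]
    if not strings:
        raise ValueError("no payloads to profile")
    classified, counts, _ = _classified_by_payload(strings, target)
    cats = ["A", "C", "G", "T", "deleted"]
    tally = np.zeros((len(target), 5), dtype=np.int64)
    col = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    for s, ec in classified.items():
        w = counts[s]
        if conditional:
            for k, obs in enumerate(ec.outcomes):
                tally[k, col[obs]] += w
                if obs != target[k]:
                    break
        else:
            last = -1
            for k, obs in enumerate(ec.outcomes):
                if obs != "-":
                    last = k
            for k, obs in enumerate(ec.outcomes):
                if obs == "-" and k > last:
                    continue
                tally[k, col[obs]] += w
    n = tally.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n[:, None] > 0, tally / np.maximum(n, 1)[:, None], np.nan)
    df = pd.DataFrame(freq, columns=cats, index=pd.RangeIndex(1, len(target) + 1, name="position"))
    df["n"] = n
    return df


def analyze_reads(
    reads: Iterable,
    target: str,
    layout: ReadLayout | None = None,
) -> tuple[pd.DataFrame, SynthesisMetrics]:
    """Extract, align and classify a read collection against a target.

    Returns a per-read table (read id, strand, payload, class counts,
    full-length flag) and the population :class:`SynthesisMetrics`.
    """
    extracted, n_absent = extract_payloads(reads, layout)
    if not extracted:
        raise ValueError(
            f"no read matched the extraction pattern ({n_absent} reads searched)"
        )
    classified, _, _ = _classified_by_payload([e.payload for e in extracted], target)
    rows = []
    for e in extracted:
        ec = classified.get(e.payload)
        if ec is None:
            continue
        rows.append(
            {
                "read_id": e.read_id,
                "strand": e.strand,
                "payload": e.payload,
                "n_correct": ec.n_correct,
                "n_del": ec.n_del,
                "n_ins": ec.n_ins,
                "n_sub": ec.n_sub,
                "full_length": e.payload == target,
            }
        )
    table = pd.DataFrame(rows)
    metrics = compute_metrics([e.payload for e in extracted], target)
    return table, metrics


def write_metrics(metrics: SynthesisMetrics, path: str | Path) -> None:
    """Write a flat key-value summary (TSV: key <tab> value)."""
    with open(path, "w") as fh:
        for k, v in metrics.as_dict().items():
            fh.write(f"{k}\t{v}\n")
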