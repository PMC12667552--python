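"""Reference target oligonucleotides used throughout the package.

These are the seven synthesis targets studied on the tetrahedral-DNA-
nanostructure (TDN) interface: a 9-mer control, five "challenging"
patterns (hairpin, two homopolymers, low/high GC content) and the 60-nt
information-storage fragment. Free-energy and GC annotations are carried
as metadata only; nothing in the package computes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChallengeSequence:
    """A named synthesis target with free-text annotation."""

    name: str
    sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in target {self.name!r}: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("target sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


#: 5' constant context (initiator) preceding the synthesized payload in reads.
INITIATOR_ANCHOR = "AGTGCTACTAGGACGACTCGAATT"

#: The 60-nt storage fragment encoding a 15-byte text message.
STORAGE_FRAGMENT = (
    "CTTCTGCGTTTCGGCTTTACCTCCTTTGTCGTTCACTGCATCGTTCCGTGCATCTTTCTT"
)

TARGETS: dict[str, ChallengeSequence] = {
    t.name: t
    for t in (
        ChallengeSequence("nine_mer", "GCTGCTGCT", "9-cycle control target"),
        ChallengeSequence("hairpin", "CGAGCTAGTCAGCTCG", "hairpin, ΔG = −7.10"),
        ChallengeSequence("homopolymer_c", "CCC", "C homopolymer"),
        ChallengeSequence("homopolymer_t", "TTTTTT", "T homopolymer"),
        ChallengeSequence("low_gc", "ATATGATATC", "GC content 20%"),
        ChallengeSequence("high_gc", "CGCGTCGCGA", "GC content 80%"),
        ChallengeSequence("storage_fragment", STORAGE_FRAGMENT, "60-nt storage fragment"),
    )
}


def get_target(name: str) -> ChallengeSequence:
    """Look up a bundled target by name; raises KeyError with choices listed."""
    try:
        return TARGETS[name]
    except KeyError:
        raise KeyError(f"unknown target {name!r}; choose from {sorted(TARGETS)}") from None
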