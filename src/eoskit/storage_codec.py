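"""Two-bits-to-one-base (TBOB) DNA information-storage codec.

The codec maps consecutive, non-overlapping 2-bit words (most significant
bit first) to single bases and back. The default map translates
00, 01, 10, 11 to G, T, C, A respectively, which is the unique convention
under which the bundled 60-nt storage fragment decodes to a 15-byte
message: three CJK characters as big-endian 16-bit Unicode code units
followed by nine ASCII letters.

The codec is byte-oriented and text-encoding-agnostic: what the bytes mean
(UTF-16BE, ASCII, ...) is the caller's concern. Non-ACGT symbols — for
example ``N`` from a tied consensus vote — are rejected, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "BaseMap",
    "DEFAULT_MAP",
    "bits_to_dna",
    "dna_to_bits",
    "bits_to_bytes",
    "bytes_to_bits",
    "encode_message",
    "decode_message",
    "demo_message",
]

_WORDS = ("00", "01", "10", "11")


@dataclass(frozen=True)
class BaseMap:
    """Bijection between the four 2-bit words and the four DNA bases.

    Parameters
    ----------
    bases
        Four distinct bases, in the order they encode 00, 01, 10, 11.
    """

    bases: str = "GTCA"

    def __post_init__(self) -> None:
        if sorted(self.bases) != ["A", "C", "G", "T"]:
            raise ValueError(
                f"base map must be a permutation of ACGT, got {self.bases!r}"
            )

    @property
    def word_to_base(self) -> dict[str, str]:
        return dict(zip(_WORDS, self.bases))

    @property
    def base_to_word(self) -> dict[str, str]:
        return dict(zip(self.bases, _WORDS))


DEFAULT_MAP = BaseMap("GTCA")


def _as_bit_string(bits: Iterable[int | str] | str) -> str:
    """Normalise a bit vector (string or iterable of 0/1) to a '01' string."""
    if isinstance(bits, str):
        s = bits
    else:
        s = "".join(str(b) for b in bits)
    bad = set(s) - {"0", "1"}
    if bad:
        raise ValueError(f"bit vector contains non-binary symbols: {sorted(bad)}")
    return s


def bits_to_dna(bits: Iterable[int | str] | str, base_map: BaseMap = DEFAULT_MAP) -> str:
    """Translate a bit vector to DNA, two bits per base, MSB-first.

    Raises ``ValueError`` on odd-length input.
    """
    s = _as_bit_string(bits)
    if len(s) % 2:
        raise ValueError(f"bit vector length {len(s)} is odd; cannot pair into bases")
    w2b = base_map.word_to_base
    return "".join(w2b[s[i : i + 2]] for i in range(0, len(s), 2))


def dna_to_bits(seq: str, base_map: BaseMap = DEFAULT_MAP) -> str:
    """Translate a DNA sequence to its bit vector (two bits per base)."""
    b2w = base_map.base_to_word
    out = []
    for pos, base in enumerate(seq):
        try:
            out.append(b2w[base])
        except KeyError:
            raise ValueError(
                f"non-ACGT symbol {base!r} at position {pos}; codec does not guess"
            ) from None
    return "".join(out)


def bits_to_bytes(bits: Iterable[int | str] | str) -> bytes:
    """Pack a bit vector into bytes, 8 bits per byte, MSB-first."""
    s = _as_bit_string(bits)
    if len(s) % 8:
        raise ValueError(f"bit vector length {len(s)} is not a multiple of 8")
    return bytes(int(s[i : i + 8], 2) for i in range(0, len(s), 8))


def bytes_to_bits(msg: bytes | bytearray) -> str:
    """Unpack bytes into a bit vector, MSB-first."""
    return "".join(f"{b:08b}" for b in bytes(msg))


def encode_message(msg: bytes | bytearray, base_map: BaseMap = DEFAULT_MAP) -> str:
    """Encode a byte message as DNA: four bases per byte."""
    return bits_to_dna(bytes_to_bits(msg), base_map)


def decode_message(seq: str, base_map: BaseMap = DEFAULT_MAP) -> bytes:
    """Decode a DNA sequence to its byte message.

    The sequence length must be divisible by 4 (whole bytes).
    """
    if len(seq) % 4:
        raise ValueError(
            f"sequence length {len(seq)} is not a multiple of 4; cannot frame bytes"
        )
    return bits_to_bytes(dna_to_bits(seq, base_map))


def demo_message() -> bytes:
    """The 15-byte demonstration message stored in the bundled fragment.

    Three Chinese characters as UTF-16BE code units followed by nine ASCII
    Latin letters — the byte layout consistent with a 120-bit payload.
    """
    return "陈嘉庚".encode("utf-16-be") + b"TanKahKee"
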