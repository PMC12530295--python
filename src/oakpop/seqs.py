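"""Nucleotide sequence containers and the integer encoding used throughout.

Sequences are held as numpy ``uint8`` arrays in a 4-state encoding:
A=0, C=1, G=2, T=3, and 255 for anything that cannot enter a pairwise
comparison (N, gap, IUPAC ambiguity).  The encoding is chosen so that
``x ^ 2`` maps a base to its transition partner and ``x ^ 1`` / ``x ^ 3``
to its two transversion partners, which keeps both the simulator and the
distance code branch-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = np.uint8(255)

#: byte value -> 4-state code (case-insensitive); everything else -> 255
ENCODE_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    ENCODE_LUT[_b] = _i

#: 4-state code -> ASCII byte, 255 -> 'N'
DECODE_LUT = np.full(256, ord("N"), dtype=np.uint8)
DECODE_LUT[:4] = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq) -> np.ndarray:
    """Encode a str/bytes/uint8-array of nucleotides into 4-state codes."""
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8 and seq.size and seq.max(initial=0) <= 3:
            return seq.astype(np.uint8, copy=True)
        arr = seq.astype(np.uint8)
    elif isinstance(seq, (bytes, bytearray)):
        arr = np.frombuffer(bytes(seq), dtype=np.uint8)
    else:
        arr = np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)
    return ENCODE_LUT[arr]


def decode(enc: np.ndarray) -> str:
    """Decode 4-state codes back to an upper-case nucleotide string."""
    return DECODE_LUT[enc].tobytes().decode("ascii")


def complement(enc: np.ndarray) -> np.ndarray:
    """Complement encoded bases; missing stays missing."""
    return np.where(enc <= 3, 3 - enc, MISSING).astype(np.uint8)


def reverse_complement(enc: np.ndarray) -> np.ndarray:
    return complement(enc)[::-1]


@dataclass
class StrainGenome:
    """Per-strain nucleotide sequence, one encoded array per chromosome.

    Ambiguous or quality-masked positions carry the code 255 and render
    as ``N`` on output; they are excluded from every pairwise comparison
    downstream (pairwise deletion).
    """

    strain: str
    sequences: dict[str, np.ndarray] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def n_masked(self) -> int:
        return int(sum((s == MISSING).sum() for s in self.sequences.values()))

    def concatenated(self) -> np.ndarray:
        """All chromosomes joined in dictionary order."""
        return np.concatenate([self.sequences[c] for c in self.sequences])

    def copy(self) -> "StrainGenome":
        return StrainGenome(
            self.strain, {c: s.copy() for c, s in self.sequences.items()}
        )
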