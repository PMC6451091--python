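"""Small DNA sequence utilities shared across the package.

Probes live on double-stranded arrays, so reverse complementation and
strict ACGT validation show up everywhere; they are centralized here.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: integer code per base used by the vectorized PWM scanner; -1 = ambiguous
BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Return *seq* if it is a non-empty strict-ACGT string, else raise.

    The offending position is reported so a bad FASTA record can be
    located without guesswork.
    """
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError(f"{name} must be a non-empty DNA string")
    for i, base in enumerate(seq):
        if base not in BASE_INDEX:
            raise ValueError(
                f"{name} contains non-ACGT character {base!r} at position {i}"
            )
    return seq


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, base in enumerate(seq):
        out[i] = BASE_INDEX.get(base, -1)
    return out


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length DNA strings into an (n, L) int8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("encode_many requires equal-length sequences")
    (length,) = lengths
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), length)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def random_dna(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Draw *n* uniform-composition DNA strings of the given length."""
    codes = rng.integers(0, 4, size=(n, length))
    lut = np.array(list(DNA_BASES))
    return ["".join(row) for row in lut[codes]]


def contains_motif(seq: str, motif: str) -> bool:
    """True if *motif* occurs in *seq* on either strand."""
    return motif in seq or revcomp(motif) in seq
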