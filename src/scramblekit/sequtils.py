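"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_RC_TABLE)[::-1]


def is_palindromic(seq: str) -> bool:
    """True when the sequence equals its own reverse complement."""
    s = seq.upper()
    return revcomp(s) == s


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= DNA_ALPHABET


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.40) -> str:
    """Random DNA with the given GC content (segment filler for toy genomes)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorized Hamming comparisons."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))
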