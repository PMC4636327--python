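"""Low-level DNA string helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def complement(seq: str) -> str:
    """Position-wise Watson-Crick complement (no reversal)."""
    return seq.translate(_COMP)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Count of positions where two equal-length strings differ.

    Raises ValueError on unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode a string as a uint8 array of ASCII codes (uppercased)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def validate_dna(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase and validate a DNA string; returns the normalized string."""
    s = seq.upper()
    allowed = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return s
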