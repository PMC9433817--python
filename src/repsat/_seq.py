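"""Byte-level nucleotide helpers shared across modules.

Sequences are handled as ASCII uint8 arrays internally; the public API uses
plain strings.
"""
from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII code -> base index 0..3, 255 for anything that is not A/C/G/T
CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    CODE_LUT[_b] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 ASCII array (copy, writable)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode_seq(arr: np.ndarray) -> str:
    return np.asarray(arr, dtype=np.uint8).tobytes().decode("ascii")


def is_acgt(seq: str) -> bool:
    """True iff ``seq`` is non-empty and contains only A, C, G, T."""
    if not seq:
        return False
    return not bool((CODE_LUT[encode_seq(seq)] == 255).any())


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def substitute(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Replace each position in place with one of the three *other* bases."""
    if len(positions) == 0:
        return
    idx = CODE_LUT[arr[positions]].astype(np.int64)
    idx = (idx + rng.integers(1, 4, size=len(positions))) % 4
    arr[positions] = BASES[idx]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return int((encode_seq(a) != encode_seq(b)).sum())
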