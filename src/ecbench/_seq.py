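"""Small nucleotide-sequence helpers shared across modules.

Sequences are plain upper-case strings over {A, C, G, T, N}; numeric code
works on uint8 views of the ASCII bytes so numpy can compare windows and
mutate bases without per-character Python loops.
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
GAP = ord("-")

# ASCII complement lookup table; N maps to N, everything else to itself.
_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP[_a] = _b

# index (0..3) of each of A,C,G,T in ASCII space; 255 marks non-ACGT.
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_INDEX[_a] = _i
_INDEX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """ASCII uint8 view of a sequence (copy, writable)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return decode(_COMP[encode(seq)][::-1])


def complement_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def substitute(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """In place, replace each position with a uniform draw over the three
    bases different from the current one. Positions must hold A/C/G/T."""
    if positions.size == 0:
        return
    idx = _BASE_INDEX[arr[positions]]
    if np.any(idx == 255):
        raise ValueError("cannot substitute a non-ACGT base")
    shift = rng.integers(1, 4, size=positions.size)
    arr[positions] = _INDEX_BASE[(idx + shift) % 4]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(_INDEX_BASE[rng.integers(0, 4, size=length)])
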