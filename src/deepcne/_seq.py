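"""Low-level DNA sequence utilities shared across the package.

Sequences cross the public API as plain Python strings over {A,C,G,T,N};
internally they are numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
CODE_N = 4

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of codes; N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string to a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGTN base {seq[bad]!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def composition_from_gc(gc: float) -> np.ndarray:
    """Base frequencies (A,C,G,T) for a given G+C fraction, A=T and C=G."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc_content must be in (0,1), got {gc}")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def random_codes(rng: np.random.Generator, length: int, composition: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=composition).astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    return decode(random_codes(rng, length, composition_from_gc(gc)))
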