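"""Fixed nucleotide alphabet and integer encodings.

The whole package orders bases as (A, T, G, C) and dinucleotides as the
16 ordered pairs AA, AT, AG, AC, TA, TT, TG, TC, GA, GT, GG, GC, CA, CT,
CG, CC.  File dialects that use other orders (e.g. JASPAR's A,C,G,T) are
re-mapped on read.
"""

from __future__ import annotations

import numpy as np

ALPHABET: str = "ATGC"
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(ALPHABET)}
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)
DINUC_INDEX: dict[str, int] = {d: i for i, d in enumerate(DINUCLEOTIDES)}

# -1 marks characters outside {A,T,G,C}
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into (A,T,G,C); raise on other characters."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"character {bad!r} outside alphabet {ALPHABET}")
    return arr


def encode_matrix(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) int8 matrix."""
    if not sequences:
        raise ValueError("no sequences to encode")
    return np.stack([encode(s) for s in sequences])


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)
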