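"""The 20-letter amino-acid alphabet and residue encoding.

Row/column order of every probability vector and matrix in this package is
the alphabetical one-letter code order ``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AMINO_ACIDS: int = 20

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Residues outside the canonical 20 that have an accepted canonical stand-in:
# selenocysteine (U) is encoded as cysteine, pyrrolysine (O) as lysine.
RESIDUE_MAP: dict[str, str] = {"U": "C", "O": "K"}

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _LOOKUP[ord(_aa)] = _i


def is_canonical(sequence: str) -> bool:
    """True if every character is one of the 20 canonical one-letter codes."""
    return bool(sequence) and all(c in AA_INDEX for c in sequence)


def encode(sequence: str) -> np.ndarray:
    """Encode a canonical sequence as an int8 array of alphabet indices.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-canonical character.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="strict"), dtype=np.uint8)
    codes = _LOOKUP[raw]
    if (codes < 0).any():
        bad = sorted({c for c in sequence if c not in AA_INDEX})
        raise ValueError(f"non-canonical residue(s) {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(AMINO_ACIDS[int(c)] for c in codes)
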