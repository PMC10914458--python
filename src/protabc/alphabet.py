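"""Amino-acid alphabet and index conventions.

Every 20x20 matrix in this package is indexed alphabetically by one-letter
code (A, C, D, ..., Y).  Index 20 is reserved for missing data ('-' or 'X')
in encoded sequences.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
GAP_CHARS = frozenset("-X")
MISSING_INDEX = 20

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# PAML .dat residue order, used only when reading/writing model files.
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
PAML_TO_ALPHA = np.array([AA_INDEX[a] for a in PAML_ORDER])

_ENCODE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i
for _c in GAP_CHARS:
    _ENCODE[ord(_c)] = MISSING_INDEX


def encode_seq(seq: str) -> np.ndarray:
    """Encode a sequence string as integer indices (missing -> 20)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"illegal sequence character {bad!r}")
    return arr.astype(np.int64)


def decode_seq(indices: np.ndarray) -> str:
    table = AMINO_ACIDS + "-"
    return "".join(table[i] for i in indices)


def is_canonical(symbol: str) -> bool:
    return symbol in AA_INDEX
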