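"""The 20-letter amino-acid alphabet and the unknown-residue convention.

Every module counts residues over the 20 canonical one-letter codes in the
fixed order below. Any other letter (ambiguity codes X/B/Z/J, the rare
U/O, stop ``*``, ``.``) is normalized to the single unknown symbol ``X``:
it keeps its position in the sequence — so windows and structure tracks
stay aligned — but contributes to no residue count.
"""

from __future__ import annotations

import numpy as np

#: Canonical residues, alphabetical by one-letter code. Index order is the
#: column order of every 20-vector in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol every non-canonical residue is mapped to.
UNKNOWN: str = "X"

#: Integer code of the unknown symbol in encoded sequences (canonical
#: residues use 0..19 in AMINO_ACIDS order).
UNKNOWN_CODE: int = 20

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA: int = len(AMINO_ACIDS)

GAP: str = "-"

# byte-level lookup tables, built once
_SANITIZE = np.full(256, ord(UNKNOWN), dtype=np.uint8)
for _aa in AMINO_ACIDS:
    _SANITIZE[ord(_aa)] = ord(_aa)
    _SANITIZE[ord(_aa.lower())] = ord(_aa)

_ENCODE = np.full(256, UNKNOWN_CODE, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i


def sanitize(seq: str) -> tuple[str, int]:
    """Upper-case ``seq`` and map non-canonical letters to :data:`UNKNOWN`.

    Returns the normalized sequence and the number of replaced characters.
    Idempotent: sanitizing a sanitized sequence changes nothing.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    clean = _SANITIZE[raw]
    # replacements: positions that became unknown and were not X already
    n_replaced = int(np.sum((clean == ord(UNKNOWN)) & (raw != ord(UNKNOWN))))
    return clean.tobytes().decode("ascii"), n_replaced


def encode(seq: str) -> np.ndarray:
    """Encode a (sanitized) sequence as uint8 codes 0..19, unknown = 20."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def is_canonical(aa: str) -> bool:
    return len(aa) == 1 and aa in AA_INDEX
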