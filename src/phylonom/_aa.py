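"""Amino-acid alphabet shared across modules.

The 20 canonical residues in the classical substitution-matrix order
(ARNDCQEGHILKMFPSTWYV). ``X`` denotes an unknown residue; together with the
gap character ``-`` it is treated as missing data by every downstream
computation (distances, likelihood, parsimony).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: integer code for missing data (gap, X) in encoded sequences
MISSING_CODE = 20

_CODE_TABLE = np.full(128, 255, dtype=np.uint8)
for _a, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_a)] = _i
_CODE_TABLE[ord("X")] = MISSING_CODE
_CODE_TABLE[ord("-")] = MISSING_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as uint8 codes (0-19 residues, 20 missing).

    Raises ``ValueError`` on characters outside the alphabet plus {X, -}.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="strict"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(codes == 255)[0]})
        raise ValueError(f"characters outside amino-acid alphabet: {bad!r}")
    return codes
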