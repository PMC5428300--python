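"""Low-level nucleotide utilities shared across modules.

Sequences are plain upper-case Python strings over {A, C, G, T, N} once they
have passed ingest normalization; IUPAC degeneracy is handled through 4-bit
masks (A=1, C=2, G=4, T=8) so that two bases are *compatible* iff their masks
intersect.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# 4-bit encoding of the 15-letter IUPAC alphabet.
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

#: byte value of each base -> mask; 0 for anything non-IUPAC (incl. gaps)
MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _m in IUPAC_MASK.items():
    MASK_TABLE[ord(_b)] = _m
    MASK_TABLE[ord(_b.lower())] = _m


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Upper-case and map ambiguity codes other than N to N.

    Returns the normalized sequence and the number of characters that were
    converted to N (so callers can log a warning).
    """
    seq = seq.upper()
    n_converted = 0
    if not set(seq) <= {"A", "C", "G", "T", "N"}:
        out = []
        for ch in seq:
            if ch in "ACGTN":
                out.append(ch)
            elif ch in IUPAC_MASK:
                out.append("N")
                n_converted += 1
            else:
                raise ValueError(f"non-nucleotide character {ch!r} in sequence")
        seq = "".join(out)
    return seq, n_converted


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gc_percent(seq: str) -> float:
    """G+C percentage, N excluded from numerator and denominator; 1 decimal."""
    arr = seq_to_bytes(seq)
    acgt = np.isin(arr, [65, 67, 71, 84])  # A C G T
    denom = int(acgt.sum())
    if denom == 0:
        return 0.0
    gc = int(np.isin(arr, [71, 67]).sum())  # G C
    return round(100.0 * gc / denom, 1)
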