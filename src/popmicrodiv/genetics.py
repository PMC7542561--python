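"""Nucleotide encoding and the standard genetic code.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, gaps) is 4.  All
codon-level statistics in the package go through the lookup tables built
here, so the encoding is fixed package-wide.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_CODE = 4

# 256-entry decoder table: byte value of base character -> code
_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement in code space (A<->T, C<->G); N stays N
COMP = np.array([T, G, C, A, N_CODE], dtype=np.uint8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# Standard genetic code, classically tabulated in TCAG order.
_TCAG = "TCAG"
_AA_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: amino acid (one letter, '*' = stop) for codon index 16*b0 + 4*b1 + b2 in ACGT coding
AA64 = np.zeros(64, dtype="<U1")
for _i, _aa in enumerate(_AA_TCAG):
    _b0, _b1, _b2 = _TCAG[_i // 16], _TCAG[(_i // 4) % 4], _TCAG[_i % 4]
    _idx = 16 * BASES.index(_b0) + 4 * BASES.index(_b1) + BASES.index(_b2)
    AA64[_idx] = _aa

IS_STOP64 = AA64 == "*"
SENSE_CODONS = [i for i in range(64) if not IS_STOP64[i]]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array (A=0..T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (codes >3 decode to ``N``)."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def codon_index(codes3: np.ndarray) -> int:
    """Index of a length-3 code array into the 64-codon tables."""
    b0, b1, b2 = (int(x) for x in codes3)
    if b0 > 3 or b1 > 3 or b2 > 3:
        raise ValueError(f"codon contains a non-ACGT base: {decode(codes3)}")
    return 16 * b0 + 4 * b1 + b2


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon string ('*' for stop)."""
    return str(AA64[codon_index(encode(codon))])


# --- per-codon-index constants used by the variant and site machinery ---

def _synonymous_neighbour_table() -> np.ndarray:
    """syn[ci, pos, b] = True if replacing position ``pos`` of codon ``ci``
    with base ``b`` (b != current base) keeps the amino acid."""
    syn = np.zeros((64, 3, 4), dtype=bool)
    for ci in range(64):
        bases = [(ci >> 4) & 3, (ci >> 2) & 3, ci & 3]
        for pos in range(3):
            for b in range(4):
                if b == bases[pos]:
                    continue
                alt = list(bases)
                alt[pos] = b
                cj = 16 * alt[0] + 4 * alt[1] + alt[2]
                syn[ci, pos, b] = AA64[cj] == AA64[ci]
    return syn


#: synonymity of every single-base neighbour, indexed [codon, position, new base]
SYN_NEIGHBOUR = _synonymous_neighbour_table()

#: Nei-Gojobori fractional synonymous sites per codon (sum over the 3 positions
#: of the fraction of the 3 single-base alternatives that are synonymous)
SYN_SITES64 = SYN_NEIGHBOUR.sum(axis=(1, 2)) / 3.0

#: positions (0..2) of each codon where *every* single-base change is synonymous
FOURFOLD_POS64 = SYN_NEIGHBOUR.sum(axis=2) == 3
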