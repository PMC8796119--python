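"""Sequence alphabet utilities shared across the toolkit.

All analysis modules work in the RNA alphabet {A, C, G, U} (plus N for
ambiguity); DNA input is converted on read (T -> U). Probe design works in
DNA space and has its own helpers here.
"""
from __future__ import annotations

import numpy as np

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

_RNA_COMP = str.maketrans("ACGUN", "UGCAN")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

# integer codes used by the vectorized scanners: A=0 C=1 G=2 U=3 N=4
A, C, G, U, N = 0, 1, 2, 3, 4

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGUN"):
    _ENC[ord(_b)] = _i

_ENC_DNA = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC_DNA[ord(_b)] = _i


def normalize_rna(seq: str, name: str = "") -> str:
    """Uppercase, convert T->U and validate against {A,C,G,U,N}.

    Raises ValueError naming the offending symbol on any other character.
    """
    s = str(seq).strip().upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        where = f" in {name!r}" if name else ""
        raise ValueError(f"non-RNA character(s) {sorted(bad)}{where}")
    return s


def normalize_dna(seq: str, name: str = "") -> str:
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        where = f" in {name!r}" if name else ""
        raise ValueError(f"non-DNA character(s) {sorted(bad)}{where}")
    return s


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA string as uint8 codes (A=0 C=1 G=2 U=3 N=4)."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("unencodable character in RNA sequence")
    return arr


def encode_dna(seq: str) -> np.ndarray:
    arr = _ENC_DNA[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("unencodable character in DNA sequence")
    return arr
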