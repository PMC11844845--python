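"""Protein sequence encoding: fixed-length integer vectors with pad masks.

Each canonical amino acid maps to its alphabetical rank among the 20
canonical one-letter codes (A=1, C=2, D=3, E=4, ..., Y=20); any other
alphabetic letter (B, J, O, U, X, Z) maps to the shared unknown index 21.
Index 0 is reserved for padding.  Sequences are truncated to the first
``max_len`` residues (N-terminal prefix) or right-padded with 0; the mask
marks real residues so downstream attention can ignore pads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"  # sorted canonical alphabet
UNKNOWN_INDEX = 21
MAX_LEN = 1000

AA_TO_INT = {aa: i + 1 for i, aa in enumerate(CANONICAL)}
INT_TO_AA = {i + 1: aa for i, aa in enumerate(CANONICAL)}


@dataclass
class EncodedProtein:
    tokens: np.ndarray  # (max_len,) int, 0 = pad
    mask: np.ndarray  # (max_len,) bool, true on the residue prefix
    original_length: int


def encode_protein(sequence: str, max_len: int = MAX_LEN) -> EncodedProtein:
    """Encode an amino-acid sequence as a length-`max_len` integer vector."""
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if not ch.isalpha():
            raise ValueError(
                f"non-alphabetic character {ch!r} at position {pos} in protein sequence"
            )
    tokens = np.zeros(max_len, dtype=np.int64)
    n = min(len(seq), max_len)
    tokens[:n] = [AA_TO_INT.get(ch, UNKNOWN_INDEX) for ch in seq[:n]]
    mask = np.zeros(max_len, dtype=bool)
    mask[:n] = True
    return EncodedProtein(tokens=tokens, mask=mask, original_length=len(seq))


def decode_tokens(tokens: np.ndarray) -> str:
    """Inverse of :func:`encode_protein` for canonical, unpadded tokens."""
    out = []
    for t in np.asarray(tokens):
        if t == 0:
            break
        if t == UNKNOWN_INDEX:
            out.append("X")
        else:
            out.append(INT_TO_AA[int(t)])
    return "".join(out)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA file, preserving record ids for joins."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records
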