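"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def complement_base(base: str) -> str:
    return COMPLEMENT[base]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` exactly (same length)."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return float(np.isin(arr, np.frombuffer(b"CGcg", dtype=np.uint8)).mean())


def seq_to_array(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; other characters as 255."""
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


SUBSTITUTION_CLASSES = [
    f"{r}>{a}" for r in BASES for a in BASES if r != a
]
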