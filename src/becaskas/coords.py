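"""PAM-relative coordinate transforms.

A planted or detected protospacer+PAM occupies a 23-bp 0-based half-open
interval ``[start, end)`` on the reference, on either strand.  PAM-relative
positions follow the field convention: -1 is the protospacer base abutting
the PAM, -20 the PAM-distal end, +1..+3 the PAM itself; positions < -20
extend into the 5' flank of the protospacer on the non-target strand.

For a minus-strand site the plus strand of the reference carries the
reverse complement, so PAM-relative positions run right-to-left and
non-target-strand substitutions appear complemented on the plus strand
(an NTS C>T reads as G>A).
"""

from __future__ import annotations

from becaskas.seq import complement_base


def pam_relative_to_genomic(start: int, end: int, strand: str, pos: int) -> int:
    """Genomic (plus-strand) coordinate of PAM-relative position ``pos``.

    ``[start, end)`` is the protospacer+PAM interval; ``pos`` may lie outside
    -20..+3 (out-of-protospacer NTS positions map into the flank).
    """
    if pos == 0:
        raise ValueError("PAM-relative position 0 does not exist")
    if strand == "+":
        pam_start = end - 3
        return pam_start + pos if pos < 0 else pam_start + pos - 1
    if strand == "-":
        return start + 2 - pos if pos < 0 else start + 3 - pos
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def genomic_to_pam_relative(start: int, end: int, strand: str, g: int) -> int:
    """Inverse of :func:`pam_relative_to_genomic` (PAM bases map to +1..+3)."""
    if strand == "+":
        pam_start = end - 3
        pos = g - pam_start
        return pos if pos < 0 else pos + 1
    if strand == "-":
        pos = start + 2 - g
        return pos if pos < 0 else pos + 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def nts_substitution_on_plus(strand: str, base_from: str, base_to: str) -> tuple[str, str]:
    """Plus-strand appearance of an NTS-frame substitution at a site on ``strand``."""
    if strand == "+":
        return base_from, base_to
    return complement_base(base_from), complement_base(base_to)


def ts_substitution_on_plus(strand: str, base_from: str, base_to: str) -> tuple[str, str]:
    """Plus-strand appearance of a target-strand substitution (TS is the
    opposite strand from the NTS)."""
    if strand == "+":
        return complement_base(base_from), complement_base(base_to)
    return base_from, base_to
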