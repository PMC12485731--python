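"""Guide RNA and base-editor deaminase profiles.

A :class:`GuideSpec` holds the 20-nt protospacer (written as the
non-target-strand sequence, 5'->3', ending adjacent to the PAM) and an IUPAC
PAM pattern (NGG for SpCas9, NRN for near-PAMless SpRY variants).

An :class:`EditorProfile` describes a deaminase's behaviour in PAM-relative
coordinates, where position -1 is the protospacer base abutting the PAM:

* ``nts_window`` — per-position conversion probability (at occupancy 1) for
  the editor's canonical change on the displaced non-target strand (NTS):
  C->T for cytosine editors, A->G for adenine editors.
* ``ts_window`` — per-position probability of the same deamination chemistry
  acting on the gRNA-paired target strand (TS).  Cytosine editors show a TS
  C->T band roughly 20-30 bp 5' of the PAM (seen as G>A in NTS coordinates);
  adenine editors show none.
* ``out_of_protospacer_period`` — cytosine editors additionally edit the NTS
  well outside the protospacer with a damped ~10.5-bp periodicity (the DNA
  helical repeat), with local maxima near -38, -49 and -60.
* ``context_multipliers`` — 5' dinucleotide-context biases (e.g. the hA3A
  deaminase's preference for a 5'TC context).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from becaskas.seq import IUPAC, matches_iupac

# Canonical HEK site 4 protospacer (SpCas9, NGG PAM).  Its cytosines sit at
# PAM-relative -18, -16 and -13 and its editing-window adenine at -17.
HEK4_PROTOSPACER = "GGCACTGCGGCTGGAGGTGG"


@dataclass(frozen=True)
class GuideSpec:
    """A gRNA: protospacer (NTS sequence, 5'->3' toward the PAM) + PAM pattern."""

    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or set(self.protospacer) - set("ACGT"):
            raise ValueError(
                "protospacer must be a 20-nt ACGT sequence, got "
                f"{self.protospacer!r}"
            )
        if len(self.pam_pattern) != 3 or set(self.pam_pattern) - set(IUPAC):
            raise ValueError(f"PAM pattern must be 3 IUPAC symbols, got {self.pam_pattern!r}")

    @property
    def seed5(self) -> str:
        """The 5-nt PAM-adjacent seed (3' end of the protospacer)."""
        return self.protospacer[-5:]

    def pam_matches(self, pam: str) -> bool:
        return matches_iupac(pam, self.pam_pattern)


@dataclass
class EditorProfile:
    """Per-position deaminase conversion probabilities in PAM-relative coordinates."""

    name: str
    base_from: str
    base_to: str
    nts_window: dict[int, float] = field(default_factory=dict)
    ts_window: dict[int, float] = field(default_factory=dict)
    out_of_protospacer_period: float | None = None
    context_multipliers: dict[str, float] = field(default_factory=dict)
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        for window in (self.nts_window, self.ts_window):
            for pos, p in window.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"window probability {p} at {pos} outside [0,1]")

    @property
    def is_abe(self) -> bool:
        return self.base_from == "A"

    def conversion_probability(self, pos: int, context5: str | None = None) -> float:
        """NTS conversion probability at PAM-relative ``pos``.

        ``context5`` is the 5' base on the NTS (so the dinucleotide is
        ``context5 + base_from``); context multipliers clip at 1.
        """
        p = self.nts_window.get(pos, 0.0)
        if p and context5 is not None:
            mult = self.context_multipliers.get(context5 + self.base_from, 1.0)
            p = min(1.0, p * mult)
        return p


def _cbe_periodic_window(amplitude: float = 0.06, period: float = 10.5) -> dict[int, float]:
    # Damped cosine over NTS -60..-31; phase anchored so maxima land near
    # -38, -49, -60 (one helical turn apart).
    window: dict[int, float] = {}
    for pos in range(-60, -30):
        d = -pos
        envelope = amplitude * math.exp(-(d - 31) / 40.0)
        window[pos] = envelope * 0.5 * (1.0 + math.cos(2.0 * math.pi * (d - 38.0) / period))
    return window


def default_editor(name: str) -> EditorProfile:
    """Bundled editor profiles: ``CBE-eBE``, ``ABE8e``, ``ABE8e-SpRY``.

    The cytosine editor converts NTS C->T in a wide window peaking 13-19 bp
    5' of the PAM, adds a TS band at -30..-20 and a damped ~10.5-bp periodic
    out-of-protospacer component; the adenine editors convert NTS A->G only
    within -18..-13.  Window values are configuration, not measurements; the
    in-protospacer peak values mirror a well-characterised on-target site.
    """
    if name in ("CBE-eBE", "CBE", "eBE"):
        nts = {
            -19: 0.35,
            -18: 0.683,
            -17: 0.55,
            -16: 0.783,
            -15: 0.60,
            -14: 0.50,
            -13: 0.644,
            -12: 0.25,
            -11: 0.12,
            -10: 0.06,
        }
        nts.update(_cbe_periodic_window())
        ts = {pos: 0.10 * math.exp(-((abs(pos) - 25) ** 2) / 18.0) for pos in range(-30, -19)}
        return EditorProfile(
            name="CBE-eBE",
            base_from="C",
            base_to="T",
            nts_window=nts,
            ts_window=ts,
            out_of_protospacer_period=10.5,
            context_multipliers={"TC": 2.0, "GC": 0.6},
            pam_pattern="NGG",
        )
    if name in ("ABE8e", "ABE"):
        nts = {-18: 0.25, -17: 0.70, -16: 0.55, -15: 0.55, -14: 0.40, -13: 0.25}
        return EditorProfile(
            name="ABE8e",
            base_from="A",
            base_to="G",
            nts_window=nts,
            pam_pattern="NGG",
        )
    if name == "ABE8e-SpRY":
        profile = default_editor("ABE8e")
        profile.name = "ABE8e-SpRY"
        profile.pam_pattern = "NRN"
        return profile
    raise ValueError(f"unknown editor profile {name!r}")
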