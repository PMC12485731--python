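"""Categorical functional annotation of off-target edits.

Classifies each called edit against a transcript model (missense /
synonymous with protein change, splice donor/acceptor within the canonical
2-bp intronic windows, intronic, intergenic), flags overlap with named
regulatory interval sets (ATAC, histone marks), and exposes a pluggable
variant-effect-scorer contract for sequence-model-based prioritisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from becaskas.seq import revcomp

SPLICE_WINDOW = 2  # canonical GT/AG dinucleotide positions


@dataclass
class Transcript:
    name: str
    contig: str
    strand: str
    cds_exons: list[tuple[int, int]]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        self.cds_exons = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(self.cds_exons, self.cds_exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.name}: overlapping exons")
        if sum(e - s for s, e in self.cds_exons) % 3 != 0:
            raise ValueError(f"transcript {self.name}: CDS length not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]


@dataclass
class GeneModel:
    transcripts: list[Transcript] = field(default_factory=list)

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModel":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        transcripts = []
        for tx in db.features_of_type(("mRNA", "transcript")):
            cds = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
            if cds:
                transcripts.append(
                    Transcript(name=tx.id, contig=tx.seqid, strand=tx.strand, cds_exons=cds)
                )
        return cls(transcripts)


@dataclass
class SiteAnnotation:
    site_id: str
    category: str  # missense|synonymous|splice_donor|splice_acceptor|intronic|intergenic
    transcript: str | None = None
    protein_change: str | None = None
    regulatory_overlap: dict[str, bool] = field(default_factory=dict)
    all_transcripts: list[str] = field(default_factory=list)


def _cds_index(tx: Transcript, g: int) -> int | None:
    """Index of genomic position ``g`` within the spliced CDS (coding order)."""
    offset = 0
    exons = tx.cds_exons if tx.strand == "+" else tx.cds_exons[::-1]
    for s, e in exons:
        if s <= g < e:
            return offset + (g - s if tx.strand == "+" else e - 1 - g)
        offset += e - s
    return None


def _cds_sequence(tx: Transcript, reference: str) -> str:
    parts = [reference[s:e] for s, e in tx.cds_exons]
    seq = "".join(parts)
    return seq if tx.strand == "+" else revcomp(seq)


def _splice_category(tx: Transcript, g: int) -> str | None:
    """Donor/acceptor if ``g`` lies within 2 bp on the intron side of an
    internal exon boundary (donor: 3' of an exon in transcription direction;
    acceptor: 5' of the next exon)."""
    for i, (s, e) in enumerate(tx.cds_exons):
        is_first = i == 0
        is_last = i == len(tx.cds_exons) - 1
        right_intron = not is_last and e <= g < e + SPLICE_WINDOW
        left_intron = not is_first and s - SPLICE_WINDOW <= g < s
        if right_intron:
            return "splice_donor" if tx.strand == "+" else "splice_acceptor"
        if left_intron:
            return "splice_acceptor" if tx.strand == "+" else "splice_donor"
    return None


def classify_edit(
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    genes: GeneModel,
    reference: str | dict[str, str],
    site_id: str = "",
) -> SiteAnnotation:
    """Primary category of one edit (first overlapping transcript wins)."""
    refs = {"": reference} if isinstance(reference, str) else reference
    ref_seq = refs.get(chrom, refs.get("", next(iter(refs.values()))))
    overlapping = [
        tx for tx in genes.transcripts
        if tx.contig in (chrom, "") and tx.span[0] - SPLICE_WINDOW <= pos < tx.span[1] + SPLICE_WINDOW
    ]
    names = [tx.name for tx in overlapping]
    for tx in overlapping:
        idx = _cds_index(tx, pos)
        if idx is not None:
            cds = _cds_sequence(tx, ref_seq)
            codon_i = idx // 3
            within = idx % 3
            codon = list(cds[3 * codon_i : 3 * codon_i + 3])
            new_base = alt_base if tx.strand == "+" else str(Seq(alt_base).complement())
            codon_new = codon.copy()
            codon_new[within] = new_base
            aa_ref = str(Seq("".join(codon)).translate())
            aa_alt = str(Seq("".join(codon_new)).translate())
            if aa_ref == aa_alt:
                return SiteAnnotation(site_id, "synonymous", tx.name,
                                      f"{aa_ref}{codon_i + 1}{aa_alt}", all_transcripts=names)
            return SiteAnnotation(site_id, "missense", tx.name,
                                  f"{aa_ref}{codon_i + 1}{aa_alt}", all_transcripts=names)
        splice = _splice_category(tx, pos)
        if splice is not None:
            return SiteAnnotation(site_id, splice, tx.name, all_transcripts=names)
        if tx.span[0] <= pos < tx.span[1]:
            return SiteAnnotation(site_id, "intronic", tx.name, all_transcripts=names)
    return SiteAnnotation(site_id, "intergenic", all_transcripts=names)


def overlap_regulatory(
    sites: pd.DataFrame, interval_sets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-site boolean overlap flags against named interval sets
    (half-open intersection of >= 1 bp)."""
    out = sites.copy()
    for name, ivs in interval_sets.items():
        by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in ivs.groupby(ivs["chrom"] if "chrom" in ivs else [""] * len(ivs)):
            order = np.argsort(grp["start"].to_numpy())
            by_contig[chrom] = (
                grp["start"].to_numpy()[order],
                grp["end"].to_numpy()[order],
            )
        flags = []
        for _, s in sites.iterrows():
            chrom = s.get("chrom", "")
            if chrom not in by_contig:
                flags.append(False)
                continue
            starts, ends = by_contig[chrom]
            hit = bool(np.any((starts < s["end"]) & (ends > s["start"])))
            flags.append(hit)
        out[f"overlaps_{name}"] = flags
    return out


Scorer = Callable[[str, str], float]


def score_variants(
    sites: pd.DataFrame,
    scorer: Scorer,
    reference: str | dict[str, str],
    window: int = 50,
) -> pd.DataFrame:
    """Apply an external variant-effect scorer to each edit.

    ``scorer(ref_window, alt_window) -> scalar`` (log2 fold-change
    convention; negative = loss).  Sites are ranked by absolute score,
    ties broken by site id.  Scorer failures propagate with the site id.
    """
    refs = {"": reference} if isinstance(reference, str) else reference
    scores = []
    for _, s in sites.iterrows():
        chrom = s.get("chrom", "")
        ref_seq = refs.get(chrom, refs.get("", next(iter(refs.values()))))
        pos = int(s["pos"])
        lo, hi = max(0, pos - window), min(len(ref_seq), pos + window + 1)
        ref_win = ref_seq[lo:hi]
        alt_win = ref_win[: pos - lo] + s["alt"] + ref_win[pos - lo + 1 :]
        try:
            scores.append(float(scorer(ref_win, alt_win)))
        except Exception as exc:
            site = s.get("site_id", s.get("name", f"{chrom}:{pos}"))
            raise RuntimeError(f"scorer failed for site {site}") from exc
    out = sites.copy()
    out["effect_score"] = scores
    tie = out["site_id"] if "site_id" in out else out.index
    out = out.assign(_tie=tie).sort_values(
        by=["effect_score", "_tie"],
        key=lambda col: -col.abs() if col.name == "effect_score" else col,
    ).drop(columns="_tie")
    out["rank"] = range(1, len(out) + 1)
    return out
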