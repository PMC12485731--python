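"""Synthetic beCasKAS experiment generator with known ground truth.

Emulates the essential structure of a base-editor off-target ssDNA-pulldown
experiment: a random reference genome, planted protospacer-like off-target
sites whose R-loop occupancy decays geometrically with mismatch count
(PAM-distal mismatches first, so the PAM-adjacent seed degrades last),
pulldown/input reads with or without gRNA at configurable editor-mRNA dose,
strand-aware deaminase conversions drawn from an editor profile, uniform
sequencing error, and paired amplicon edit-frequency tables.

Reads are emitted pre-aligned (all-match CIGAR, MD/NM tags) because read
alignment is outside the scope of the analysis; the pulldown enrichment and
the per-read editing probability are both proportional to site occupancy,
which is the latent variable tying unwinding to editing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from becaskas.coords import (
    nts_substitution_on_plus,
    pam_relative_to_genomic,
    ts_substitution_on_plus,
)
from becaskas.guides import EditorProfile, GuideSpec
from becaskas.seq import BASES, complement_base, revcomp

DEFAULT_CHROM = "chr_sim"


class InvalidConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Experimental design of one synthetic run.

    ``background_depth`` is mean reads per kbp; ``enrichment_factor`` is the
    fold-increase of read-start density inside an R-loop at occupancy 1;
    ``dose_scalars`` multiply occupancy to emulate an editor-mRNA dilution
    series.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.45
    n_offtargets: int = 12
    mismatch_distribution: dict[int, int] = field(
        default_factory=lambda: {0: 1, 1: 2, 2: 2, 3: 3, 4: 2, 6: 2}
    )
    read_length: int = 100
    background_depth: float = 50.0
    enrichment_factor: float = 20.0
    sequencing_error: float = 0.002
    dose_scalars: list[float] = field(default_factory=lambda: [1.0])
    replicates: int = 3
    occupancy_max: float = 0.8
    occupancy_decay: float = 0.65
    rng_seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise InvalidConfigError("genome_length must be positive")
        if self.genome_length < 10 * self.read_length:
            raise InvalidConfigError("genome_length must be >= 10x read_length")
        for name in ("gc_fraction", "sequencing_error", "occupancy_max", "occupancy_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0,1]")
        if sum(self.mismatch_distribution.values()) != self.n_offtargets:
            raise InvalidConfigError(
                "mismatch_distribution counts must sum to n_offtargets"
            )


@dataclass
class TruthSite:
    """One planted site: location, homology and latent editing truth.

    ``true_conversion`` / ``ts_conversion`` map PAM-relative positions to the
    per-read conversion probability (given the read derives from an R-loop)
    on the non-target and target strands respectively.
    """

    site_id: str
    chrom: str
    start: int  # protospacer+PAM interval, 0-based half-open
    end: int
    strand: str
    mismatch_count: int
    seed_match_length: int
    occupancy: float
    true_conversion: dict[int, float] = field(default_factory=dict)
    ts_conversion: dict[int, float] = field(default_factory=dict)


@dataclass
class TruthSet:
    sites: list[TruthSite]

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def on_target(self) -> TruthSite:
        return min(self.sites, key=lambda s: s.mismatch_count)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t"
                    f"{round(1000 * s.occupancy)}\t{s.strand}\n"
                )

    def to_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            for pos, p in sorted(s.true_conversion.items()):
                rows.append(
                    dict(
                        site=s.site_id, chrom=s.chrom, start=s.start, end=s.end,
                        strand=s.strand, mismatches=s.mismatch_count,
                        seed_match_length=s.seed_match_length,
                        occupancy=s.occupancy, position=pos, frame="NTS",
                        conversion=p,
                    )
                )
            for pos, p in sorted(s.ts_conversion.items()):
                rows.append(
                    dict(
                        site=s.site_id, chrom=s.chrom, start=s.start, end=s.end,
                        strand=s.strand, mismatches=s.mismatch_count,
                        seed_match_length=s.seed_match_length,
                        occupancy=s.occupancy, position=pos, frame="TS",
                        conversion=p,
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class SimRead:
    """A pre-aligned single-end read (plus-strand sequence)."""

    name: str
    chrom: str
    start: int  # 0-based leftmost reference position
    seq: str


def generate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> str:
    """Random genome of the configured length and GC content (deterministic
    under ``rng_seed``)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=probs)
    return bases.tobytes().decode()


def write_fasta(sequence: str, path: str | Path, chrom: str = DEFAULT_CHROM, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    from becaskas.seq import IUPAC

    return "".join(rng.choice(sorted(IUPAC[sym])) for sym in pattern)


def _site_conversions(
    reference: str, site: TruthSite, editor: EditorProfile
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-position conversion probabilities given the planted sequence.

    A window position contributes only where the corresponding strand's base
    actually is the editor's substrate; NTS probabilities pick up the 5'
    dinucleotide-context multiplier (clipped at 1).
    """

    def nts_base(g: int) -> str:
        return reference[g] if site.strand == "+" else complement_base(reference[g])

    nts: dict[int, float] = {}
    for pos, p in editor.nts_window.items():
        g = pam_relative_to_genomic(site.start, site.end, site.strand, pos)
        if not 0 < g < len(reference) - 1:
            continue
        if nts_base(g) != editor.base_from:
            continue
        g5 = g - 1 if site.strand == "+" else g + 1
        prob = min(1.0, p * editor.context_multipliers.get(nts_base(g5) + editor.base_from, 1.0))
        if prob > 0:
            nts[pos] = prob
    ts: dict[int, float] = {}
    for pos, p in editor.ts_window.items():
        g = pam_relative_to_genomic(site.start, site.end, site.strand, pos)
        if not 0 <= g < len(reference):
            continue
        if complement_base(nts_base(g)) != editor.base_from:
            continue
        if p > 0:
            ts[pos] = p
    return nts, ts


def plant_offtargets(
    reference: str,
    guide: GuideSpec,
    config: SimConfig,
    editor: EditorProfile,
    chrom: str = DEFAULT_CHROM,
    rng: np.random.Generator | None = None,
) -> tuple[str, TruthSet]:
    """Insert protospacer-like sequences (+PAM) into the reference.

    Mismatches are placed PAM-distal first, so a site with m mismatches keeps
    a (20 - m)-nt PAM-adjacent seed; occupancy follows the geometric decay
    ``occupancy_max * decay**m``.  Returns the modified reference and the
    ground-truth site set.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.rng_seed, 1])
    site_len = len(guide.protospacer) + len(guide.pam_pattern)
    margin = 120  # clearance for flanking profile windows and read overhang
    min_gap = 2 * config.read_length + 200

    mm_counts: list[int] = []
    for mm, n in sorted(config.mismatch_distribution.items()):
        mm_counts.extend([mm] * n)

    # non-overlapping placement by rejection sampling
    placed: list[int] = []
    starts: list[int] = []
    attempts = 0
    lo, hi = margin, config.genome_length - margin - site_len
    if hi <= lo:
        raise PlacementError("genome too short for any site placement")
    while len(starts) < len(mm_counts):
        attempts += 1
        if attempts > 1000 * max(1, len(mm_counts)):
            raise PlacementError(
                f"could not place {len(mm_counts)} non-overlapping sites in "
                f"{config.genome_length} bp"
            )
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - p) >= min_gap for p in placed):
            placed.append(cand)
            starts.append(cand)

    ref = list(reference)
    sites: list[TruthSite] = []
    for i, (mm, start) in enumerate(zip(mm_counts, starts)):
        strand = "+" if rng.random() < 0.5 else "-"
        proto = list(guide.protospacer)
        for k in range(mm):  # PAM-distal first: -20, -19, ...
            idx = k
            choices = [b for b in BASES if b != proto[idx]]
            proto[idx] = choices[int(rng.integers(0, 3))]
        pam = _concrete_pam(guide.pam_pattern, rng)
        site_seq = "".join(proto) + pam
        if strand == "-":
            site_seq = revcomp(site_seq)
        ref[start : start + site_len] = site_seq
        occupancy = config.occupancy_max * config.occupancy_decay**mm
        sites.append(
            TruthSite(
                site_id=f"site_{i:03d}",
                chrom=chrom,
                start=start,
                end=start + site_len,
                strand=strand,
                mismatch_count=mm,
                seed_match_length=len(guide.protospacer) - mm,
                occupancy=occupancy,
            )
        )

    new_reference = "".join(ref)
    for site in sites:
        site.true_conversion, site.ts_conversion = _site_conversions(
            new_reference, site, editor
        )
    return new_reference, TruthSet(sites)


def _parse_condition(condition: str | tuple[str, str]) -> tuple[bool, bool]:
    if isinstance(condition, tuple):
        assay, grna = condition
    else:
        assay, _, grna = condition.partition(":")
    pulldown = {"pulldown": True, "input": False}[assay]
    with_grna = {"plus_gRNA": True, "minus_gRNA": False, "+": True, "-": False}[grna]
    return pulldown, with_grna


def simulate_reads(
    reference: str,
    truth: TruthSet,
    editor: EditorProfile,
    condition: str | tuple[str, str],
    config: SimConfig,
    dose_scalar: float = 1.0,
    replicate: int = 0,
    chrom: str = DEFAULT_CHROM,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Simulate one library, sorted by position.

    Background read starts are uniform at ``background_depth``; in
    pulldown/+gRNA the start density inside each site interval is multiplied
    by ``1 + enrichment_factor * occupancy * dose_scalar``.  In any +gRNA
    condition each read overlapping a site is "edited" (derives from an
    R-loop-bearing genome) with probability ``occupancy * dose_scalar``, and
    edited reads pick up conversions per position from the site truth,
    complemented on the plus strand as strand requires.  Uniform sequencing
    error applies everywhere.
    """
    config.validate()
    pulldown, with_grna = _parse_condition(condition)
    if rng is None:
        rng = np.random.default_rng(
            [config.rng_seed, 2, int(pulldown), int(with_grna), replicate,
             int(round(dose_scalar * 1_000_000))]
        )
    L = len(reference)
    rl = config.read_length
    bg_per_bp = config.background_depth / 1000.0

    n_bg = rng.poisson(bg_per_bp * (L - rl + 1))
    starts = [rng.integers(0, L - rl + 1, size=n_bg)]
    if pulldown and with_grna:
        # coverage inside a site is boosted by reads overlapping it, so extra
        # read starts are drawn from the full overlap-compatible span
        for site in truth:
            boost = config.enrichment_factor * site.occupancy * dose_scalar
            lo = max(0, site.start - rl + 1)
            hi = min(L - rl + 1, site.end)
            lam = bg_per_bp * (hi - lo) * boost
            n_extra = rng.poisson(lam)
            if n_extra:
                starts.append(rng.integers(lo, hi, size=n_extra))
    all_starts = np.sort(np.concatenate(starts)).astype(np.int64)
    all_starts = np.clip(all_starts, 0, L - rl)

    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    seqs = [bytearray(ref_arr[s : s + rl]) for s in all_starts]

    if with_grna:
        for site in truth:
            p_edit = min(1.0, site.occupancy * dose_scalar)
            if p_edit <= 0:
                continue
            plus_subs: list[tuple[int, int, int]] = []  # (g, from_byte, to_byte)
            probs: list[float] = []
            for frame, window in (("NTS", site.true_conversion), ("TS", site.ts_conversion)):
                conv = nts_substitution_on_plus if frame == "NTS" else ts_substitution_on_plus
                for pos, p in window.items():
                    g = pam_relative_to_genomic(site.start, site.end, site.strand, pos)
                    if not 0 <= g < L:
                        continue
                    b_from, b_to = conv(site.strand, editor.base_from, editor.base_to)
                    plus_subs.append((g, ord(b_from), ord(b_to)))
                    probs.append(p)
            if not plus_subs:
                continue
            i0 = int(np.searchsorted(all_starts, site.start - rl + 1, side="left"))
            i1 = int(np.searchsorted(all_starts, site.end, side="left"))
            for i in range(i0, i1):
                if rng.random() >= p_edit:
                    continue
                s = int(all_starts[i])
                for (g, b_from, b_to), p in zip(plus_subs, probs):
                    off = g - s
                    if 0 <= off < rl and seqs[i][off] == b_from and rng.random() < p:
                        seqs[i][off] = b_to

    err = config.sequencing_error
    if err > 0:
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in range(len(seqs)):
            n_err = rng.binomial(rl, err)
            if n_err == 0:
                continue
            positions = rng.choice(rl, size=n_err, replace=False)
            for pos in positions:
                cur = seqs[i][pos]
                alt = base_bytes[int(rng.integers(0, 4))]
                while alt == cur:
                    alt = base_bytes[int(rng.integers(0, 4))]
                seqs[i][pos] = int(alt)

    cond_tag = ("pd" if pulldown else "in") + ("P" if with_grna else "M")
    return [
        SimRead(name=f"{cond_tag}_r{replicate}_{i:07d}", chrom=chrom, start=int(s),
                seq=bytes(q).decode())
        for i, (s, q) in enumerate(zip(all_starts, seqs))
    ]


def _md_and_nm(ref_slice: str, seq: str) -> tuple[str, int]:
    md = []
    run = 0
    nm = 0
    for r, q in zip(ref_slice, seq):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def write_sam(
    reads: list[SimRead], reference: str, path: str | Path, chrom: str = DEFAULT_CHROM
) -> None:
    """Coordinate-sorted single-end SAM with all-match CIGAR and MD/NM tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in sorted(reads, key=lambda r: r.start):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            a.query_sequence = read.seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            md, nm = _md_and_nm(reference[read.start : read.start + len(read.seq)], read.seq)
            a.set_tag("MD", md)
            a.set_tag("NM", nm)
            out.write(a)


def load_sam(path: str | Path) -> list[SimRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            reads.append(
                SimRead(name=a.query_name, chrom=a.reference_name,
                        start=a.reference_start, seq=a.query_sequence)
            )
    return reads


def simulate_amplicon_table(
    rloop_freqs: pd.DataFrame | TruthSet,
    occupancy_scaling: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site amplicon edit frequencies as a scaled, noisy copy of the
    in-R-loop (pulldown-measured) frequencies.

    ``amplicon = occupancy_scaling * rloop + N(0, noise_sd)``, truncated to
    [0,1].  Accepts either a frame with columns ``site, position,
    rloop_freq`` or a TruthSet (pulldown frequency = occupancy x conversion).
    """
    if not 0 < occupancy_scaling <= 1:
        raise ValueError("occupancy_scaling must be in (0,1]")
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(rloop_freqs, TruthSet):
        rows = [
            dict(site=s.site_id, position=pos, rloop_freq=s.occupancy * p)
            for s in rloop_freqs
            for pos, p in sorted(s.true_conversion.items())
        ]
        table = pd.DataFrame(rows)
    else:
        table = rloop_freqs.copy()
    noise = rng.normal(0.0, noise_sd, size=len(table)) if noise_sd > 0 else 0.0
    table["amplicon_freq"] = np.clip(
        occupancy_scaling * table["rloop_freq"].to_numpy() + noise, 0.0, 1.0
    )
    return table


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
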