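"""Strand-aware base-conversion pileup and PAM-relative edit profiling.

The deaminase acts on the displaced non-target strand (NTS) of the R-loop,
so conversions are reported in an NTS frame with PAM-relative coordinates:
position -1 abuts the PAM, the canonical cytosine-editor window sits around
-19..-13, the target-strand (TS) band around -30..-20, and out-of-
protospacer NTS edits extend to -60 with a ~10.5-bp helical periodicity.
For a site whose protospacer lies on the reference minus strand, positions
mirror and substitutions complement so that the NTS frame always reports
the editor's canonical change (a plus-strand G>A at a minus-strand site is
an NTS C>T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from becaskas.coords import genomic_to_pam_relative, pam_relative_to_genomic
from becaskas.guides import EditorProfile
from becaskas.seq import BASE_INDEX, BASES, complement_base, seq_to_array
from becaskas.simulate import SimRead


@dataclass
class ConversionPileup:
    """Per-position base counts over a set of intervals.

    ``base_counts[chrom]`` is a (length, 4) matrix of observed A/C/G/T counts
    restricted to the piled-up intervals; depth and the 12 substitution-class
    counts derive from it and the reference.
    """

    base_counts: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True where the position was piled up
    reference: dict[str, str]

    def depth(self, chrom: str, pos: int) -> int:
        return int(self.base_counts[chrom][pos].sum())

    def substitution_count(self, chrom: str, pos: int, ref: str, alt: str) -> int:
        if self.reference[chrom][pos] != ref:
            return 0
        return int(self.base_counts[chrom][pos, BASE_INDEX[alt]])

    def frequency(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        d = self.depth(chrom, pos)
        if d == 0:
            return float("nan")
        return self.substitution_count(chrom, pos, ref, alt) / d

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, counts in self.base_counts.items():
            ref = self.reference[chrom]
            for pos in np.flatnonzero(self.mask[chrom]):
                depth = int(counts[pos].sum())
                row = dict(chrom=chrom, pos=int(pos), ref=ref[pos], depth=depth)
                for b in BASES:
                    row[b] = int(counts[pos, BASE_INDEX[b]])
                rows.append(row)
        return pd.DataFrame(rows)


def pileup(
    reads: list[SimRead],
    intervals: pd.DataFrame,
    reference: str | dict[str, str],
) -> ConversionPileup:
    """Tally every aligned base of every read over the given intervals."""
    refs = {"": reference} if isinstance(reference, str) else reference
    if isinstance(reference, str):
        intervals = intervals.copy()
        if "chrom" not in intervals:
            intervals["chrom"] = ""
    base_counts = {c: np.zeros((len(s), 4), dtype=np.int64) for c, s in refs.items()}
    mask = {c: np.zeros(len(s), dtype=bool) for c, s in refs.items()}
    for _, iv in intervals.iterrows():
        chrom = iv.get("chrom", "")
        if chrom not in refs:
            raise ValueError(f"interval contig {chrom!r} not in reference")
        s, e = int(iv["start"]), int(iv["end"])
        if s < 0 or e > len(refs[chrom]):
            raise ValueError(f"interval {chrom}:{s}-{e} outside reference")
        mask[chrom][s:e] = True
    for read in reads:
        chrom = read.chrom if read.chrom in refs else ""
        if chrom not in refs:
            continue
        m = mask[chrom]
        arr = seq_to_array(read.seq)
        g = np.arange(read.start, read.start + len(arr))
        keep = m[g] & (arr < 4)
        if keep.any():
            np.add.at(base_counts[chrom], (g[keep], arr[keep]), 1)
    return ConversionPileup(base_counts=base_counts, mask=mask, reference=refs)


def pam_relative_profile(
    site,
    pile: ConversionPileup,
    editor: EditorProfile,
    upstream: int = 60,
    downstream: int = 10,
) -> pd.DataFrame:
    """Per-position NTS- and TS-frame conversion frequencies for one site.

    ``site`` needs ``chrom``, ``start``, ``end`` (protospacer+PAM interval)
    and ``strand``.  Positions run -upstream..-1 then +1..+downstream.
    Frequencies are NaN where depth is zero.
    """
    chrom = site.chrom if site.chrom in pile.reference else ""
    ref = pile.reference[chrom]
    counts = pile.base_counts[chrom]
    rows = []
    positions = list(range(-upstream, 0)) + list(range(1, downstream + 1))
    for pos in positions:
        g = pam_relative_to_genomic(site.start, site.end, site.strand, pos)
        if not 0 <= g < len(ref):
            continue
        depth = int(counts[g].sum())
        for frame in ("NTS", "TS"):
            if frame == "NTS":
                b_from = editor.base_from if site.strand == "+" else complement_base(editor.base_from)
                b_to = editor.base_to if site.strand == "+" else complement_base(editor.base_to)
            else:
                b_from = complement_base(editor.base_from) if site.strand == "+" else editor.base_from
                b_to = complement_base(editor.base_to) if site.strand == "+" else editor.base_to
            if ref[g] != b_from:
                alt = 0
                freq = np.nan  # not a substrate position in this frame
            else:
                alt = int(counts[g, BASE_INDEX[b_to]])
                freq = alt / depth if depth > 0 else np.nan
            rows.append(
                dict(position=pos, frame=frame, genomic_pos=g, depth=depth,
                     alt=alt, freq=freq)
            )
    return pd.DataFrame(rows)


def call_edits(
    pile: ConversionPileup,
    error_rate: float,
    min_depth: int = 20,
    min_freq: float = 0.02,
    q_threshold: float = 0.05,
    editor: EditorProfile | None = None,
) -> pd.DataFrame:
    """Binomial edit calls against the per-substitution sequencing-error rate.

    Each candidate (position, alt) with depth >= ``min_depth`` is tested
    one-sided against ``error_rate / 3`` (the per-substitution share of a
    uniform error model); BH across all tested candidates.  With an editor
    given, candidates are restricted to its canonical change and the
    complement (the two strand frames); otherwise all 12 classes are tested.
    """
    if not 0 < error_rate < 0.1:
        raise ValueError("error_rate must be in (0, 0.1)")
    allowed: set[tuple[str, str]] | None = None
    if editor is not None:
        allowed = {
            (editor.base_from, editor.base_to),
            (complement_base(editor.base_from), complement_base(editor.base_to)),
        }
    rows = []
    for chrom, counts in pile.base_counts.items():
        ref = pile.reference[chrom]
        for pos in np.flatnonzero(pile.mask[chrom]):
            depth = int(counts[pos].sum())
            if depth < min_depth:
                continue
            rb = ref[pos]
            if rb not in BASE_INDEX:
                continue
            for alt in BASES:
                if alt == rb:
                    continue
                if allowed is not None and (rb, alt) not in allowed:
                    continue
                k = int(counts[pos, BASE_INDEX[alt]])
                rows.append(dict(chrom=chrom, pos=int(pos), ref=rb, alt=alt,
                                 depth=depth, alt_count=k, freq=k / depth))
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "depth", "alt_count",
                     "freq", "p", "q", "called"]
        )
    df = pd.DataFrame(rows)
    df["p"] = stats.binom.sf(df["alt_count"] - 1, df["depth"], error_rate / 3.0)
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df["called"] = (df["q"] < q_threshold) & (df["freq"] >= min_freq)
    return df


def context_spectrum(
    calls: pd.DataFrame,
    reference: str | dict[str, str],
    flank: int = 5,
    strand_col: str | None = None,
) -> dict:
    """Substitution-class table and flank base-frequency matrix around calls.

    Sequences are taken in the NTS frame: calls flagged minus-strand in
    ``strand_col`` are reverse-complemented before tallying, so a G>A at a
    minus-strand site contributes as C>T with its NTS-oriented context.
    """
    from becaskas.seq import SUBSTITUTION_CLASSES, revcomp

    refs = {"": reference} if isinstance(reference, str) else reference
    called = calls[calls["called"]] if "called" in calls else calls
    if called.empty:
        raise ValueError("no calls to summarise")
    class_counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    freq = np.zeros((2 * flank + 1, 4))
    for _, c in called.iterrows():
        chrom = c.get("chrom", "")
        ref = refs.get(chrom, next(iter(refs.values())))
        pos = int(c["pos"])
        rb, ab = c["ref"], c["alt"]
        window = ref[max(0, pos - flank) : pos + flank + 1]
        if len(window) != 2 * flank + 1:
            continue
        if strand_col is not None and c[strand_col] == "-":
            rb, ab = complement_base(rb), complement_base(ab)
            window = revcomp(window)
        class_counts[f"{rb}>{ab}"] += 1
        for off, b in enumerate(window):
            if b in BASE_INDEX:
                freq[off, BASE_INDEX[b]] += 1
    totals = freq.sum(axis=1, keepdims=True)
    freq = np.divide(freq, totals, out=np.zeros_like(freq), where=totals > 0)
    flank_frame = pd.DataFrame(freq, columns=list(BASES))
    flank_frame.index = range(-flank, flank + 1)
    # 5' dinucleotide enrichment at offset -1 relative to uniform background
    five_prime = flank_frame.loc[-1]
    return dict(
        class_counts=pd.Series(class_counts),
        flank_frequencies=flank_frame,
        five_prime_enrichment=(five_prime / 0.25).to_dict(),
    )


def detect_periodicity(
    profile: pd.DataFrame,
    pos_range: tuple[int, int] = (-60, -31),
    max_lag: int = 14,
    min_lag: int = 8,
    threshold: float = 0.3,
) -> dict:
    """Dominant period of out-of-protospacer NTS editing by autocorrelation.

    Mean-subtracted autocorrelation over the position range; the dominant
    period is the lag in [min_lag, max_lag] with the highest normalised
    autocorrelation, reported as significant above ``threshold``.  Local
    maxima of the profile itself are returned as peak offsets.
    """
    lo, hi = pos_range
    nts = profile[(profile["frame"] == "NTS")].set_index("position")
    positions = list(range(lo, hi + 1))
    if len(positions) < 2 * max_lag:
        raise ValueError("position range too short for the requested lags")
    values = np.array([nts["freq"].get(p, np.nan) for p in positions], dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    x = values - values.mean()
    denom = float(np.dot(x, x))
    if np.allclose(values, values.mean()):  # flat profile: no structure
        return dict(period=None, autocorr=0.0, significant=False, maxima=[])
    ac = {lag: float(np.dot(x[:-lag], x[lag:]) / denom) for lag in range(min_lag, max_lag + 1)}
    period = max(ac, key=ac.get)
    maxima = [
        positions[i]
        for i in range(1, len(values) - 1)
        if values[i] > values[i - 1] and values[i] >= values[i + 1] and values[i] > 0
    ]
    significant = ac[period] >= threshold
    return dict(
        period=period if significant else None,
        autocorr=ac[period],
        autocorrelations=ac,
        significant=significant,
        maxima=maxima,
    )


def top_edited_sites(
    profiles: dict[str, pd.DataFrame], n: int = 100
) -> tuple[list[str], pd.DataFrame]:
    """Rank sites by maximum single-position NTS conversion frequency (ties
    by total summed frequency) and return the top-``n`` ids with a
    site x position frequency matrix."""
    scored = []
    for site_id, prof in profiles.items():
        nts = prof[prof["frame"] == "NTS"]
        freqs = nts["freq"].fillna(0.0)
        scored.append((site_id, float(freqs.max()) if len(freqs) else 0.0,
                       float(freqs.sum())))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    top = [s[0] for s in scored[:n]]
    mats = []
    for site_id in top:
        nts = profiles[site_id][profiles[site_id]["frame"] == "NTS"]
        mats.append(nts.set_index("position")["freq"].rename(site_id))
    matrix = pd.concat(mats, axis=1).T if mats else pd.DataFrame()
    return top, matrix


def aggregate_profile(profiles: dict[str, pd.DataFrame], pooled: bool = False) -> pd.DataFrame:
    """Average per-position NTS/TS frequencies across sites.

    ``pooled=False``: unweighted mean of per-site frequencies (each site one
    vote); ``pooled=True``: pooled-read ratio sum(alt)/sum(depth).  Both
    conventions are legitimate; they differ when depths vary across sites.
    """
    stacked = pd.concat(profiles.values(), keys=profiles.keys(), names=["site"])
    grouped = stacked.groupby(["position", "frame"])
    if pooled:
        agg = grouped.apply(
            lambda g: g["alt"].sum() / g["depth"].sum() if g["depth"].sum() > 0 else np.nan,
            include_groups=False,
        ).rename("freq")
    else:
        agg = grouped["freq"].mean().rename("freq")
    return agg.reset_index()


def calls_to_vcf(calls: pd.DataFrame, path, reference_name: str = "synthetic") -> None:
    """Minimal VCF of called edits (CHROM, 1-based POS, REF, ALT; DP/AF in INFO)."""
    called = calls[calls["called"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, c in called.iterrows():
            chrom = c.get("chrom", "") or "chr_sim"
            fh.write(
                f"{chrom}\t{int(c['pos']) + 1}\t.\t{c['ref']}\t{c['alt']}\t.\tPASS\t"
                f"DP={int(c['depth'])};AF={c['freq']:.4f}\n"
            )
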