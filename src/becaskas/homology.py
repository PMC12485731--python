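"""gRNA homology scanning within peaks and PAM-adjacent seed analysis.

An exhaustive ungapped scan of every position and both strands of each peak
(+/- 30 bp flank) scores 20-mers against the protospacer (+2 per match, -3
per mismatch, a standard nucleotide-search scheme) and requires an exact
IUPAC PAM match immediately 3'.  The longest run of consecutive matches
abutting the PAM is the seed match length — the quantity that dominates
R-loop initiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from becaskas.guides import GuideSpec
from becaskas.seq import IUPAC, gc_fraction, revcomp, seq_to_array

MATCH_SCORE = 2
MISMATCH_PENALTY = 3


@dataclass
class HomologyHit:
    peak_id: str
    chrom: str
    start: int  # protospacer+PAM genomic interval, 0-based half-open
    end: int
    strand: str
    score: int
    matches: int
    mismatch_positions: tuple[int, ...]  # PAM-relative, -20..-1
    seed_match_length: int
    protospacer_seq: str  # matched 20-mer, 5'->3' toward the PAM
    pam_seq: str


def _pam_mask(seq_arr: np.ndarray, pattern: str, n_positions: int, proto_len: int) -> np.ndarray:
    """Boolean per candidate start: PAM pattern matches right after the 20-mer."""
    ok = np.ones(n_positions, dtype=bool)
    for j, sym in enumerate(pattern):
        allowed = np.array([b in IUPAC[sym] for b in "ACGT"] + [False], dtype=bool)
        col = seq_arr[proto_len + j : proto_len + j + n_positions]
        idx = np.where(col == 255, 4, col)
        ok &= allowed[idx]
    return ok


def _scan_one_strand(seq: str, guide: GuideSpec) -> list[tuple[int, int, np.ndarray]]:
    """All (offset, matches, per-position match mask) with a valid PAM."""
    proto = seq_to_array(guide.protospacer)
    arr = seq_to_array(seq)
    k = len(proto)
    total = len(arr) - k - len(guide.pam_pattern) + 1
    if total <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)[:total]
    match = windows == proto
    pam_ok = _pam_mask(arr, guide.pam_pattern, total, k)
    hits = []
    for i in np.flatnonzero(pam_ok):
        m = match[i]
        hits.append((int(i), int(m.sum()), m))
    return hits


def _seed_length(match_mask: np.ndarray) -> int:
    n = 0
    for v in match_mask[::-1]:  # PAM-adjacent end last in 5'->3'
        if not v:
            break
        n += 1
    return n


def scan_peaks(
    peaks: pd.DataFrame,
    reference: str | dict[str, str],
    guide: GuideSpec,
    min_score: int = 20,
    flank: int = 30,
) -> list[HomologyHit]:
    """Best gRNA-homology hit per peak (score >= ``min_score``).

    Ties broken by greater seed match length, then leftmost genomic start.
    Peaks outside the reference raise an error naming the peak.
    """
    refs = {"": reference} if isinstance(reference, str) else reference
    k = len(guide.protospacer)
    plen = len(guide.pam_pattern)
    hits: list[HomologyHit] = []
    for _, peak in peaks.iterrows():
        chrom = peak.get("chrom", "")
        ref = refs.get(chrom, refs.get("", next(iter(refs.values()))))
        start, end = int(peak["start"]), int(peak["end"])
        name = str(peak.get("name", f"{chrom}:{start}-{end}"))
        if start < 0 or end > len(ref):
            raise ValueError(f"peak {name} outside reference bounds")
        s0 = max(0, start - flank)
        s1 = min(len(ref), end + flank)
        seq = ref[s0:s1]
        candidates = []
        for i, m, mask in _scan_one_strand(seq, guide):
            candidates.append(("+", s0 + i, m, mask))
        for i, m, mask in _scan_one_strand(revcomp(seq), guide):
            # offset i on the revcomp maps to plus interval end s1 - i
            candidates.append(("-", s1 - i - k - plen, m, mask))
        best = None
        for strand, gstart, m, mask in candidates:
            score = MATCH_SCORE * m - MISMATCH_PENALTY * (k - m)
            if score < min_score:
                continue
            seed = _seed_length(mask)
            key = (-score, -seed, gstart, strand)  # '+' preferred on full tie
            if best is None or key < best[0]:
                best = (key, strand, gstart, m, mask, score, seed)
        if best is None:
            continue
        _, strand, gstart, m, mask, score, seed = best
        gend = gstart + k + plen
        site_seq = ref[gstart:gend]
        if strand == "-":
            site_seq = revcomp(site_seq)
        mm_positions = tuple(int(j - k) for j in np.flatnonzero(~mask))
        hits.append(
            HomologyHit(
                peak_id=name, chrom=chrom, start=gstart, end=gend, strand=strand,
                score=score, matches=m, mismatch_positions=mm_positions,
                seed_match_length=seed, protospacer_seq=site_seq[:k],
                pam_seq=site_seq[k:],
            )
        )
    return hits


def hits_to_frame(hits: list[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                peak_id=h.peak_id, chrom=h.chrom, start=h.start, end=h.end,
                strand=h.strand, score=h.score, matches=h.matches,
                seed_match_length=h.seed_match_length,
                mismatch_positions=",".join(map(str, h.mismatch_positions)),
                protospacer_seq=h.protospacer_seq, pam_seq=h.pam_seq,
            )
            for h in hits
        ]
    )


def build_pwm(hits: list[HomologyHit], pseudocount: float = 0.5) -> pd.DataFrame:
    """20x4 position frequency matrix of hit protospacer sequences
    (5'->3' toward the PAM), pseudocount per base; rows sum to 1."""
    if not hits:
        raise ValueError("need at least one hit to build a PWM")
    k = len(hits[0].protospacer_seq)
    counts = np.full((k, 4), pseudocount)
    index = {b: i for i, b in enumerate("ACGT")}
    for h in hits:
        for j, b in enumerate(h.protospacer_seq):
            counts[j, index[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pwm = pd.DataFrame(freqs, columns=list("ACGT"))
    pwm.index = range(-k, 0)  # PAM-relative positions
    return pwm


def pwm_information_content(pwm: pd.DataFrame) -> pd.Series:
    p = pwm.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.nansum(p * np.log2(p), axis=1)
    return pd.Series(ic, index=pwm.index, name="bits")


def seed_rank_curves(
    sites: pd.DataFrame, thresholds: tuple[int, ...] = (8, 11)
) -> pd.DataFrame:
    """Cumulative counts of edited sites by rank, overall and for sites with
    PAM-adjacent seed matches of at least each threshold length.

    ``sites`` needs ``seed_match_length``, ``edited`` (bool) and a ranking
    column ``rank_score`` (descending).
    """
    df = sites.sort_values("rank_score", ascending=False).reset_index(drop=True)
    out = pd.DataFrame({"rank": np.arange(1, len(df) + 1)})
    out["all"] = df["edited"].astype(int).cumsum()
    for t in thresholds:
        out[f"seed_ge_{t}"] = (
            (df["edited"] & (df["seed_match_length"] >= t)).astype(int).cumsum()
        )
    return out


def _contains_motif(seq: str, motif: str) -> bool:
    """Motif (seed5 + IUPAC PAM) occurrence on either strand."""
    seed, pam = motif[:-3], motif[-3:]
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - len(seed) - 3 + 1):
            if s[i : i + len(seed)] == seed and all(
                b in IUPAC[p] for b, p in zip(s[i + len(seed) : i + len(seed) + 3], pam)
            ):
                return True
    return False


def motif_occurrence(
    peaks: pd.DataFrame,
    reference: str | dict[str, str],
    guide: GuideSpec,
    n_background: int = 1000,
    rng: np.random.Generator | None = None,
    gc_tolerance: float = 0.05,
) -> dict:
    """Occurrence rate of the 5-nt PAM-adjacent seed + PAM in peaks vs a
    GC- and length-matched genomic background, with a two-proportion test.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    refs = {"": reference} if isinstance(reference, str) else reference
    motif = guide.seed5 + guide.pam_pattern

    peak_seqs = []
    for _, p in peaks.iterrows():
        ref = refs.get(p.get("chrom", ""), next(iter(refs.values())))
        peak_seqs.append(ref[int(p["start"]) : int(p["end"])])
    peak_frac = float(np.mean([_contains_motif(s, motif) for s in peak_seqs]))
    peak_gcs = [gc_fraction(s) for s in peak_seqs]
    lengths = [len(s) for s in peak_seqs]

    chroms = list(refs)
    bg_hits = 0
    sampled = 0
    attempts = 0
    max_attempts = 100 * n_background
    while sampled < n_background:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "background sampling failed: could not GC-match enough intervals"
            )
        j = int(rng.integers(0, len(peak_seqs)))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ref = refs[chrom]
        length = lengths[j]
        if len(ref) <= length:
            continue
        start = int(rng.integers(0, len(ref) - length))
        seq = ref[start : start + length]
        if abs(gc_fraction(seq) - peak_gcs[j]) > gc_tolerance:
            continue
        sampled += 1
        if _contains_motif(seq, motif):
            bg_hits += 1
    bg_frac = bg_hits / n_background

    n_peak_hits = int(round(peak_frac * len(peak_seqs)))
    table = np.array(
        [
            [n_peak_hits, len(peak_seqs) - n_peak_hits],
            [bg_hits, n_background - bg_hits],
        ]
    )
    if table[:, 0].sum() in (0, len(peak_seqs) + n_background):
        p_value = 1.0
    else:
        _, p_value, _, _ = stats.chi2_contingency(table, correction=False)
    return dict(
        peak_fraction=peak_frac,
        background_fraction=bg_frac,
        n_peaks=len(peak_seqs),
        n_background=n_background,
        p_value=float(p_value),
        motif=motif,
    )
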