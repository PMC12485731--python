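"""Genome-wide ssDNA signal: 1-kbp binning, replicate/condition correlation,
and sharp-peak calling of pulldown vs input with a local Poisson background.

The peak caller follows the classic local-lambda scheme: sliding windows of
pulldown read starts are tested against a Poisson rate taken as the
depth-ratio-scaled maximum of input rates estimated at 1 kb, 5 kb, 10 kb
around the window and genome-wide, with BH correction across all windows and
merging of nearby significant windows into sharp peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from becaskas.simulate import SimRead


class UnsortedReadsError(ValueError):
    """Raised when an operation requiring coordinate-sorted reads sees
    out-of-order positions; sort the input first."""


class UndefinedCorrelationError(ValueError):
    pass


def _starts_by_contig(reads: list[SimRead], require_sorted: bool = False) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for r in reads:
        out.setdefault(r.chrom, []).append(r.start)
    arrays = {}
    for chrom, starts in out.items():
        arr = np.asarray(starts, dtype=np.int64)
        if require_sorted and np.any(np.diff(arr) < 0):
            raise UnsortedReadsError(
                f"reads on {chrom} are not coordinate-sorted; sort the input first"
            )
        arrays[chrom] = np.sort(arr)
    return arrays


def bin_counts(
    samples: dict[str, list[SimRead]],
    contig_lengths: dict[str, int],
    bin_width: int = 1000,
) -> pd.DataFrame:
    """Contiguous, non-overlapping fixed-width bins of read-start counts.

    Each read is assigned to exactly one bin by its 5' position; the last bin
    of a contig is truncated.  Returns a frame with bin coordinates, one raw
    count column per sample and one depth-normalised (CPM) column per sample.
    """
    if bin_width < 100:
        raise ValueError("bin_width must be >= 100")
    rows = []
    for chrom, length in contig_lengths.items():
        edges = list(range(0, length, bin_width)) + [length]
        for i in range(len(edges) - 1):
            rows.append((chrom, edges[i], edges[i + 1]))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for name, reads in samples.items():
        counts = np.zeros(len(bins), dtype=np.int64)
        offset = 0
        by_contig = _starts_by_contig(reads, require_sorted=True)
        for chrom, length in contig_lengths.items():
            n_bins = (length + bin_width - 1) // bin_width
            starts = by_contig.get(chrom, np.empty(0, dtype=np.int64))
            if np.any(starts < 0) or np.any(starts >= length):
                raise ValueError(f"read start outside contig {chrom}")
            idx = starts // bin_width
            np.add.at(counts, offset + idx, 1)
            offset += n_bins
        bins[name] = counts
        total = counts.sum()
        bins[f"{name}_cpm"] = counts / total * 1e6 if total > 0 else 0.0
    return bins


def correlate(bins: pd.DataFrame, sample_a: str, sample_b: str) -> float:
    """Pearson r of log2(CPM + 1) between two samples on a shared bin grid."""
    x = np.log2(bins[f"{sample_a}_cpm"].to_numpy() + 1.0)
    y = np.log2(bins[f"{sample_b}_cpm"].to_numpy() + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance sample; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class PeakCallParams:
    window: int = 300
    step: int = 50
    merge_distance: int = 100
    local_scales: tuple[int, ...] = (1000, 5000, 10000)
    q_threshold: float = 0.05


def _window_counts(starts: np.ndarray, span_starts: np.ndarray, width: int) -> np.ndarray:
    """Read-start counts in half-open spans [s, s+width)."""
    lo = np.searchsorted(starts, span_starts, side="left")
    hi = np.searchsorted(starts, span_starts + width, side="left")
    return (hi - lo).astype(np.float64)


def call_peaks(
    pulldown: list[SimRead],
    input_reads: list[SimRead],
    contig_lengths: dict[str, int],
    params: PeakCallParams | None = None,
    read_length: int = 100,
) -> pd.DataFrame:
    """Sharp enrichment peaks of pulldown over input ("total" peak calls).

    Returns a narrowPeak-style frame: chrom, start, end, name, score
    (round(-10 log10 q), capped 1000), strand, enrichment, -log10 p,
    -log10 q, summit offset.
    """
    if params is None:
        params = PeakCallParams()
    pd_starts = _starts_by_contig(pulldown)
    in_starts = _starts_by_contig(input_reads)
    total_pd = sum(len(v) for v in pd_starts.values())
    total_in = sum(len(v) for v in in_starts.values())
    genome = sum(contig_lengths.values())
    if total_in == 0:
        warnings.warn(
            "empty input sample: falling back to genome-wide pulldown background"
        )
        depth_ratio = 1.0
    else:
        depth_ratio = total_pd / total_in

    win, step = params.window, params.step
    records = []  # (chrom, win_start, count, lam, p)
    for chrom, length in contig_lengths.items():
        ps = pd_starts.get(chrom, np.empty(0, dtype=np.int64))
        ins = in_starts.get(chrom, np.empty(0, dtype=np.int64))
        win_starts = np.arange(0, max(1, length - win + 1), step, dtype=np.int64)
        counts = _window_counts(ps, win_starts, win)

        if total_in == 0:
            lam = np.full_like(counts, total_pd * win / genome)
        else:
            rates = [np.full_like(counts, total_in * win / genome)]
            for scale in params.local_scales:
                span_starts = win_starts + win // 2 - scale // 2
                c = _window_counts(ins, span_starts, scale)
                rates.append(c * win / scale)
            lam = np.maximum.reduce(rates) * depth_ratio
        lam = np.maximum(lam, 1e-9)
        p = stats.poisson.sf(counts - 1, lam)
        for ws, c, l, pv in zip(win_starts, counts, lam, p):
            records.append((chrom, int(ws), float(c), float(l), float(pv)))

    if not records:
        return _empty_peak_frame()
    df = pd.DataFrame(records, columns=["chrom", "win_start", "count", "lam", "p"])
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    sig = df[df["q"] <= params.q_threshold]
    if sig.empty:
        return _empty_peak_frame()

    peaks = []
    for chrom, group in sig.groupby("chrom", sort=False):
        group = group.sort_values("win_start")
        cov = _coverage(pd_starts.get(chrom, np.empty(0, dtype=np.int64)),
                        contig_lengths[chrom], read_length)
        cur_start = cur_end = None
        members: list[pd.Series] = []
        for _, row in group.iterrows():
            ws, we = row["win_start"], row["win_start"] + win
            if cur_end is None or ws > cur_end + params.merge_distance:
                if members:
                    peaks.append(_emit_peak(chrom, cur_start, cur_end, members, cov))
                cur_start, cur_end, members = ws, we, [row]
            else:
                cur_end = max(cur_end, we)
                members.append(row)
        if members:
            peaks.append(_emit_peak(chrom, cur_start, cur_end, members, cov))

    out = pd.DataFrame(peaks)
    out["name"] = [f"peak_{i:05d}" for i in range(len(out))]
    return out[
        ["chrom", "start", "end", "name", "score", "strand",
         "enrichment", "neg_log10_p", "neg_log10_q", "summit_offset"]
    ]


def _coverage(starts: np.ndarray, length: int, read_length: int) -> np.ndarray:
    diff = np.zeros(length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, np.minimum(starts + read_length, length), -1)
    return np.cumsum(diff[:-1])


def _emit_peak(chrom: str, start: float, end: float, members: list, cov: np.ndarray) -> dict:
    start, end = int(start), int(end)
    best = min(members, key=lambda r: r["p"])
    enrichment = max(float(r["count"]) / float(r["lam"]) for r in members)
    q = max(float(best["q"]), 1e-300)
    p = max(float(best["p"]), 1e-300)
    summit = int(start + np.argmax(cov[start:end]))
    return dict(
        chrom=chrom, start=start, end=end,
        score=min(1000, int(round(-10 * np.log10(q)))),
        strand=".",
        enrichment=enrichment,
        neg_log10_p=-np.log10(p),
        neg_log10_q=-np.log10(q),
        summit_offset=summit - start,
    )


def _empty_peak_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "enrichment", "neg_log10_p", "neg_log10_q", "summit_offset"]
    )


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, p in peaks.iterrows():
            fh.write(
                f"{p['chrom']}\t{p['start']}\t{p['end']}\t{p['name']}\t{p['score']}\t"
                f".\t{p['enrichment']:.4f}\t{p['neg_log10_p']:.4f}\t"
                f"{p['neg_log10_q']:.4f}\t{p['summit_offset']}\n"
            )
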