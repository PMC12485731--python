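"""Differential peak calling: consensus peaks across replicates, then
negative-binomial testing of +gRNA vs -gRNA pulldown counts at FDR < 0.05.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import RESULTS, SIM, ensure_dirs, sam_path

from becaskas import differential
from becaskas.simulate import load_sam

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "enrichment", "neg_log10_p", "neg_log10_q", "summit_offset"]


def main() -> None:
    ensure_dirs()
    peak_sets = [
        pd.read_csv(RESULTS / f"total_peaks_rep{rep}.narrowPeak", sep="\t",
                    header=None, names=NARROWPEAK_COLS)
        for rep in range(SIM.replicates)
    ]
    consensus = differential.consensus_peaks(peak_sets, min_support=2)

    samples = {}
    for grna in ("plus_gRNA", "minus_gRNA"):
        for rep in range(SIM.replicates):
            samples[f"{grna}_rep{rep}"] = load_sam(sam_path("pulldown", grna, rep))
    counts = differential.count_reads_in_intervals(consensus, samples)
    sample_cols = list(samples)
    condition = ["plus_gRNA"] * SIM.replicates + ["minus_gRNA"] * SIM.replicates

    # with only a handful of consensus intervals, normalise on the
    # genome-wide 1-kbp bins rather than on the (signal-laden) peaks
    bins = pd.read_csv(RESULTS / "bins_1kbp.tsv", sep="\t")
    bin_cols = [f"pulldown_{c}" for c in sample_cols]
    sf = differential.size_factors(bins[bin_cols].to_numpy())

    result = differential.test_differential(counts[sample_cols], condition,
                                            fdr=0.05, sample_size_factors=sf)
    table = pd.concat([counts.reset_index(drop=True), result.reset_index(drop=True)], axis=1)
    table.to_csv(RESULTS / "differential_peaks.tsv", sep="\t", index=False)
    sig = table[table["is_differential"]]
    sig[["chrom", "start", "end"]].to_csv(
        RESULTS / "differential_peaks.bed", sep="\t", index=False, header=False)

    print(f"{len(consensus)} consensus peaks (support >= 2 of {SIM.replicates})")
    print(f"{len(sig)} differential peaks at FDR < 0.05 "
          f"(median log2FC {sig['log2fc'].median():.2f})")


if __name__ == "__main__":
    main()
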