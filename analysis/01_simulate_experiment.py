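"""Generate the synthetic base-editor pulldown experiment.

Writes the reference genome and planted-site truth to results/, and the
twelve aligned libraries (pulldown/input x +/- gRNA x 3 replicates) to
scratch/ as coordinate-sorted SAM.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONDITIONS, EDITOR, GUIDE, RESULTS, SCRATCH, SIM, ensure_dirs, sam_path

from becaskas import simulate as sim


def main() -> None:
    ensure_dirs()
    reference = sim.generate_reference(SIM)
    reference, truth = sim.plant_offtargets(reference, GUIDE, SIM, EDITOR)
    sim.write_fasta(reference, SCRATCH / "reference.fa")
    truth.to_bed(RESULTS / "truth_sites.bed")
    truth.to_table().to_csv(RESULTS / "truth_table.tsv", sep="\t", index=False)

    n_total = 0
    for assay, grna in CONDITIONS:
        for rep in range(SIM.replicates):
            reads = sim.simulate_reads(reference, truth, EDITOR, (assay, grna),
                                       SIM, replicate=rep)
            sim.write_sam(reads, reference, sam_path(assay, grna, rep))
            n_total += len(reads)

    print(f"planted {len(truth)} sites (occupancies "
          f"{min(s.occupancy for s in truth):.3f}-{max(s.occupancy for s in truth):.3f}) "
          f"on a {SIM.genome_length/1000:.0f}-kbp genome")
    print(f"wrote {len(CONDITIONS) * SIM.replicates} libraries, {n_total} reads total")
    print(f"truth tables -> {RESULTS}, reads -> {SCRATCH}")


if __name__ == "__main__":
    main()
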