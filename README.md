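# becaskas

Nomination and quantification of CRISPR base-editor off-target sites from
ssDNA pulldown sequencing.

Base editors (a nickase-dead Cas9 fused to a cytosine or adenine deaminase)
edit DNA wherever their gRNA unwinds a target into an R-loop, exposing the
non-target strand (NTS) as single-stranded DNA. Pulling down labelled ssDNA
and sequencing it reads out both *where* the editor forms R-loops and *what*
it edits there — including off-target sites with little gRNA homology that
homology-directed searches miss. This package implements the computational
side of such an experiment for genomics researchers evaluating editor/gRNA
pairs:

- **signal** — 1-kbp binning of ssDNA read counts, replicate/condition
  Pearson correlation on log2(CPM+1), and sharp "total" peak calling of
  pulldown vs input with a local Poisson background
  (λ = depth-scaled max of input rates at 1/5/10 kb and genome-wide).
- **differential** — consensus peaks across replicates and a
  negative-binomial Wald test of +gRNA vs −gRNA pulldown counts
  (median-of-ratios size factors, method-of-moments dispersions shrunk
  halfway in log space toward an α(μ)=a₁/μ+a₀ trend, moderated-t reference,
  BH FDR < 0.05).
- **homology** — exhaustive ungapped protospacer scan within peaks
  (+2/−3 scoring, IUPAC PAM gate), PAM-adjacent seed lengths, position
  frequency matrices, and seed+PAM occurrence tests against GC-matched
  genomic background.
- **edits** — strand-aware conversion pileup and PAM-relative editing
  profiles (position −1 abuts the PAM; NTS/TS frames; minus-strand sites
  mirrored and complemented), binomial edit calling against the sequencing
  error rate, mutational context spectra, and autocorrelation-based
  detection of the ~10.5-bp helical periodicity of out-of-protospacer edits.
- **quantify** — through-origin regression of amplicon on in-R-loop edit
  frequencies (the occupancy scaling), absolute edits per genome
  (Σ site-position frequency × scaling × ploidy), peaks-per-edit, editor
  fold comparisons, and dose-response summaries.
- **annotate** — missense/synonymous/splice/intronic/intergenic
  classification against transcript models, regulatory-interval overlap,
  and a pluggable variant-effect-scorer interface.
- **simulate** — a synthetic-experiment generator with full ground truth:
  planted protospacer-like sites whose occupancy decays geometrically with
  PAM-distal-first mismatches, editor profiles (wide CBE window + TS band +
  periodic out-of-protospacer edits; narrow ABE window), ±gRNA and
  pulldown/input conditions, replicates, dose scaling, sequencing error,
  and paired amplicon tables.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic experiment
(150-kbp genome, 12 planted off-targets, 3 replicates of
pulldown/input × ±gRNA, cytosine-editor profile):

```bash
python analysis/01_simulate_experiment.py
python analysis/02_signal_and_peaks.py
python analysis/03_differential_peaks.py
python analysis/04_homology_scan.py
python analysis/05_edit_profiles.py
python analysis/06_quantify.py
python analysis/07_annotate_sites.py
```

Output from a run of stages 03–06:

```
10 consensus peaks (support >= 2 of 3)
10 differential peaks at FDR < 0.05 (median log2FC 1.26)
10 of 10 differential peaks carry a gRNA homology hit (seed lengths 16-20)
PWM information content: PAM-adjacent 5-mer 1.26 bits vs PAM-distal 0.58 bits per position
seed+PAM motif occurs in 100.0% of peaks vs 9.8% of GC-matched background (p = 1.05e-18)
41 edit calls across 10 sites; most-edited site diff_000 (max NTS frequency 0.61)
occupancy scaling (amplicon/R-loop slope): 0.840 (generating value 0.84)
edits per genome: estimated 11.23 vs ground truth 11.81
10 differential peaks -> 0.9 peaks per edit
```

Reading this: every gRNA-dependent R-loop planted above the detection floor
is recovered by the ±gRNA differential test; their homology hits concentrate
sequence information in the 5-nt PAM-adjacent seed; the most-edited site
converts its best cytosine at 61%; and scaling the in-R-loop frequencies by
the amplicon-derived occupancy (0.84) reconstructs the true absolute editing
burden of the nominated sites to within 5%.

The same machinery is scriptable through the `becaskas` CLI
(`simulate`, `peaks`, `diff`, `homology`, `edits`, `quantify`, `annotate`,
`run`) for SAM/FASTA/BED/TSV inputs.

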