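# Methods

This note documents the models, estimators, defaults and numerical choices
behind becaskas, and what the synthetic-data generator does and does not
emulate.

## The measurement model

A base editor bound at a (partially) protospacer-matched site unwinds an
R-loop, exposing the non-target strand (NTS). Two observables follow:

1. **Unwinding** — pulldown of labelled ssDNA enriches reads over the site
   in proportion to *occupancy* ω ∈ [0,1], the fraction of genomes carrying
   an R-loop there.
2. **Editing** — the deaminase converts bases within strand- and
   position-specific windows. The frequency measured in pulldown reads is
   conditional on an R-loop being present; the absolute (population)
   frequency measured by amplicon sequencing is the conditional frequency
   scaled by occupancy.

Occupancy is therefore the latent variable linking the two assays, and the
through-origin slope of amplicon frequency on in-R-loop frequency estimates
it (quantify.fit_occupancy).

## Synthetic-experiment generator

`simulate` produces a uniform-composition random genome at a configurable
GC fraction, then plants protospacer-like sites:

- **Mismatch placement** is PAM-distal first, so a site with *m* mismatches
  keeps a (20−m)-nt PAM-adjacent seed — the geometry that dominates Cas9
  R-loop initiation.
- **Occupancy** follows ω = ω_max · δ^m (defaults ω_max = 0.8, δ = 0.65).
  The geometric decay is a modelling choice that reproduces the qualitative
  seed-homology behaviour of real off-target surveys; both parameters are
  configuration, not claims.
- **Reads**: background read starts are uniform at `background_depth`
  (default 50 reads/kbp, read length 100 bp). In pulldown/+gRNA the start
  density of reads overlapping a site is multiplied by
  1 + `enrichment_factor`·ω·dose (default enrichment 20). Overlapping reads
  are drawn from the full overlap-compatible span because coverage inside a
  pulled-down region comes from fragments spanning it.
- **Editing**: in any +gRNA condition (pulldown *and* input — the genome is
  edited regardless of which library is sequenced), each read overlapping a
  site derives from an R-loop-bearing genome with probability ω·dose;
  such reads convert each covered window position independently with the
  site's per-position truth probability. Conversions are defined on the NTS
  and complemented on the plus strand as the site's strand requires.
- **Sequencing error** is uniform per base (default 0.002), substituting a
  uniformly random different base.
- Reads are emitted pre-aligned (single-end, forward flag, all-match CIGAR,
  consistent MD/NM) as coordinate-sorted SAM; alignment is out of scope.

**Editor profiles.** The bundled cytosine profile (CBE-eBE) has NTS C→T
probabilities peaking at −19…−13 (values at −18/−16/−13 match a
well-characterised on-target site: 0.683/0.783/0.644), a target-strand C→T
band at −30…−20 (seen as G>A in plus-strand coordinates at plus-strand
sites), a 5′TC context multiplier (the hA3A deaminase preference), and a
damped cosine of period 10.5 bp over NTS −60…−31 phased so local maxima
fall near −38/−49/−60 — one helical turn apart. The adenine profile (ABE8e)
confines NTS A→G to −18…−13 (target adenine at −17 converting at 0.70) with
no TS or periodic terms. ABE8e-SpRY differs only in its NRN PAM.

**What the generator does not emulate**: non-uniform genomic background
(replication/transcription ssDNA, mappability), PCR duplicates, paired-end
fragments, transfected-plasmid contaminant reads, indels, and bulged
protospacer binding. Consequently replicate bin correlations on synthetic
data concentrate entirely in enriched bins (a uniform background is pure
Poisson noise), and passing tests demonstrate estimator correctness under
the stated model, not robustness to real-genome artefacts.

## Peak calling (total calls)

Sliding windows (300 bp, step 50 bp) of pulldown read starts are tested
one-sided against Poisson λ_local = depth-ratio × max of input rates
estimated at 1 kb, 5 kb, 10 kb around the window and genome-wide; BH
correction across all windows; windows with q ≤ 0.05 within 100 bp are
merged and the summit is the maximum-coverage position. Constants are
exposed in `PeakCallParams`. An empty input sample falls back to the
genome-wide pulldown rate with a warning. The max-of-scales background makes
the null conservative by construction (window fractions below α stay below
α), which is the intended operating character for sharp-peak nomination.

## Differential calling (±gRNA)

Consensus intervals are overlap-merged peaks supported by ≥ 2 replicates
(of 3). Counts per interval are modelled as NB with mean sf·μ and
dispersion α:

- **Size factors**: median-of-ratios over all-positive intervals, rescaled
  to geometric mean 1; falls back to total-count ratios (with a warning)
  when no interval qualifies. For *small* consensus sets, where most
  intervals respond to treatment, factors should be supplied from a
  genome-wide background (the 1-kbp bin matrix) via `sample_size_factors` —
  otherwise normalisation absorbs the signal.
- **Dispersion**: pooled within-condition method-of-moments
  α̂ = Σ(df_c·(s²_c − μ̂_c)) / Σ(df_c·μ̂_c²), floored at one tenth of the
  fitted trend α(μ) = a₁/μ + a₀ (least squares on usable gene-wise points)
  so the estimator is continuous through zero sample overdispersion, then
  shrunk halfway toward the trend in log space.
- **Test**: Wald statistic log2FC/SE with the delta-method SE from the NB
  variance, referred to a **moderated t with df = 2(n₁+n₂−2)**. The t
  reference is the limma-style analogue of the equal-weight shrink (a prior
  as informative as the residual df); a plain normal reference is
  anti-conservative at 3 vs 3 (empirical FDP ≈ 0.075 at the q<0.05 cutoff
  on an NB simulation with dispersion 0.1), while the moderated t holds the
  false-discovery proportion near 0.01 there and loses little power on
  Poisson-dispersed data, which is what the read simulator produces.
  Differential peaks are intervals with q < 0.05 *and* positive fold change
  (gRNA-dependent R-loops gain signal; one-sided by design).

## Homology scan

Every offset and both strands of each peak (±30 bp flank) are scored
ungapped against the protospacer (+2 match / −3 mismatch — the standard
nucleotide-search scheme standing in for local-alignment bitscores), gated
on an exact IUPAC PAM match. Best hit per peak; ties break by longer
PAM-adjacent seed, then leftmost start, then plus strand. The seed length
is the run of consecutive matches starting at −1. PWMs use pseudocount 0.5
per base. The seed+PAM occurrence test samples background intervals
length-matched to a random peak and accepted when within ±0.05 GC of it,
and compares proportions by a χ² test without continuity correction.
Bulged/gapped binding and genome-wide (non-peak) scanning are out of scope.

## Edit profiling and calling

The pileup tallies every aligned base over requested intervals. Profiles
map genomic positions to PAM-relative coordinates covering −60…−1 and the
PAM (+1…+10 available); at minus-strand sites positions mirror and
substitutions complement so the NTS frame always reports the editor's
canonical change. Positions whose reference base is not the frame's
substrate are reported as missing, not zero. Aggregates are emitted in both
conventions — unweighted mean of per-site frequencies and pooled
Σalt/Σdepth — because the two differ when depth varies across sites.

Edit calls test alt counts one-sided against error_rate/3 (the
per-substitution share of a uniform error model), BH-corrected, with
declared defaults min_depth 20, min_freq 0.02, q < 0.05; with an editor
specified, candidate classes are its canonical change and the complement.

Periodicity: mean-subtracted autocorrelation of the NTS profile over
−60…−31; dominant period is the argmax lag in [8,14], reported when the
normalised autocorrelation exceeds 0.3; profile local maxima are returned
alongside. A numerically flat profile short-circuits to "no structure".

Top-site ranking uses the maximum single-position NTS frequency, ties by
summed frequency, then site id.

## Quantification

edits_per_genome = Σ_sites Σ_called-positions freq × scaling × ploidy, with
ploidy defaulting to 2 (the per-genome convention is exposed because
published totals do not state whether both alleles are summed);
peaks_per_edit divides the differential-peak count by it. Fold comparisons
round to 3 significant figures. Dose-response folds are
highest-dose/lowest-dose per metric, with metrics at fold ≤ 1.2 flagged
flat.

## Annotation

CDS edits are translated in transcript frame (strand-aware codon
extraction, standard code); splice donor/acceptor categories use the
canonical 2-bp intronic windows at internal exon boundaries; otherwise
intronic within a transcript span, else intergenic. The first overlapping
transcript is primary; all overlaps are retained. Regulatory overlap is
half-open interval intersection (≥1 bp). Deep-learning effect prediction is
deliberately excluded; `score_variants` defines the contract —
scorer(reference window, edited window) → scalar, log2-fold-change
convention — so an external model can be plugged in.

## Problem sizes and determinism

The bundled analysis uses a 150-kbp genome, 12 sites, 3 replicates at
50 reads/kbp; recovery tests use single sites covered at ~3,000× and a
36-kbp, 50-site genome at ~500×; the differential calibration study uses
20,000 NB intervals. These sizes give every estimator the depth its
variance analysis assumes while keeping each script and the test suite in
the minutes range. All randomness flows through numpy Generators seeded
from explicit configuration; identical configuration and seed reproduce
byte-identical outputs.

## Known limitations

- The NB caller supports only the two-condition contrast; no covariates.
- Exact invariance of Wald statistics to rescaling one sample's counts is
  impossible under geometric-mean-1 size factors (all normalised counts
  scale by c^(1/n), perturbing moment dispersions ~1%); log2FC is exactly
  invariant.
- The motif test conditions only on GC and length, not on higher-order
  composition.
- Multi-hit peaks report their best homology hit only.
- `edits_per_genome` inherits the call thresholds: sub-threshold positions
  (e.g. weak periodic out-of-protospacer edits) are excluded from the
  estimate, biasing it slightly below truth at low depth.
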