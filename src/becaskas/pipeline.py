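"""End-to-end orchestration of the two nomination strategies.

Runs a (synthetic or precomputed) experiment through signal -> differential
-> homology -> edits -> quantify -> annotate, writing stage outputs and a
manifest with parameters, seeds and content digests.  Pure in-process
orchestration, no workflow engine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from becaskas import differential, edits, homology, quantify, signal, simulate
from becaskas.guides import GuideSpec, default_editor, HEK4_PROTOSPACER

logger = logging.getLogger("becaskas")


@dataclasses.dataclass
class RunConfig:
    outdir: str = "becaskas_run"
    protospacer: str = HEK4_PROTOSPACER
    pam_pattern: str = "NGG"
    editor: str = "CBE-eBE"
    peak_q: float = 0.05
    differential_fdr: float = 0.05
    homology_min_score: int = 20
    edit_min_depth: int = 20
    edit_min_freq: float = 0.02
    amplicon_scaling: float = 0.66
    ploidy: int = 2
    rng_seed: int = 0
    sim: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if not 0 < cfg.differential_fdr < 1:
            raise ValueError("differential_fdr must be in (0,1)")
        return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a synthetic experiment; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage simulate: generating synthetic experiment")

    sim_cfg = simulate.SimConfig(rng_seed=config.rng_seed, **config.sim)
    guide = GuideSpec(config.protospacer, config.pam_pattern)
    editor = default_editor(config.editor)

    reference = simulate.generate_reference(sim_cfg)
    reference, truth = simulate.plant_offtargets(reference, guide, sim_cfg, editor)
    simulate.write_fasta(reference, out / "reference.fa")
    truth.to_bed(out / "truth_sites.bed")
    truth.to_table().to_csv(out / "truth_table.tsv", sep="\t", index=False)

    contigs = {simulate.DEFAULT_CHROM: len(reference)}
    samples: dict[str, list] = {}
    for rep in range(sim_cfg.replicates):
        for assay in ("pulldown", "input"):
            for grna in ("plus_gRNA", "minus_gRNA"):
                name = f"{assay}_{grna}_rep{rep}"
                reads = simulate.simulate_reads(
                    reference, truth, editor, (assay, grna), sim_cfg, replicate=rep
                )
                samples[name] = reads
                simulate.write_sam(reads, reference, out / f"{name}.sam")

    logger.info("stage signal: binning and total peak calling")
    bins = signal.bin_counts(samples, contigs)
    bins.to_csv(out / "bins.tsv", sep="\t", index=False)
    rep_r = signal.correlate(bins, "pulldown_plus_gRNA_rep0", "pulldown_plus_gRNA_rep1")

    peak_sets = []
    for rep in range(sim_cfg.replicates):
        peaks = signal.call_peaks(
            samples[f"pulldown_plus_gRNA_rep{rep}"],
            samples[f"input_plus_gRNA_rep{rep}"],
            contigs,
            signal.PeakCallParams(q_threshold=config.peak_q),
            read_length=sim_cfg.read_length,
        )
        signal.write_narrowpeak(peaks, out / f"total_peaks_rep{rep}.narrowPeak")
        peak_sets.append(peaks)

    logger.info("stage differential: consensus + NB testing")
    consensus = differential.consensus_peaks(peak_sets, min_support=2)
    plus = {f"plus_{r}": samples[f"pulldown_plus_gRNA_rep{r}"] for r in range(sim_cfg.replicates)}
    minus = {f"minus_{r}": samples[f"pulldown_minus_gRNA_rep{r}"] for r in range(sim_cfg.replicates)}
    count_table = differential.count_reads_in_intervals(consensus, {**plus, **minus})
    sample_cols = list(plus) + list(minus)
    condition = ["plus_gRNA"] * len(plus) + ["minus_gRNA"] * len(minus)
    if len(consensus) >= 1:
        diff = differential.test_differential(
            count_table[sample_cols], condition, fdr=config.differential_fdr
        )
        diff = pd.concat([consensus.reset_index(drop=True), diff.reset_index(drop=True)], axis=1)
    else:
        diff = pd.DataFrame()
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    differential_peaks = diff[diff.get("is_differential", pd.Series(dtype=bool))] if len(diff) else diff

    logger.info("stage homology: gRNA scan within consensus peaks")
    scan_input = consensus.assign(name=[f"cons_{i}" for i in range(len(consensus))])
    hits = homology.scan_peaks(scan_input, reference, guide,
                               min_score=config.homology_min_score)
    homology.hits_to_frame(hits).to_csv(out / "homology_hits.tsv", sep="\t", index=False)
    if hits:
        homology.build_pwm(hits).to_csv(out / "pwm.tsv", sep="\t")

    logger.info("stage edits: pileup and profiles over hits")
    pooled_reads = []
    for rep in range(sim_cfg.replicates):
        pooled_reads.extend(samples[f"pulldown_plus_gRNA_rep{rep}"])
    profiles = {}
    call_frames = []
    for hit in hits:
        iv = pd.DataFrame([dict(chrom=hit.chrom, start=max(0, hit.start - 80),
                                end=min(len(reference), hit.end + 20))])
        pile = edits.pileup(pooled_reads, iv, {simulate.DEFAULT_CHROM: reference})
        profiles[hit.peak_id] = edits.pam_relative_profile(hit, pile, editor)
        calls = edits.call_edits(pile, sim_cfg.sequencing_error,
                                 min_depth=config.edit_min_depth,
                                 min_freq=config.edit_min_freq, editor=editor)
        calls["site_id"] = hit.peak_id
        call_frames.append(calls)
    all_calls = pd.concat(call_frames, ignore_index=True) if call_frames else pd.DataFrame()
    if len(all_calls):
        all_calls.to_csv(out / "edit_calls.tsv", sep="\t", index=False)
        edits.calls_to_vcf(all_calls, out / "edit_calls.vcf")

    logger.info("stage quantify: occupancy fit and edits per genome")
    rng = __import__("numpy").random.default_rng([config.rng_seed, 99])
    amplicon = simulate.simulate_amplicon_table(truth, config.amplicon_scaling,
                                                noise_sd=0.02, rng=rng)
    fit = quantify.fit_occupancy(amplicon)
    called = all_calls[all_calls["called"]] if len(all_calls) else pd.DataFrame(columns=["freq"])
    quant = quantify.edits_per_genome(called, fit.scaling, ploidy=config.ploidy,
                                      n_differential_peaks=len(differential_peaks))
    summary = dict(
        replicate_pearson_r=rep_r,
        n_total_peaks=[len(p) for p in peak_sets],
        n_consensus=len(consensus),
        n_differential_peaks=int(len(differential_peaks)),
        n_homology_hits=len(hits),
        n_edit_calls=int(called["freq"].count()) if len(called) else 0,
        occupancy_scaling=fit.scaling,
        edits_per_genome=quant.edits_per_genome,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = dict(
        parameters=dataclasses.asdict(config),
        sim_config=simulate.config_to_dict(sim_cfg),
        outputs={p.name: _digest(p) for p in sorted(out.iterdir()) if p.is_file()
                 and p.name != "manifest.json"},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
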