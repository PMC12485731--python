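"""Shared configuration for the numbered analysis drivers.

The synthetic experiment mirrors the structure of the HEK4-gRNA cytosine
base-editor study: a 150-kbp genome, twelve planted off-target sites whose
R-loop occupancy decays with PAM-distal mismatch load, pulldown/input
libraries with and without gRNA in triplicate at ~50 reads/kbp background.
Reads (large) go under scratch/; tables under results/.
"""

from pathlib import Path

from becaskas.guides import GuideSpec, HEK4_PROTOSPACER, default_editor
from becaskas.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"

SEED = 20_240_901

GUIDE = GuideSpec(HEK4_PROTOSPACER)
EDITOR = default_editor("CBE-eBE")

SIM = SimConfig(
    genome_length=150_000,
    gc_fraction=0.45,
    n_offtargets=12,
    mismatch_distribution={0: 1, 1: 2, 2: 3, 3: 3, 4: 2, 6: 1},
    read_length=100,
    background_depth=50.0,
    enrichment_factor=20.0,
    sequencing_error=0.002,
    replicates=3,
    occupancy_max=0.8,
    occupancy_decay=0.65,
    rng_seed=SEED,
)

CONDITIONS = [(assay, grna) for assay in ("pulldown", "input")
              for grna in ("plus_gRNA", "minus_gRNA")]


def sam_path(assay: str, grna: str, rep: int) -> Path:
    return SCRATCH / f"{assay}_{grna}_rep{rep}.sam"


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
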