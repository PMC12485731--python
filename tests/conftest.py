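import numpy as np
import pandas as pd
import pytest

from becaskas import simulate as sim
from becaskas.guides import GuideSpec, HEK4_PROTOSPACER, default_editor


@pytest.fixture(scope="session")
def hek4() -> GuideSpec:
    return GuideSpec(HEK4_PROTOSPACER)


@pytest.fixture(scope="session")
def cbe():
    return default_editor("CBE-eBE")


@pytest.fixture(scope="session")
def abe():
    return default_editor("ABE8e")


@pytest.fixture(scope="session")
def small_experiment(hek4, cbe):
    """A modest planted experiment shared across signal/homology tests."""
    cfg = sim.SimConfig(
        genome_length=100_000,
        n_offtargets=5,
        mismatch_distribution={0: 1, 1: 1, 2: 2, 3: 1},
        background_depth=50.0,
        enrichment_factor=20.0,
        rng_seed=3,
    )
    reference = sim.generate_reference(cfg)
    reference, truth = sim.plant_offtargets(reference, hek4, cfg, cbe)
    pulldown = sim.simulate_reads(reference, truth, cbe, ("pulldown", "plus_gRNA"), cfg)
    input_reads = sim.simulate_reads(reference, truth, cbe, ("input", "plus_gRNA"), cfg)
    return dict(cfg=cfg, reference=reference, truth=truth,
                pulldown=pulldown, input=input_reads)


@pytest.fixture(scope="session")
def deep_on_target(hek4):
    """Single on-target site at occupancy 1 with explicit conversion truths,
    covered at ~3000x — the parameter-recovery workhorse."""
    from becaskas.guides import EditorProfile

    editor = EditorProfile(
        name="CBE-printed", base_from="C", base_to="T",
        nts_window={-18: 0.683, -16: 0.783, -13: 0.644},
    )
    cfg = sim.SimConfig(
        genome_length=5000, n_offtargets=1, mismatch_distribution={0: 1},
        background_depth=30_000.0, enrichment_factor=0.0,
        occupancy_max=1.0, sequencing_error=0.002, rng_seed=11,
    )
    reference = sim.generate_reference(cfg)
    reference, truth = sim.plant_offtargets(reference, hek4, cfg, editor)
    reads = sim.simulate_reads(reference, truth, editor, ("pulldown", "plus_gRNA"), cfg)
    return dict(cfg=cfg, reference=reference, truth=truth, reads=reads, editor=editor)


def nb_counts(rng, mean, dispersion, size=None):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


@pytest.fixture(scope="session")
def site_interval():
    def make(site, reference, pad_left=80, pad_right=20):
        return pd.DataFrame([dict(
            chrom=site.chrom,
            start=max(0, site.start - pad_left),
            end=min(len(reference), site.end + pad_right),
        )])

    return make
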