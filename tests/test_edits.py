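"""Pileup, PAM-relative profiling, edit calling, spectra and periodicity."""

import numpy as np
import pandas as pd
import pytest

from becaskas import edits
from becaskas import simulate as sim
from becaskas.coords import pam_relative_to_genomic
from becaskas.guides import EditorProfile
from becaskas.seq import revcomp
from becaskas.simulate import SimRead


class TestPileup:
    def test_uniform_conversion(self):
        ref = "A" * 10 + "C" + "A" * 10
        reads = [SimRead(f"r{i}", "", 5, "AAAAATAAAAA") for i in range(100)]
        pile = edits.pileup(reads, pd.DataFrame([dict(start=0, end=21)]), ref)
        assert pile.substitution_count("", 10, "C", "T") == 100
        assert pile.frequency("", 10, "C", "T") == 1.0

    def test_no_reads_reports_missing(self):
        ref = "ACGT" * 10
        pile = edits.pileup([], pd.DataFrame([dict(start=0, end=40)]), ref)
        assert pile.depth("", 5) == 0
        assert np.isnan(pile.frequency("", 5, "C", "T"))

    def test_matches_per_read_recount(self, small_experiment):
        """Oracle: brute-force per-read, per-base tally."""
        reference = small_experiment["reference"]
        reads = small_experiment["pulldown"][:3000]
        iv = pd.DataFrame([dict(chrom="chr_sim", start=20_000, end=21_000)])
        pile = edits.pileup(reads, iv, {"chr_sim": reference})
        oracle = {}
        for r in reads:
            for off, base in enumerate(r.seq):
                g = r.start + off
                if 20_000 <= g < 21_000:
                    oracle.setdefault(g, {"A": 0, "C": 0, "G": 0, "T": 0})
                    oracle[g][base] += 1
        for g, counts in oracle.items():
            for b, n in counts.items():
                assert pile.base_counts["chr_sim"][g, "ACGT".index(b)] == n
        total = sum(sum(c.values()) for c in oracle.values())
        assert pile.base_counts["chr_sim"][20_000:21_000].sum() == total


class TestPamRelativeProfile:
    def test_plus_strand_coordinate_map(self, deep_on_target):
        site = deep_on_target["truth"].sites[0]
        iv = pd.DataFrame([dict(chrom=site.chrom, start=site.start - 80,
                                end=site.end + 20)])
        pile = edits.pileup(deep_on_target["reads"], iv,
                            {site.chrom: deep_on_target["reference"]})
        prof = edits.pam_relative_profile(site, pile, deep_on_target["editor"])
        nts = prof[prof["frame"] == "NTS"].set_index("position")
        for pos, truth in site.true_conversion.items():
            depth = nts.loc[pos, "depth"]
            sd = np.sqrt(truth * (1 - truth) / depth)
            assert abs(nts.loc[pos, "freq"] - truth) <= 3 * sd

    def test_mirrored_simulation_gives_identical_profile(self, deep_on_target):
        """Reverse-complement invariance, exact on counts: mirroring the
        reference, site and every read leaves the NTS-frame profile equal."""
        site = deep_on_target["truth"].sites[0]
        ref = deep_on_target["reference"]
        editor = deep_on_target["editor"]
        L = len(ref)
        mirrored_ref = revcomp(ref)
        mirrored_site = sim.TruthSite(
            site_id=site.site_id, chrom=site.chrom,
            start=L - site.end, end=L - site.start,
            strand="-" if site.strand == "+" else "+",
            mismatch_count=site.mismatch_count,
            seed_match_length=site.seed_match_length,
            occupancy=site.occupancy,
        )
        mirrored_reads = [
            SimRead(r.name, r.chrom, L - (r.start + len(r.seq)), revcomp(r.seq))
            for r in deep_on_target["reads"]
        ]

        def profile(reads, reference, s):
            iv = pd.DataFrame([dict(chrom=s.chrom, start=max(0, s.start - 80),
                                    end=min(len(reference), s.end + 80))])
            pile = edits.pileup(reads, iv, {s.chrom: reference})
            return edits.pam_relative_profile(s, pile, editor)

        a = profile(deep_on_target["reads"], ref, site)
        b = profile(mirrored_reads, mirrored_ref, mirrored_site)
        merged = a.merge(b, on=["position", "frame"], suffixes=("_fwd", "_rc"))
        assert (merged["depth_fwd"] == merged["depth_rc"]).all()
        assert (merged["alt_fwd"] == merged["alt_rc"]).all()

    def test_abe_has_no_ts_edits(self, hek4, abe):
        cfg = sim.SimConfig(genome_length=4000, n_offtargets=1,
                            mismatch_distribution={0: 1}, occupancy_max=1.0,
                            background_depth=20_000.0, enrichment_factor=0.0,
                            sequencing_error=0.0, rng_seed=6)
        ref = sim.generate_reference(cfg)
        ref, truth = sim.plant_offtargets(ref, hek4, cfg, abe)
        site = truth.sites[0]
        reads = sim.simulate_reads(ref, truth, abe, ("pulldown", "plus_gRNA"), cfg)
        iv = pd.DataFrame([dict(chrom=site.chrom, start=site.start - 80,
                                end=site.end + 20)])
        pile = edits.pileup(reads, iv, {site.chrom: ref})
        prof = edits.pam_relative_profile(site, pile, abe)
        ts = prof[(prof["frame"] == "TS") & prof["freq"].notna()]
        assert (ts["freq"] == 0).all()


class TestCallEdits:
    def make_pile(self, depth, alt, ref="A" * 10 + "C" + "A" * 10, pos=10, alt_base="T"):
        counts = np.zeros((len(ref), 4), dtype=np.int64)
        for g, b in enumerate(ref):
            counts[g, "ACGT".index(b)] = depth
        counts[pos, "ACGT".index(ref[pos])] = depth - alt
        counts[pos, "ACGT".index(alt_base)] = alt
        mask = np.ones(len(ref), dtype=bool)
        return edits.ConversionPileup({"": counts}, {"": mask}, {"": ref})

    def test_overwhelming_signal_called(self):
        calls = edits.call_edits(self.make_pile(1000, 300), 0.01)
        hit = calls[(calls["pos"] == 10) & (calls["alt"] == "T")]
        assert hit["called"].item()

    def test_below_min_depth_never_called(self):
        calls = edits.call_edits(self.make_pile(10, 9), 0.01, min_depth=20)
        assert not ((calls.get("pos") == 10) & calls.get("called", pd.Series(dtype=bool))).any()

    def test_null_calibration(self):
        """At pure sequencing error, essentially nothing is called."""
        rng = np.random.default_rng(23)
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        counts = np.zeros((2000, 4), dtype=np.int64)
        err = 0.005
        for g, b in enumerate(ref):
            depth = 500
            n_err = rng.binomial(depth, err)
            counts[g, "ACGT".index(b)] = depth - n_err
            for _ in range(n_err):
                alts = [x for x in "ACGT" if x != b]
                counts[g, "ACGT".index(alts[int(rng.integers(0, 3))])] += 1
        pile = edits.ConversionPileup({"": counts}, {"": np.ones(2000, bool)}, {"": ref})
        calls = edits.call_edits(pile, err)
        assert calls["called"].mean() <= 0.0025

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            edits.call_edits(self.make_pile(100, 10), 0.5)


class TestContextSpectrum:
    def test_tc_context_fraction(self):
        ref = "GGTCGG" + "AATCAA" * 5
        calls = pd.DataFrame([
            dict(chrom="", pos=p, ref="C", alt="T", called=True)
            for p in [3, 9, 15, 21, 27, 33]
        ])
        out = edits.context_spectrum(calls, ref, flank=2)
        assert out["class_counts"]["C>T"] == 6
        assert out["flank_frequencies"].loc[-1, "T"] == 1.0
        assert np.allclose(out["flank_frequencies"].sum(axis=1), 1.0, atol=1e-9)

    def test_cbe_simulation_enriches_five_prime_t(self, hek4, cbe):
        cfg = sim.SimConfig(genome_length=5000, n_offtargets=1,
                            mismatch_distribution={0: 1}, occupancy_max=1.0,
                            background_depth=20_000.0, enrichment_factor=0.0,
                            sequencing_error=0.001, rng_seed=25)
        ref = sim.generate_reference(cfg)
        ref, truth = sim.plant_offtargets(ref, hek4, cfg, cbe)
        site = truth.sites[0]
        reads = sim.simulate_reads(ref, truth, cbe, ("pulldown", "plus_gRNA"), cfg)
        iv = pd.DataFrame([dict(chrom=site.chrom, start=site.start - 80,
                                end=site.end + 20)])
        pile = edits.pileup(reads, iv, {site.chrom: ref})
        calls = edits.call_edits(pile, 0.001, editor=cbe)
        out = edits.context_spectrum(calls, {site.chrom: ref})
        assert out["class_counts"]["C>T"] + out["class_counts"]["G>A"] > 0
        assert np.allclose(out["flank_frequencies"].sum(axis=1), 1.0, atol=1e-9)


class TestPeriodicity:
    def test_synthetic_cosine_recovered(self):
        rng = np.random.default_rng(26)
        positions = list(range(-60, -30))
        amp = 0.05
        freq = [amp * (1 + np.cos(2 * np.pi * (-p - 38) / 10.5)) / 2
                + rng.normal(0, 0.1 * amp) for p in positions]
        prof = pd.DataFrame(dict(position=positions, frame="NTS",
                                 freq=np.clip(freq, 0, 1)))
        out = edits.detect_periodicity(prof)
        assert out["period"] in (10, 11)

    def test_flat_profile_not_significant(self):
        prof = pd.DataFrame(dict(position=range(-60, -30), frame="NTS", freq=0.02))
        out = edits.detect_periodicity(prof)
        assert out["period"] is None

    def test_short_range_raises(self):
        prof = pd.DataFrame(dict(position=range(-40, -30), frame="NTS", freq=0.02))
        with pytest.raises(ValueError):
            edits.detect_periodicity(prof, pos_range=(-40, -31))

    def test_cbe_default_maxima_near_helical_positions(self, hek4, cbe):
        cfg = sim.SimConfig(genome_length=6000, n_offtargets=1,
                            mismatch_distribution={0: 1}, occupancy_max=1.0,
                            background_depth=20_000.0, enrichment_factor=0.0,
                            sequencing_error=0.001, rng_seed=4)
        ref = sim.generate_reference(cfg)
        ref, truth = sim.plant_offtargets(ref, hek4, cfg, cbe)
        site = truth.sites[0]
        reads = sim.simulate_reads(ref, truth, cbe, ("pulldown", "plus_gRNA"), cfg)
        iv = pd.DataFrame([dict(chrom=site.chrom, start=site.start - 80,
                                end=site.end + 20)])
        pile = edits.pileup(reads, iv, {site.chrom: ref})
        prof = edits.pam_relative_profile(site, pile, cbe)
        out = edits.detect_periodicity(prof)
        for target in (-38, -49, -60):
            assert any(abs(m - target) <= 2 for m in out["maxima"]), target


class TestTopSites:
    def make_profile(self, max_freq):
        return pd.DataFrame(dict(position=[-16, -13], frame="NTS",
                                 depth=[100, 100], alt=[0, 0],
                                 freq=[max_freq, max_freq / 2]))

    def test_ranking_by_max_frequency(self):
        profiles = {"lo": self.make_profile(0.5), "hi": self.make_profile(0.8)}
        top, matrix = edits.top_edited_sites(profiles)
        assert top == ["hi", "lo"]
        assert matrix.loc["hi", -16] == 0.8

    def test_n_clamped_to_site_count(self):
        profiles = {"a": self.make_profile(0.1)}
        top, _ = edits.top_edited_sites(profiles, n=100)
        assert top == ["a"]


class TestAggregation:
    def test_pooled_ratio_matches_recount(self):
        """Pooled aggregate equals sum(alt)/sum(depth) recomputed by hand."""
        p1 = pd.DataFrame(dict(position=[-16], frame=["NTS"], depth=[100], alt=[50],
                               freq=[0.5]))
        p2 = pd.DataFrame(dict(position=[-16], frame=["NTS"], depth=[300], alt=[30],
                               freq=[0.1]))
        pooled = edits.aggregate_profile({"a": p1, "b": p2}, pooled=True)
        assert pooled["freq"].item() == pytest.approx(80 / 400)
        mean = edits.aggregate_profile({"a": p1, "b": p2}, pooled=False)
        assert mean["freq"].item() == pytest.approx(0.3)
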