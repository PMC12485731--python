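"""gRNA homology scanning, PWM construction, seed curves and motif rates."""

import numpy as np
import pandas as pd
import pytest

from becaskas import homology
from becaskas.guides import GuideSpec
from becaskas.seq import IUPAC, revcomp


def naive_best_hit(peak_seq, guide, s0, min_score):
    """Independent all-windows scorer (pure python, no shared code paths)."""
    k = 20
    best = None
    for strand in ("+", "-"):
        seq = peak_seq if strand == "+" else revcomp(peak_seq)
        for i in range(len(seq) - k - 2):
            window = seq[i : i + k]
            pam = seq[i + k : i + k + 3]
            if any(b not in "ACGT" for b in window + pam):
                continue
            if not all(b in IUPAC[p] for b, p in zip(pam, guide.pam_pattern)):
                continue
            m = sum(a == b for a, b in zip(window, guide.protospacer))
            score = 2 * m - 3 * (k - m)
            if score < min_score:
                continue
            seed = 0
            for a, b in zip(reversed(window), reversed(guide.protospacer)):
                if a != b:
                    break
                seed += 1
            gstart = s0 + i if strand == "+" else s0 + len(peak_seq) - i - k - 3
            key = (-score, -seed, gstart, strand)
            if best is None or key < best[0]:
                best = (key, strand, gstart, score, seed)
    return best


class TestScanPeaks:
    def test_perfect_hit_scores_forty(self, hek4):
        ref = "T" * 50 + hek4.protospacer + "AGG" + "T" * 50
        peaks = pd.DataFrame([dict(chrom="", start=40, end=90, name="p")])
        hits = homology.scan_peaks(peaks, ref, hek4)
        assert len(hits) == 1
        assert hits[0].score == 40
        assert hits[0].seed_match_length == 20
        assert hits[0].start == 50

    def test_scoring_formula_with_distal_mismatches(self, hek4):
        proto = list(hek4.protospacer)
        for i in range(3):  # PAM-distal mismatches
            proto[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[i]]
        ref = "T" * 30 + "".join(proto) + "TGG" + "T" * 30
        peaks = pd.DataFrame([dict(chrom="", start=0, end=len(ref), name="p")])
        hits = homology.scan_peaks(peaks, ref, hek4, min_score=0)
        assert hits[0].score == 2 * 17 - 3 * 3 == 25
        assert hits[0].matches == 17
        assert hits[0].seed_match_length == 17

    def test_pam_gate_ngg_vs_nrn(self, hek4):
        ref = "T" * 30 + hek4.protospacer + "AGT" + "T" * 30
        peaks = pd.DataFrame([dict(chrom="", start=0, end=len(ref), name="p")])
        assert homology.scan_peaks(peaks, ref, hek4) == []
        spry = GuideSpec(hek4.protospacer, "NRN")
        hits = homology.scan_peaks(peaks, ref, spry)
        assert len(hits) == 1 and hits[0].pam_seq == "AGT"

    def test_peak_outside_reference_named_in_error(self, hek4):
        peaks = pd.DataFrame([dict(chrom="", start=0, end=500, name="bad_peak")])
        with pytest.raises(ValueError, match="bad_peak"):
            homology.scan_peaks(peaks, "ACGT" * 20, hek4)

    def test_matches_naive_scorer_on_random_peaks(self, hek4):
        """Oracle equivalence on 100 random peaks: scores, positions, strands."""
        rng = np.random.default_rng(12)
        ref = "".join(rng.choice(list("ACGT"), size=60_000))
        # spike some degenerate protospacer copies so hits exist
        ref_list = list(ref)
        for i in range(20):
            pos = 200 + i * 2500
            proto = list(hek4.protospacer)
            for j in range(int(rng.integers(0, 7))):
                proto[j] = rng.choice([b for b in "ACGT" if b != proto[j]])
            ins = "".join(proto) + rng.choice(list("ACGT")) + "GG"
            ref_list[pos : pos + 23] = ins
        ref = "".join(ref_list)
        rows = []
        for i in range(100):
            start = int(rng.integers(0, len(ref) - 400))
            rows.append(dict(chrom="", start=start, end=start + int(rng.integers(80, 400)),
                             name=f"p{i}"))
        peaks = pd.DataFrame(rows)
        hits = {h.peak_id: h for h in homology.scan_peaks(peaks, ref, hek4, min_score=10, flank=30)}
        for _, p in peaks.iterrows():
            s0 = max(0, p["start"] - 30)
            s1 = min(len(ref), p["end"] + 30)
            oracle = naive_best_hit(ref[s0:s1], hek4, s0, min_score=10)
            got = hits.get(p["name"])
            if oracle is None:
                assert got is None
            else:
                _, strand, gstart, score, seed = oracle
                assert got is not None
                assert (got.strand, got.start, got.score, got.seed_match_length) == (
                    strand, gstart, score, seed)

    def test_strand_symmetry(self, hek4):
        rng = np.random.default_rng(13)
        core = "".join(rng.choice(list("ACGT"), size=100))
        ref = core[:40] + hek4.protospacer + "CGG" + core[40:]
        peaks = pd.DataFrame([dict(chrom="", start=0, end=len(ref), name="p")])
        fwd = homology.scan_peaks(peaks, ref, hek4, flank=0)[0]
        rc = homology.scan_peaks(peaks, revcomp(ref), hek4, flank=0)[0]
        assert fwd.strand == "+" and rc.strand == "-"
        assert rc.start == len(ref) - fwd.end
        assert (rc.score, rc.seed_match_length) == (fwd.score, fwd.seed_match_length)


class TestPwm:
    def make_hit(self, seq, peak_id="p"):
        return homology.HomologyHit(
            peak_id=peak_id, chrom="", start=0, end=23, strand="+", score=40,
            matches=20, mismatch_positions=(), seed_match_length=20,
            protospacer_seq=seq, pam_seq="AGG")

    def test_single_hit_dominates_columns(self, hek4):
        pwm = homology.build_pwm([self.make_hit(hek4.protospacer)])
        for pos, base in zip(pwm.index, hek4.protospacer):
            assert pwm.loc[pos, base] == pytest.approx((1 + 0.5) / 3.0)

    def test_rows_sum_to_one(self, hek4):
        rng = np.random.default_rng(14)
        hits = [self.make_hit("".join(rng.choice(list("ACGT"), size=20)), f"p{i}")
                for i in range(30)]
        pwm = homology.build_pwm(hits)
        assert np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_information_concentrates_pam_adjacent(self, hek4):
        rng = np.random.default_rng(15)
        hits = []
        for i in range(200):
            distal = "".join(rng.choice(list("ACGT"), size=15))
            hits.append(self.make_hit(distal + hek4.protospacer[-5:], f"p{i}"))
        pwm = homology.build_pwm(hits)
        ic = homology.pwm_information_content(pwm)
        assert ic.loc[-5:].mean() > ic.loc[:-6].mean() + 1.0


class TestSeedCurves:
    def test_uniform_seed_collapses_curves(self):
        sites = pd.DataFrame(dict(seed_match_length=[20] * 5, edited=[True] * 5,
                                  rank_score=range(5)))
        out = homology.seed_rank_curves(sites)
        assert (out["all"] == out["seed_ge_8"]).all()
        assert (out["all"] == out["seed_ge_11"]).all()

    def test_threshold_plateaus(self):
        sites = pd.DataFrame(dict(seed_match_length=[20, 12, 9, 6],
                                  edited=[True] * 4, rank_score=[4, 3, 2, 1]))
        out = homology.seed_rank_curves(sites)
        assert out["seed_ge_11"].iloc[-1] == 2
        assert out["seed_ge_8"].iloc[-1] == 3
        assert out["all"].iloc[-1] == 4

    def test_total_curve_dominates(self):
        rng = np.random.default_rng(16)
        sites = pd.DataFrame(dict(
            seed_match_length=rng.integers(4, 21, size=50),
            edited=rng.random(50) < 0.7,
            rank_score=rng.random(50)))
        out = homology.seed_rank_curves(sites)
        assert (out["all"] >= out["seed_ge_8"]).all()
        assert (out["seed_ge_8"] >= out["seed_ge_11"]).all()


class TestMotifOccurrence:
    def test_all_peaks_contain_motif(self, hek4):
        rng = np.random.default_rng(17)
        ref = "".join(rng.choice(list("ACGT"), size=30_000))
        motif = hek4.seed5 + "TGG"
        ref_list = list(ref)
        rows = []
        for i in range(10):
            pos = 500 + i * 2000
            ref_list[pos : pos + 8] = motif
            rows.append(dict(chrom="", start=pos - 100, end=pos + 100, name=f"p{i}"))
        out = homology.motif_occurrence(pd.DataFrame(rows), "".join(ref_list), hek4,
                                        n_background=100, rng=np.random.default_rng(0))
        assert out["peak_fraction"] == 1.0
        assert out["background_fraction"] < 0.3
        assert out["p_value"] < 1e-4

    def test_background_fraction_matches_enumeration_oracle(self, hek4):
        """The sampler's background rate agrees with exhaustive window
        enumeration on the same genome."""
        rng = np.random.default_rng(18)
        ref = "".join(rng.choice(list("ACGT"), size=40_000))
        length = 300
        peaks = pd.DataFrame([dict(chrom="", start=s, end=s + length, name=f"p{i}")
                              for i, s in enumerate(range(0, 3000, 300))])
        out = homology.motif_occurrence(peaks, ref, hek4, n_background=400,
                                        rng=np.random.default_rng(1), gc_tolerance=1.0)
        motif = hek4.seed5 + hek4.pam_pattern
        oracle_hits = sum(
            homology._contains_motif(ref[s : s + length], motif)
            for s in range(0, len(ref) - length, length)
        )
        oracle_rate = oracle_hits / ((len(ref) - length) // length)
        se = np.sqrt(oracle_rate * (1 - oracle_rate) / 400)
        assert abs(out["background_fraction"] - oracle_rate) <= 4 * se + 0.02

    def test_enrichment_p_decreases_with_motif_density(self, hek4):
        rng = np.random.default_rng(19)
        base = "".join(rng.choice(list("ACGT"), size=30_000))
        motif = hek4.seed5 + "AGG"
        ps = []
        for n_planted in (2, 6, 10):
            ref_list = list(base)
            rows = []
            for i in range(10):
                pos = 500 + i * 2000
                if i < n_planted:
                    ref_list[pos : pos + 8] = motif
                rows.append(dict(chrom="", start=pos - 100, end=pos + 100, name=f"p{i}"))
            out = homology.motif_occurrence(pd.DataFrame(rows), "".join(ref_list), hek4,
                                            n_background=150, rng=np.random.default_rng(2))
            ps.append(out["p_value"])
        assert ps[0] > ps[1] > ps[2]
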