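"""The penetrance screen: calling, filters, pattern classification."""

import numpy as np
import pytest

import sporepool.screen as scr
import sporepool.simulate as sim
from sporepool.simulate import PoolDesign

DESIGN = PoolDesign(
    samples=["wt", "ab", "b", "c"],
    lineages=["a", "b", "c"],
    presence={
        "wt": {"a": "counterselected", "b": "counterselected", "c": "counterselected"},
        "ab": {"a": "fixed", "b": "fixed", "c": "absent"},
        "b": {"a": "absent", "b": "fixed", "c": "absent"},
        "c": {"a": "absent", "b": "absent", "c": "fixed"},
    },
)


def site(depths, alts, pos=100, vtype="snp", alt="A", ref="G", sufficient=None):
    sc = scr.SiteCall("contig_1", pos, ref, vtype, alt)
    sc.depth = dict(depths)
    sc.alt_count = dict(alts)
    sc.sufficient = sufficient if sufficient is not None else {s: d > 0 for s, d in depths.items()}
    return sc


class TestCoverageFilter:
    def test_forty_percent_rule(self):
        cfg = scr.ScreenConfig()
        calls = [site({"wt": 25, "ab": 10}, {"ab": 10})]
        scr.apply_coverage_filter(calls, {"wt": 54.0, "ab": 50.0}, cfg)
        assert calls[0].sufficient["wt"] is True  # 25 >= 0.4*54 = 21.6
        assert calls[0].sufficient["ab"] is False  # 10 < 0.4*50 = 20

    def test_zero_fraction_accepts_every_covered_site(self):
        cfg = scr.ScreenConfig(coverage_fraction=0.0)
        calls = [site({"wt": 1, "ab": 0}, {"wt": 1})]
        scr.apply_coverage_filter(calls, {"wt": 100.0, "ab": 100.0}, cfg)
        assert calls[0].sufficient["wt"] is True
        assert calls[0].sufficient["ab"] is False  # uncovered can never count

    def test_nonpositive_mean_coverage_rejected(self):
        with pytest.raises(ValueError):
            scr.apply_coverage_filter([], {"wt": 0.0}, scr.ScreenConfig())


class TestScreenPatterns:
    CFG = scr.ScreenConfig()  # literal defaults: penetrance 1.0, absence 0

    def classify(self, sc, cfg=None):
        return scr.screen_patterns([sc], DESIGN, cfg or self.CFG)[0]

    def test_two_sample_pattern_matches_its_lineage(self):
        cand = self.classify(site({"wt": 44, "ab": 44, "b": 107, "c": 50},
                                  {"ab": 44, "b": 107}))
        assert cand.classification == "pattern_candidate"
        assert cand.matched_lineage == "b"
        assert cand.pattern == frozenset({"ab", "b"})

    def test_penetrant_everywhere_is_reference_error(self):
        cand = self.classify(site({"wt": 30, "ab": 28, "b": 31, "c": 29},
                                  {"wt": 30, "ab": 28, "b": 31, "c": 29}))
        assert cand.classification == "reference_error"

    def test_half_frequency_is_partial_penetrance_never_candidate(self):
        cand = self.classify(site({"wt": 40, "ab": 40, "b": 40, "c": 40}, {"ab": 20}))
        assert cand.classification == "partial_penetrance"

    def test_alt_reads_outside_pattern_block_candidacy(self):
        cand = self.classify(site({"wt": 40, "ab": 40, "b": 40, "c": 40},
                                  {"ab": 40, "b": 40, "wt": 1}))
        assert cand.classification == "partial_penetrance"
        cfg = scr.ScreenConfig(absence_max_alt=2)
        cand = self.classify(site({"wt": 40, "ab": 40, "b": 40, "c": 40},
                                  {"ab": 40, "b": 40, "wt": 1}), cfg)
        assert cand.classification == "pattern_candidate"

    def test_uncovered_outside_sample_cannot_assert_absence(self):
        cand = self.classify(site({"wt": 0, "ab": 40, "b": 40, "c": 40},
                                  {"ab": 40, "b": 40}))
        assert cand.classification == "inconsistent"

    def test_penetrant_but_thin_coverage_is_low_coverage(self):
        sc = site({"wt": 40, "ab": 12, "b": 40, "c": 40}, {"ab": 12, "b": 40})
        sc.sufficient["ab"] = False
        cand = self.classify(sc)
        assert cand.classification == "low_coverage"

    def test_pattern_without_matching_lineage_is_inconsistent(self):
        # {wt} is nobody's expected pattern
        cand = self.classify(site({"wt": 40, "ab": 40, "b": 40, "c": 40}, {"wt": 40}))
        assert cand.classification == "inconsistent"

    def test_strict_mode_demands_coverage_outside_the_pattern_too(self):
        cfg = scr.ScreenConfig(strict_all_samples=True)
        sc = site({"wt": 5, "ab": 40, "b": 40, "c": 40}, {"ab": 40, "b": 40})
        sc.sufficient["wt"] = False
        assert self.classify(sc, cfg).classification == "low_coverage"
        assert self.classify(sc).classification == "pattern_candidate"

    def test_classifications_partition_all_sites(self):
        rng = np.random.default_rng(4)
        sites = []
        for _ in range(300):
            depths = {s: int(rng.integers(0, 60)) for s in DESIGN.samples}
            alts = {s: int(rng.integers(0, d + 1)) for s, d in depths.items() if d}
            sites.append(site(depths, alts))
        cands = scr.screen_patterns(sites, DESIGN, self.CFG)
        assert len(cands) == len(sites)
        assert all(c.classification in scr.CLASSIFICATIONS for c in cands)

    def test_raising_coverage_fraction_never_adds_candidates(self):
        rng = np.random.default_rng(5)
        sites = []
        for _ in range(250):
            depths = {s: int(rng.integers(0, 60)) for s in DESIGN.samples}
            alts = {s: (d if rng.random() < 0.3 else int(rng.integers(0, d + 1)))
                    for s, d in depths.items() if d}
            sites.append(site(depths, alts))
        mean_cov = {s: 50.0 for s in DESIGN.samples}
        previous = None
        for frac in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            cfg = scr.ScreenConfig(coverage_fraction=frac)
            scr.apply_coverage_filter(sites, mean_cov, cfg)
            n = sum(c.classification == "pattern_candidate"
                    for c in scr.screen_patterns(sites, DESIGN, cfg))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_design_without_pattern_rejected(self):
        bad = PoolDesign(["s1"], ["x"], {"s1": {"x": "absent"}})
        with pytest.raises(ValueError):
            scr.screen_patterns([], bad, self.CFG)


class TestIndelNormalisation:
    def test_left_alignment_in_homopolymer(self):
        ref = "ACGAAAAATCG"
        #      0123456789
        assert scr.left_align_deletion(ref, 6, 1) == 3
        pos, seq = scr.left_align_insertion(ref, 7, "A")
        assert (pos, seq) == (2, "A")

    def test_left_alignment_noop_outside_runs(self):
        ref = "ACGTACGT"
        assert scr.left_align_deletion(ref, 4, 1) == 4
        assert scr.left_align_insertion(ref, 4, "G") == (4, "G")


class TestHomopolymerFlag:
    REF = sim.ReferenceGenome({"c": "ACGTAAAAACGTGGCTTAC"})
    #                               0123456789

    def flag(self, vtype, pos, alt):
        sc = scr.SiteCall("c", pos, self.REF.contigs["c"][pos], vtype, alt)
        cand = scr.CandidateMutation(sc, frozenset(), "reference_error")
        scr.flag_homopolymers([cand], self.REF, scr.ScreenConfig())
        return cand.homopolymer_flag

    def test_one_base_deletion_in_run_flagged(self):
        assert self.flag("del", 5, 1) is True

    def test_snp_in_run_exempt(self):
        assert self.flag("snp", 5, "G") is False

    def test_insertion_extending_short_run_not_flagged(self):
        # inserting T after pos 16 touches a 2-T run only
        assert self.flag("ins", 16, "T") is False

    def test_insertion_into_long_run_flagged(self):
        assert self.flag("ins", 6, "A") is True

    def test_three_base_deletion_exempt(self):
        assert self.flag("del", 4, 3) is False


class TestReferenceCorrections:
    def test_single_snp_changes_one_base(self):
        ref = sim.ReferenceGenome({"c": "ACGTACGTAC"})
        sc = site({"s": 10}, {"s": 10}, pos=4, ref="A", alt="G")
        sc.contig = "c"
        cand = scr.CandidateMutation(sc, frozenset(), "reference_error")
        fixed, log = scr.apply_reference_corrections(ref, [cand])
        assert fixed.contigs["c"] == "ACGTGCGTAC"
        assert log[0]["pos"] == 4

    def test_deletion_correction_shortens_contig(self):
        ref = sim.ReferenceGenome({"c": "A" * 10_000})
        sc = scr.SiteCall("c", 500, "A", "del", 1)
        cand = scr.CandidateMutation(sc, frozenset(), "reference_error")
        fixed, _ = scr.apply_reference_corrections(ref, [cand])
        assert len(fixed.contigs["c"]) == 9_999

    def test_insertion_correction_lengthens_contig(self):
        ref = sim.ReferenceGenome({"c": "ACGTACGTAC"})
        sc = scr.SiteCall("c", 3, "T", "ins", "GG")
        cand = scr.CandidateMutation(sc, frozenset(), "reference_error")
        fixed, _ = scr.apply_reference_corrections(ref, [cand])
        assert fixed.contigs["c"] == "ACGTGGACGTAC"

    def test_overlapping_corrections_rejected(self):
        ref = sim.ReferenceGenome({"c": "ACGTACGTAC"})
        a = scr.CandidateMutation(scr.SiteCall("c", 2, "GTA", "del", 3),
                                  frozenset(), "reference_error")
        b = scr.CandidateMutation(scr.SiteCall("c", 4, "A", "snp", "C"),
                                  frozenset(), "reference_error")
        with pytest.raises(scr.ConsistencyError):
            scr.apply_reference_corrections(ref, [a, b])


class TestVcfExport:
    def test_vcf_is_readable_and_one_based(self, tmp_path):
        ref = sim.ReferenceGenome({"c": "ACGTACGTACGT"})
        snp = scr.CandidateMutation(site({"wt": 10, "ab": 12, "b": 9, "c": 11},
                                         {"ab": 12, "b": 9}, pos=4, ref="A", alt="T"),
                                    frozenset({"ab", "b"}), "pattern_candidate",
                                    matched_lineage="b")
        snp.site.contig = "c"
        out = tmp_path / "v.vcf"
        scr.write_vcf([snp], list(DESIGN.samples), ref, str(out))
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        f = body[0].split("\t")
        assert (f[0], f[1], f[3], f[4]) == ("c", "5", "A", "T")
        assert "CLASS=pattern_candidate" in f[7] and "LINEAGE=b" in f[7]
        assert f[9:] == ["10:0", "12:12", "9:9", "11:0"]
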