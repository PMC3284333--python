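"""Simulator: genome generation, lesion planting, pools and reads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sporepool.simulate as sim
from sporepool._seq import revcomp


class TestGenerateGenome:
    def test_deterministic_and_total_length(self):
        a = sim.generate_genome(2, [50_000, 30_000], 0.55, seed=7)
        b = sim.generate_genome(2, [50_000, 30_000], 0.55, seed=7)
        assert a.contigs == b.contigs
        assert a.total_length == 80_000

    def test_different_seed_differs(self):
        a = sim.generate_genome(1, [10_000], 0.5, seed=1)
        b = sim.generate_genome(1, [10_000], 0.5, seed=2)
        assert a.contigs != b.contigs

    def test_gc_content_calibrated(self):
        g = sim.generate_genome(1, [1_000_000], 0.5, seed=3)
        seq = g.contigs["contig_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    @pytest.mark.parametrize("args", [
        (1, [0], 0.5), (1, [-5], 0.5), (1, [100], 0.0), (1, [100], 1.0), (2, [100], 0.5),
    ])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            sim.generate_genome(*args, seed=1)


class TestPlantMutations:
    def test_snp_changes_exactly_one_position(self, small_genome):
        seq = small_genome.contigs["contig_1"]
        pos = next(i for i, b in enumerate(seq) if b == "G")
        spec = sim.MutationSpec("snp", "contig_1", pos, "G", "A")
        mut, truth = sim.plant_mutations(small_genome, [spec])
        mseq = mut.contigs["contig_1"]
        diffs = [i for i in range(len(seq)) if seq[i] != mseq[i]]
        assert diffs == [pos] and mseq[pos] == "A"
        assert truth.specs[0].pos == pos

    def test_large_deletion_shortens_by_its_length(self, small_genome):
        seq = small_genome.contigs["contig_1"]
        spec = sim.MutationSpec("large_deletion", "contig_1", 10_000, seq[10_000:11_100])
        mut, _ = sim.plant_mutations(small_genome, [spec])
        assert len(mut.contigs["contig_1"]) == len(seq) - 1100

    def test_complex_replacement_length_and_copies(self, small_genome):
        rng = np.random.default_rng(5)
        seq = small_genome.contigs["contig_1"]
        spec = sim.complex_replacement_spec(small_genome, "contig_1", 20_000, 1100, rng)
        # shrink the final segment by 20 b to make a near-balanced event
        plan = list(spec.replacement_plan)
        s, e, o = plan[-1]
        plan[-1] = (s, e - 20, o)
        spec = sim.MutationSpec("complex_replacement", "contig_1", 20_000,
                                spec.ref_allele, replacement_plan=tuple(plan))
        mut, _ = sim.plant_mutations(small_genome, [spec])
        mseq = mut.contigs["contig_1"]
        assert len(mseq) == len(seq) - 20
        # every planned segment appears verbatim (or reverse-complemented)
        cursor = 20_000
        for s, e, o in spec.replacement_plan:
            frag = seq[s:e] if o == "+" else revcomp(seq[s:e])
            assert mseq[cursor : cursor + (e - s)] == frag
            cursor += e - s

    def test_ref_mismatch_rejected(self, small_genome):
        seq = small_genome.contigs["contig_1"]
        wrong = "A" if seq[100] != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            sim.plant_mutations(small_genome, [sim.MutationSpec("snp", "contig_1", 100, wrong, "T")])

    def test_overlapping_specs_rejected(self, small_genome):
        seq = small_genome.contigs["contig_1"]
        a = sim.MutationSpec("small_deletion", "contig_1", 500, seq[500:503])
        b = sim.MutationSpec("snp", "contig_1", 502, seq[502], "A" if seq[502] != "A" else "C")
        with pytest.raises(ValueError, match="overlap"):
            sim.plant_mutations(small_genome, [a, b])

    def test_projection_roundtrips_through_indels(self, small_genome):
        seq = small_genome.contigs["contig_1"]
        specs = [
            sim.MutationSpec("small_deletion", "contig_1", 1000, seq[1000:1002]),
            sim.MutationSpec("small_insertion", "contig_1", 2000, seq[2000], "TTT"),
        ]
        mut, _ = sim.plant_mutations(small_genome, specs)
        mseq = mut.contigs["contig_1"]
        for pos in (500, 1500, 2500, 40_000):
            proj = sim.project_position(specs, "contig_1", pos)
            assert mseq[proj] == seq[pos]
        assert sim.project_position(specs, "contig_1", 1001) is None


class TestSimulatePool:
    @pytest.fixture()
    def setup(self, small_genome):
        rng = np.random.default_rng(11)
        specs = sim.random_snp_specs(small_genome, 21, rng, lineage="colour")
        causative = sim.MutationSpec("snp", specs[0].contig, specs[0].pos,
                                     specs[0].ref_allele, specs[0].alt_allele,
                                     lineage="colour", causative=True)
        _, truth = sim.plant_mutations(small_genome, [causative] + specs[1:])
        design = sim.PoolDesign(
            ["colour", "wt", "other"], ["colour"],
            {"colour": {"colour": "fixed"}, "wt": {"colour": "counterselected"},
             "other": {"colour": "absent"}}, n_isolates=40)
        return truth, design

    def test_selection_fixes_causative(self, setup):
        truth, design = setup
        pool = sim.simulate_pool(truth, design, "colour", seed=1)
        assert pool.counts[0] == 40

    def test_absent_lineage_contributes_nothing(self, setup):
        truth, design = setup
        pool = sim.simulate_pool(truth, design, "other", seed=1)
        assert (pool.counts == 0).all()

    def test_counterselected_removes_causative_keeps_background(self, setup):
        truth, design = setup
        pool = sim.simulate_pool(truth, design, "wt", seed=2)
        assert pool.counts[0] == 0
        assert (pool.counts[1:] > 0).any()

    def test_segregating_counts_near_binomial_center(self, setup):
        # Binomial(40, .5) lies in [10, 30] except with probability ~2e-3
        truth, design = setup
        counts = []
        for seed in range(30):
            pool = sim.simulate_pool(truth, design, "colour", seed=seed)
            counts.extend(pool.counts[1:].tolist())
        counts = np.array(counts)
        assert np.mean((counts >= 10) & (counts <= 30)) > 0.99
        assert abs(counts.mean() - 20) < 1.0

    def test_unknown_sample_rejected(self, setup):
        truth, design = setup
        with pytest.raises(ValueError):
            sim.simulate_pool(truth, design, "nope", seed=1)


class TestSimulateReads:
    def test_read_count_tracks_coverage(self, mapped_pool):
        r1, r2 = mapped_pool["reads"]
        total_bases = (len(r1) + len(r2)) * 76
        expect = 35 * mapped_pool["genome"].total_length
        assert abs(total_bases - expect) / expect < 0.02

    def test_error_free_reads_match_their_source(self, small_genome):
        truth = sim.TruthTable([], n_isolates=4)
        design = sim.PoolDesign(["s"], ["x"], {"s": {"x": "absent"}}, 4)
        pool = sim.simulate_pool(truth, design, "s", seed=3)
        r1, r2 = sim.simulate_reads(small_genome, pool, 2, 76, 2000, 200, 0.0, 0.0, seed=4)
        seq = small_genome.contigs["contig_1"]
        for i in range(0, len(r1), 37):
            s, e = int(r1.frag_start[i]), int(r1.frag_end[i])
            assert r1.seqs[i].tobytes().decode() == seq[s : s + 76]
            assert revcomp(r2.seqs[i].tobytes().decode()) == seq[e - 76 : e]

    def test_fixed_mutation_present_in_every_covering_read(self, mapped_pool):
        spec = mapped_pool["truth"].specs[0]
        col = mapped_pool["pileup"].column(spec.contig, spec.pos)
        assert col.depth > 0
        assert col.base_counts.get(spec.alt_allele, 0) == col.depth

    def test_fastq_output_deterministic(self, small_genome, tmp_path):
        truth = sim.TruthTable([], n_isolates=4)
        design = sim.PoolDesign(["s"], ["x"], {"s": {"x": "absent"}}, 4)
        outs = []
        for run in range(2):
            pool = sim.simulate_pool(truth, design, "s", seed=5)
            r1, _ = sim.simulate_reads(small_genome, pool, 1, 50, 800, 80,
                                       0.01, 0.002, seed=6)
            p = tmp_path / f"r{run}.fastq"
            r1.write_fastq(str(p))
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_fastq_roundtrip_preserves_reads_and_names(self, small_genome, tmp_path):
        truth = sim.TruthTable([], n_isolates=2)
        design = sim.PoolDesign(["s"], ["x"], {"s": {"x": "absent"}}, 2)
        pool = sim.simulate_pool(truth, design, "s", seed=5)
        r1, _ = sim.simulate_reads(small_genome, pool, 0.5, 60, 900, 90, 0.0, 0.0, seed=6)
        p = tmp_path / "x.fastq"
        r1.write_fastq(str(p))
        back = sim.ReadSet.from_fastq(str(p))
        assert (back.seqs == r1.seqs).all()
        assert back.name(0) == r1.name(0)
        assert (back.frag_start == r1.frag_start).all()

    def test_segregating_allele_frequency_calibrated(self, small_genome):
        # pooled read-level alt frequency of a segregating locus -> 0.5
        rng = np.random.default_rng(0)
        specs = sim.random_snp_specs(small_genome, 8, rng, lineage="L")
        _, truth = sim.plant_mutations(small_genome, specs)
        design = sim.PoolDesign(["s"], ["L"], {"s": {"L": "segregating"}}, 40)
        fracs = []
        for seed in range(6):
            pool = sim.simulate_pool(truth, design, "s", seed=seed)
            fracs.extend((pool.counts / 40).tolist())
        mean = float(np.mean(fracs))
        se = 0.5 / np.sqrt(40 * len(fracs))
        assert abs(mean - 0.5) < 3 * se + 0.02

    def test_invalid_rates_rejected(self, small_genome):
        truth = sim.TruthTable([], n_isolates=2)
        design = sim.PoolDesign(["s"], ["x"], {"s": {"x": "absent"}}, 2)
        pool = sim.simulate_pool(truth, design, "s", seed=1)
        with pytest.raises(ValueError):
            sim.simulate_reads(small_genome, pool, -1, 76, 2000, 200, 0, 0, seed=1)
        with pytest.raises(ValueError):
            sim.simulate_reads(small_genome, pool, 5, 76, 2000, 200, 1.5, 0, seed=1)


class TestSpecValidation:
    @given(st.integers(min_value=4, max_value=10))
    @settings(max_examples=20, deadline=None)
    def test_oversized_small_indels_rejected(self, n):
        with pytest.raises(ValueError):
            sim.MutationSpec("small_deletion", "c", 0, "A" * n)

    def test_truth_table_tsv(self, mapped_pool, tmp_path):
        p = tmp_path / "truth.tsv"
        mapped_pool["truth"].to_tsv(str(p), ["mut", "wt"])
        lines = p.read_text().splitlines()
        assert lines[0].startswith("contig\tpos_0based")
        assert len(lines) == 1 + len(mapped_pool["truth"].records)
        assert any(row.split("\t")[6] == "1" for row in lines[1:])  # causative flag
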