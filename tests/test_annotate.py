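"""Gene models, consequence calls, stop-loss extension, splice defects."""

import numpy as np
import pytest

import sporepool.annotate as ann
import sporepool.screen as scr
import sporepool.simulate as sim
from sporepool._seq import revcomp
from sporepool.pipeline import SENSE_CODONS, install_gene


def snp(contig, pos, ref, alt):
    return scr.SiteCall(contig, pos, ref, "snp", alt)


@pytest.fixture(scope="module")
def locus():
    """A well-formed two-intron plus-strand gene embedded in random sequence."""
    genome = sim.generate_genome(1, [6000], 0.5, seed=33)
    rng = np.random.default_rng(34)
    genome, model = install_gene(genome, "contig_1", 1000,
                                 exon_lens=[120, 90, 90], intron_lens=[60, 74],
                                 rng=rng, gene_id="g1", stop_codon="TGA",
                                 downstream_sense_codons=40)
    return genome, model


class TestGeneModel:
    def test_intron_coordinates_are_exon_gaps(self, locus):
        _, model = locus
        assert model.introns == [(1120, 1180), (1270, 1344)]

    def test_cds_translates_without_internal_stop(self, locus):
        genome, model = locus
        pep = model.peptide(genome)
        assert len(pep) == (120 + 90 + 90) // 3 - 1
        assert pep[0] == "M" and "*" not in pep

    def test_translation_matches_exon_concatenation_oracle(self, locus):
        genome, model = locus
        seq = genome.contigs["contig_1"]
        concat = "".join(seq[s:e] for s, e in model.exons)
        from Bio.Seq import Seq
        oracle = str(Seq(concat).translate()).split("*")[0]
        assert model.peptide(genome) == oracle

    def test_minus_strand_translation(self):
        # build a minus-strand gene by reverse-complementing a plus locus
        genome = sim.generate_genome(1, [3000], 0.5, seed=35)
        rng = np.random.default_rng(36)
        genome, model = install_gene(genome, "contig_1", 500,
                                     exon_lens=[60, 60], intron_lens=[30],
                                     rng=rng, gene_id="f")
        fwd_pep = model.peptide(genome)
        L = 3000
        rc = sim.ReferenceGenome({"contig_1": revcomp(genome.contigs["contig_1"])})
        flipped = ann.GeneModel("f", "contig_1", "-",
                                [(L - e, L - s) for s, e in model.exons])
        assert flipped.peptide(rc) == fwd_pep

    def test_gff3_roundtrip(self, locus, tmp_path):
        genome, model = locus
        p = tmp_path / "m.gff3"
        ann.write_gff3([model], str(p))
        back = ann.load_gene_models(str(p), genome)
        assert len(back) == 1
        assert back[0].exons == model.exons
        assert back[0].strand == model.strand


class TestClassifyVariant:
    def test_donor_first_base_transition(self, locus):
        genome, model = locus
        pos = model.introns_tx_order()[1][0]
        q = ann.classify_variant(snp("contig_1", pos, "G", "A"), [model], genome)
        assert q.category == "splice_donor"
        assert "intron 2" in q.detail and "base 1" in q.detail

    def test_donor_second_base(self, locus):
        genome, model = locus
        pos = model.introns_tx_order()[0][0] + 1
        q = ann.classify_variant(snp("contig_1", pos, "T", "C"), [model], genome)
        assert q.category == "splice_donor" and "base 2" in q.detail

    def test_acceptor_bases(self, locus):
        genome, model = locus
        end = model.introns_tx_order()[0][1]
        q = ann.classify_variant(snp("contig_1", end - 1, "G", "T"), [model], genome)
        assert q.category == "splice_acceptor"

    def test_deep_intronic(self, locus):
        genome, model = locus
        mid = sum(model.introns[0]) // 2
        ref = genome.contigs["contig_1"][mid]
        alt = "A" if ref != "A" else "G"
        q = ann.classify_variant(snp("contig_1", mid, ref, alt), [model], genome)
        assert q.category == "intronic"

    def test_stop_loss_call(self, locus):
        genome, model = locus
        pos = model.exons[-1][1] - 1  # third base of TGA
        q = ann.classify_variant(snp("contig_1", pos, "A", "G"), [model], genome)
        assert q.category == "stop_loss"

    def test_nonsense_and_missense_and_synonymous(self):
        genome = sim.ReferenceGenome({"c": "ATGTGGAAACTTTGACCCGGG"})
        model = ann.GeneModel("g", "c", "+", [(0, 15)])
        #  codons: ATG TGG AAA CTT TGA
        q = ann.classify_variant(snp("c", 4, "G", "A"), [model], genome)  # TGG->TAG
        assert q.category == "nonsense"
        q = ann.classify_variant(snp("c", 6, "A", "C"), [model], genome)  # AAA->CAA
        assert q.category == "missense"
        q = ann.classify_variant(snp("c", 8, "A", "G"), [model], genome)  # AAA->AAG (K)
        assert q.category == "synonymous"

    def test_far_from_any_gene_is_intergenic(self, locus):
        genome, model = locus
        q = ann.classify_variant(snp("contig_1", 5500, genome.contigs["contig_1"][5500], "A"),
                                 [model], genome)
        assert q.category == "intergenic"

    def test_exonic_indels(self, locus):
        genome, model = locus
        s = model.exons[0][0] + 10
        dele = scr.SiteCall("contig_1", s, genome.contigs["contig_1"][s : s + 2], "del", 2)
        assert ann.classify_variant(dele, [model], genome).category == "frameshift_indel"
        dele3 = scr.SiteCall("contig_1", s, genome.contigs["contig_1"][s : s + 3], "del", 3)
        assert ann.classify_variant(dele3, [model], genome).category == "inframe_indel"

    def test_large_deletion_over_cds(self, locus):
        genome, model = locus
        spec = sim.MutationSpec("large_deletion", "contig_1", model.exons[1][0] - 50,
                                genome.contigs["contig_1"][model.exons[1][0] - 50:
                                                           model.exons[1][0] + 550])
        q = ann.classify_variant(spec, [model], genome)
        assert q.category == "cds_deletion"

    def test_every_variant_gets_exactly_one_category(self, locus):
        genome, model = locus
        rng = np.random.default_rng(2)
        for pos in rng.integers(0, 6000, size=120):
            ref = genome.contigs["contig_1"][int(pos)]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            q = ann.classify_variant(snp("contig_1", int(pos), ref, alt), [model], genome)
            assert q.category in ann.CATEGORIES


class TestStopLossExtension:
    def _gene(self, tail: str):
        # ... ATG TAC TAG >tail< ; mutate TAG -> CAG to break the stop
        seq = "ATGTAC" + "TAG" + tail
        genome = sim.ReferenceGenome({"c": seq + "A" * ((3 - len(seq) % 3) % 3)})
        model = ann.GeneModel("g", "c", "+", [(0, 9)])
        mutated = sim.ReferenceGenome({"c": "ATGTAC" + "CAG" + tail})
        return mutated, model

    def test_two_codon_extension_hand_counted(self):
        mutated, model = self._gene("GGGTAACCC")
        ext = ann.stop_loss_extension(model, mutated)
        assert ext.n_aa == 2  # Q, G then TAA

    def test_immediate_stop_gives_one_residue(self):
        mutated, model = self._gene("TAACCCCCC")
        assert ann.stop_loss_extension(model, mutated).n_aa == 1

    def test_alternative_convention_counts_one_fewer(self):
        mutated, model = self._gene("GGGTAACCC")
        assert ann.stop_loss_extension(model, mutated, include_mutated_codon=False).n_aa == 1

    def test_no_stop_before_contig_end_flagged(self):
        mutated, model = self._gene("GGG")
        ext = ann.stop_loss_extension(model, mutated)
        assert ext.runs_off_contig

    def test_still_a_stop_rejected(self):
        genome = sim.ReferenceGenome({"c": "ATGTACTAGGGGTAA"})
        model = ann.GeneModel("g", "c", "+", [(0, 9)])
        with pytest.raises(ValueError):
            ann.stop_loss_extension(model, genome)

    def test_matches_brute_force_scan_on_random_tails(self):
        rng = np.random.default_rng(99)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(100):
            tail = bases[rng.integers(0, 4, size=600)].tobytes().decode()
            mutated, model = self._gene(tail)
            seq = mutated.contigs["c"]
            oracle = ann.scan_next_inframe_stop(seq, 6)
            ext = ann.stop_loss_extension(model, mutated)
            if oracle is None:
                assert ext.runs_off_contig
            else:
                assert ext.n_aa == oracle


class TestSpliceDefects:
    def test_retention_of_non_triplet_intron_frameshifts(self, locus):
        genome, model = locus
        variants = ann.splice_defect_transcripts(model, genome, disrupted_intron=1)
        ret = variants[0]
        assert ret.name == "retention"
        assert ret.frameshift  # intron 2 is 74 b, not a multiple of 3
        wt = model.peptide(genome)
        assert ret.peptide[: ret.diverges_at_aa] == wt[: ret.diverges_at_aa]
        assert ret.peptide != wt

    def test_retention_of_triplet_intron_is_in_frame(self):
        genome = sim.generate_genome(1, [4000], 0.5, seed=44)
        rng = np.random.default_rng(45)
        genome, model = install_gene(genome, "contig_1", 800,
                                     exon_lens=[90, 90], intron_lens=[60], rng=rng)
        var = ann.splice_defect_transcripts(model, genome, 0)[0]
        assert not var.frameshift
        assert len(var.cds) == 180 + 60

    def test_cryptic_donor_transcript_lengths_hand_computed(self, locus):
        genome, model = locus
        intron2 = model.introns_tx_order()[1]
        cryptic = intron2[0] - 31  # a false 5' site 31 b inside exon 2
        variants = ann.splice_defect_transcripts(model, genome, 1, cryptic_donor=cryptic)
        assert len(variants) == 2
        ret, cry = variants
        assert len(ret.cds) == 300 + 74  # full CDS plus retained intron 2
        assert len(cry.cds) == 300 - 31  # 31 coding bases lost to the false site
        assert cry.frameshift

    def test_cryptic_site_outside_gene_rejected(self, locus):
        genome, model = locus
        with pytest.raises(ValueError):
            ann.splice_defect_transcripts(model, genome, 1, cryptic_donor=5900)

    def test_bad_intron_index_rejected(self, locus):
        genome, model = locus
        with pytest.raises(ValueError):
            ann.splice_defect_transcripts(model, genome, 5)


class TestInstallGene:
    def test_installed_gene_has_canonical_splice_sites(self, locus):
        genome, model = locus
        seq = genome.contigs["contig_1"]
        for s, e in model.introns:
            assert seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG"

    def test_sense_codon_table_excludes_stops(self):
        assert len(SENSE_CODONS) == 61
        assert not set(SENSE_CODONS) & ann.STOPS
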