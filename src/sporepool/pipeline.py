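"""End-to-end orchestration: simulate (or import), clean, map, pile up,
screen, scan for structural lesions, annotate, and report.

The bundled simulation scenario mirrors the four-pool crossing design of a
haploid mutant screen: three mutant lineages (one plain SNP, one
splice-donor SNP inside a planted two-intron gene, one stop-loss SNP in a
planted gene with a long open stretch downstream), a resequenced wild-type
pool in which every causative allele was selected against, and
transition-biased background lesions segregating 1:1 in the pools whose
crosses carried them.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import annotate as ann
from . import mapping, pileup as pl, screen as scr, simulate as sim, structural as sv

SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ann.STOPS]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# synthetic gene installation
# ---------------------------------------------------------------------------

def install_gene(
    genome: sim.ReferenceGenome,
    contig: str,
    start: int,
    exon_lens: list[int],
    intron_lens: list[int],
    rng: np.random.Generator,
    gene_id: str = "gene1",
    stop_codon: str = "TGA",
    downstream_sense_codons: int = 0,
) -> tuple[sim.ReferenceGenome, ann.GeneModel]:
    """Overwrite reference sequence with a well-formed plus-strand gene.

    The CDS is random sense codons opening with ATG and closing with
    ``stop_codon``; introns are GT..AG.  ``downstream_sense_codons`` sense
    codons followed by TAA are written after the gene so that a stop-loss
    mutation has a defined in-frame extension length.
    """
    if len(intron_lens) != len(exon_lens) - 1:
        raise ValueError("need one fewer intron than exons")
    total_cds = sum(exon_lens)
    if total_cds % 3:
        raise ValueError("total exon length must be a multiple of 3")
    n_codons = total_cds // 3
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    codons[0] = "ATG"
    cds = "".join(codons[:-1]) + stop_codon
    pieces, exons = [], []
    cur = start
    off = 0
    for i, el in enumerate(exon_lens):
        pieces.append(cds[off : off + el])
        exons.append((cur, cur + el))
        off += el
        cur += el
        if i < len(intron_lens):
            il = intron_lens[i]
            if il < 6:
                raise ValueError("introns must be >= 6 b")
            mid = "".join(SENSE_CODONS[j][0] for j in rng.integers(0, len(SENSE_CODONS), size=il - 4))
            pieces.append("GT" + mid + "AG")
            cur += il
    tail = ""
    if downstream_sense_codons:
        tail = "".join(SENSE_CODONS[i] for i in
                       rng.integers(0, len(SENSE_CODONS), size=downstream_sense_codons)) + "TAA"
    block = "".join(pieces) + tail
    seq = genome.contigs[contig]
    if start + len(block) > len(seq):
        raise ValueError("gene does not fit on contig")
    newseq = seq[:start] + block + seq[start + len(block):]
    contigs = dict(genome.contigs)
    contigs[contig] = newseq
    return sim.ReferenceGenome(contigs), ann.GeneModel(gene_id, contig, "+", exons)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat run configuration (YAML-serialisable)."""

    mode: str = "simulate"
    seed: int | None = 42
    outdir: str = "sporepool_out"
    # simulation block
    genome_length: int = 2_000_000
    n_contigs: int = 1
    gc: float = 0.5
    n_background: int = 120
    n_isolates: int = 40
    coverage: float = 50.0
    read_len: int = 76
    insert_mean: int = 2000
    insert_sd: int = 200
    error_rate: float = 0.005
    n_rate: float = 0.001
    # mapper block
    seed_len: int = 20
    max_mismatches: int = 3
    # screen block
    screen: scr.ScreenConfig = field(default_factory=lambda: scr.ScreenConfig(
        penetrance_min=0.9, absence_max_alt=2, min_absent_depth=5))
    min_alt_reads: int = 2
    min_alt_fraction: float = 0.2
    # structural block
    sv_min_len: int = 500
    sv_other_min_depth: float = 5.0
    sv_gap_join: int = 50
    sv_window: int = 100
    sv_z: float = 6.0
    # real mode
    sam_files: dict[str, list[str]] = field(default_factory=dict)
    reference_fasta: str | None = None
    gff3: str | None = None
    design: dict | None = None
    write_fastq: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        screen_raw = raw.pop("screen", None)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        if screen_raw:
            cfg.screen = scr.ScreenConfig(**screen_raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise ConfigError("simulate mode requires a seed")
        if self.mode == "real":
            if not self.reference_fasta or not self.sam_files:
                raise ConfigError("real mode requires reference_fasta and sam_files")
            for p in [self.reference_fasta, self.gff3, *(
                    f for lst in self.sam_files.values() for f in lst)]:
                if p and not os.path.exists(p):
                    raise ConfigError(f"input file missing: {p}")

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "screen"}
        payload["screen"] = self.screen.__dict__
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scenario construction (simulate mode)
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    reference: sim.ReferenceGenome
    truth: sim.TruthTable
    design: sim.PoolDesign
    models: list[ann.GeneModel]
    causative: dict[str, sim.MutationSpec]


def build_scenario(cfg: PipelineConfig, rng: np.random.Generator) -> Scenario:
    """The three-lineage, four-pool demonstration cross."""
    lens = [cfg.genome_length // cfg.n_contigs] * cfg.n_contigs
    lens[-1] += cfg.genome_length - sum(lens)
    genome = sim.generate_genome(cfg.n_contigs, lens, cfg.gc, rng=rng)
    contig = list(genome.contigs)[0]
    L = lens[0]

    # gene A: two introns; causative lesion of the spore-colour lineage is a
    # G->A transition in the first base of intron 2 (donor site)
    gA_start = L // 4
    # intron 2 is deliberately not a multiple of 3: its retention after a
    # donor-site hit frameshifts the peptide, as in the modelled mutant
    genome, gene_a = install_gene(genome, contig, gA_start,
                                  exon_lens=[300, 210, 240], intron_lens=[60, 74],
                                  rng=rng, gene_id="geneA")
    # gene B: single exon ending TGA, 106 sense codons + TAA downstream, so
    # the stop-loss A->G lesion extends the protein by 107 residues
    gB_start = L // 2
    genome, gene_b = install_gene(genome, contig, gB_start,
                                  exon_lens=[600], intron_lens=[], rng=rng,
                                  gene_id="geneB", stop_codon="TGA",
                                  downstream_sense_codons=106)

    intron2 = gene_a.introns_tx_order()[1]
    donor_pos = intron2[0]
    seq = genome.contigs[contig]
    assert seq[donor_pos] == "G"
    snp_colour = sim.MutationSpec("snp", contig, donor_pos, "G", "A",
                               lineage="colour", causative=True)
    stop_third = gene_b.exons[-1][1] - 1
    assert seq[stop_third] == "A" and seq[stop_third - 2 : stop_third + 1] == "TGA"
    snp_b = sim.MutationSpec("snp", contig, stop_third, "A", "G",
                             lineage="mutB", causative=True)
    # plain causative SNP for lineage mutA, away from the genes
    protect = [(gA_start - 200, gene_a.span[1] + 200),
               (gB_start - 200, gene_b.span[1] + 330 + 200)]
    snp_a = sim.random_snp_specs(genome, 1, rng, lineage="mutA", causative=True,
                                 exclude=protect, contig=contig)[0]
    protect2 = protect + [(snp_a.pos - 2, snp_a.pos + 2)]

    per_lineage = cfg.n_background // 3
    rest = cfg.n_background - 2 * per_lineage
    bg = []
    for lineage, n in (("mutA", per_lineage), ("colour", per_lineage), ("mutB", rest)):
        bg += sim.random_snp_specs(genome, n, rng, lineage=lineage, exclude=protect2)
        protect2 = protect2 + [(s.pos, s.pos + 1) for s in bg[-n:]]

    specs = [snp_a, snp_colour, snp_b] + bg
    _, truth = sim.plant_mutations(genome, specs, n_isolates=cfg.n_isolates)

    design = sim.PoolDesign(
        samples=["wt", "mutA_colour", "colour", "mutB"],
        lineages=["mutA", "colour", "mutB"],
        presence={
            "wt": {"mutA": "counterselected", "colour": "counterselected", "mutB": "counterselected"},
            "mutA_colour": {"mutA": "fixed", "colour": "fixed", "mutB": "absent"},
            "colour": {"mutA": "absent", "colour": "fixed", "mutB": "absent"},
            "mutB": {"mutA": "absent", "colour": "counterselected", "mutB": "fixed"},
        },
        n_isolates=cfg.n_isolates,
    )
    return Scenario(genome, truth, design, [gene_a, gene_b],
                    {"mutA": snp_a, "colour": snp_colour, "mutB": snp_b})


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    summaries: list[pl.SummaryStats]
    candidates: list[scr.CandidateMutation]
    structural: list[sv.StructuralCandidate]
    consequences: list[ann.Consequence]
    table3: list[dict]
    provenance: dict

    def pattern_candidates(self) -> list[scr.CandidateMutation]:
        return [c for c in self.candidates if c.classification == "pattern_candidate"]

    def reference_errors(self) -> list[scr.CandidateMutation]:
        return [c for c in self.candidates if c.classification == "reference_error"]


def _table3_rows(candidates: list[scr.CandidateMutation],
                 design: sim.PoolDesign,
                 consequences: dict[tuple, ann.Consequence]) -> list[dict]:
    """Per-genotype variant counts in the layout of the run-summary table."""
    rows = []
    patterns = {"wild type": frozenset(["wt"]) if "wt" in design.samples else None}
    for lineage in design.lineages:
        patterns[lineage] = design.expected_pattern(lineage)
    for label, pat in patterns.items():
        if pat is None:
            continue
        covered = []
        for c in candidates:
            presence = frozenset(s for s in design.samples
                                 if (c.site.alt_fraction(s) or 0.0) >= 0.2)
            if presence == pat and all(c.site.sufficient.get(s, False) for s in pat):
                covered.append(c)
        pen = [c for c in covered if c.classification == "pattern_candidate"
               and c.pattern == pat]
        notes = []
        for c in pen:
            q = consequences.get(c.site.key)
            if q is not None and q.category != "intergenic":
                notes.append(f"{q.category} of {q.gene_id}")
        rows.append({
            "genotype": label,
            "samples": ",".join(sorted(pat)),
            "n_variants_coverage_ok": len(covered),
            "n_full_penetrance": len(pen),
            "location": "; ".join(notes) if notes else "-",
        })
    return rows


def render_tables(report: RunReport) -> dict[str, str]:
    """Table-2- and Table-3-style TSV renderings plus a text digest."""
    t2 = ["sample\ttotal_reads\tread_length\ttotal_mb\tcoverage\tmapped_reads\tmapped_pct"]
    for s in report.summaries:
        t2.append(f"{s.sample_id}\t{s.total_reads}\t{s.read_length}\t{s.total_mb}\t"
                  f"{s.coverage:.0f}x\t{s.mapped_reads}\t{s.mapped_pct}")
    t3 = ["genotype\tsamples\tn_variants_coverage_ok\tn_full_penetrance\tlocation"]
    for r in report.table3:
        t3.append(f"{r['genotype']}\t{r['samples']}\t{r['n_variants_coverage_ok']}\t"
                  f"{r['n_full_penetrance']}\t{r['location']}")
    text = ["== sequencing summary =="] + t2 + ["", "== variant screen =="] + t3
    text += ["", f"pattern candidates: {len(report.pattern_candidates())}",
             f"reference errors:   {len(report.reference_errors())}",
             f"structural candidates: {len(report.structural)}"]
    return {"table2.tsv": "\n".join(t2) + "\n",
            "table3.tsv": "\n".join(t3) + "\n",
            "report.txt": "\n".join(text) + "\n"}


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _map_sample(cfg: PipelineConfig, index: mapping.ReferenceIndex,
                reads1: sim.ReadSet, reads2: sim.ReadSet):
    """clean -> map mates and singles -> pair -> counts."""
    c1, c2, singles, counts = mapping.clean_reads(reads1, reads2)
    al1 = mapping.map_reads(c1, index, cfg.seed_len, cfg.max_mismatches)
    al2 = mapping.map_reads(c2, index, cfg.seed_len, cfg.max_mismatches)
    als = mapping.map_reads(singles, index, cfg.seed_len, cfg.max_mismatches) \
        if len(singles) else None
    mapping.pair_inserts(al1, al2)
    mapped = len(al1) + len(al2) + (len(als) if als else 0)
    return al1, al2, als, counts, mapped


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> RunReport:
    """Execute every stage and write artifacts under ``cfg.outdir``.

    Deterministic for a fixed config: per-sample random streams are spawned
    from the master seed, so reruns are byte-identical apart from run
    timestamps (which are deliberately excluded from artifacts).
    """
    cfg.validate()
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)

    if cfg.mode == "simulate":
        return _run_simulate(cfg, outdir)
    return _run_real(cfg, outdir)


def _run_simulate(cfg: PipelineConfig, outdir: str) -> RunReport:
    master = np.random.SeedSequence(cfg.seed)
    ss = master.spawn(1 + 4)
    scenario = build_scenario(cfg, np.random.default_rng(ss[0]))
    reference = scenario.reference
    reference.to_fasta(os.path.join(outdir, "reference.fasta"))
    ann.write_gff3(scenario.models, os.path.join(outdir, "genes.gff3"))
    index = mapping.ReferenceIndex(reference, cfg.seed_len)

    pileups: dict[str, pl.Pileup] = {}
    summaries: list[pl.SummaryStats] = []
    pairs_by_sample: dict[str, tuple] = {}
    for si, sample in enumerate(scenario.design.samples):
        rng = np.random.default_rng(ss[1 + si])
        pool = sim.simulate_pool(scenario.truth, scenario.design, sample, rng=rng)
        r1, r2 = sim.simulate_reads(reference, pool, cfg.coverage, cfg.read_len,
                                    cfg.insert_mean, cfg.insert_sd, cfg.error_rate,
                                    cfg.n_rate, rng=rng)
        if cfg.write_fastq:
            r1.write_fastq(os.path.join(outdir, f"{sample}_1.fastq"))
            r2.write_fastq(os.path.join(outdir, f"{sample}_2.fastq"))
        al1, al2, als, counts, mapped = _map_sample(cfg, index, r1, r2)
        batches = [al1, al2] + ([als] if als else [])
        pileups[sample] = pl.build_pileup(sample, batches, reference)
        summaries.append(pl.sequencing_summary(
            sample, counts["retained_reads"], cfg.read_len, mapped, reference.total_length))
        pairs_by_sample[sample] = (al1, al2)

    scenario.truth.to_tsv(os.path.join(outdir, "truth.tsv"), scenario.design.samples)
    return _screen_and_report(cfg, outdir, reference, pileups, scenario.design,
                              scenario.models, summaries, pairs_by_sample,
                              mutant_samples=[s for s in scenario.design.samples if s != "wt"])


def _run_real(cfg: PipelineConfig, outdir: str) -> RunReport:
    reference = sim.ReferenceGenome.from_fasta(cfg.reference_fasta)
    if cfg.design is None:
        raise ConfigError("real mode requires a design block")
    design = sim.PoolDesign(**cfg.design)
    models = ann.load_gene_models(cfg.gff3, reference) if cfg.gff3 else []
    pileups = {}
    summaries = []
    for sample, paths in cfg.sam_files.items():
        recs = []
        for p in paths:
            recs.extend(mapping.import_sam(p, sample))
        pileups[sample] = pl.build_pileup(sample, [recs], reference)
        lens = [len(r.seq) for r in recs[:1000]]
        rl = int(round(np.mean(lens))) if lens else 0
        summaries.append(pl.sequencing_summary(sample, len(recs), rl, len(recs),
                                               reference.total_length))
    return _screen_and_report(cfg, outdir, reference, pileups, design, models,
                              summaries, {}, mutant_samples=list(pileups))


def _screen_and_report(cfg, outdir, reference, pileups, design, models, summaries,
                       pairs_by_sample, mutant_samples) -> RunReport:
    mean_cov = {s: p.mean_coverage() for s, p in pileups.items()}
    calls = scr.call_small_variants(pileups, cfg.min_alt_reads, cfg.min_alt_fraction)
    calls = scr.apply_coverage_filter(calls, mean_cov, cfg.screen)
    candidates = scr.screen_patterns(calls, design, cfg.screen)
    candidates = scr.flag_homopolymers(candidates, reference, cfg.screen)
    scr.write_vcf(candidates, list(design.samples), reference,
                  os.path.join(outdir, "variants.vcf"))

    structural: list[sv.StructuralCandidate] = []
    for sample in mutant_samples:
        structural += sv.find_uncovered_regions(
            pileups, sample, cfg.sv_min_len, cfg.sv_other_min_depth, cfg.sv_gap_join)
        if sample in pairs_by_sample:
            al1, al2 = pairs_by_sample[sample]
            structural += sv.insert_size_anomalies(
                al1, al2, cfg.insert_mean, cfg.insert_sd, cfg.sv_window, cfg.sv_z,
                target_sample=sample)
    sv.write_bed(structural, os.path.join(outdir, "structural.bed"))

    consequences: dict[tuple, ann.Consequence] = {}
    cons_list = []
    for cand in candidates:
        if cand.classification != "pattern_candidate":
            continue
        q = ann.classify_variant(cand.site, models, reference)
        consequences[cand.site.key] = q
        cons_list.append(q)
    with open(os.path.join(outdir, "consequences.tsv"), "w") as fh:
        fh.write("contig\tpos_1based\tcategory\tgene\tdetail\n")
        for q in cons_list:
            v = q.variant
            fh.write(f"{v.contig}\t{v.pos + 1}\t{q.category}\t{q.gene_id or '.'}\t{q.detail}\n")

    table3 = _table3_rows(candidates, design, consequences)
    report = RunReport(summaries, candidates, structural, cons_list, table3,
                       provenance={"config_digest": cfg.digest(), "seed": cfg.seed,
                                   "samples": list(design.samples)})
    for name, text in render_tables(report).items():
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write(text)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump({"provenance": report.provenance, "table3": table3,
                   "n_pattern_candidates": len(report.pattern_candidates()),
                   "n_reference_errors": len(report.reference_errors()),
                   "n_structural": len(structural)}, fh, indent=2)
    return report


# ---------------------------------------------------------------------------
# reference-error demonstration (shared defects in the mapping reference)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceErrorDemo:
    true_genome: sim.ReferenceGenome
    reference: sim.ReferenceGenome  # the defective assembly reads are mapped to
    defects: list[sim.MutationSpec]  # edits that turned the true genome into it
    candidates: list[scr.CandidateMutation]
    corrected: sim.ReferenceGenome


def _homopolymer_runs(seq: str, min_len: int, max_len: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i + 1
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if min_len <= j - i <= max_len:
            runs.append((i, j))
        i = j
    return runs


def reference_error_demo(
    seed: int,
    n_snp_defects: int = 30,
    n_indel_defects: int = 20,
    genome_length: int = 150_000,
    coverage: float = 40.0,
    read_len: int = 76,
    n_isolates: int = 40,
    error_rate: float = 0.002,
    use_sam_roundtrip: bool = True,
    workdir: str | None = None,
) -> ReferenceErrorDemo:
    """Plant shared assembly defects and verify the screen separates them.

    The sequenced pools all descend from the *true* genome; the mapping
    reference carries ``n_snp_defects`` substitution errors plus
    ``n_indel_defects`` single-base indels inside homopolymer runs (the
    signature error mode of pyrosequencing-derived assemblies).  Every
    defect should surface as a variant penetrant in *all* samples —
    a reference error, never a candidate mutation — and correcting the
    reference at those sites must reproduce the true genome.

    Reads are realigned to the defective reference with gapped alignments
    (via SAM import when ``use_sam_roundtrip``), since homopolymer-indel
    evidence requires CIGAR-level detail.
    """
    import tempfile

    ss = np.random.SeedSequence(seed).spawn(4)
    rng = np.random.default_rng(ss[0])
    true_genome = sim.generate_genome(1, [genome_length], 0.5, rng=rng)
    contig = list(true_genome.contigs)[0]
    seq = true_genome.contigs[contig]

    # keep defects out of the terminal zones: coverage there is inherently
    # thin (fragments must fit on the contig), so the screen correctly
    # refuses to classify such sites and the demonstration would conflate
    # two effects
    edge = 2000
    ins_runs = [r for r in _homopolymer_runs(seq, 3, 6) if edge < r[0] and r[1] < len(seq) - edge]
    del_runs = [r for r in _homopolymer_runs(seq, 4, 8) if edge < r[0] and r[1] < len(seq) - edge]
    rng.shuffle(ins_runs)
    rng.shuffle(del_runs)
    defects: list[sim.MutationSpec] = []
    used: list[tuple[int, int]] = []

    def free(s0: int, e0: int) -> bool:
        return all(e0 + 10 < s or e < s0 - 10 for s, e in used)

    half = n_indel_defects // 2
    for s0, e0 in ins_runs:
        if len(defects) >= half:
            break
        if free(s0, e0):
            defects.append(sim.MutationSpec("small_insertion", contig, e0 - 1,
                                            seq[e0 - 1], seq[s0], lineage="defect"))
            used.append((s0, e0))
    for s0, e0 in del_runs:
        if len(defects) >= n_indel_defects:
            break
        if free(s0, e0):
            defects.append(sim.MutationSpec("small_deletion", contig, s0, seq[s0],
                                            lineage="defect"))
            used.append((s0, e0))
    defects += sim.random_snp_specs(
        true_genome, n_snp_defects, rng, lineage="defect",
        exclude=[(s - 10, e + 10) for s, e in used] + [(0, edge), (len(seq) - edge, len(seq))])
    reference, _ = sim.plant_mutations(true_genome, defects)

    design = sim.PoolDesign(["s1", "s2"], ["dummy"],
                            {"s1": {"dummy": "fixed"}, "s2": {"dummy": "absent"}},
                            n_isolates=n_isolates)
    truth = sim.TruthTable([], n_isolates=n_isolates)
    piles: dict[str, pl.Pileup] = {}
    for i, sample in enumerate(design.samples):
        srng = np.random.default_rng(ss[1 + i])
        pool = sim.simulate_pool(truth, design, sample, rng=srng)
        r1, r2 = sim.simulate_reads(true_genome, pool, coverage, read_len,
                                    error_rate=error_rate, n_rate=0.0, rng=srng)
        recs = mapping.true_alignments(r1, reference, projection_specs=defects)
        recs += mapping.true_alignments(r2, reference, projection_specs=defects)
        if use_sam_roundtrip:
            with tempfile.TemporaryDirectory(dir=workdir) as td:
                sam = os.path.join(td, f"{sample}.sam")
                mapping.write_sam(recs, reference, sam)
                recs = mapping.import_sam(sam, sample)
        piles[sample] = pl.build_pileup(sample, [recs], reference)

    screen_cfg = scr.ScreenConfig(penetrance_min=0.9, absence_max_alt=2,
                                  min_absent_depth=5)
    calls = scr.call_small_variants(piles, min_alt_reads=2, min_alt_fraction=0.2)
    mean_cov = {s: p.mean_coverage() for s, p in piles.items()}
    calls = scr.apply_coverage_filter(calls, mean_cov, screen_cfg)
    candidates = scr.screen_patterns(calls, design, screen_cfg)
    candidates = scr.flag_homopolymers(candidates, reference, screen_cfg)
    errors = [c for c in candidates if c.classification == "reference_error"]
    corrected, _ = scr.apply_reference_corrections(reference, errors)
    return ReferenceErrorDemo(true_genome, reference, defects, candidates, corrected)


def defect_found(demo: ReferenceErrorDemo, defect: sim.MutationSpec) -> scr.CandidateMutation | None:
    """The reference-error candidate corresponding to a planted defect."""
    pos_ref = None
    for probe in (defect.pos, defect.pos - 1, defect.ref_span[1]):
        if 0 <= probe:
            pos_ref = sim.project_position(demo.defects, defect.contig, probe)
        if pos_ref is not None:
            break
    for cand in demo.candidates:
        if cand.classification != "reference_error":
            continue
        if cand.site.contig == defect.contig and abs(cand.site.pos - (pos_ref or -99)) <= 8:
            return cand
    return None


# ---------------------------------------------------------------------------
# dedicated structural demonstration (coverage-gap vs insert complementarity)
# ---------------------------------------------------------------------------

@dataclass
class StructuralDemo:
    reference: sim.ReferenceGenome
    lesion: sim.MutationSpec
    gaps: list[sv.StructuralCandidate]
    anomalies: list[sv.StructuralCandidate]


def structural_demo(
    balanced: bool,
    seed: int,
    genome_length: int = 100_000,
    del_len: int = 1100,
    coverage: float = 50.0,
    read_len: int = 76,
    insert_mean: int = 2000,
    insert_sd: int = 200,
    n_isolates: int = 40,
    min_len: int = 500,
    other_min_depth: float = 5.0,
    window: int = 100,
    z: float = 6.0,
) -> StructuralDemo:
    """Two-pool simulation of a kilobase lesion, fixed in the carrier pool.

    ``balanced=True`` plants a deletion whose interval is replaced by
    duplicated/inverted flanking copies of equal total length (detectable
    only as a coverage gap); ``balanced=False`` plants a plain deletion
    (detectable by both the gap scan and the insert-size screen).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss[0])
    genome = sim.generate_genome(1, [genome_length], 0.5, rng=rng)
    contig = list(genome.contigs)[0]
    start = genome_length // 2 - del_len // 2
    if balanced:
        lesion = sim.complex_replacement_spec(genome, contig, start, del_len, rng,
                                              lineage="sv", causative=True)
    else:
        lesion = sim.MutationSpec("large_deletion", contig, start,
                                  genome.contigs[contig][start : start + del_len],
                                  lineage="sv", causative=True)
    _, truth = sim.plant_mutations(genome, [lesion], n_isolates=n_isolates)
    design = sim.PoolDesign(["mut", "wt"], ["sv"],
                            {"mut": {"sv": "fixed"}, "wt": {"sv": "counterselected"}},
                            n_isolates=n_isolates)
    index = mapping.ReferenceIndex(genome, 20)
    piles = {}
    pairs = {}
    for i, sample in enumerate(design.samples):
        srng = np.random.default_rng(ss[1 + i])
        pool = sim.simulate_pool(truth, design, sample, rng=srng)
        r1, r2 = sim.simulate_reads(genome, pool, coverage, read_len, insert_mean,
                                    insert_sd, error_rate=0.002, n_rate=0.0, rng=srng)
        al1 = mapping.map_reads(r1, index)
        al2 = mapping.map_reads(r2, index)
        mapping.pair_inserts(al1, al2)
        piles[sample] = pl.build_pileup(sample, [al1, al2], genome)
        pairs[sample] = (al1, al2)
    gaps = sv.find_uncovered_regions(piles, "mut", min_len, other_min_depth)
    anomalies = sv.insert_size_anomalies(*pairs["mut"], insert_mean, insert_sd,
                                         window, z, target_sample="mut")
    return StructuralDemo(genome, lesion, gaps, anomalies)
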