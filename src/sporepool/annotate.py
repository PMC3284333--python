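"""Gene-model overlay and molecular-consequence computation.

Covers the consequence classes that matter for haploid mutant screens:
splice-donor/acceptor disruption (first/last two intron bases), stop-loss
with C-terminal extension to the next in-frame stop, frameshifting and
in-frame small indels, and kilobase deletions removing coding sequence.
Transcript-level effects of a broken donor site (intron retention, cryptic
5' site usage) are modelled explicitly, with the derived peptides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from ._seq import revcomp
from .mapping import ConsistencyError
from .simulate import MutationSpec, ReferenceGenome
from .screen import SiteCall

CATEGORIES = ("intergenic", "intronic", "splice_donor", "splice_acceptor", "synonymous",
              "missense", "nonsense", "stop_loss", "frameshift_indel", "inframe_indel",
              "cds_deletion")

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    """A coding gene: ordered CDS exons on one strand, 0-based half-open."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # genomic ascending

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e >= s2:
                raise ValueError(f"{self.gene_id}: exons overlap or touch")
        if any(e <= s for s, e in self.exons):
            raise ValueError(f"{self.gene_id}: empty exon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic-ascending inter-exon gaps."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def introns_tx_order(self) -> list[tuple[int, int]]:
        ivs = self.introns
        return ivs if self.strand == "+" else ivs[::-1]

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        seq = genome.contigs[self.contig]
        cat = "".join(seq[s:e] for s, e in self.exons)
        return cat if self.strand == "+" else revcomp(cat)

    def peptide(self, genome: ReferenceGenome) -> str:
        pep, _ = translate_cds(self.cds_sequence(genome))
        return pep

    def check_splice_sites(self, genome: ReferenceGenome) -> None:
        seq = genome.contigs[self.contig]
        for s, e in self.introns:
            intron = seq[s:e] if self.strand == "+" else revcomp(seq[s:e])
            if not (intron.startswith("GT") and intron.endswith("AG")):
                warnings.warn(f"{self.gene_id}: non-canonical intron {s}-{e}")

    def cds_index_of(self, pos: int) -> int | None:
        """Map a genomic position inside an exon to its 0-based CDS index."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                idx = off + (pos - s)
                if self.strand == "+":
                    return idx
                total = sum(e2 - s2 for s2, e2 in self.exons)
                return total - 1 - idx
            off += e - s
        return None


def translate_cds(cds: str, table: int = 1) -> tuple[str, bool]:
    """Translate to the first stop; returns (peptide, stop_found)."""
    usable = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(usable).translate(table=table))
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], True
    return aa, False


@dataclass
class Consequence:
    variant: object
    category: str
    gene_id: str | None = None
    detail: str = ""


def _variant_fields(variant) -> tuple[str, int, str, str, int]:
    """(contig, pos, kind, alt, ref_span_len) for SiteCall or MutationSpec."""
    if isinstance(variant, MutationSpec):
        kind = {"snp": "snp", "small_insertion": "ins", "small_deletion": "del",
                "large_deletion": "del", "complex_replacement": "del"}[variant.kind]
        span = variant.ref_span
        alt = variant.alt_allele
        return variant.contig, variant.pos, kind, alt, span[1] - span[0]
    sc: SiteCall = variant
    if sc.var_type == "snp":
        return sc.contig, sc.pos, "snp", str(sc.alt), 1
    if sc.var_type == "ins":
        return sc.contig, sc.pos, "ins", str(sc.alt), 1
    return sc.contig, sc.pos, "del", "", int(sc.alt)


def classify_variant(
    variant,
    models: Sequence[GeneModel],
    genome: ReferenceGenome,
) -> Consequence:
    """Assign exactly one consequence category to a variant.

    The category follows from coordinates, alleles and the gene model
    alone: splice_donor iff a SNP hits the first two transcribed intron
    bases (acceptor: the last two); stop_loss iff a SNP turns the CDS stop
    into a sense codon; deletions overlapping coding sequence are
    cds_deletion (small in-frame/frameshift indels are reported as such);
    exonic SNPs are classified by codon comparison on the coding strand.
    """
    contig, pos, kind, alt, span_len = _variant_fields(variant)
    if contig not in genome.contigs:
        raise ConsistencyError(f"variant contig {contig!r} not in genome")
    var_iv = (pos, pos + span_len)
    for model in models:
        if model.contig != contig:
            continue
        g0, g1 = model.span
        if var_iv[1] <= g0 or var_iv[0] >= g1:
            continue
        return _classify_in_gene(variant, model, genome, contig, pos, kind, alt, span_len)
    return Consequence(variant, "intergenic")


def _classify_in_gene(variant, model, genome, contig, pos, kind, alt, span_len) -> Consequence:
    seq = genome.contigs[contig]
    gid = model.gene_id

    if kind == "del" and span_len > 3:
        if any(s < pos + span_len and e > pos for s, e in model.exons):
            return Consequence(variant, "cds_deletion", gid,
                               f"deletes {span_len} b overlapping CDS")
        return Consequence(variant, "intronic", gid, "large intragenic non-coding deletion")

    if kind in ("ins", "del"):
        hit_pos = pos if kind == "del" else pos  # insertion anchored after pos
        in_exon = any(s <= hit_pos < e for s, e in model.exons)
        if kind == "ins":
            in_exon = any(s <= pos < e - 1 for s, e in model.exons)  # between two exon bases
        if not in_exon:
            return _intron_site(variant, model, pos, gid)
        length = span_len if kind == "del" else len(alt)
        if length % 3 == 0:
            return Consequence(variant, "inframe_indel", gid, f"{kind} of {length} b, in frame")
        return Consequence(variant, "frameshift_indel", gid, f"{kind} of {length} b shifts frame")

    # SNP
    for ti, (s, e) in enumerate(model.introns_tx_order(), start=1):
        if not s <= pos < e:
            continue
        if model.strand == "+":
            donor = (s, s + 1)
            acceptor = (e - 2, e - 1)
        else:
            donor = (e - 1, e - 2)
            acceptor = (s + 1, s)
        if pos in donor:
            offset = donor.index(pos) + 1
            return Consequence(variant, "splice_donor", gid,
                               f"intron {ti}, donor base {offset}, "
                               f"{seq[pos]}->{alt}")
        if pos in acceptor:
            offset = acceptor.index(pos) + 1
            return Consequence(variant, "splice_acceptor", gid,
                               f"intron {ti}, acceptor base {offset}")
        return Consequence(variant, "intronic", gid, f"intron {ti}")

    cds_idx = model.cds_index_of(pos)
    if cds_idx is None:
        return Consequence(variant, "intergenic")
    cds = model.cds_sequence(genome)
    ci = cds_idx // 3
    within = cds_idx % 3
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        return Consequence(variant, "missense", gid, "partial terminal codon")
    base = alt if model.strand == "+" else revcomp(alt)
    mut = codon[:within] + base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_mut = str(Seq(mut).translate())
    det = f"codon {ci + 1} {codon}->{mut} ({aa_ref}->{aa_mut})"
    if aa_ref == "*" and aa_mut != "*":
        return Consequence(variant, "stop_loss", gid, det)
    if aa_mut == "*" and aa_ref != "*":
        return Consequence(variant, "nonsense", gid, det)
    if aa_ref == aa_mut:
        return Consequence(variant, "synonymous", gid, det)
    return Consequence(variant, "missense", gid, det)


def _intron_site(variant, model, pos, gid) -> Consequence:
    for ti, (s, e) in enumerate(model.introns_tx_order(), start=1):
        if s <= pos < e:
            return Consequence(variant, "intronic", gid, f"intron {ti}")
    return Consequence(variant, "intronic", gid, "non-coding within gene span")


# ---------------------------------------------------------------------------
# stop-loss extension
# ---------------------------------------------------------------------------

@dataclass
class StopLossExtension:
    n_aa: int
    peptide: str
    runs_off_contig: bool = False


def stop_loss_extension(
    model: GeneModel,
    genome: ReferenceGenome,
    include_mutated_codon: bool = True,
) -> StopLossExtension:
    """Length of the C-terminal extension after a stop-loss mutation.

    ``genome`` must already carry the mutation.  Translation proceeds in
    frame from the (former) stop codon through downstream genomic sequence
    to the next in-frame stop.  By default the residue encoded by the
    mutated stop codon counts toward the extension and the new terminal
    stop does not; ``include_mutated_codon=False`` gives the other
    convention (one fewer residue).
    """
    seq = genome.contigs[model.contig]
    if model.strand == "+":
        stop_start = model.exons[-1][1] - 3
        tail = seq[stop_start:]
    else:
        stop_end = model.exons[0][0] + 3
        tail = revcomp(seq[:stop_end])
    first = tail[:3]
    if first in STOPS:
        raise ValueError("terminal codon is still a stop; not a stop-loss genome")
    aa, found = translate_cds(tail)
    if not found:
        return StopLossExtension(len(aa) - (0 if include_mutated_codon else 1), aa,
                                 runs_off_contig=True)
    n = len(aa) if include_mutated_codon else len(aa) - 1
    return StopLossExtension(n, aa)


def scan_next_inframe_stop(seq: str, start: int) -> int | None:
    """Brute-force index (codon count) of the first in-frame stop from
    ``start``; independent oracle for :func:`stop_loss_extension`."""
    i = start
    count = 0
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOPS:
            return count
        count += 1
        i += 3
    return None


# ---------------------------------------------------------------------------
# splice-defect transcripts
# ---------------------------------------------------------------------------

@dataclass
class TranscriptVariant:
    name: str
    cds: str
    peptide: str
    premature_stop: bool
    frameshift: bool
    diverges_at_aa: int | None  # 0-based first differing residue vs wild type


def _spliced_cds(model: GeneModel, seq: str, removed: list[tuple[int, int]]) -> str:
    """Gene-span sequence with ``removed`` genomic intervals spliced out."""
    g0, g1 = model.span
    keep = []
    cur = g0
    for s, e in sorted(removed):
        if s < cur:
            raise ValueError("overlapping splice intervals")
        keep.append(seq[cur:s])
        cur = e
    keep.append(seq[cur:g1])
    cat = "".join(keep)
    return cat if model.strand == "+" else revcomp(cat)


def splice_defect_transcripts(
    model: GeneModel,
    genome: ReferenceGenome,
    disrupted_intron: int,
    cryptic_donor: int | None = None,
) -> list[TranscriptVariant]:
    """Transcripts produced when one donor site is destroyed.

    ``disrupted_intron`` is a 0-based index in transcription order.  Always
    emits the retention transcript (that intron kept, all others spliced);
    if ``cryptic_donor`` (genomic coordinate of the first base of the new
    intron on the plus strand, or its last base for minus-strand genes) is
    given, also the transcript spliced from the cryptic 5' site to the
    intron's normal acceptor.  Peptides are translated from the model's
    start codon; frameshifts are reported with the residue where the
    peptide diverges from wild type.
    """
    introns_tx = model.introns_tx_order()
    if not 0 <= disrupted_intron < len(introns_tx):
        raise ValueError("disrupted_intron out of range")
    seq = genome.contigs[model.contig]
    wt_pep = model.peptide(genome)
    bad = introns_tx[disrupted_intron]
    out: list[TranscriptVariant] = []

    removed = [iv for iv in model.introns if iv != bad]
    out.append(_mk_variant("retention", model, seq, removed, bad[1] - bad[0], wt_pep))

    if cryptic_donor is not None:
        g0, g1 = model.span
        if not g0 <= cryptic_donor < g1:
            raise ValueError("cryptic_donor outside gene span")
        if model.strand == "+":
            new_iv = (cryptic_donor, bad[1])
        else:
            new_iv = (bad[0], cryptic_donor + 1)
        if new_iv[1] <= new_iv[0]:
            raise ValueError("cryptic donor does not define a valid intron")
        removed_c = sorted([iv for iv in model.introns if iv != bad] + [new_iv])
        spliced_extra = (new_iv[1] - new_iv[0]) - (bad[1] - bad[0])
        out.append(_mk_variant("cryptic_donor", model, seq, removed_c, -spliced_extra, wt_pep))
    return out


def _mk_variant(name, model, seq, removed, length_change, wt_pep) -> TranscriptVariant:
    cds = _spliced_cds(model, seq, removed)
    pep, stop = translate_cds(cds)
    div = None
    for i, (a, b) in enumerate(zip(pep, wt_pep)):
        if a != b:
            div = i
            break
    if div is None and len(pep) != len(wt_pep):
        div = min(len(pep), len(wt_pep))
    return TranscriptVariant(name, cds, pep, premature_stop=stop and len(pep) < len(wt_pep),
                             frameshift=length_change % 3 != 0, diverges_at_aa=div)


# ---------------------------------------------------------------------------
# GFF3 import
# ---------------------------------------------------------------------------

def load_gene_models(path: str, genome: ReferenceGenome | None = None) -> list[GeneModel]:
    """Read coding gene models from GFF3 (gene/mRNA/CDS rows).

    GFF 1-based inclusive coordinates become 0-based half-open.  Models
    whose spliced CDS is not a multiple of three, or whose introns are not
    GT..AG, draw a warning but are kept.
    """
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas or [gene]
        for parent in parents:
            cds = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
            if not cds:
                continue
            exons = [(f.start - 1, f.end) for f in cds]
            gid = gene.id if len(parents) == 1 else parent.id
            model = GeneModel(gid, gene.seqid, gene.strand, exons)
            if genome is not None:
                if model.contig not in genome.contigs:
                    warnings.warn(f"{gid}: contig {model.contig!r} not in genome")
                    continue
                if model.span[1] > len(genome.contigs[model.contig]):
                    warnings.warn(f"{gid}: model extends past contig end")
                    continue
                if sum(e - s for s, e in exons) % 3 != 0:
                    warnings.warn(f"{gid}: CDS length not a multiple of 3")
                model.check_splice_sites(genome)
            models.append(model)
    return models


def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.span
            fh.write(f"{m.contig}\tsporepool\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{m.contig}\tsporepool\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.t1;Parent={m.gene_id}\n")
            phase = 0
            exons = m.exons if m.strand == "+" else m.exons[::-1]
            for s, e in exons:
                fh.write(f"{m.contig}\tsporepool\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                         f"ID=cds-{m.gene_id};Parent={m.gene_id}.t1\n")
                phase = (3 - ((e - s) - phase) % 3) % 3
    return None
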