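"""Synthetic cross / pool / read simulator with ground truth.

Emulates the experimental design of bulked-segregant mutation mapping in a
haploid fungus: mutant lineages carry EMS-style lesions (transition-biased
SNPs, sub-4-base indels, kilobase deletions and deletion-replaced-by-
duplicated-flank rearrangements); phenotype-selected pools of haploid
single-spore isolates fix the causative locus while unselected background
lesions segregate 1:1; paired reads are drawn from ~2-kb fragments with
substitution errors and occasional undetermined ('N') bases.

Every planted lesion is recorded in a :class:`TruthTable` keyed to
coordinates on the unmodified reference, so downstream detectors can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, TRANSITION, decode, encode, revcomp, revcomp_arr

SMALL_INDEL_MAX = 3  # indels of < 4 bases count as "small"
LARGE_DELETION_MIN = 500

KINDS = ("snp", "small_insertion", "small_deletion", "large_deletion", "complex_replacement")
PRESENCE_STATES = ("fixed", "segregating", "absent", "counterselected")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Named contigs over the {A,C,G,T,N} alphabet."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        allowed = set("ACGTN")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            extra = set(seq) - allowed
            if extra:
                raise ValueError(f"contig {name!r} contains invalid bases {sorted(extra)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def to_fasta(self, path: str) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        return cls(contigs)


@dataclass(frozen=True)
class MutationSpec:
    """A planted lesion, in coordinates of the unmodified reference.

    ``pos`` is 0-based.  Conventions per kind:

    * ``snp`` — ``ref_allele``/``alt_allele`` are single bases.
    * ``small_insertion`` — ``alt_allele`` (1-3 b) is inserted *after* ``pos``;
      ``ref_allele`` is the anchor base at ``pos``.
    * ``small_deletion`` — ``ref_allele`` (1-3 b) is removed starting at
      ``pos``; ``alt_allele`` is empty.
    * ``large_deletion`` — as small_deletion but >= 500 b.
    * ``complex_replacement`` — the interval ``[pos, pos+len(ref_allele))`` is
      removed and replaced by concatenated copies of flanking source
      intervals listed in ``replacement_plan`` (reference coordinates;
      orientation ``"+"`` or ``"-"`` for an inverted copy).
    """

    kind: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str = ""
    replacement_plan: tuple[tuple[int, int, str], ...] = ()
    lineage: str = ""
    causative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp alt equals ref")
        elif self.kind == "small_insertion":
            if not 1 <= len(self.alt_allele) <= SMALL_INDEL_MAX:
                raise ValueError("small insertions are 1-3 bases")
        elif self.kind == "small_deletion":
            if not 1 <= len(self.ref_allele) <= SMALL_INDEL_MAX:
                raise ValueError("small deletions are 1-3 bases")
        elif self.kind == "large_deletion":
            if len(self.ref_allele) < LARGE_DELETION_MIN:
                raise ValueError(f"large deletions are >= {LARGE_DELETION_MIN} b")
        elif self.kind == "complex_replacement":
            if not self.replacement_plan:
                raise ValueError("complex_replacement requires a replacement_plan")
            for s, e, o in self.replacement_plan:
                if e <= s or o not in "+-":
                    raise ValueError("replacement_plan segments are (start, end, '+'|'-')")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval [start, end) occupied by the lesion."""
        if self.kind in ("snp", "small_insertion"):
            return self.pos, self.pos + 1
        return self.pos, self.pos + len(self.ref_allele)

    @property
    def length_change(self) -> int:
        if self.kind == "snp":
            return 0
        if self.kind == "small_insertion":
            return len(self.alt_allele)
        if self.kind == "complex_replacement":
            ins = sum(e - s for s, e, _ in self.replacement_plan)
            return ins - len(self.ref_allele)
        return -len(self.ref_allele)


@dataclass
class PoolDesign:
    """Which lineages each sequenced pool carries and how they were selected.

    ``presence[sample][lineage]`` is one of:

    * ``fixed`` — the lineage's phenotype was selected for: its causative
      lesion is carried by all isolates; its background lesions segregate 1:1.
    * ``counterselected`` — the lineage entered the cross but the wild-type
      allele was selected: causative absent, background segregates 1:1.
    * ``segregating`` — lineage in the cross, no selection at all: causative
      and background both segregate 1:1.
    * ``absent`` — lineage not in this pool's pedigree at all.
    """

    samples: list[str]
    lineages: list[str]
    presence: dict[str, dict[str, str]]
    n_isolates: int = 40

    def __post_init__(self) -> None:
        if self.n_isolates <= 0:
            raise ValueError("n_isolates must be positive")
        for s in self.samples:
            row = self.presence.get(s)
            if row is None:
                raise ValueError(f"no presence row for sample {s!r}")
            for l in self.lineages:
                state = row.get(l)
                if state not in PRESENCE_STATES:
                    raise ValueError(f"presence[{s!r}][{l!r}] = {state!r} invalid")

    def expected_pattern(self, lineage: str) -> frozenset[str]:
        """Samples in which the lineage's causative lesion is fixed."""
        return frozenset(s for s in self.samples if self.presence[s][lineage] == "fixed")

    def causative_count(self, sample: str, lineage: str, rng: np.random.Generator) -> int:
        state = self.presence[sample][lineage]
        if state == "fixed":
            return self.n_isolates
        if state == "segregating":
            return int(rng.binomial(self.n_isolates, 0.5))
        return 0

    def background_count(self, sample: str, lineage: str, rng: np.random.Generator) -> int:
        state = self.presence[sample][lineage]
        if state == "absent":
            return 0
        return int(rng.binomial(self.n_isolates, 0.5))


@dataclass
class TruthRecord:
    spec: MutationSpec
    counts: dict[str, int] = field(default_factory=dict)

    def expected_frequency(self, sample: str, n_isolates: int) -> float:
        return self.counts.get(sample, 0) / n_isolates


@dataclass
class TruthTable:
    """Ground truth: planted lesions plus realised per-pool isolate counts."""

    records: list[TruthRecord]
    n_isolates: int = 40

    @property
    def specs(self) -> list[MutationSpec]:
        return [r.spec for r in self.records]

    def causative(self) -> list[TruthRecord]:
        return [r for r in self.records if r.spec.causative]

    def to_tsv(self, path: str, samples: Sequence[str]) -> None:
        with open(path, "w") as fh:
            cols = ["contig", "pos_0based", "kind", "ref", "alt", "lineage", "causative"]
            cols += [f"count_{s}" for s in samples]
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                sp = r.spec
                row = [sp.contig, str(sp.pos), sp.kind, sp.ref_allele or ".", sp.alt_allele or ".",
                       sp.lineage, "1" if sp.causative else "0"]
                row += [str(r.counts.get(s, 0)) for s in samples]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# genome generation and mutation planting
# ---------------------------------------------------------------------------

def generate_genome(
    n_contigs: int,
    lengths: Sequence[int],
    gc: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceGenome:
    """Draw a random haploid reference of ``n_contigs`` i.i.d. contigs.

    Base probabilities are ``gc/2`` for each of G and C and ``(1-gc)/2`` for
    each of A and T; deterministic for a fixed seed.
    """
    if n_contigs != len(lengths):
        raise ValueError("n_contigs must equal len(lengths)")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for i, length in enumerate(lengths):
        arr = BASES[rng.choice(4, size=length, p=p)]
        contigs[f"contig_{i + 1}"] = decode(arr)
    return ReferenceGenome(contigs)


def _build_alt(seq: str, spec: MutationSpec) -> str:
    if spec.kind == "complex_replacement":
        parts = []
        for s, e, orient in spec.replacement_plan:
            seg = seq[s:e]
            parts.append(seg if orient == "+" else revcomp(seg))
        return "".join(parts)
    return spec.alt_allele


def _check_specs(genome: ReferenceGenome, specs: Sequence[MutationSpec]) -> None:
    by_contig: dict[str, list[MutationSpec]] = {}
    for sp in specs:
        seq = genome.contigs.get(sp.contig)
        if seq is None:
            raise ValueError(f"spec on unknown contig {sp.contig!r}")
        s, e = sp.ref_span
        if e > len(seq):
            raise ValueError(f"spec at {sp.contig}:{sp.pos} extends past contig end")
        if sp.kind == "snp":
            if seq[sp.pos] != sp.ref_allele:
                raise ValueError(
                    f"ref mismatch at {sp.contig}:{sp.pos}: genome has "
                    f"{seq[sp.pos]!r}, spec says {sp.ref_allele!r}")
        elif sp.kind == "small_insertion":
            if sp.ref_allele and seq[sp.pos] != sp.ref_allele:
                raise ValueError(f"insertion anchor mismatch at {sp.contig}:{sp.pos}")
        else:
            if seq[s:e] != sp.ref_allele:
                raise ValueError(f"ref mismatch at {sp.contig}:{sp.pos} ({sp.kind})")
        by_contig.setdefault(sp.contig, []).append(sp)
    for contig, lst in by_contig.items():
        lst.sort(key=lambda sp: sp.ref_span)
        for a, b in zip(lst, lst[1:]):
            if a.ref_span[1] > b.ref_span[0]:
                raise ValueError(f"overlapping specs on {contig}: {a.pos} and {b.pos}")


def apply_specs(seq: str, specs: Sequence[MutationSpec]) -> str:
    """Apply non-overlapping specs (all on one contig) in descending order."""
    buf = bytearray(seq, "ascii")
    for sp in sorted(specs, key=lambda s: s.pos, reverse=True):
        if sp.kind == "snp":
            buf[sp.pos] = ord(sp.alt_allele)
        elif sp.kind == "small_insertion":
            buf[sp.pos + 1 : sp.pos + 1] = sp.alt_allele.encode()
        else:
            alt = _build_alt(seq, sp)
            s, e = sp.ref_span
            buf[s:e] = alt.encode()
    return buf.decode("ascii")


def plant_mutations(
    genome: ReferenceGenome, specs: Sequence[MutationSpec], n_isolates: int = 40
) -> tuple[ReferenceGenome, TruthTable]:
    """Apply lesions to a copy of ``genome``; record them in a TruthTable.

    Truth coordinates always refer to the unmodified reference.  Specs must
    be non-overlapping and match the reference at their position.
    """
    _check_specs(genome, specs)
    mutant = {}
    for contig, seq in genome.contigs.items():
        here = [sp for sp in specs if sp.contig == contig]
        mutant[contig] = apply_specs(seq, here) if here else seq
    truth = TruthTable([TruthRecord(sp) for sp in specs], n_isolates=n_isolates)
    return ReferenceGenome(mutant), truth


def project_position(specs: Sequence[MutationSpec], contig: str, pos: int) -> int | None:
    """Map a reference position to the mutant coordinate system.

    Returns None for positions inside a deleted/replaced interval.
    """
    shift = 0
    for sp in sorted((s for s in specs if s.contig == contig), key=lambda s: s.pos):
        s, e = sp.ref_span
        if sp.kind == "snp":
            continue
        if sp.kind == "small_insertion":
            if pos > sp.pos:
                shift += len(sp.alt_allele)
            continue
        if pos >= e:
            shift += sp.length_change
        elif pos >= s:
            return None
    return pos + shift


# ---------------------------------------------------------------------------
# random lesion factories (EMS spectrum)
# ---------------------------------------------------------------------------

def random_snp_specs(
    genome: ReferenceGenome,
    n: int,
    rng: np.random.Generator,
    lineage: str = "",
    transition_fraction: float = 0.9,
    causative: bool = False,
    exclude: Iterable[tuple[int, int]] = (),
    contig: str | None = None,
) -> list[MutationSpec]:
    """Draw ``n`` random SNPs, transition-biased as expected after EMS.

    ``exclude`` lists reference intervals (on the chosen contig) that must
    stay untouched; positions are drawn without replacement genome-wide.
    """
    names = [contig] if contig else list(genome.contigs)
    lens = np.array([len(genome.contigs[c]) for c in names])
    specs: list[MutationSpec] = []
    used: set[tuple[str, int]] = set()
    excl = list(exclude)
    attempts = 0
    while len(specs) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place requested SNPs (too many exclusions?)")
        ci = int(rng.choice(len(names), p=lens / lens.sum()))
        cname = names[ci]
        pos = int(rng.integers(0, lens[ci]))
        if (cname, pos) in used or any(s <= pos < e for s, e in excl):
            continue
        ref = genome.contigs[cname][pos]
        if ref == "N":
            continue
        if rng.random() < transition_fraction:
            alt = TRANSITION[ref]
        else:
            choices = [b for b in "ACGT" if b != ref and b != TRANSITION[ref]]
            alt = choices[int(rng.integers(0, len(choices)))]
        used.add((cname, pos))
        specs.append(MutationSpec("snp", cname, pos, ref, alt, lineage=lineage, causative=causative))
    return specs


def complex_replacement_spec(
    genome: ReferenceGenome,
    contig: str,
    start: int,
    del_len: int,
    rng: np.random.Generator,
    lineage: str = "",
    causative: bool = True,
    n_segments: int = 4,
    invert_one: bool = True,
) -> MutationSpec:
    """Plan a deletion replaced by duplicated (one optionally inverted)
    copies of flanking sequence of approximately the deleted length.

    Mirrors the balanced rearrangement in which the locus keeps its overall
    length, so spanning mate-pair inserts look normal while the deleted
    interval itself has zero read coverage in the carrier.
    """
    seq = genome.contigs[contig]
    end = start + del_len
    if end > len(seq):
        raise ValueError("deletion extends past contig end")
    seg_len = del_len // n_segments
    plan: list[tuple[int, int, str]] = []
    for i in range(n_segments):
        want = seg_len if i < n_segments - 1 else del_len - seg_len * (n_segments - 1)
        # duplicated source regions alternate between the two flanks, as in
        # the rearranged locus this models; one-sided sourcing would make
        # the lesion a plain tandem-shift and defeat its balanced character
        if i % 2 == 0 and start - want >= 0:
            s = int(rng.integers(max(0, start - 3 * want), start - want + 1))
        else:
            s = int(rng.integers(end, min(len(seq) - want, end + 3 * want) + 1))
        orient = "-" if (invert_one and i == n_segments // 2) else "+"
        plan.append((s, s + want, orient))
    return MutationSpec(
        "complex_replacement", contig, start, seq[start:end],
        replacement_plan=tuple(plan), lineage=lineage, causative=causative,
    )


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

@dataclass
class PoolGenotype:
    """Realised genotype composition of one sequenced pool.

    ``counts[i]`` is the number of isolates carrying spec ``i`` of the truth
    table; ``carriers[i]`` lists those isolates' indices.
    """

    sample: str
    n_isolates: int
    counts: np.ndarray
    carriers: list[np.ndarray]
    truth: TruthTable


def simulate_pool(
    truth: TruthTable,
    design: PoolDesign,
    sample: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PoolGenotype:
    """Draw the isolate composition of one phenotype-selected pool.

    Causative lesions follow the selection regime of the design; every
    background lesion of a lineage present in the cross is carried by
    Binomial(n, 1/2) isolates, independently (loci treated as unlinked).
    Realised counts are recorded back into the truth table.
    """
    if sample not in design.samples:
        raise ValueError(f"sample {sample!r} not in design")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = design.n_isolates
    counts = np.zeros(len(truth.records), dtype=np.int64)
    carriers: list[np.ndarray] = []
    for i, rec in enumerate(truth.records):
        sp = rec.spec
        if sp.lineage not in design.lineages:
            raise ValueError(f"spec lineage {sp.lineage!r} not in design")
        if sp.causative:
            c = design.causative_count(sample, sp.lineage, rng)
        else:
            c = design.background_count(sample, sp.lineage, rng)
        counts[i] = c
        if c == n:
            idx = np.arange(n)
        elif c == 0:
            idx = np.empty(0, dtype=np.int64)
        else:
            idx = rng.choice(n, size=c, replace=False)
        carriers.append(np.sort(idx))
        rec.counts[sample] = c
    return PoolGenotype(sample, n, counts, carriers, truth)


def isolate_genomes(genome: ReferenceGenome, pool: PoolGenotype) -> list[ReferenceGenome]:
    """Materialise the haploid genome of every isolate in the pool."""
    specs = pool.truth.specs
    out = []
    for iso in range(pool.n_isolates):
        mine = [sp for i, sp in enumerate(specs) if iso in pool.carriers[i]]
        mut = {}
        for contig, seq in genome.contigs.items():
            here = [sp for sp in mine if sp.contig == contig]
            mut[contig] = apply_specs(seq, here) if here else seq
        out.append(ReferenceGenome(mut))
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """A batch of same-length reads held as a uint8 matrix.

    Truth provenance (sample, isolate, source contig, fragment interval in
    the isolate's own coordinates, mate index) is carried in parallel arrays
    and serialised into read names as
    ``sim:<sample>:<isolate>:<contig>:<frag_start>:<frag_end>/<mate>``.
    """

    seqs: np.ndarray  # (N, L) uint8
    sample: str
    contig_names: list[str]
    contig_idx: np.ndarray  # (N,) int32
    frag_start: np.ndarray  # (N,) int64, isolate-genome coords
    frag_end: np.ndarray
    isolate: np.ndarray  # (N,) int32
    mate: np.ndarray  # (N,) int8: 1 or 2; 0 for unpaired

    def __len__(self) -> int:
        return int(self.seqs.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1]) if len(self) else 0

    def name(self, i: int) -> str:
        return (f"sim:{self.sample}:{self.isolate[i]}:"
                f"{self.contig_names[self.contig_idx[i]]}:{self.frag_start[i]}:{self.frag_end[i]}")

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.seqs[mask], self.sample, self.contig_names,
                       self.contig_idx[mask], self.frag_start[mask], self.frag_end[mask],
                       self.isolate[mask], self.mate[mask])

    def write_fastq(self, path: str) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                suffix = f"/{self.mate[i]}" if self.mate[i] else ""
                fh.write(f"@{self.name(i)}{suffix}\n{decode(self.seqs[i])}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path: str, sample: str = "") -> "ReadSet":
        names, seqs = [], []
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(path) as fh:
            for title, seq, _ in FastqGeneralIterator(fh):
                names.append(title.split()[0])
                seqs.append(seq.upper())
        if not seqs:
            raise ValueError(f"no reads in {path}")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("reads must be uniform length")
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L).copy()
        return cls._from_names(mat, names, sample)

    @classmethod
    def _from_names(cls, mat: np.ndarray, names: list[str], sample: str) -> "ReadSet":
        n = len(names)
        cidx = np.zeros(n, dtype=np.int32)
        fs = np.zeros(n, dtype=np.int64)
        fe = np.zeros(n, dtype=np.int64)
        iso = np.full(n, -1, dtype=np.int32)
        mate = np.zeros(n, dtype=np.int8)
        cnames: list[str] = []
        cmap: dict[str, int] = {}
        for i, nm in enumerate(names):
            body, _, m = nm.partition("/")
            mate[i] = int(m) if m in ("1", "2") else 0
            parts = body.split(":")
            if len(parts) == 6 and parts[0] == "sim":
                _, smp, isol, contig, s, e = parts
                sample = sample or smp
                if contig not in cmap:
                    cmap[contig] = len(cnames)
                    cnames.append(contig)
                cidx[i] = cmap[contig]
                fs[i], fe[i], iso[i] = int(s), int(e), int(isol)
        if not cnames:
            cnames = ["?"]
        return cls(mat, sample, cnames, cidx, fs, fe, iso, mate)


def simulate_reads(
    genome: ReferenceGenome,
    pool: PoolGenotype,
    coverage: float,
    read_len: int = 76,
    insert_mean: int = 2000,
    insert_sd: int = 200,
    error_rate: float = 0.002,
    n_rate: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReadSet, ReadSet]:
    """Draw mate pairs from ~``insert_mean``-base fragments of pool isolates.

    Fragments are apportioned to isolates uniformly and placed uniformly
    along each isolate's contigs (length-weighted); mate 1 reads the
    fragment 5' end on the forward strand, mate 2 the 3' end reverse-
    complemented.  Substitution errors are i.i.d. at ``error_rate``; every
    base is independently replaced by 'N' at ``n_rate``.  Total emitted
    bases approximate ``coverage``x the reference length.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    for r in (error_rate, n_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)

    genomes = isolate_genomes(genome, pool)
    n_iso = pool.n_isolates
    total_pairs = int(round(coverage * genome.total_length / (2 * read_len)))
    per_iso = rng.multinomial(total_pairs, np.full(n_iso, 1.0 / n_iso))
    contig_names = list(genome.contigs)

    chunks1, chunks2 = [], []
    meta_c, meta_s, meta_e, meta_i = [], [], [], []
    for iso in range(n_iso):
        npairs = int(per_iso[iso])
        if npairs == 0:
            continue
        g = genomes[iso]
        lens = np.array([len(g.contigs[c]) for c in contig_names], dtype=np.int64)
        ccount = rng.multinomial(npairs, lens / lens.sum())
        for ci, cn in enumerate(contig_names):
            m = int(ccount[ci])
            if m == 0:
                continue
            arr = encode(g.contigs[cn])
            L = lens[ci]
            flen = np.clip(np.rint(rng.normal(insert_mean, insert_sd, size=m)).astype(np.int64),
                           read_len, L)
            start = (rng.random(m) * (L - flen + 1)).astype(np.int64)
            end = start + flen
            offs = np.arange(read_len)
            r1 = arr[start[:, None] + offs]
            r2 = revcomp_arr(arr[(end - read_len)[:, None] + offs])
            chunks1.append(r1)
            chunks2.append(r2)
            meta_c.append(np.full(m, ci, dtype=np.int32))
            meta_s.append(start)
            meta_e.append(end)
            meta_i.append(np.full(m, iso, dtype=np.int32))

    def _cat(chunks, dtype=None):
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=dtype or np.int64)

    seqs1 = np.concatenate(chunks1) if chunks1 else np.empty((0, read_len), dtype=np.uint8)
    seqs2 = np.concatenate(chunks2) if chunks2 else np.empty((0, read_len), dtype=np.uint8)
    cidx = _cat(meta_c, np.int32)
    fs, fe = _cat(meta_s), _cat(meta_e)
    iso = _cat(meta_i, np.int32)

    for seqs in (seqs1, seqs2):
        if error_rate > 0 and seqs.size:
            err = rng.random(seqs.shape) < error_rate
            idx = np.nonzero(err)
            if idx[0].size:
                # substitute with one of the three other bases, uniformly
                cur = seqs[idx]
                shift = rng.integers(1, 4, size=cur.size)
                code = np.searchsorted(np.sort(BASES), cur)  # ACGT are sorted ASCII
                seqs[idx] = BASES[(code + shift) % 4]
        if n_rate > 0 and seqs.size:
            nn = rng.random(seqs.shape) < n_rate
            seqs[nn] = ord("N")

    mk = lambda seqs, mate: ReadSet(
        seqs, pool.sample, contig_names, cidx.copy(), fs.copy(), fe.copy(), iso.copy(),
        np.full(len(fs), mate, dtype=np.int8))
    return mk(seqs1, 1), mk(seqs2, 2)
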