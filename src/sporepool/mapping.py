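"""Read cleaning and placement on the reference.

The internal mapper is a deliberately minimal unique-best seed-and-extend
aligner: exact k-mer seeds, ungapped extension with a mismatch budget, and
a strict "unique best placement or unmapped" rule that mirrors conservative
variant screening.  It is sufficient for low-divergence simulated data;
alignments of real data produced by a full aligner are imported from SAM
instead (:func:`import_sam`), keeping gapped CIGAR evidence intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._seq import decode, encode, revcomp, revcomp_arr
from .simulate import ReadSet, ReferenceGenome

CIGAR_CONSUMES_REF = set("MDN=X")
CIGAR_CONSUMES_READ = set("MIS=X")


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Internally inconsistent data (e.g. alignment past contig end)."""


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_reads(reads1: ReadSet, reads2: ReadSet) -> tuple[ReadSet, ReadSet, ReadSet, dict]:
    """Drop any read containing an undetermined base ('N').

    A surviving read whose mate was dropped moves to the singles set and is
    later mapped unpaired.  Returns (mate1, mate2, singles, counts).
    """
    if len(reads1) != len(reads2):
        raise FormatError("mate files are not record-aligned")
    has_n1 = (reads1.seqs == ord("N")).any(axis=1)
    has_n2 = (reads2.seqs == ord("N")).any(axis=1)
    keep_pair = ~has_n1 & ~has_n2
    single1 = ~has_n1 & has_n2
    single2 = has_n1 & ~has_n2
    c1, c2 = reads1.subset(keep_pair), reads2.subset(keep_pair)
    s1, s2 = reads1.subset(single1), reads2.subset(single2)
    singles = ReadSet(
        np.concatenate([s1.seqs, s2.seqs]), reads1.sample, reads1.contig_names,
        np.concatenate([s1.contig_idx, s2.contig_idx]),
        np.concatenate([s1.frag_start, s2.frag_start]),
        np.concatenate([s1.frag_end, s2.frag_end]),
        np.concatenate([s1.isolate, s2.isolate]),
        np.concatenate([s1.mate, s2.mate]),
    )
    counts = {
        "input_reads": 2 * len(reads1),
        "dropped": int(has_n1.sum() + has_n2.sum()),
        "retained_pairs": int(keep_pair.sum()),
        "singles": len(singles),
    }
    counts["retained_reads"] = 2 * counts["retained_pairs"] + counts["singles"]
    return c1, c2, singles, counts


def clean_reads_fastq(path1: str, path2: str) -> tuple[ReadSet, ReadSet, ReadSet, dict]:
    return clean_reads(ReadSet.from_fastq(path1), ReadSet.from_fastq(path2))


# ---------------------------------------------------------------------------
# reference index and mapper
# ---------------------------------------------------------------------------

_POS_BITS = 40
_MULTI_CAP = 16


class ReferenceIndex:
    """Exact k-mer index over all contigs (positions packed into int64)."""

    def __init__(self, genome: ReferenceGenome, k: int = 20):
        if not genome.contigs:
            raise ValueError("empty reference")
        self.genome = genome
        self.k = k
        self.contig_names = list(genome.contigs)
        self.arrays = [encode(genome.contigs[c]) for c in self.contig_names]
        self.lengths = np.array([a.size for a in self.arrays], dtype=np.int64)
        from ._seq import kmer_codes

        codes_all, packed_all = [], []
        for ci, arr in enumerate(self.arrays):
            codes = kmer_codes(arr, k)
            if codes.size == 0:
                continue
            valid = codes != (np.uint64(1) << np.uint64(63))
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[valid])
            packed_all.append((np.int64(ci) << np.int64(_POS_BITS)) | pos.astype(np.int64))
        codes = np.concatenate(codes_all)
        packed = np.concatenate(packed_all)
        order = np.argsort(codes, kind="stable")
        codes, packed = codes[order], packed[order]
        uniq, start, count = np.unique(codes, return_index=True, return_counts=True)
        self.single: dict[int, int] = {}
        self.multi: dict[int, np.ndarray] = {}
        single_mask = count == 1
        self.single = dict(zip(uniq[single_mask].tolist(), packed[start[single_mask]].tolist()))
        for u, s, c in zip(uniq[~single_mask], start[~single_mask], count[~single_mask]):
            self.multi[int(u)] = packed[s : s + min(int(c), _MULTI_CAP + 1)]

    def lookup(self, code: int) -> np.ndarray | int | None:
        hit = self.single.get(code)
        if hit is not None:
            return hit
        return self.multi.get(code)


@dataclass
class Alignments:
    """Batch of ungapped placements for one ReadSet (internal mapper output).

    ``seqs`` holds read bases in reference orientation; ``strand`` is True
    where the read mapped reverse-complemented.  ``observed_insert`` is -1
    until :func:`pair_inserts` fills it for same-contig mate pairs.
    """

    sample: str
    contig_names: list[str]
    read_idx: np.ndarray  # index into the source ReadSet
    contig: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    nmis: np.ndarray
    seqs: np.ndarray  # (N, L) uint8, reference orientation
    n_input: int = 0
    observed_insert: np.ndarray = field(default=None)  # type: ignore[assignment]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.observed_insert is None:
            self.observed_insert = np.full(len(self.read_idx), -1, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.read_idx.size)

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1]) if len(self) else 0

    @property
    def mapped_fraction(self) -> float:
        return len(self) / self.n_input if self.n_input else 0.0


def _codes_at_offsets(seqs: np.ndarray, k: int, offsets: Sequence[int]) -> np.ndarray:
    """2-bit k-mer codes of each read at the given offsets -> (n_off, N)."""
    tab = np.zeros(256, dtype=np.uint64)
    for v, b in enumerate(b"ACGT"):
        tab[b] = v
    bits = tab[seqs]
    out = np.empty((len(offsets), seqs.shape[0]), dtype=np.uint64)
    for oi, off in enumerate(offsets):
        acc = np.zeros(seqs.shape[0], dtype=np.uint64)
        for i in range(k):
            acc <<= np.uint64(2)
            acc |= bits[:, off + i]
        out[oi] = acc
    return out


def map_reads(
    reads: ReadSet,
    reference: ReferenceGenome | ReferenceIndex,
    seed_len: int = 20,
    max_mismatches: int = 3,
) -> Alignments:
    """Place reads by unique best ungapped alignment.

    A read is reported iff exactly one placement (over both strands and all
    seed hits) achieves the minimal mismatch count and that count is within
    ``max_mismatches``; ties and misses are left unmapped.  Reads whose
    every seed k-mer occurs more than 16 times in the reference are treated
    as ambiguous.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, seed_len)
    k = index.k
    L = reads.read_length
    n = len(reads)
    if n == 0:
        return Alignments(reads.sample, index.contig_names, *(np.empty(0, dtype=np.int64),) * 5,
                          np.empty((0, 0), dtype=np.uint8), n_input=0,
                          contig_lengths=dict(zip(index.contig_names, index.lengths.tolist())))
    if k > L:
        raise ValueError("seed_len exceeds read length")
    offsets = sorted({0, min(k, L - k), min(2 * k, L - k), L - k})
    fwd = reads.seqs
    rev = revcomp_arr(reads.seqs)
    codes_f = _codes_at_offsets(fwd, k, offsets)
    codes_r = _codes_at_offsets(rev, k, offsets)

    # concatenated genome for batched mismatch counting
    clens = index.lengths
    starts = np.concatenate([[0], np.cumsum(clens)])
    gcat = np.concatenate(index.arrays)
    glen = int(starts[-1])

    cand_read, cand_gpos, cand_strand = [], [], []
    single, multi = index.single, index.multi
    shift = np.int64(_POS_BITS)
    mask_pos = (np.int64(1) << shift) - np.int64(1)
    for i in range(n):
        seen: set[tuple[int, int]] = set()
        for strand, codes in ((0, codes_f), (1, codes_r)):
            for oi, off in enumerate(offsets):
                code = int(codes[oi, i])
                hit = single.get(code)
                if hit is not None:
                    packs = (hit,)
                else:
                    arr = multi.get(code)
                    if arr is None:
                        continue
                    if arr.size > _MULTI_CAP:
                        seen.add((-1, -1))  # poison: hyper-repetitive seed
                        continue
                    packs = arr.tolist()
                for p in packs:
                    ci = p >> _POS_BITS
                    cpos = (p & int(mask_pos)) - off
                    if cpos < 0 or cpos + L > clens[ci]:
                        continue
                    seen.add((strand, int(starts[ci] + cpos)))
        if (-1, -1) in seen:
            continue
        for strand, g in seen:
            cand_read.append(i)
            cand_gpos.append(g)
            cand_strand.append(strand)

    if not cand_read:
        return Alignments(reads.sample, index.contig_names,
                          np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                          np.empty(0, dtype=np.int64), np.empty(0, dtype=bool),
                          np.empty(0, dtype=np.int64), np.empty((0, L), dtype=np.uint8),
                          n_input=n,
                          contig_lengths=dict(zip(index.contig_names, index.lengths.tolist())))

    cr = np.array(cand_read, dtype=np.int64)
    cg = np.array(cand_gpos, dtype=np.int64)
    cs = np.array(cand_strand, dtype=bool)
    offs = np.arange(L)
    nmis = np.empty(cr.size, dtype=np.int64)
    B = 200_000
    for lo in range(0, cr.size, B):
        hi = min(lo + B, cr.size)
        win = gcat[cg[lo:hi, None] + offs]
        rd = np.where(cs[lo:hi, None], rev[cr[lo:hi]], fwd[cr[lo:hi]])
        nmis[lo:hi] = (win != rd).sum(axis=1)

    # unique best per read
    order = np.lexsort((nmis, cr))
    cr, cg, cs, nmis = cr[order], cg[order], cs[order], nmis[order]
    first = np.concatenate([[True], cr[1:] != cr[:-1]])
    idx_first = np.nonzero(first)[0]
    best_r, best_g, best_s, best_m = cr[idx_first], cg[idx_first], cs[idx_first], nmis[idx_first]
    # ambiguous if the next candidate of the same read ties the best
    nxt = idx_first + 1
    has_next = nxt < cr.size
    tie = np.zeros(idx_first.size, dtype=bool)
    tie[has_next] = (cr[nxt[has_next]] == best_r[has_next]) & (nmis[nxt[has_next]] == best_m[has_next])
    ok = (best_m <= max_mismatches) & ~tie
    best_r, best_g, best_s, best_m = best_r[ok], best_g[ok], best_s[ok], best_m[ok]

    ci = np.searchsorted(starts, best_g, side="right") - 1
    pos = best_g - starts[ci]
    oriented = np.where(best_s[:, None], rev[best_r], fwd[best_r])
    return Alignments(reads.sample, index.contig_names, best_r, ci.astype(np.int64),
                      pos.astype(np.int64), best_s, best_m, oriented, n_input=n,
                      contig_lengths=dict(zip(index.contig_names, index.lengths.tolist())))


def pair_inserts(al1: Alignments, al2: Alignments) -> None:
    """Fill ``observed_insert`` (outer distance) for same-contig mate pairs."""
    L1, L2 = al1.read_length, al2.read_length
    m1 = {int(r): j for j, r in enumerate(al1.read_idx)}
    for j2, r in enumerate(al2.read_idx):
        j1 = m1.get(int(r))
        if j1 is None:
            continue
        if al1.contig[j1] != al2.contig[j2]:
            continue
        left = min(al1.pos[j1], al2.pos[j2])
        right = max(al1.pos[j1] + L1, al2.pos[j2] + L2)
        ins = right - left
        al1.observed_insert[j1] = ins
        al2.observed_insert[j2] = ins


# ---------------------------------------------------------------------------
# gapped records (SAM import, truth-guided realignment)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """A single (possibly gapped) placement, SAM-like, 0-based."""

    read_id: str
    sample_id: str
    contig: str
    pos: int
    strand: str  # '+'/'-'
    seq: str  # reference orientation
    cigar: tuple[tuple[str, int], ...]
    mate_contig: str | None = None
    mate_pos: int | None = None
    observed_insert: int | None = None
    n_mismatches: int | None = None

    @property
    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar if op in CIGAR_CONSUMES_REF)


def _parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    out, num = [], ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDNSHP=X":
                raise FormatError(f"bad CIGAR {text!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"bad CIGAR {text!r}")
    return tuple(out)


def import_sam(path: str, sample_id: str) -> list[AlignmentRecord]:
    """Read primary mapped records from a (headered) SAM file via pysam.

    SAM's 1-based POS becomes 0-based; unmapped, secondary and
    supplementary records are skipped.
    """
    import pysam

    records: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            for lineno, rec in enumerate(fh, 1):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_name is None or rec.query_sequence is None:
                    continue
                cigar = (tuple(("MIDNSHP=XB"[op], ln) for op, ln in rec.cigartuples)
                         if rec.cigartuples else (("M", len(rec.query_sequence)),))
                records.append(AlignmentRecord(
                    read_id=rec.query_name, sample_id=sample_id,
                    contig=rec.reference_name, pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    seq=rec.query_sequence.upper(), cigar=cigar,
                    mate_contig=rec.next_reference_name,
                    mate_pos=rec.next_reference_start if rec.next_reference_start >= 0 else None,
                    observed_insert=abs(rec.template_length) or None,
                ))
    except (ValueError, OSError, NotImplementedError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    return records


def write_sam(records: Iterable[AlignmentRecord], reference: ReferenceGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in reference.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in records:
            flag = 16 if r.strand == "-" else 0
            cig = "".join(f"{n}{op}" for op, n in r.cigar)
            tlen = r.observed_insert if r.observed_insert is not None else 0
            rnext = "=" if (r.mate_contig == r.contig and r.mate_contig) else (r.mate_contig or "*")
            pnext = (r.mate_pos + 1) if r.mate_pos is not None else 0
            fh.write(f"{r.read_id}\t{flag}\t{r.contig}\t{r.pos + 1}\t60\t{cig}\t"
                     f"{rnext}\t{pnext}\t{tlen}\t{r.seq}\t*\n")


def alignments_to_records(al: Alignments, reads: ReadSet) -> list[AlignmentRecord]:
    L = al.read_length
    out = []
    for j in range(len(al)):
        i = int(al.read_idx[j])
        ins = int(al.observed_insert[j])
        out.append(AlignmentRecord(
            read_id=reads.name(i), sample_id=al.sample,
            contig=al.contig_names[int(al.contig[j])], pos=int(al.pos[j]),
            strand="-" if al.strand[j] else "+", seq=decode(al.seqs[j]),
            cigar=((("M", L),)), observed_insert=None if ins < 0 else ins,
            n_mismatches=int(al.nmis[j]),
        ))
    return out


def true_alignments(
    reads: ReadSet,
    reference: ReferenceGenome,
    projection_specs: Sequence = (),
    pad: int = 30,
) -> list[AlignmentRecord]:
    """Gapped alignments recovered from simulation ground truth.

    Each read is realigned (edlib, infix mode) inside a window around its
    true source locus, optionally projected through ``projection_specs``
    when the mapping reference differs from the source genomes (the
    reference-defect scenario).  Serves as the oracle producer of gapped
    CIGAR evidence that the ungapped internal mapper cannot emit.
    """
    import edlib

    from .simulate import project_position

    out: list[AlignmentRecord] = []
    L = reads.read_length
    for i in range(len(reads)):
        contig = reads.contig_names[int(reads.contig_idx[i])]
        refseq = reference.contigs[contig]
        if reads.mate[i] == 2:
            src_start = int(reads.frag_end[i]) - L
            query = revcomp(decode(reads.seqs[i]))
            strand = "-"
        else:
            src_start = int(reads.frag_start[i])
            query = decode(reads.seqs[i])
            strand = "+"
        tgt = src_start
        if projection_specs:
            proj = None
            for d in range(0, 50):
                proj = project_position(projection_specs, contig, src_start + d)
                if proj is not None:
                    proj -= d
                    break
            if proj is None:
                continue
            tgt = proj
        w0 = max(0, tgt - pad)
        w1 = min(len(refseq), tgt + L + pad)
        res = edlib.align(query, refseq[w0:w1], task="path", mode="HW")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        loc0, loc1 = res["locations"][0]
        pos = w0 + loc0
        cigar = tuple((op if op in "ID" else "M", n)
                      for op, n in _merge_ops(_parse_cigar(res["cigar"])))
        dist = int(res["editDistance"])
        # parsimony: edit distance treats one substitution and one indel as
        # equal cost, and edlib breaks such ties arbitrarily near read ends;
        # prefer the ungapped representation whenever it explains the read
        # with no more edits than the gapped one
        if dist > 0 and len(cigar) > 1:
            qarr = np.frombuffer(query.encode(), dtype=np.uint8)
            best = None
            for cand in {pos, w0 + loc1 + 1 - L}:
                if 0 <= cand and cand + L <= len(refseq):
                    ref_w = np.frombuffer(refseq[cand : cand + L].encode(), dtype=np.uint8)
                    nm = int((ref_w != qarr).sum())
                    if nm <= dist and (best is None or nm < best[1]):
                        best = (cand, nm)
            if best is not None:
                pos, dist = best[0], best[1]
                cigar = (("M", L),)
        out.append(AlignmentRecord(
            read_id=reads.name(i) + (f"/{reads.mate[i]}" if reads.mate[i] else ""),
            sample_id=reads.sample, contig=contig, pos=pos, strand=strand,
            seq=query, cigar=cigar, n_mismatches=dist))
    return out


def _merge_ops(cig: tuple[tuple[str, int], ...]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in cig:
        op = "M" if op in "=X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out
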