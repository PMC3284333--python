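"""Per-sample pileups, coverage tracks and sequencing summary statistics.

A pileup is accumulated in two phases: alignment batches contribute to
per-contig depth *difference* arrays and to raw mismatch-key chunks
(position * 256 + base byte), and :func:`build_pileup` integrates the depth
and merges the keys once at the end.  Alt evidence therefore costs memory
proportional to the number of alt observations, not genome size x depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._seq import encode
from .mapping import AlignmentRecord, Alignments, ConsistencyError
from .simulate import ReferenceGenome


@dataclass
class PileupColumn:
    contig: str
    pos: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]
    ins_counts: dict[str, int] = field(default_factory=dict)
    del_counts: dict[int, int] = field(default_factory=dict)


class Pileup:
    """Sparse per-sample pileup over one reference."""

    def __init__(self, sample: str, reference: ReferenceGenome):
        self.sample = sample
        self.reference = reference
        self.contig_names = list(reference.contigs)
        # accumulation state
        self._diff = {c: np.zeros(len(reference.contigs[c]) + 1, dtype=np.int64)
                      for c in self.contig_names}
        self._mis_chunks: dict[str, list[tuple[np.ndarray, np.ndarray]]] = \
            {c: [] for c in self.contig_names}
        self._mis_extra: dict[str, Counter] = {c: Counter() for c in self.contig_names}
        self._iv_chunks: dict[str, list[np.ndarray]] = {c: [] for c in self.contig_names}
        self._final = False
        # final state
        self.depth: dict[str, np.ndarray] = {}
        self.mis_keys: dict[str, np.ndarray] = {}
        self.mis_counts: dict[str, np.ndarray] = {}
        self.read_starts: dict[str, np.ndarray] = {}
        self.read_ends: dict[str, np.ndarray] = {}
        self.insertions: dict[tuple[str, int], Counter] = {}
        self.deletions: dict[tuple[str, int], Counter] = {}

    # -- finalisation ------------------------------------------------------
    def _finalise(self) -> None:
        if self._final:
            return
        for c in self.contig_names:
            self.depth[c] = np.cumsum(self._diff[c][:-1]).astype(np.int32)
            chunks = self._mis_chunks[c]
            extra = self._mis_extra[c]
            if extra:
                ek = np.fromiter(extra.keys(), dtype=np.int64, count=len(extra))
                ec = np.fromiter(extra.values(), dtype=np.int64, count=len(extra))
                chunks.append((ek, ec))
            if chunks:
                keys = np.concatenate([k for k, _ in chunks])
                cnts = np.concatenate([v for _, v in chunks])
                uk, inv = np.unique(keys, return_inverse=True)
                uc = np.zeros(uk.size, dtype=np.int64)
                np.add.at(uc, inv, cnts)
                self.mis_keys[c], self.mis_counts[c] = uk, uc
            else:
                self.mis_keys[c] = np.empty(0, dtype=np.int64)
                self.mis_counts[c] = np.empty(0, dtype=np.int64)
            ivs = self._iv_chunks[c]
            if ivs:
                iv = np.concatenate(ivs)
                order = np.argsort(iv[:, 0], kind="stable")
                iv = iv[order]
                self.read_starts[c] = np.ascontiguousarray(iv[:, 0])
                self.read_ends[c] = np.ascontiguousarray(iv[:, 1])
            else:
                self.read_starts[c] = np.empty(0, dtype=np.int64)
                self.read_ends[c] = np.empty(0, dtype=np.int64)
        self._diff = {}
        self._mis_chunks = {}
        self._mis_extra = {}
        self._iv_chunks = {}
        self._final = True

    # -- accessors ---------------------------------------------------------
    def iter_mismatches(self) -> Iterator[tuple[str, int, str, int]]:
        """Yield (contig, pos, alt_base, count) for every recorded mismatch."""
        self._finalise()
        for c in self.contig_names:
            keys, cnts = self.mis_keys[c], self.mis_counts[c]
            for k, n in zip(keys.tolist(), cnts.tolist()):
                yield c, k >> 8, chr(k & 0xFF), n

    def mismatch_arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        self._finalise()
        return self.mis_keys[contig], self.mis_counts[contig]

    def column(self, contig: str, pos: int) -> PileupColumn:
        self._finalise()
        d = int(self.depth[contig][pos])
        ref = self.reference.contigs[contig][pos]
        keys, cnts = self.mis_keys[contig], self.mis_counts[contig]
        lo = np.searchsorted(keys, pos << 8)
        hi = np.searchsorted(keys, (pos + 1) << 8)
        counts: dict[str, int] = {}
        alt_total = 0
        for k, n in zip(keys[lo:hi].tolist(), cnts[lo:hi].tolist()):
            counts[chr(k & 0xFF)] = n
            alt_total += n
        counts[ref] = counts.get(ref, 0) + d - alt_total
        return PileupColumn(contig, pos, ref, d, counts,
                            dict(self.insertions.get((contig, pos), ())),
                            dict(self.deletions.get((contig, pos), ())))

    def depth_at(self, contig: str, pos: int) -> int:
        self._finalise()
        return int(self.depth[contig][pos])

    def spanning_depth(self, contig: str, start: int, end: int) -> int:
        """Reads whose aligned interval fully covers [start, end).

        The informative denominator for indel evidence: a read that starts
        or ends inside a homopolymer run is consistent with either allele
        and must not count against penetrance.
        """
        self._finalise()
        starts, ends = self.read_starts[contig], self.read_ends[contig]
        hi = np.searchsorted(starts, start, side="right")
        return int((ends[:hi] >= end).sum())

    def mean_coverage(self) -> float:
        """Mean depth over covered positions (depth >= 1)."""
        self._finalise()
        tot = n = 0
        for arr in self.depth.values():
            cov = arr[arr > 0]
            tot += int(cov.sum())
            n += cov.size
        return tot / n if n else 0.0

    def coverage_track(self, contig: str) -> np.ndarray:
        self._finalise()
        return self.depth[contig]


def _add_ungapped(pile: Pileup, al: Alignments) -> None:
    L = al.read_length
    if len(al) == 0:
        return
    for ci, cname in enumerate(al.contig_names):
        sel = al.contig == ci
        if not sel.any():
            continue
        pos = al.pos[sel]
        seqs = al.seqs[sel]
        refarr = encode(pile.reference.contigs[cname])
        if (pos < 0).any() or (pos + L > refarr.size).any():
            raise ConsistencyError(f"alignment beyond end of {cname}")
        diff = pile._diff[cname]
        np.add.at(diff, pos, 1)
        np.add.at(diff, pos + L, -1)
        pile._iv_chunks[cname].append(np.stack([pos, pos + L], axis=1).astype(np.int64))
        offs = np.arange(L)
        win = refarr[pos[:, None] + offs]
        ri, cj = np.nonzero(win != seqs)
        if ri.size:
            key = ((pos[ri] + cj) << np.int64(8)) | seqs[ri, cj].astype(np.int64)
            uk, uc = np.unique(key, return_counts=True)
            pile._mis_chunks[cname].append((uk, uc.astype(np.int64)))


def _add_gapped(pile: Pileup, rec: AlignmentRecord) -> None:
    seq = rec.seq
    refseq = pile.reference.contigs.get(rec.contig)
    if refseq is None:
        raise ConsistencyError(f"alignment on unknown contig {rec.contig}")
    rp, qp = rec.pos, 0
    diff = pile._diff[rec.contig]
    extra = pile._mis_extra[rec.contig]
    pile._iv_chunks[rec.contig].append(
        np.array([[rec.pos, rec.pos + rec.ref_length]], dtype=np.int64))
    for op, n in rec.cigar:
        if op in "M=X":
            if rp + n > len(refseq):
                raise ConsistencyError(f"alignment beyond end of {rec.contig}")
            diff[rp] += 1
            diff[rp + n] -= 1
            for j in range(n):
                if seq[qp + j] != refseq[rp + j]:
                    extra[((rp + j) << 8) | ord(seq[qp + j])] += 1
            rp += n
            qp += n
        elif op == "I":
            if rp > 0:
                pile.insertions.setdefault((rec.contig, rp - 1), Counter())[seq[qp : qp + n]] += 1
            qp += n
        elif op == "D":
            pile.deletions.setdefault((rec.contig, rp), Counter())[n] += 1
            rp += n
        elif op == "S":
            qp += n
        elif op in "HP":
            pass
        else:  # N
            rp += n


def build_pileup(
    sample: str,
    alignments: Iterable[Alignments | Sequence[AlignmentRecord]],
    reference: ReferenceGenome,
) -> Pileup:
    """Accumulate a per-sample pileup from mapper batches and/or SAM records."""
    pile = Pileup(sample, reference)
    for item in alignments:
        if isinstance(item, Alignments):
            _add_ungapped(pile, item)
        else:
            for rec in item:
                _add_gapped(pile, rec)
    pile._finalise()
    return pile


# ---------------------------------------------------------------------------
# sequencing summary (run-report arithmetic)
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Per-sample sequencing summary in report units.

    ``total_mb`` is megabases rounded to the nearest integer; ``coverage``
    is fold coverage of the genome (total bases / genome length);
    ``mapped_pct`` is rounded to one decimal.
    """

    sample_id: str
    total_reads: int
    read_length: int
    total_mb: int
    coverage: float
    mapped_reads: int
    mapped_pct: float


def sequencing_summary(
    sample_id: str,
    total_reads: int,
    read_length: int,
    mapped_reads: int,
    genome_length: int,
) -> SummaryStats:
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total_bases = total_reads * read_length
    total_mb = int(round(total_bases / 1e6))
    coverage = total_bases / genome_length
    mapped_pct = round(100.0 * mapped_reads / total_reads, 1) if total_reads else 0.0
    return SummaryStats(sample_id, total_reads, read_length, total_mb, coverage,
                        mapped_reads, mapped_pct)
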