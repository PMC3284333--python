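"""Kilobase-scale lesion detection.

Two complementary strategies: (1) intervals with zero read coverage in one
pool but normal depth in all others (deletions relative to the reference);
(2) windows where the observed outer distance of mate pairs deviates
coherently from the library insert size (unbalanced indels).  A deletion
whose interval was replaced by duplicated flanking sequence of similar
length leaves spanning inserts unchanged — such lesions appear only in the
coverage scan, which is exactly why both detectors are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import Alignments
from .pileup import Pileup


@dataclass
class StructuralCandidate:
    contig: str
    start: int
    end: int
    evidence: str  # 'coverage_gap' | 'insert_anomaly'
    target_sample: str
    mean_depth: dict[str, float] = field(default_factory=dict)
    median_insert: float | None = None
    expected_insert: float | None = None
    deviation: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _zero_runs(depth: np.ndarray) -> list[tuple[int, int]]:
    zero = depth == 0
    if not zero.any():
        return []
    d = np.diff(zero.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if zero[0]:
        starts = np.concatenate([[0], starts])
    if zero[-1]:
        ends = np.concatenate([ends, [zero.size]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_close(runs: list[tuple[int, int]], gap_join: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < gap_join:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def find_uncovered_regions(
    tracks: dict[str, Pileup],
    target: str,
    min_len: int = 500,
    other_min_depth: float = 5.0,
    gap_join: int = 50,
) -> list[StructuralCandidate]:
    """Maximal zero-coverage runs private to ``target``.

    Runs separated by fewer than ``gap_join`` covered bases are merged
    first; a merged run is reported iff it is at least ``min_len`` long and
    every *other* sample averages at least ``other_min_depth`` over it —
    a region bare in all pools is unsequenceable, not a deletion.
    """
    if target not in tracks:
        raise ValueError(f"target sample {target!r} not among tracks")
    tpile = tracks[target]
    out: list[StructuralCandidate] = []
    for contig in tpile.contig_names:
        depth_t = tpile.coverage_track(contig)
        for s, e in _merge_close(_zero_runs(depth_t), gap_join):
            if e - s < min_len:
                continue
            means = {smp: float(p.coverage_track(contig)[s:e].mean())
                     for smp, p in tracks.items()}
            if all(means[smp] >= other_min_depth for smp in tracks if smp != target):
                out.append(StructuralCandidate(contig, int(s), int(e), "coverage_gap",
                                               target, mean_depth=means))
    return out


def collect_pairs(al1: Alignments, al2: Alignments) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """(contig_names, contig_idx, leftmost, observed_insert) for mapped pairs."""
    m1 = {int(r): j for j, r in enumerate(al1.read_idx)}
    ci, left, ins = [], [], []
    L1, L2 = al1.read_length, al2.read_length
    for j2, r in enumerate(al2.read_idx):
        j1 = m1.get(int(r))
        if j1 is None or al1.contig[j1] != al2.contig[j2]:
            continue
        lo = min(int(al1.pos[j1]), int(al2.pos[j2]))
        hi = max(int(al1.pos[j1]) + L1, int(al2.pos[j2]) + L2)
        ci.append(int(al1.contig[j1]))
        left.append(lo)
        ins.append(hi - lo)
    return (al1.contig_names, np.array(ci, dtype=np.int64),
            np.array(left, dtype=np.int64), np.array(ins, dtype=np.int64))


def insert_size_anomalies(
    al1: Alignments,
    al2: Alignments,
    expected_insert: float,
    expected_sd: float,
    window: int = 100,
    z_threshold: float = 6.0,
    coherence_ratio: float = 1.0,
    target_sample: str | None = None,
) -> list[StructuralCandidate]:
    """Windows of mate pairs whose median outer distance is shifted.

    Pairs are ordered by leftmost mapped coordinate; every run of
    ``window`` consecutive pairs whose median insert deviates from
    ``expected_insert`` by more than ``z_threshold * expected_sd /
    sqrt(window)`` is flagged, and overlapping flagged windows are merged.
    Deletions lengthen spanning inserts coherently (positive deviation);
    insertions shorten them (negative deviation).
    """
    import warnings

    names, ci, left, ins = collect_pairs(al1, al2)
    sample = target_sample or al1.sample
    if ins.size == 0:
        warnings.warn("no paired alignments; insert-size screen is empty")
        return []
    if al1.contig_lengths:
        # fragments near a contig end are length-truncated, which biases the
        # local insert median short; mask the affected terminal zone
        margin = expected_insert + 4 * expected_sd
        keep = np.ones(ins.size, dtype=bool)
        for cidx, cname in enumerate(names):
            clen = al1.contig_lengths.get(cname)
            if clen:
                keep &= (ci != cidx) | (left <= clen - margin)
        ci, left, ins = ci[keep], left[keep], ins[keep]
        if ins.size == 0:
            return []
    thresh = z_threshold * expected_sd / np.sqrt(window)
    out: list[StructuralCandidate] = []
    for c in np.unique(ci):
        sel = ci == c
        order = np.argsort(left[sel], kind="stable")
        lf = left[sel][order]
        iv = ins[sel][order].astype(np.float64)
        n = iv.size
        if n < window:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(iv, window)
        q25, med, q75 = np.percentile(sw, [25, 50, 75], axis=1)
        dev = med - expected_insert
        # a real unbalanced lesion shifts every spanning pair the same way;
        # require the whole interquartile range to clear the threshold so
        # that incoherent relocations (duplicated sequence mapping back to
        # its source) cannot mimic it
        flag = (q25 - expected_insert > thresh) | (q75 - expected_insert < -thresh)
        if not flag.any():
            continue
        idx = np.nonzero(flag)[0]
        # group flagged windows into runs of overlapping windows, then join
        # groups closer than one library insert into a single locus: a
        # duplicative rearrangement emits short blocks of opposite-sign
        # shifts that cancel at locus scale, a genuine unbalanced lesion
        # shifts the whole locus one way
        breaks = np.nonzero(np.diff(idx) > window)[0]
        groups = np.split(idx, breaks + 1)
        loci: list[list[int]] = []
        for g in groups:
            s_pair, e_pair = int(g[0]), int(g[-1]) + window - 1
            if loci and lf[s_pair] - lf[loci[-1][1]] < expected_insert:
                loci[-1][1] = e_pair
            else:
                loci.append([s_pair, e_pair])
        min_extent = 0.75 * expected_insert
        for s_pair, e_pair in loci:
            # every fragment spanning a real unbalanced lesion shifts, so
            # the anomaly must extend over roughly one library insert of
            # leftmost positions; short coherent blocks are relocation
            # artifacts of duplicated sequence
            if lf[e_pair] - lf[s_pair] < min_extent:
                continue
            # judge the run of flagged window *centers*: the locus-wide
            # shift there must dominate the spread (a coherent lesion
            # moves every spanning pair by the same amount, scrambled
            # relocations leave a wide or sign-mixed distribution)
            c0, c1 = s_pair + window // 2, e_pair - window // 2
            core = iv[c0 : c1 + 1] if c1 >= c0 else iv[s_pair : e_pair + 1]
            bq25, gmed, bq75 = np.percentile(core, [25, 50, 75])
            if abs(gmed - expected_insert) <= max(thresh, coherence_ratio * (bq75 - bq25)):
                continue
            gdev = (gmed - expected_insert) / (expected_sd / np.sqrt(window))
            out.append(StructuralCandidate(
                names[int(c)], int(lf[s_pair]), int(lf[e_pair]) + 1, "insert_anomaly",
                sample, median_insert=float(gmed), expected_insert=float(expected_insert),
                deviation=float(gdev)))
    return out


def write_bed(candidates: list[StructuralCandidate], path: str) -> None:
    """0-based half-open BED with evidence columns."""
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda x: (x.contig, x.start)):
            extra = ""
            if c.evidence == "insert_anomaly":
                extra = f"\tmedian_insert={c.median_insert:.0f};deviation={c.deviation:.1f}"
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.evidence}\t{c.target_sample}{extra}\n")


def write_bedgraph(pile: Pileup, path: str) -> None:
    """Per-sample coverage as bedGraph (runs of equal depth collapsed)."""
    with open(path, "w") as fh:
        for contig in pile.contig_names:
            d = pile.coverage_track(contig)
            change = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [d.size]])
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{contig}\t{s}\t{e}\t{int(d[s])}\n")
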