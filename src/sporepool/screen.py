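"""Penetrance-filtered small-variant screen across pooled samples.

The screen detects SNPs and sub-4-base indels per sample, requires local
depth of at least a fraction (default 40%) of that sample's mean coverage,
and then classifies every site by its cross-sample presence pattern:

* penetrant in **all** samples -> an error in the reference assembly,
  not a mutation;
* penetrant (all reads carry the variant) in exactly the samples expected
  for one mutant lineage, with **zero** supporting reads in every other
  covered sample -> a candidate causative mutation for that lineage;
* supported but sub-penetrant anywhere -> a segregating background variant
  or sequencing noise, never a candidate.

This penetrance logic is what lets a pool of phenotype-selected haploid
isolates pinpoint the causative lesion: selection fixes it (read fraction
1.0) while unlinked background lesions ride at ~0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import homopolymer_run
from .mapping import ConsistencyError
from .pileup import Pileup
from .simulate import PoolDesign, ReferenceGenome

SMALL_INDEL_MAX = 3


@dataclass
class ScreenConfig:
    """Thresholds of the variant screen.

    coverage_fraction: minimum local depth as a fraction of the sample's
        mean coverage for the sample's evidence to count (0.4 = the 40% rule).
    penetrance_min: minimum alt read fraction treated as full penetrance
        (1.0 = literally every read; relax slightly for error-prone data).
    absence_max_alt: alt reads tolerated in samples outside the pattern.
    min_absent_depth: depth needed in an outside sample to assert absence.
    homopolymer_min_run: run length from which 1-base indels are flagged as
        likely homopolymer artifacts of the reference assembly.
    strict_all_samples: if True, also require sufficient coverage in the
        samples *outside* the pattern (the stricter reading of the 40% rule).
    """

    coverage_fraction: float = 0.4
    penetrance_min: float = 1.0
    absence_max_alt: int = 0
    min_absent_depth: int = 1
    homopolymer_min_run: int = 3
    strict_all_samples: bool = False

    def __post_init__(self):
        if not 0 <= self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction in [0, 1]")
        if not 0 < self.penetrance_min <= 1:
            raise ValueError("penetrance_min in (0, 1]")
        for v in (self.absence_max_alt, self.min_absent_depth, self.homopolymer_min_run):
            if v < 0:
                raise ValueError("count thresholds must be >= 0")


@dataclass
class SiteCall:
    """One putative small variant with per-sample read support.

    ``var_type`` is 'snp' (alt = base), 'ins' (alt = inserted string,
    anchored after ``pos``) or 'del' (alt = deleted length, starting at
    ``pos``).  Indels are left-aligned before cross-sample merging so that
    identical events share a key.
    """

    contig: str
    pos: int
    ref_allele: str
    var_type: str
    alt: str | int
    depth: dict[str, int] = field(default_factory=dict)
    alt_count: dict[str, int] = field(default_factory=dict)
    sufficient: dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.var_type, self.alt)

    def alt_fraction(self, sample: str) -> float | None:
        d = self.depth.get(sample, 0)
        if d == 0:
            return None
        return self.alt_count.get(sample, 0) / d

    @property
    def is_indel(self) -> bool:
        return self.var_type in ("ins", "del")

    @property
    def indel_length(self) -> int:
        if self.var_type == "ins":
            return len(self.alt)  # type: ignore[arg-type]
        if self.var_type == "del":
            return int(self.alt)
        return 0


CLASSIFICATIONS = ("pattern_candidate", "reference_error", "low_coverage",
                   "partial_penetrance", "inconsistent")


@dataclass
class CandidateMutation:
    site: SiteCall
    pattern: frozenset[str]
    classification: str
    matched_lineage: str | None = None
    homopolymer_flag: bool = False


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an insertion (anchored after ``pos``) left through equal bases."""
    while pos >= 0 and ref[pos] == seq[-1]:
        seq = ref[pos] + seq[:-1]
        pos -= 1
    return pos, seq


def left_align_deletion(ref: str, pos: int, length: int) -> int:
    """Shift a deletion starting at ``pos`` left through equal bases."""
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _indel_ambiguity_interval(ref: str, sc: "SiteCall") -> tuple[int, int]:
    """[start, end) a read must span to attest the indel either way."""
    if sc.var_type == "del":
        base = ref[sc.pos]
        length = int(sc.alt)
    else:
        base = str(sc.alt)[0]
        length = 1
    r0 = sc.pos
    while r0 > 0 and ref[r0 - 1] == base:
        r0 -= 1
    r1 = sc.pos + length
    while r1 < len(ref) and ref[r1] == base:
        r1 += 1
    # a generous anchor margin: reads with only a base or two beyond the
    # run sit on an alignment-representation knife edge (indel vs shifted
    # mismatches at equal edit cost) and cannot be scored reliably
    margin = 10
    return max(0, r0 - margin), min(len(ref), r1 + margin)


def call_small_variants(
    pileups: dict[str, Pileup],
    min_alt_reads: int = 1,
    min_alt_fraction: float = 0.0,
) -> list[SiteCall]:
    """Merge per-sample pileup evidence into shared variant keys.

    A site is emitted when in at least one sample the alt allele is seen on
    >= ``min_alt_reads`` reads and on >= ``min_alt_fraction`` of the reads
    there (the defaults emit every site with a single supporting read).
    Alt alleles are restricted to SNPs and indels of < 4 bases.  All
    pileups must be built against the same reference; once a site
    qualifies, its read support in *every* sample is attached, however
    small.
    """
    if not pileups:
        return []
    seqs = [p.reference.contigs for p in pileups.values()]
    if any(s is not seqs[0] and s != seqs[0] for s in seqs[1:]):
        raise ConsistencyError("pileups are built on different references")
    reference = next(iter(pileups.values())).reference
    samples = list(pileups)
    calls: dict[tuple, SiteCall] = {}

    # --- SNPs: vectorised per contig -------------------------------------
    n_code = ord("N")
    for contig, refseq in reference.contigs.items():
        selected = []
        per_sample: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for s in samples:
            keys, cnts = pileups[s].mismatch_arrays(contig)
            per_sample[s] = (keys, cnts)
            if keys.size == 0:
                continue
            pos = keys >> 8
            ok = ((keys & 0xFF) != n_code) & (cnts >= min_alt_reads)
            if min_alt_fraction > 0:
                depth = pileups[s].depth[contig][pos]
                ok &= cnts >= min_alt_fraction * depth
            selected.append(keys[ok])
        if not selected:
            continue
        cand = np.unique(np.concatenate(selected))
        if cand.size == 0:
            continue
        gathered = {}
        for s in samples:
            keys, cnts = per_sample[s]
            idx = np.searchsorted(keys, cand)
            idx_c = np.clip(idx, 0, max(keys.size - 1, 0))
            hit = (keys.size > 0) & (keys[idx_c] == cand) if keys.size else np.zeros(cand.size, bool)
            vals = np.zeros(cand.size, dtype=np.int64)
            vals[hit] = cnts[idx_c[hit]]
            gathered[s] = vals
        for j, key in enumerate(cand.tolist()):
            pos, base = key >> 8, chr(key & 0xFF)
            sc = SiteCall(contig, pos, refseq[pos], "snp", base)
            for s in samples:
                if gathered[s][j]:
                    sc.alt_count[s] = int(gathered[s][j])
            calls[sc.key] = sc

    # --- indels: dict-backed, left-aligned --------------------------------
    indel_calls: dict[tuple, SiteCall] = {}
    for sample in samples:
        pile = pileups[sample]
        for (contig, pos), counter in pile.insertions.items():
            seq0 = reference.contigs[contig]
            for ins, cnt in counter.items():
                if len(ins) > SMALL_INDEL_MAX or "N" in ins:
                    continue
                p, s = left_align_insertion(seq0, pos, ins)
                anchor_ref = seq0[p] if p >= 0 else ""
                key = (contig, p, "ins", s)
                sc = indel_calls.get(key)
                if sc is None:
                    sc = indel_calls[key] = SiteCall(contig, p, anchor_ref, "ins", s)
                sc.alt_count[sample] = sc.alt_count.get(sample, 0) + cnt
        for (contig, pos), counter in pile.deletions.items():
            seq0 = reference.contigs[contig]
            for dlen, cnt in counter.items():
                if dlen > SMALL_INDEL_MAX:
                    continue
                p = left_align_deletion(seq0, pos, dlen)
                key = (contig, p, "del", int(dlen))
                sc = indel_calls.get(key)
                if sc is None:
                    sc = indel_calls[key] = SiteCall(contig, p, seq0[p : p + dlen], "del", int(dlen))
                sc.alt_count[sample] = sc.alt_count.get(sample, 0) + cnt

    # fill depths; apply the evidence floor to indels.  An indel's depth is
    # the number of reads spanning its full ambiguity interval (the
    # homopolymer run it sits in, plus one anchor base each side): reads
    # that start or end inside the run carry no information about it.
    for sc in indel_calls.values():
        ref = reference.contigs[sc.contig]
        a, b = _indel_ambiguity_interval(ref, sc)
        for s in samples:
            # every read that reported the indel necessarily covers the
            # site, even if its anchor is short of the spanning margin
            sc.depth[s] = max(pileups[s].spanning_depth(sc.contig, a, b),
                              sc.alt_count.get(s, 0))
        if any(sc.alt_count.get(s, 0) >= min_alt_reads
               and (sc.alt_fraction(s) or 0.0) >= min_alt_fraction for s in samples):
            calls[sc.key] = sc
    for sc in calls.values():
        if not sc.depth:
            for s in samples:
                sc.depth[s] = pileups[s].depth_at(sc.contig, sc.pos)
    return sorted(calls.values(), key=lambda s: s.key)


def apply_coverage_filter(
    calls: list[SiteCall],
    mean_coverage: dict[str, float],
    cfg: ScreenConfig,
) -> list[SiteCall]:
    """Mark, per sample, whether local depth clears the coverage rule.

    A sample's evidence at a site counts only where depth >= coverage_fraction
    x that sample's mean coverage.
    """
    for sample, mc in mean_coverage.items():
        if mc <= 0:
            raise ValueError(f"mean coverage for {sample!r} must be positive")
    for sc in calls:
        for sample, mc in mean_coverage.items():
            need = cfg.coverage_fraction * mc
            sc.sufficient[sample] = sc.depth.get(sample, 0) >= need and sc.depth.get(sample, 0) > 0
    return calls


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def screen_patterns(
    calls: list[SiteCall],
    design: PoolDesign,
    cfg: ScreenConfig,
) -> list[CandidateMutation]:
    """Classify every called site by its cross-sample penetrance pattern."""
    samples = list(design.samples)
    all_set = frozenset(samples)
    patterns: dict[frozenset[str], str] = {}
    for lineage in design.lineages:
        pat = design.expected_pattern(lineage)
        if not pat:
            raise ValueError(f"design gives lineage {lineage!r} no expected pattern")
        patterns[pat] = lineage

    out: list[CandidateMutation] = []
    for sc in calls:
        pen_full, pen_lowcov, subpen, any_alt = set(), set(), set(), set()
        for s in samples:
            af = sc.alt_fraction(s)
            if af is None:
                continue
            if sc.alt_count.get(s, 0) > 0:
                any_alt.add(s)
            if af >= cfg.penetrance_min:
                (pen_full if sc.sufficient.get(s, False) else pen_lowcov).add(s)
            elif af > 0:
                subpen.add(s)
        pset = frozenset(pen_full)
        cls: str
        lineage: str | None = None
        if pset == all_set:
            cls = "reference_error"
        elif pset in patterns:
            lineage = patterns[pset]
            outside = all_set - pset
            if any(sc.depth.get(s, 0) < cfg.min_absent_depth for s in outside):
                cls, lineage = "inconsistent", None
            elif any(sc.alt_count.get(s, 0) > cfg.absence_max_alt for s in outside):
                cls, lineage = "partial_penetrance", None
            elif cfg.strict_all_samples and any(not sc.sufficient.get(s, False) for s in outside):
                cls, lineage = "low_coverage", None
            else:
                cls = "pattern_candidate"
        elif pen_lowcov and (frozenset(pen_full | pen_lowcov) in patterns
                             or pen_full | pen_lowcov == all_set):
            cls = "low_coverage"
        elif subpen:
            cls = "partial_penetrance"
        else:
            cls = "inconsistent"
        out.append(CandidateMutation(sc, pset, cls, matched_lineage=lineage))
    return out


def flag_homopolymers(
    candidates: list[CandidateMutation],
    reference: ReferenceGenome,
    cfg: ScreenConfig,
) -> list[CandidateMutation]:
    """Flag 1-base indels sitting in reference single-base runs.

    Such events are the signature error mode of pyrosequencing-derived
    assemblies and dominate the shared "reference error" class.
    """
    for cand in candidates:
        sc = cand.site
        if not sc.is_indel or sc.indel_length != 1:
            cand.homopolymer_flag = False
            continue
        seq = reference.contigs[sc.contig]
        if sc.var_type == "del":
            s, e = homopolymer_run(seq, sc.pos)
            run = e - s
        else:  # insertion of base b after pos
            b = sc.alt[0]  # type: ignore[index]
            run = 0
            i = sc.pos
            while i >= 0 and seq[i] == b:
                run += 1
                i -= 1
            i = sc.pos + 1
            while i < len(seq) and seq[i] == b:
                run += 1
                i += 1
        cand.homopolymer_flag = run >= cfg.homopolymer_min_run
    return candidates


# ---------------------------------------------------------------------------
# reference correction
# ---------------------------------------------------------------------------

def apply_reference_corrections(
    reference: ReferenceGenome,
    errors: list[CandidateMutation],
) -> tuple[ReferenceGenome, list[dict]]:
    """Substitute the consensus alt at every shared reference-error site.

    Corrections are applied per contig in descending coordinate order; the
    change log records each edit and its cumulative length shift so old
    coordinates can be projected onto the corrected assembly.
    """
    per_contig: dict[str, list[SiteCall]] = {}
    for cand in errors:
        per_contig.setdefault(cand.site.contig, []).append(cand.site)
    for contig, lst in per_contig.items():
        lst.sort(key=lambda s: s.pos)
        prev_end = -1
        for sc in lst:
            start = sc.pos
            end = sc.pos + (sc.indel_length if sc.var_type == "del" else 1)
            if start < prev_end:
                raise ConsistencyError(f"overlapping corrections on {contig} at {start}")
            prev_end = end

    log: list[dict] = []
    corrected: dict[str, str] = {}
    for contig, seq in reference.contigs.items():
        buf = bytearray(seq, "ascii")
        shift_total = 0
        for sc in sorted(per_contig.get(contig, []), key=lambda s: s.pos, reverse=True):
            if sc.var_type == "snp":
                buf[sc.pos] = ord(sc.alt)  # type: ignore[arg-type]
                shift = 0
            elif sc.var_type == "ins":
                buf[sc.pos + 1 : sc.pos + 1] = str(sc.alt).encode()
                shift = len(str(sc.alt))
            else:
                buf[sc.pos : sc.pos + int(sc.alt)] = b""
                shift = -int(sc.alt)
            shift_total += shift
            log.append({"contig": contig, "pos": sc.pos, "type": sc.var_type,
                        "ref": sc.ref_allele, "alt": sc.alt, "shift": shift})
        corrected[contig] = buf.decode("ascii")
        if shift_total:
            log.append({"contig": contig, "pos": None, "type": "net_shift",
                        "ref": "", "alt": "", "shift": shift_total})
    log.reverse()
    return ReferenceGenome(corrected), log


# ---------------------------------------------------------------------------
# VCF-like export
# ---------------------------------------------------------------------------

def write_vcf(
    candidates: list[CandidateMutation],
    samples: list[str],
    reference: ReferenceGenome,
    path: str,
) -> None:
    """Write candidates as VCF with per-sample depth / alt-count fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Screen classification">\n')
        fh.write('##INFO=<ID=PATTERN,Number=1,Type=String,Description="Penetrant samples">\n')
        fh.write('##INFO=<ID=LINEAGE,Number=1,Type=String,Description="Matched design lineage">\n')
        fh.write('##INFO=<ID=HP,Number=0,Type=Flag,Description="Homopolymer-run 1-base indel">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\t" + "QUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for cand in sorted(candidates, key=lambda c: c.site.key):
            sc = cand.site
            seq = reference.contigs[sc.contig]
            if sc.var_type == "snp":
                pos1, ref, alt = sc.pos + 1, sc.ref_allele, str(sc.alt)
            elif sc.var_type == "ins":
                anchor = seq[sc.pos] if sc.pos >= 0 else "N"
                pos1, ref, alt = max(sc.pos, 0) + 1, anchor, anchor + str(sc.alt)
            else:
                a = sc.pos - 1
                anchor = seq[a] if a >= 0 else "N"
                pos1 = max(a, 0) + 1
                ref = anchor + seq[sc.pos : sc.pos + int(sc.alt)]
                alt = anchor
            info = f"CLASS={cand.classification};PATTERN={','.join(sorted(cand.pattern)) or '.'}"
            if cand.matched_lineage:
                info += f";LINEAGE={cand.matched_lineage}"
            if cand.homopolymer_flag:
                info += ";HP"
            cols = [sc.contig, str(pos1), ".", ref, alt, ".", "PASS", info, "DP:AC"]
            cols += [f"{sc.depth.get(s, 0)}:{sc.alt_count.get(s, 0)}" for s in samples]
            fh.write("\t".join(cols) + "\n")
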