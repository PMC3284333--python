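# Methods

`sporepool` implements bulked-segregant mutation mapping for haploid fungi
that can be crossed but have no marker maps: pools of phenotype-selected
single-spore isolates are sequenced, and the causative lesion is the variant
fixed in exactly the pools whose selection required it. This note records
the model, the simulator it is validated against, the numerical choices, and
the limits of what the tests demonstrate.

## The genetic model

Each mutant lineage carries one causative lesion plus a residue of
mutagen-induced background lesions. A cross against a marker strain yields
haploid single-spore isolates; selecting isolates for the mutant phenotype
fixes the causative allele in the pool (isolate frequency 1.0), while every
unlinked heterozygous-in-the-cross locus segregates 1:1 and lands at
Binomial(n, ½)/n in a pool of n isolates. With n = 40 the probability that
a background locus imitates fixation or absence is 2·0.5⁴⁰ ≈ 1.8·10⁻¹²,
which is what makes a penetrance filter on read fractions decisive.

Loci are treated as unlinked — isolates draw each background lesion
independently. Real meioses have linkage; loci near a causative gene would
ride toward fixation with it and could pass the penetrance filter as
passengers. No linkage map exists for the organism modelled, so this is out
of scope, and a real hit list may therefore contain linked passengers that
the simulation never produces. Genetics is haploid throughout; no
heterozygous genotype state exists anywhere in the code.

## The screen

1. **Cleaning** — any read containing an undetermined base is removed;
   a surviving mate is kept and mapped unpaired.
2. **Mapping** — the internal mapper is ungapped seed-and-extend (exact
   k-mer seed, default k = 20, extension budget 3 mismatches) with a strict
   unique-best rule: ties and repeats are unmapped. This mirrors
   conservative screening; gapped alignments of real data are imported from
   SAM instead, and indel evidence always enters via CIGAR.
3. **Pileup** — per-sample depth plus sparse alt evidence (mismatch counts,
   insertion strings anchored after their position, deletion lengths at
   their start). Indels are left-aligned through homopolymer runs before
   cross-sample merging so identical events share a key.
4. **Coverage rule** — a sample's evidence at a site counts only where local
   depth is at least `coverage_fraction` (default 0.4) of that sample's mean
   coverage, the mean being taken over covered positions only (an incomplete
   mapping should not deflate it). Low-coverage regions are refused, not
   guessed.
5. **Penetrance classification** — per site, the set of samples where the
   alt fraction reaches `penetrance_min` with sufficient depth is compared
   with each lineage's expected sample pattern. Penetrant everywhere →
   an error in the reference assembly, not a mutation. Penetrant in exactly
   one lineage's pattern with at most `absence_max_alt` supporting reads in
   every other covered sample → candidate for that lineage. Sub-penetrant
   support anywhere → segregating background or noise. A pattern-matching
   site whose outside samples are uncovered cannot assert absence and is
   classed inconsistent; penetrant-but-thin sites are classed low_coverage.

### Threshold defaults and the error model

`ScreenConfig` defaults are the literal rules (penetrance 1.0, zero alt
reads tolerated elsewhere, absence assertable from one read). Those are
correct for error-free evidence but not for substitution noise: with
i.i.d. errors at rate e and depth d, full literal penetrance survives with
probability (1−e)^d (≈ 0.78 at e = 0.005, d = 50), and a specific alt base
appears spuriously in another sample with probability 1−(1−e/3)^d (≈ 8%).
The bundled pipeline configuration therefore runs the screen at
`penetrance_min = 0.9`, `absence_max_alt = 2`, `min_absent_depth = 5`, with
a call floor of 2 alt reads and 20% alt fraction. At d ≈ 50 these keep the
miss probability per causative site and the false-absence probability both
below 10⁻⁴ while leaving the background-rejection margin astronomically
wide (a Binomial(40, ½) pool reaches 90% read penetrance with probability
≈ 3·10⁻⁹). These were fixed from the closed forms above, not fitted.

### Indel evidence accounting

A 1-base indel inside a homopolymer run is representationally degenerate:
within the run, and at equal edit cost near a read end, an aligner may emit
either the indel or a shifted tail of mismatches. Two measures make the
counts stable. First, alignments produced by the truth-guided realigner
prefer the ungapped representation whenever it explains the read with no
more edits (parsimony). Second, the depth denominator for an indel site is
the number of reads spanning the run plus a 10-base anchor on each side —
reads entering the run with less anchor carry no usable information —
floored at the alt count itself, since a read that reported the indel
certainly covers it.

## Structural lesions

Two detectors, deliberately complementary:

* **Coverage gaps** — maximal zero-depth runs in the target pool (runs
  separated by < `gap_join` = 50 b merged), at least `min_len` = 500 b long,
  with every other pool averaging ≥ `other_min_depth` = 5× over the run.
  A region bare in all pools is unsequenceable, not a deletion. At 40×,
  P(depth 0) ≈ e⁻⁴⁰ per position, so random holes of any length are
  essentially impossible and the thresholds are generous.
* **Insert-size anomalies** — mate pairs ordered by leftmost coordinate;
  a sliding window of 100 pairs is flagged when its interquartile range of
  observed outer distances clears `z · sd/√window` (z = 6) on one side of
  the library insert. Flagged windows are merged into loci (gaps smaller
  than one insert joined), and a locus is reported only if (a) it extends
  over at least 0.75 insert lengths of leftmost positions — every fragment
  spanning a real unbalanced lesion shifts, so the anomaly must be that
  wide — and (b) the median shift over the flagged core exceeds both the
  threshold and the core's interquartile spread.

The second detector's coherence conditions are what preserve the method's
signature result: a deletion whose interval was replaced by duplicated
copies of flanking sequence keeps spanning inserts near normal, while reads
from the copies map back to their source and generate short, sign-mixed
insert shifts. A bare windowed median flags those; requiring locus-scale
extent and coherence rejects them, so the balanced replacement is found
*only* by the coverage scan — and a plain deletion of the same size by both
detectors, with a median shift equal to the deleted length. Fragments
whose leftmost position lies within one insert plus 4 sd of a contig end
are excluded (fragment-length truncation there biases the local median
short).

## The simulator

The generator reproduces the study conditions the screen assumes: a random
haploid reference (single 2-Mb contig in the bundled demonstration;
arbitrary contigs supported); EMS-style lesions (90% transitions), three
causative lesions — a plain SNP, a G→A hit on the first base of a planted
gene's second intron (donor site), and an A→G hit on a planted TGA stop —
120 background SNPs split across the three lineages; four pools of 40
isolates (wild type with every causative allele counterselected, a double
mutant, a single mutant sharing one lineage, and an independent mutant);
and paired reads of 76 b from Normal(2000, 200) fragments at 50× with
substitution errors at 0.5% and N-replacement at 0.1%. Pools realise each
causative count by selection state and each background count as
Binomial(40, ½), assigning carriers to isolates uniformly; reads are drawn
per isolate, uniformly along contigs.

Planted genes are written directly into the reference: random sense codons
behind ATG, GT..AG introns, a TGA stop, and — for the stop-loss gene — 106
sense codons then TAA downstream, so the extension after the A→G lesion is
exactly 107 residues under the convention below. The second intron's
length is not a multiple of three, so its retention frameshifts the
peptide. The balanced rearrangement generator deletes an interval and
refills it with duplicated copies of flanking segments (sources alternating
between the two flanks, one copy inverted), reproducing a
length-conserving, coverage-visible, insert-silent lesion.

What the simulator does **not** model, hence what green tests cannot show:
linkage (above); base-quality profiles and quality-aware filtering (errors
are uniform i.i.d.; real error hotspots could defeat the absence rule at
`absence_max_alt = 2`); mate-pair chimeras and PCR duplicates; indel
sequencing errors (indel logic is exercised through planted true indels and
reference defects instead); diploid genotypes.

## Consequence annotation

Gene models are coding exons on one strand (GFF3 in, 0-based half-open
internally). Classification is purely coordinate/allele-driven: donor =
first two transcribed intron bases, acceptor = last two; exonic SNPs by
codon comparison on the coding strand (standard nuclear code); sub-4-base
indels in CDS split by length mod 3; larger deletions overlapping CDS are
cds_deletion. Stop-loss extension translates in frame from the mutated
stop through downstream genomic sequence to the next in-frame stop; by
default the residue encoded by the mutated stop codon counts and the new
terminal stop does not (`include_mutated_codon=False` gives the
one-smaller convention; the field's usage varies and deposited annotations
may follow either). Splice-defect transcripts are built mechanically:
retention keeps the broken intron; a supplied cryptic 5′ site splices from
there to the normal acceptor. Cryptic sites are inputs, not predictions —
in the study this pipeline models they were established by RT-PCR.

## Determinism and problem sizes

Every stochastic step takes a `numpy` Generator; the pipeline spawns
per-sample streams from one master seed, so a configuration re-runs
byte-identically. The test suite and `scripts/acceptance.py` use desk-scale
genomes — 0.1–0.3 Mb for recovery and defect scenarios, ten 200-kb
replicates for the recovery rate, 100-kb two-pool simulations for the
structural demonstrations — sizes at which every expected count is exact
(the binomial arguments above are size-independent) while a full run stays
in minutes. The bundled `examples/demo.yaml` runs the same scenario at
2 Mb.

## Known limitations

* The internal mapper is ungapped: reads over planted small indels in
  *sample* genomes fail to map, so indel-variant evidence must come through
  imported gapped SAM (or the truth realigner in simulations). Documented
  rather than fixed; real data should be mapped with a production aligner.
* Reported mapped fractions on simulated data are ≈ 100%, unlike the 60–87%
  of real jumping libraries; the pipeline reports what it measures and does
  not emulate library artifacts.
* Multi-allelic sites are handled allele-by-allele (each alt keyed
  separately); no joint genotype likelihood exists.
* Contig-terminal zones (about one insert length) have inherently thin
  mate-pair coverage; the screen classes sites there low_coverage, and the
  insert detector masks them entirely.
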