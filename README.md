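# sporepool

Pooled-progeny whole-genome sequencing analysis for mapping causative
mutations in haploid fungal crosses — with a full synthetic
cross/pool/read simulator so every stage is verifiable at desk scale.

## The problem

Forward-genetic screens in filamentous fungi produce mutants whose
causative lesion is unknown, and most species have no SNP maps or mapping
strains to narrow it down. If the organism can be crossed, there is a
shortcut: cross the mutant, select single-spore (haploid) isolates for the
mutant phenotype, pool ~40 of them, and sequence the pool alongside pools
for the other genotypes of the cross. Selection fixes the causative allele
in its pool — **every** read covering the site carries it (100%
penetrance) — while each unlinked background lesion segregates 1:1 and
shows up in only about half the reads: for a pool of n = 40 haploids, a
background locus imitates fixation with probability 2·0.5⁴⁰ ≈ 2·10⁻¹².
Variants shared by *all* pools, including the re-sequenced wild type, are
errors in the reference assembly, not mutations.

`sporepool` implements that screen end to end for anyone running such a
pooled cross design (or wanting to validate one before sequencing):

* **simulate** — reference genomes, EMS-spectrum lesions (transition-biased
  SNPs, sub-4-base indels, kilobase deletions, deletion-replaced-by-
  duplicated-flank rearrangements), phenotype-selected haploid pools, and
  mate-pair reads from ~2-kb fragments, all with an exact truth table;
* **clean / map / pileup** — N-read removal, a minimal unique-best
  ungapped mapper (or SAM import from a production aligner), per-sample
  pileups and coverage tracks, sequencing summary tables;
* **screen** — the coverage-filtered (≥ 40% of a sample's mean),
  100%-penetrance, cross-sample-pattern classification separating
  candidate mutations from segregating background and reference errors,
  with homopolymer-indel flagging and reference correction;
* **structural** — sample-specific zero-coverage intervals and coherent
  mate-pair insert-size shifts, two detectors that are deliberately
  complementary: a deletion whose interval was replaced by duplicated
  flanking sequence is invisible to the insert screen but obvious as a
  coverage gap;
* **annotate** — gene-model overlay: splice-donor/acceptor hits, the
  transcripts and peptides of a broken donor site (intron retention,
  cryptic 5′ site), stop-loss lesions with their C-terminal extension to
  the next in-frame stop, frameshift/in-frame indels, CDS deletions.

The statistics the screen turns on are the read-fraction penetrance
p̂ = alt/depth per pool, the local-coverage rule depth ≥ 0.4·mean, and the
fixed-vs-Binomial(n, ½) contrast between selected and unselected loci; the
structural screen tests windows of mate-pair outer distances against the
library insert (median and interquartile coherence at z·σ/√w). See
`docs/methods.md` for the model, thresholds, and their calibration.

## Worked example

The bundled configuration simulates the four-pool cross design at full
scale — a 2-Mb reference, three mutant lineages (a plain SNP, a
splice-donor G→A in a planted two-intron gene, a stop-loss A→G in a
planted single-exon gene), 120 background SNPs, four pools of 40 isolates
at 50× mate-pair coverage with 0.5% sequencing error — then runs the whole
screen:

```
sporepool run --config examples/demo.yaml --outdir demo_out
```

prints

```
pattern candidates: 3
reference errors:   0
structural:         0
```

and `demo_out/table3.tsv` holds the per-genotype screen summary:

```
genotype	samples	n_variants_coverage_ok	n_full_penetrance	location
wild type	wt	0	0	-
mutA	mutA_colour	1	1	-
colour	colour,mutA_colour	1	1	splice_donor of geneA
mutB	mutB	1	1	stop_loss of geneB
```

Reading it: of the thousands of sites with any read-level deviation, the
penetrance filter leaves exactly one candidate per mutant lineage — each
at the planted coordinate — and the consequence caller identifies the
splice-donor hit (first base of intron 2) and the stop-loss (TGA→TGG,
whose predicted protein gains 107 residues before the next in-frame stop,
see `demo_out/consequences.tsv`). The 120 segregating background lesions
all surface near 50% penetrance and are classed as such; none reach
candidacy. Other artifacts: `variants.vcf` (every called site with
per-pool depth/alt counts and its classification), `structural.bed`,
`table2.tsv` (per-pool read/coverage summary), `truth.tsv` (the planted
ground truth), `report.json`.

The same library functions drive everything programmatically
(`sporepool.run_pipeline`, `sporepool.structural_demo`, ...), and each
stage exists as a CLI subcommand (`simulate`, `clean`, `map`, `pileup`,
`screen`, `structural`, `annotate`, `run`, `report`) for file-based use,
including SAM import for reads mapped with an external aligner.

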