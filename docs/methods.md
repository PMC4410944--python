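# Methods

## Generative model

The simulator emulates an F1 hybrid of two inbred strains (maternal ×
paternal) profiled by ChIP-seq and strand-specific RNA-seq.

**Genome.** Each chromosome is an i.i.d. uniform ACGT sequence. The paternal
haplotype equals the maternal one except at SNP positions, drawn as a
Bernoulli process at rate `snp_rate` (default 1/500 bp, the order of
strain-distinguishing SNP density in inter-subspecific mouse crosses) and
substituted with a uniformly chosen different base. Inside every DMR
additional SNPs are forced at `dmr_snp_spacing` (default 200 bp) so allelic
assignment always has evidence there. With `snp_rate = 0` the two haplotypes
are identical and no SNPs are forced.

**Annotation layout.** Chromosomes carry a pericentric block at the start
and a telomeric block at the end; genes occupy regularly spaced slots in
between, with ERVK/LINE repeats and intergenic CGIs parcelled into the
intergenic gaps (with margins that keep all enrichment classes disjoint).
`n_imprinted` genes (default 18, matching the size of a curated
non-redundant imprinted panel) each host one intragenic DMR overlapping
exactly one methylated CGI, placed mid-gene so it stays clear of the TSS
window. The expected expressed allele alternates maternal/paternal across
imprinted loci; the methylated (silenced) allele is the opposite one.
About half of the non-imprinted genes get an unmethylated promoter CGI.

**ChIP tracks.** A track of `chip_depth` reads (default 60,000 over the
420 kb demo genome, i.e. ~7× base coverage) is drawn from a piecewise-
uniform density: weight 1 per background bp, weight `fold` per bp of each
interval the mark is enriched over. Defaults: ATRX/H3.3/H3K9me3 8× and
H4K20me3 6× at DMRs and pericentric blocks (telomeric/ERVK slightly lower),
H3K4me3 6× at promoter CGIs and DMRs, input 1× everywhere. A read
overlapping a DMR is drawn from the methylated allele with probability
`dmr_bias` (0.85–0.9 for the heterochromatic marks, 0.1 for H3K4me3, 0.5
for input) — biases are high but sub-unity because ChIP enrichment of the
wrong allele is never zero in practice; elsewhere the haplotype is a fair
coin. The read records the haplotype base at every SNP it covers, which is
the only allelic evidence the analysis may consult.

**RNA-seq.** Reads come only from expressed genes, allocated
length-proportionally; each read's haplotype is Bernoulli(maternal
fraction) of its gene (0.5 for background genes, 0.9 toward the expected
allele for imprinted genes). The KO condition substitutes a de-repressed
fraction table: at 5 of the 18 imprinted loci the expected-allele fraction
moves 0.3 toward 0.5 (e.g. 0.9 → 0.6), all other genes unchanged — loss of
the heterochromatic machinery re-activates the silenced allele without
touching biallelic genes. Library strandedness follows the dUTP convention
(read strand opposite the transcript strand); the convention is declared in
the config and shared with the allelic counter. Both PolyA fractions share
the generative model and differ only in label.

**What is deliberately not modelled** (and hence what passing tests do not
show about real data): sequencing error, PCR duplicates, mappability and
reference-mapping bias (real PolyA− baselines show a ~54 % reference-strain
artifact), indels, copy-number variation, aligner behaviour (reads are
emitted pre-placed at true coordinates), partial restriction digestion, and
fragment-size effects.

## Analysis rules and thresholds

| parameter | default | meaning |
|---|---|---|
| informative-read floor | 50 | genes kept iff informative reads > 50 (strict) |
| strong / moderate skew | 0.66 / 0.60 | imprinting categories, strict > |
| disruption delta | 0.10 | WT/KO expected-allele shift, strict >, both conditions past the floor |
| repeat fold / floor | 2.0 / 50 | class enriched iff RPM fold over input > 2; < 50 raw ChIP reads excluded |
| enrichment percentiles | 25 / 75 | low < P25, high > P75 of the baseline; enriched iff > P75 of the random-fragment null |
| peak caller | 1 kb window, fold 2, merge 500 bp, ≥ 10 reads | windows kept on ChIP RPM > fold × input RPM |
| promoter window | TSS ± 1 kb | CGI positional classification; promoter wins over intragenic |
| transcribed | RPKM > 1 | cascade transcription filter |

**Parental assignment.** Each SNP a read covers votes
maternal/paternal/neither by base identity; unanimous votes assign the read,
any conflict or an all-neither pattern makes it ambiguous, and a read
counts once regardless of how many concordant SNPs it covers (avoids
pseudo-replication). Reads overlapping no SNP are uninformative. Skew for a
target is computed over informative reads only.

**Strand-specific counting.** A read contributes to a gene iff it overlaps
the gene body and its strand matches the transcript under the declared
convention; overlapping antisense gene pairs therefore partition cleanly.

## Numerical choices

* **Coordinates** are 0-based half-open everywhere; 1-based only in
  VCF/SAM serialization (maternal allele = REF, paternal = ALT, phased
  genotype `0|1`).
* **Percentiles** use the floor-type order statistic (numpy
  `method="lower"`): P25 of 1..100 is exactly 25, so the strict "<"/">"
  boundary classes behave as printed; it also makes percentile comparisons
  exact on integer baselines.
* **Threshold comparisons** (skew categories, the 10 % disruption delta,
  the 2-fold repeat rule) are evaluated in exact rational arithmetic
  (`Fraction` of read counts against the decimal cutoff) so binary-float
  artifacts cannot flip a boundary case; reported values are floats.
* **Zero-input folds** are reported as an `inf` sentinel with a flag rather
  than an error (sparse synthetic inputs make them legitimate).
* **Empty survivor sets / zero-informative targets** yield `None`
  ("undefined") fractions, never exceptions.
* **Restriction sites** are IUPAC-expanded and scanned on both strands
  (reverse-orientation matches for non-palindromic sites), overlapping
  matches included; the cut offset defaults to the blunt midpoint of the
  recognition sequence and is per-enzyme configurable. Band intensity
  defaults to the mass model (molar amount × fragment length, as for
  intercalating dyes), switchable to molar-proportional.
* **Vectorized allelic counting** (`count_allelic_rna_batch`) locates genes
  by coordinates and strand and derives votes from haplotype bases at SNPs
  — never from simulator truth labels; the test-suite asserts exact
  equality of its tallies with the per-read path.
* **Determinism.** Every stochastic component takes a seed; per-track
  generators are derived from (seed, track label) so adding a track never
  perturbs another. Re-running the pipeline with one config reproduces
  byte-identical reports.

## Problem sizes

The demo genome is 2 × ~210 kb with 60 genes; ChIP tracks are 60,000 reads
and RNA libraries 500,000 reads, sized so each DMR collects ≥ ~100
informative ChIP reads and each gene ~900 informative RNA reads — enough
that a 10 % allelic shift stands several standard errors above binomial
noise. The control panels use 1,500 short SNP-dense genes (1 SNP / 25 bp)
with ~130 informative reads per gene for the baseline and ~1,400 for the
WT/KO disruption screen; the latter depth was fixed by a power calculation
(the chance that binomial noise alone moves any of 1,500 balanced genes by
more than 10 % must stay ≪ 1 per screen).

## Design choices where the design was open

* The peak caller is a plain window/fold/merge scheme with parameters in
  config, and ground-truth peak BEDs are accepted anywhere peaks are
  consumed, so callers can be swapped without touching downstream code.
* The repeat low-coverage exclusion is applied to the ChIP track's raw
  mapped reads (the track whose sparsity makes folds unstable).
* Paired-end mates are not simulated; the assignment rule for pairs
  (concordant mates count once, discordant pairs ambiguous) is documented
  in `allelic` but exercised only single-end.
* Multi-placement repeat reads: class-level tallies count every overlapped
  repeat instance once per instance, while unique-interval quantitation
  counts each read once per interval — preserving repeat sensitivity
  without double-counting peaks.

## Limitations

Synthetic genomes are far below genome scale, so absolute numbers
(peak counts, CGI tallies) are demonstration-sized; only the statistical
structure — enrichment folds, allelic biases, skew distributions, threshold
behaviour — is meant to transfer. Reference-mapping bias, the dominant real
artifact in allele-specific analysis, is intentionally absent, so baselines
here are centred at exactly 50 %.
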