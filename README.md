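# imprintscan

Allele-resolved chromatin and expression analysis of genomically imprinted
loci, exercised end-to-end on synthetic diploid genomes.

## The problem

Imprinted genes are expressed from one parental allele. Their imprinting
control regions are differentially methylated (DMRs): one allele carries DNA
methylation and constitutive-heterochromatin marks (H3K9me3, H4K20me3, the
ATRX-deposited histone variant H3.3), the other carries active marks
(H3K4me3). Bulk ChIP-seq and RNA-seq average over both alleles, so resolving
this structure requires an F1 hybrid of two inbred strains whose SNPs let
each sequencing read be assigned to its parental haplotype.

This package implements that analysis as a tested, reusable pipeline:

* **`synthetic_data`** — a diploid-genome and read simulator: two haplotypes
  differing only at phased SNPs; imprinted genes hosting methylated
  intragenic CGIs/DMRs; per-mark enrichment folds and allelic biases; a KO
  condition that de-represses a subset of DMR-regulated genes; uniform
  background reads elsewhere. Ground truth is emitted for every parameter so
  recovery can be tested.
* **`quantify`** — read counting in intervals, reads-per-million (RPM)
  normalization, a random-fragment null (fragment lengths resampled from a
  template interval set), repeat-class enrichment (classes with < 50 raw
  ChIP reads excluded; enriched iff RPM fold over input > 2), low/mid/high
  percentile classes (strict < P25 / > P75), and a window/fold/merge peak
  caller.
* **`cgi_annotate`** — CGI positional classes (promoter / intragenic /
  intergenic, promoter wins) and the sequential filter cascade
  (methylation → H3K9me3∧H4K20me3 → H3.3 → transcription) that isolates
  ATRX-associated islands.
* **`allelic`** — SNP-based parental assignment (per-read unanimous voting;
  conflicts are ambiguous), strand-specific gene-level counting (dUTP
  convention), the > 50 informative-read floor, imprinting categories
  (strong > 66 %, moderate > 60 % skew toward the expected allele), and the
  WT-vs-KO disruption call (allelic shift > 10 %). Threshold comparisons use
  exact rational arithmetic so printed boundaries are strict.
* **`digest`** — in-silico RFLP allelic discrimination: IUPAC restriction-
  site scanning on both strands, per-allele amplicon fragment prediction,
  and band-intensity quantitation of allelic enrichment relative to input.
* **`table1`/`pipeline`/`cli`** — the packaged 21-row catalogue of mouse
  imprinted DMRs with ATRX status and mark levels, the end-to-end demo
  pipeline, and the `imprintscan` command-line surface.

The key statistic throughout is the **parental skew** of a target with
maternal/paternal informative-read counts (m, p):

    skew = reads on the expected allele / (m + p)

with binomial sampling error sqrt(f(1−f)/n) at true fraction f and
n = m + p informative reads.

## Worked example

```bash
python analysis/01_simulate.py --seed 0      # build genome + 8 read tracks
python analysis/02_enrichment.py             # peaks, repeats, CGI profiles
python analysis/03_cgi_cascade.py            # sequential CGI filtering
python analysis/04_allelic_imprinting.py     # allelic ChIP + RNA, WT vs KO
python analysis/05_digest.py                 # in-silico RFLP validation
python analysis/06_table1_summary.py         # the DMR catalogue
```

Step 3 prints the cascade converging on the planted imprinted islands:

```
after all           44 CGIs remain, 41% ATRX-bound
after methylated    18 CGIs remain, 100% ATRX-bound
after het_marks     18 CGIs remain, 100% ATRX-bound
after H3.3          18 CGIs remain, 100% ATRX-bound
after transcribed   18 CGIs remain, 100% ATRX-bound
```

and step 4 the allele-resolved picture:

```
ChIP at 18 DMRs: heterochromatic marks skew 0.79-0.94 toward the methylated allele; H3K4me3 0.07-0.14
imprinted genes called strong (>66% skew) in WT: 18 of 18
control-gene baseline skew: 50.3% (SD 2.0%, n=36)
KO-disrupted genes (>10% allelic shift): chr1_g0000, chr1_g0010, chr1_g0023, chr2_g0033, chr2_g0046
```

The five disrupted genes are exactly the five whose expected-allele fraction
the simulated KO shifted by 0.3; heterochromatic marks sit on the methylated
allele at every DMR while H3K4me3 marks the opposite allele; unskewed
control genes average 50 %. The same run is available as one command,
`imprintscan run-all --seed 0 --out results/pipeline`, which also writes a
run log with every threshold applied.

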