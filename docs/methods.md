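# Methods

## The problem

Ethyl methanesulfonate (EMS) alkylates guanine, so a mutagenized plant
carries a few thousand heterozygous G:C→A:T transitions and essentially
nothing else. When such a line segregates a recessive mutant, the causal
allele can in principle be found by whole-genome sequencing alone: every
induced SNP is a molecular marker, and within a selfed pedigree the causal
site must be homozygous alternate in pooled mutants, heterozygous in a
segregating sibling, and homozygous reference in a true-breeding wild-type
sibling. No outcross is needed, so no foreign segregation variance is
introduced.

Two obstacles make the naive version of this fail. First, short-read
variant calling produces false positives at a rate that dwarfs the true
mutation count in mutagenized material. Second, many false calls are not
random: specific genomic positions (reference errors, sub-line drift,
paralogous or collapsed repeats) yield spurious variant calls
reproducibly, in any sample. This package implements the remedy: a strict
quality cascade tuned to the EMS spectrum, subtraction of positions
called in independently mutagenized lineages (which cannot share true
EMS alleles), and allele-frequency cosegregation across pedigree roles.

## Pipeline stages

1. **Genotype calling** (`caller`). A binomial consensus model over
   per-position reference/alternate read counts. The per-read alternate
   probability is e/3 under hom-ref, 1/2 under het, 1−e under hom-alt
   (e = per-base error). The call is the maximum-likelihood genotype
   (ties resolved to hom-ref) and the variant quality is the Phred-scaled
   posterior of hom-ref under a uniform prior, capped at 255. This is a
   deliberately simple, fully documented stand-in for a production
   pileup caller: the published settings of such callers are not
   reproducible from their descriptions, and nothing downstream depends
   on caller internals beyond genotype, quality, depth, and strand
   counts.

2. **Filter cascade** (`filters`). Seven composable filters applied in a
   fixed order, with survivor accounting at five checkpoints:
   depth within [2, 100] (the upper bound doubles as the repetitive-region
   screen), RMS mapping quality ≥ 10, no call within 3 bp of indel/gap
   evidence, biallelic positions only, homozygous-alternate calls at
   quality ≥ 20, zero reference reads with alternate support on both
   strands, and finally the EMS spectrum restriction to G→A and C→T on
   the reference strand. Every threshold is inclusive on the retained
   side. Records lacking strand-resolved counts fail the purity filter
   under the strict default, with a configuration escape hatch.

3. **Cross-lineage subtraction** (`subtract`). Positions called in more
   than one independently mutagenized lineage are error-prone positions;
   they are removed from each line's survivor set. Matching is
   allele-agnostic (chromosome + position), because an error-prone
   position may surface different alleles in different samples. Sharing
   *within* a lineage is informative (siblings inherit their founder's
   mutations) and is retained. Phenotypically normal mutagenized siblings
   serve as marker donors ("EVIL twins"): their lineage-unique SNP sets
   are exactly the per-line unique VCFs this stage emits.

4. **Effect annotation** (`effects`). CDS-aware codon classification with
   the standard genetic code: synonymous (LOW), missense (MODERATE),
   nonsense / stop-loss / start-loss / splice-site (HIGH), intronic and
   intergenic (MODIFIER). The splice window is the 2 intronic bases on
   each side of internal exon junctions. Codon-change strings uppercase
   the mutated base (`Cag/Tag`); amino-acid changes read refAA, 1-based
   codon number, altAA with `stop` for termination (`Q225stop`). The
   module also houses the expected-load calculator: with C bp of coding
   sequence and rate r per bp, the expected genic load is C·r and the
   nonsynonymous load C·r·(1−s) with synonymous fraction s = 1/3 by
   default (30 Mbp at 1/125,000 gives 240 and 160).

5. **Cosegregation mapping** (`mapping`). The mutant pool's lineage-unique
   survivors are the markers. Their raw allele frequencies — computed
   from the count tables, never from genotype calls — are read in the
   wild-type sibling pool ("Hormigas" scatter). The causal region is the
   only place where the wild-type sibling is reference at
   mutant-homozygous markers, so an explicit run detector finds maximal
   runs of ≥ `min_interval_markers` (default 3) consecutive markers with
   wild-type frequency ≤ `wt_max_freq` (default 0.2); runs rank by marker
   count, then mean frequency, then coordinate. Candidates are then
   reduced along a fixed chain: cascade survivors → lineage-unique → not
   called in either sibling → protein-altering → pedigree-consistent →
   inside the top interval (skipped and flagged when no interval
   qualifies).

   Pedigree consistency requires mutant-pool frequency ≥ 0.9, the
   heterozygous sibling inside [0.2, 0.8], and the wild-type sibling
   ≤ 0.2. A role whose frequency is missing, or which *fails* its window
   on fewer than `min_consistency_depth` reads (default 10), yields the
   verdict `insufficient_coverage` rather than exclusion: at seven-fold
   coverage a true heterozygote misses a fixed window too often for a
   hard cut to be defensible, and the report keeps the two verdicts
   separate.

## The synthetic study design

The simulator (`simulate`) is first-class, tested code; its defaults *are*
the study conditions, and the end-to-end acceptance checks run against it.

- **Genome**: 5 Mb in two 2.5 Mb chromosomes, uniform base composition,
  100 non-overlapping genes (1–4 CDS exons, ATG start, clean internal
  codons, terminal stop, mean CDS ≈ 1.2 kb).
- **Mutagenesis**: three independent lineages, each receiving independent
  G:C→A:T mutations at 1/125,000 per bp (≈ 40 per founder), heterozygous
  on a random founder haplotype. One planted mutation in the focal
  lineage converts a mid-CDS codon to a premature stop; it is appended to
  the lineage's mutation set and recorded as ground truth.
- **Pedigree**: the focal founder is selfed three times, selecting a
  causal-site heterozygote each generation; the resulting family supplies
  13 pooled homozygous mutants, one heterozygous sibling, and one
  homozygous-reference sibling selfed once into a 17-member wild-type
  pool. Two unrelated lineages are propagated identically without
  selection. Meioses place Poisson crossovers (no interference, uniform
  positions). The default of 0.1 crossovers per chromosome per meiosis
  keeps the crossover density per Mb at the few-percent scale of a real
  grass chromosome after shrinking it to 2.5 Mb; one crossover per
  miniature chromosome would make every marker effectively unlinked.
- **Sequencing**: per-site depth is Poisson at the line's target
  (45×/7×/30×/3×/43× for wild-type pool, het sibling, mutant pool, and
  the two unrelated lines), reads split between strands Binomial(n, 1/2),
  per-base error 0.001 (a typical post-quality-filter substitution rate
  for short-read data).
- **Planted artifacts**: 50 error-prone positions emit a site-specific
  spurious base per read with probability 0.9 in every line regardless
  of genotype — the read-level signature of paralogy/misassembly, with
  no mechanistic model behind it; 50 homozygous non-EMS-spectrum
  background differences shared by all lineages emulate drift between
  the material and the reference assembly; 100 indel positions provide
  gap evidence for the proximity filter.

What the generator does **not** emulate: read-level artifacts (quality
strings, mapping, indel realignment), GC-biased coverage, linked-error
tracks, multi-transcript genes, UTRs (SNPs inside a gene but outside CDS
are intronic), and genome-scale marker counts. Passing tests therefore
demonstrate the logic of the method — spectrum filtering, subtraction,
cosegregation — at desk scale, not variant-calling performance on real
alignments.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere; conversions live only in
  readers/writers.
- All filter thresholds are inclusive on the retained side.
- Caller genotype ties break toward hom-ref (fewer false variants); the
  interval ranker breaks ties by marker count, then mean frequency, then
  coordinate; the multinomial read sampler resolves tied alternate bases
  lexicographically.
- Founder mutations are heterozygous in the treated generation (seed
  mutagenesis of a diploid alkylates single strands; homozygosity cannot
  arise before the first selfing).
- Zero-depth sites yield `no_call` with quality 0 and a missing allele
  frequency; frequency-dependent logic treats missing as
  "insufficient coverage", never as zero.
- Percentages in summary tables round half-up (one decimal for
  percent-unique cells, whole numbers for stage reductions). A handful of
  published-style percent cells differ from exact arithmetic by one unit
  in the last decimal; the implementation always follows the arithmetic.
- On a 20-seed sweep of the default design the final candidate list
  contains the planted causal SNP in 19/20 runs and is exactly that
  single SNP in 15/20 (the remainder are a linked protein-altering
  mutation inside the mapped interval — indistinguishable by this design
  without more recombinants — or a heterozygous-sibling frequency excursion
  at 7× coverage). The acceptance suite asserts ≥ 18/20 and ≥ 15/20.

## Known limitations

- The caller is intentionally minimal: no base-quality weighting, no
  mapping-quality downgrade, no indel genotyping.
- RMS mapping quality in simulated data is a constant 60, so the
  mapping-quality filter is exercised only by unit fixtures.
- The run-based interval detector assumes a single causal region; two
  mutants segregating simultaneously would need the ranked interval list
  rather than only the top interval.
- Error-prone positions are genotype-independent emitters; correlated
  error tracks and saturation of error-position discovery across many
  lines are out of scope.
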