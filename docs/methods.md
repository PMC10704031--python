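# Methods

## The mapping problem

An inbred line carries a single recessive causal SNP induced by EMS
mutagenesis, together with a load of background EMS mutations. Crossing
it to another inbred line and selecting F2 individuals that show the
recessive phenotype enriches the mutant allele around the causal locus:
every selected individual is homozygous mutant at the causal site, while
alleles at unlinked sites still segregate 1:2:1. Pooled sequencing of the
selected bulk converts that enrichment into an allele-frequency signal —
the SNP-index — that equals 1 at the causal site, decays with genetic
distance, and fluctuates around 0.5 far away. `bsamap` simulates this
world, computes the statistics, and filters candidates the way a mapping
study does.

## Simulation model

**Genome and map.** Chromosomes are (name, length) pairs with a uniform
recombination rate in cM/Mb (global or per chromosome). Default 2.5
cM/Mb — the order of magnitude of the tomato genome-wide average; the
value only sets how fast linkage decays and is freely configurable.

**Mutations.** The EMS parent is homozygous for the alternate allele at
one causal site and `n_background` background sites placed uniformly
(position collisions are resampled). A fraction
`ems_transition_fraction` (default 0.9) of background substitutions are
G>A or C>T, the canonical EMS signature from guanine alkylation; the
remainder are uniform over the other substitution classes. The causal
substitution defaults to T>A on the genomic strand, mirroring a causal
SNP inside a minus-strand gene whose coding-strand change is A>T.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the genetic map length in Morgans, positions uniform, no interference
(the Haldane model), and random starting phase. This is the standard
minimal model; crossover interference would slightly reduce double
crossovers at short scales but does not change any of the statistics
tested here in expectation. F2 individuals are two independent F1
gametes; BC1 individuals are one F1 gamete plus the recurrent parent's
(trivially homozygous) contribution. Phenotype is strictly recessive:
mutant iff homozygous alternate at the causal site — no incomplete
penetrance, no phenotyping error.

**Pools and reads.** A pool is a uniform without-replacement sample of
individuals of one phenotype class. Sequencing draws a Poisson depth per
site (a fixed-depth mode exists for exact tests), samples one of the
pool's `2n` haplotypes per read with replacement, and miscalls ref↔alt
with probability `error_rate`. Third alleles are out of scope
(biallelic world). Defaults follow the study design the package
emulates: pools of 28 (single-pool design) and 45 + 50 (two-pool
design), parent depths ~32–33×, pool depths ~34× and ~110×, error rate
0.001 in the scenario config.

**What the generator does not emulate.** Real pooled sequencing has
mapping artifacts, depth that tracks GC and repeat content, allele-
specific biases, index hopping, and genotyping error in the phenotyped
panel. A green recovery test therefore establishes that the statistics
and cascades are implemented correctly for the stated sampling model —
not that the thresholds would survive a real resequencing run
unchanged.

**Randomness.** Every operation takes an explicit seed;
`numpy.random.SeedSequence.spawn` derives independent child streams in
the scenario runner so identical (config, seed) reproduce all outputs
bitwise.

## Statistics

**SNP-index.** `alt / (ref + alt)`, reported missing below a depth
floor (default 8 reads — the index of a 3-read site is too unstable to
use; the threshold is a config value, not an inference). Missingness
propagates: a Δ with a missing constituent is missing, never
zero-filled.

**Sliding windows.** Windows `[k·step+1, k·step+window]` tile each
chromosome (defaults 2 Mb / 50 kb); the window statistic is the mean
over non-missing sites, missing below `min_sites` (default 10). The
defaults suit real SNP densities (thousands of sites per chromosome);
the synthetic examples use smaller windows matched to their simulated
density of a few sites per Mb. Window means are checked against a
literal brute-force rescan in the tests.

**Null bands.** The no-linkage null is simulated directly: each pool
member's genotype is drawn from the unselected F2 distribution (1:2:1,
i.e. dosage ~ Binomial(2, ½)), reads are binomial at the stated depth,
and the statistic (index for one pool, Δ for two independent pools) is
recomputed `n_reps` times (default 10,000). The band at level `1−α` is
the (α/2, 1−α/2) empirical quantile pair with linear interpolation.
Bands are computed at the median observed depth by the Model layer; a
depth-grid variant with nearest-depth matching exists for strongly
heterogeneous depths. By construction bands nest across levels and widen
as depth falls; both properties are asserted in tests rather than
assumed.

**Peak calls.** Windows whose statistic exceeds the band's upper bound
are merged when they overlap or abut; each maximal interval is reported
with its peak window value.

## Filter cascades

Genotype calls from pool counts use fixed index thresholds: homozygous-
alternate at index ≥ 0.9, homozygous-reference at ≤ 0.1, heterozygous
between, missing below the depth floor. The source study states its
exclusions only qualitatively; 0.9/0.1 is standard MutMap-style
practice and both thresholds are configurable.

The single-pool cascade retains sites called homozygous-alternate in
the mutant-phenotype pool (stages: called → not heterozygous → not
reference-congruent, optionally preceded by a peak-region restriction).
The two-pool cascade additionally requires both parents to be callable,
the contrasting pool's call to differ from the mutant parent's, and the
distant parent's call to differ from the mutant parent's. "Same
genotype" means equality of call labels, not of raw indexes. A MISSING
call on either side of a difference test fails that stage — a
difference cannot be established from absent evidence. Every site
records pass/fail per stage and the first stage that excluded it, so
stage-by-stage survivor counts (the published-style audit trail) are
reproducible. Intergenic candidates stay in the set; reports break them
out by region class so genic candidates can be prioritised.

## Variant effects

Gene models are single-transcript (alternative splicing out of scope),
1-based inclusive, with spliced strand-corrected CDS sequences read from
GFF3 + FASTA through gffutils/Biopython. Region classes: coding exon
(labelled with the 1-based spliced-CDS position), UTR exon (no coding
offset), intron (ordinal and offset both counted from the transcript 5'
end — the label dialect does not define the offset origin, so this
choice is explicit and symmetric with the exon rule), upstream /
downstream within 2 kb of the transcript start / end (strand-aware), and
intergenic. Containing genes win over flank hits; ties break by
distance, then gene id. Codon effects use the standard nuclear code via
Biopython; a stated reference allele that contradicts the CDS raises
rather than proceeding. Indels are only flagged frameshift / in-frame by
length mod 3.

## Segregation statistics

The segregation test is the two-class Pearson chi-square against an a:b
ratio, with the Yates continuity correction as a first-class option,
judged against the printed df=1, α=0.05 critical value 3.84. The
published table this mirrors is internally inconsistent about the
correction (its F2 row matches Yates, its BC1 row matches uncorrected
Pearson), so no single "convention" is guessed: every result records
which correction produced it. Ratios render as `x.xx:1` to match the
reporting dialect. Co-segregation counts phenotyped mutants whose
marker call is not homozygous-alternate; missing calls are tallied but
excluded from the denominator. Relative expression is the standard
2^−ΔΔCt.

## Numerical and design notes

- Counts are exact integers end to end; indexes are float64; missing is
  NaN everywhere.
- Read sampling uses the binomial equivalence of per-read haplotype
  draws with replacement — exact, not an approximation.
- Empirical quantiles use numpy's default linear interpolation.
- The acceptance script simulates its stochastic target at depth 34 with
  zero error; the probability of a zero-depth causal site (which would
  make the index undefined) is e^−34 ≈ 2·10⁻¹⁵.
- Recovery tests use populations of 200–300 so requested pool sizes of
  28/45/50 exist with overwhelming probability; simulated site counts
  (~100–300) keep the suite inside a CI budget and do not affect the
  per-site statistics being tested.

## Known limitations

- No read-level simulation (FASTQ), alignment or variant calling; the
  simulator starts at allele counts.
- Strictly biallelic SNVs; multi-allelic records are skipped on input.
- One transcript per gene; indel consequences limited to frame flags.
- Null bands condition on a single depth (or a depth grid), not on the
  joint depth distribution across sites.
- Phenotypes are fully penetrant and monogenic by construction.
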