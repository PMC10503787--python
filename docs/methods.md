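# Methods

This note documents the statistical model behind `dnmkit`, the design of
the synthetic-data generator, the numerical choices made where the
design was genuinely open, and what a passing test suite does and does
not establish.

## 1. The estimation problem

A germline de novo mutation (DNM) is present in an offspring but absent
from both parents' genomes. With deep (~50×) short-read sequencing of
pedigrees, DNMs appear as Mendelian violations: the offspring is
heterozygous where both parents are identical homozygotes. Naive
violation counts are dominated by artifacts (somatic mutations,
mapping/realignment errors, under-genotyped parental carriers), so the
rate estimator combines a stringent screen with three calibrations:

μ = n·(1 − FDR) / (2 · CS · (1 − FNR))

* **n** — curated candidate count per offspring. Mutations shared by
  full sibs (parental germline mosaics) are counted once per carrier in
  per-offspring totals; the unique-mutation tally is reported separately.
* **FDR** — the fraction of post-filter candidates the automated
  curation removes. Because `n` is the *post-curation* count, the
  pipeline applies FDR = 0 in the formula and reports the curation FDR
  alongside; multiplying pre-curation counts by (1 − FDR) is identical
  in expectation.
* **CS** — callable sites: positions where the offspring's depth lies
  strictly between half and double the mean trio depth, computed by
  interval arithmetic over per-sample depth tracks. Using the same
  relative-depth rule for candidates and for CS keeps numerator and
  denominator commensurate.
* **FNR** — the probability that the allelic-balance (AB) filter
  discards a true heterozygote, estimated from obligate heterozygotes:
  sites where one parent is 0/0 and the other 1/1 (parents passing the
  same depth/quality checks as in screening). Only the AB component
  enters: depth is conditioned on through CS, and offspring calls that
  are not heterozygous at obligate sites are genotyping misses of a
  different mechanism and are excluded from both numerator and
  denominator.

The factor 2 counts the two haploid genomes assayed per offspring.

### Filters

Site-level hard filters follow common short-read caller annotations
(removal when QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0; a missing annotation never
removes — rank sums are undefined without het carriers). Individual
filters remove a candidate when any trio member has DP ≤ 20, DP ≥ 100 or
GQ ≤ 80; when an identical-homozygote parent shows the de novo allele in
its AD; when the offspring AB falls outside (0.3, 0.7) (strict: AB = 0.3
is kept) or its depth outside (0.5, 2)× the trio mean; or within 5 bp of
an indel segregating in the trio. Cohort filters remove identical
candidates recurring in different families (artifact signature) while
keeping full-sib sharing as mosaicism, and flag candidates within 100 bp
of each other as clustered.

### Automated curation

Visual read inspection is replaced by the two automatable criteria it
implements in practice: (1) the summed parental raw-read support of the
de novo allele reaches 10% of the summed parental depth — raw-read
counts are taken from a separate support channel when provided, because
the caller may have dropped exactly those reads from the parents' AD
(otherwise the VCF AD is used); (2) the site lies in a poor-mapping
mask. Candidates with zero summed parental depth are uncurateable and
removed. The same mask is excluded from CS so the numerator and
denominator stay consistent.

### Aggregation and uncertainty

The aggregate rate is the mean of per-offspring rates. The 95% CI is a
t interval over **family mean rates**: full sibs share mosaic mutations,
so per-offspring rates within a clutch are positively correlated and
the family is the independent sampling unit — a per-offspring t interval
demonstrably undercovers in simulations with the default mosaic
fraction. Group (e.g. population) comparisons use Welch's t-test on
per-offspring rates (unequal variances, Welch–Satterthwaite df).
Transmission of F1 mutations to F2 offspring is tested against
Binomial(n, 0.5) by a pooled df = 1 chi-square and an exact binomial
test. `Ne = π/(4μ)` assumes mutation–drift equilibrium.

### Spectrum analyses

Substitutions are collapsed into six strand-symmetric classes
(transitions A:T>G:C and C:G>T:A), strong/weak pairing categories
(S = C/G, W = A/T) and CpG context (reference C followed by G or G
preceded by C; CpG>TpG flags the deamination signature). The
transition:transversion test uses a 1:2 null (uniform over the six
classes). CpG islands are predicted by the classical composition
criteria — length ≥ 200 bp, GC ≥ 50%, observed/expected CpG ≥ 0.6 with
obs/exp = N_CpG·L/(N_C·N_G) — via sliding 200-bp seed windows (step 1)
that are merged, re-tested, and boundary-refined: window averaging blurs
edges by up to a window length, so each merged interval is snapped to
its maximal-scoring CpG subsegment (Kadane scan, +1 per CpG start and a
per-base penalty of half the minimum CpG-start density an island can
have under the criteria) before the final criteria check. Islands are
classified TSS > TTS > intragenic > intergenic by whether they contain a
gene's transcription start/termination base or overlap a gene body.
Regional rates use the pooled form μ = Σn/(2·ΣL) ("zero-inflated":
robust to most offspring having zero mutations in a small compartment);
compartment rates are deliberately *not* FNR-corrected, matching how
such per-compartment tables are usually tabulated, while the
genome-wide rate is. Coding effects are determined by strand-aware
in-frame translation; intronic positions within 2 bp of an exon
boundary are splice-site hits. Parent-of-origin phasing follows reads
carrying the de novo allele to flanking offspring-het sites whose
observed allele occurs in exactly one parent's genotype; any conflict
between reads yields `unknown` (strict policy). α is the
paternal:maternal ratio over resolved mutations.

## 2. The synthetic-data generator

`dnmkit.simulate` builds a world in which every downstream stage has
known truth.

**Genome.** Background sequence at GC 0.42 with strong CpG depletion
(~90% of CpG dinucleotides rewritten; obs/exp ≈ 0.1), emulating a
methylated vertebrate genome. CpG islands (default 8/Mb, mean ~700 bp)
are high-GC, CpG-rich segments planted with a bias toward gene TSS/TTS
so all four island classes arise; gene models (default 8/Mb) have
UTR/exon/intron structure with valid CDS (start/stop codon, length
divisible by 3, no internal stop), and CDS codons are sampled with the
same CpG suppression — including across codon junctions — so genes do
not mimic islands.

**Pedigrees.** Three designs: two-generation (F0 pair → clutch of full
sibs), three-generation inbred (F0 pair → two F1 sibs who mate → F2
clutch) and three-generation outbred (two F0 pairs → unrelated F1 pair →
F2 clutch). Default clutch size 10, emulating the crossing design the
pipeline targets.

**Founder diversity.** A panel of segregating sites at density set by
the target nucleotide diversity π = 0.004 (site density π/E[2f(1−f)]
with allele frequencies uniform on (0.05, 0.95)); founders are
Hardy-Weinberg draws, descendants receive fair (0.5/0.5) Mendelian
transmission with the transmitted haplotype recorded for phasing truth.

**Mutations.** Per offspring and parental side, DNM counts are Poisson
at rate 2·L·μ (default μ = 4.56×10⁻⁹, the scale of upper-teleost
estimates; tests use inflated rates for counting power), positions
weighted so CpG sites mutate at 3.4× the non-CpG rate with the genome
average preserved, alleles drawn with a transition bias and a strong
CpG C>T bias. A fraction `mosaic_fraction` (default 0.2) of events is
early-embryonic: the event count is scaled by the reciprocal of the
per-sib transmission probability (default 0.5, configurable — data do
not pin this quantity down) so the marginal per-offspring rate is
unchanged, and each sib carries the mutation independently. Note the
*observed* sib-shared fraction under these defaults is well below the
event-level 0.2 (an event must reach ≥ 2 of 10 sibs to be seen as
shared); reproducing a ~20% observed shared fraction would require an
event-level fraction near 0.55. F1 mutations transmit to each F2
offspring with probability 0.5 (recorded as truth for the transmission
test).

**Evidence.** Depth is negative-binomial via per-sample gamma window
means (1 kb windows; mean 50×, shape 25 — a realistic ~±20% CV for
PCR-free WGS) mixed with per-site Poisson draws; the window means are
also the emitted bedGraph tracks, which makes candidate filtering and
callability consistent by construction. Allelic depths are binomial
around the true allele fraction; clean homozygotes see the specific
alternate allele in a read at rate 2×10⁻⁴. GQ is 99 except for a 0.5%
low tail — deep, well-behaved calls rarely dip below the GQ 80 cut.
Artifacts: (a) somatic/artifact offspring hets (default 10⁻⁷/bp per
offspring) with Beta(1.5, 8) allele fractions, a 60% low-GQ tail, 50%
violating one hard site filter, and placement biased into the
poor-mapping mask (default 1% of the genome) and near planted decoy
indels; (b) under-genotyped parental carriers (default 10⁻⁷/bp per
trio): the parent truly carries the variant (offspring inherits it) but
the caller records 0/0 — with probability 0.8 the supporting reads
appear only in the raw-support channel, which is precisely the case the
≥10% curation rule exists to catch. Read observations for phasing link
each mutation to a genuinely informative flanking site (present for
~70% of mutations by default, matching the resolution rates such
pipelines report).

**What the generator does not emulate:** alignment and realignment
artifacts beyond the low-MQ mask and INFO draws, indel DNMs (indels are
decoys only), sex chromosomes, batch effects between sequencing
platforms, overdispersed allelic depth (real FNRs run a few percent,
higher than the binomial ~1% here — the pipeline's FNR calibration
absorbs this difference by construction), and mitochondria. A green
test therefore establishes the estimator's internal consistency and its
recovery of planted truth under a realistic noise model, not robustness
to every failure mode of real sequencing.

## 3. Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; conversion
  happens only at the VCF/GFF (1-based) format boundary.
* Boundary semantics follow the removal conditions verbatim: DP/GQ cuts
  are inclusive (DP ≤ 20 removes), AB and the hard site filters are
  strict (AB = 0.3, QD = 2.0 are kept). The candidate depth-ratio rule
  and the callable-site rule are both strict inequalities.
* The curation threshold is "support ≥ 10%" (the stricter reading of
  "up to 10% or more").
* Recurrence is keyed on position *and* allele; both violation
  orientations (0/0 parents and 1/1 parents) are screened even though
  reference-to-alternate mutations dominate in practice.
* DP_trio is the mean (not the sum) of the three members' depths; the
  literal sum would make the lower bound exceed any single member's
  depth and remove everything.
* Multiallelic records are decomposed to biallelic rows before
  screening; calls touching another alternate become missing.
* Candidates with zero summed parental depth at curation are removed as
  uncurateable; zero offspring AD yields a degenerate-AB removal.
* Welch's t is used for group comparisons (fractional df); CIs are
  family-clustered t intervals (see §1), a deliberate departure from
  per-offspring intervals, which undercover under mosaicism.
* The master seed spawns per-stage child seeds (`SeedSequence.spawn`),
  so identical seeds reproduce identical datasets byte-for-byte while
  stages stay independently re-runnable.

## 4. Known limitations

* The FNR calibration addresses only allelic-balance losses; GQ- and
  depth-related losses of true DNMs (~5% under default noise) are not
  corrected, biasing μ̂ slightly downward, partially offset by rare
  uncaught artifacts. Both effects are well inside the CI width at
  realistic sample sizes.
* With few families the family-clustered CI is wide (df = families − 1);
  this is honest about the information actually available.
* CGI boundary refinement assumes islands sit in a CpG-depleted
  background; on genomes without depletion the Kadane snap will trim
  aggressively.
* Phasing uses the simulator's read-observation table; it does not
  parse BAMs.
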