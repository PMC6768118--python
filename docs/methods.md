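# Methods note

This note records the statistical model behind `methylrad`, the default
parameters and why they were chosen, and the known limits of the synthetic
data generator.

## Signature-site model

FspEI recognizes 5-methylcytosine in CCGG and CCWGG (W = A/T) contexts and
cuts on both sides of the motif, releasing a 32-bp fragment at CCGG
(14 + 4 + 14) and a 31-bp fragment at CCWGG (13 + 5 + 13), motif centered.
CCGG is palindromic and the reverse complement of CCAGG is CCTGG — itself a
CCWGG motif — so every recognition locus is recognized on both strands.
The scanner therefore collapses strands: each locus is emitted once with
strand "both", identified as `chrom:motif_start:motif_class`. Fragments
that would overrun a contig boundary or contain an N are dropped, because
no unambiguous signature read can arise from them.

Read-to-site assignment matches each read prefix (both orientations)
against the fragment catalog, exactly first and then within one
substitution; reads matching no fragment are unassigned and reads matching
more than one site are ambiguous and discarded. A site is *authentic* in a
sample when it is supported by at least `min_depth = 3` reads — the
threshold the assay's authors use to separate signal from sporadic
mis-assignment. Counts are normalized to reads per million (RPM) assigned
reads; between-sample agreement is the Pearson correlation of
log2(RPM + 1) over sites authentic in at least one sample.

## Read QC

Reads are removed when mean Phred < 30 or when more than 8% of bases are
N; paired reads are dropped together if either mate fails. Both cutoffs
are inclusive-pass (mean exactly 30 passes; exactly 8% N passes), which
the threshold-sweep tests pin down as the operational boundary. The source
description of the 8% rule is ambiguous about whether it applies to reads
or sites; it is applied to reads here, since N content is a property of a
read's base calls.

## Differential methylation

Counts are compared between groups with a conditional exact test on
negative-binomial (NB) marginals, in the spirit of the classic exact test
for overdispersed counts:

1. **Library scaling.** Each sample's counts are scaled to the
   geometric-mean library size and rounded; the conditional argument
   requires exchangeable totals under the null, which only holds at equal
   effective library sizes.
2. **Dispersion.** A single common dispersion φ is estimated by pooled
   method of moments: within each group, E[s²] = μ + φμ², so
   φ̂ = Σ(s² − m) / Σ(m² − s²/n) pooled over features and groups. The
   denominator correction (subtracting s²/n) removes the E[m²] = μ² +
   Var(X)/n bias of the squared sample mean; with n = 3 replicates the
   uncorrected form understates φ by roughly 10% at typical depth. The
   estimate is floored at zero.
3. **Exact test.** The sum of n i.i.d. NB(μ, φ) variables is NB(nμ, φ/n).
   Conditional on the two-group total, the p-value is the sum of
   probabilities of all treated-group sums no more probable than the one
   observed (minimum-likelihood two-sided rule). At φ = 0 the marginals
   are Poisson and the conditional law is exactly binomial; the
   implementation reduces to the conditional binomial test, which the
   suite verifies against exact rational arithmetic.
4. **Effect size and call.** log₂FC = log2((mean RPM treated + 0.5) /
   (mean RPM control + 0.5)); a feature is significant at p < 0.05 and
   |log₂FC| > 1 (both strict), the rule used in the motivating study.
   Benjamini–Hochberg q-values are reported alongside. Note that with
   hundreds of null features the raw-p rule alone caps the precision of
   the flagged set near 70% (≈ 5% false flags among nulls are expected by
   construction); the q-value column is the right basis for
   high-precision follow-up lists, and the precision property in the test
   suite is evaluated on the BH-corrected call.

Gene-level analysis sums the counts of a gene's promoter/UTR/exon/intron
sites and runs the same test; intergenic and CTCF-only sites do not enter
gene aggregation.

## Annotation

Sites are classified by their motif midpoint against gene models from
GFF3: 5'UTR > 3'UTR > exon > intron > promoter > CTCF > intergenic
(most-specific wins). The promoter is the 2,000 bp upstream of the
strand-aware TSS; introns are derived as gaps between exons; CTCF regions
are optional user-supplied BED intervals. Ties between genes at the same
element kind resolve to the lexically smallest gene id for determinism.

## Screen, enrichment, qPCR

A candidate gene must (i) carry ≥ 1 significantly differential site,
(ii) be internally concordant — in strict mode every significant site
agrees with the gene-level direction; majority mode requires > 50% — and
(iii) appear on the supplied pathway list. Enrichment uses the upper-tail
hypergeometric probability with BH correction; terms with zero query
overlap are not tested and do not enter the correction. qPCR relative
expression follows the Livak 2^-ΔΔCt method (amplification efficiency
assumed 2, technical replicates averaged per sample, control-group mean
ΔCt as baseline), group differences use Welch's t-test on log₂ relative
expression, and a gene is concordant when methylation and expression
change in opposite directions.

## Synthetic data generator

Defaults: 3 chromosomes × 100 kb, 30 genes (3 hyper, 2 hypo, 1 discordant,
24 null), 302 planted sites (6 genic per gene, 4 intergenic per gene
block, 2 CTCF sites near the first hyper gene), planted |log₂FC| = 2,
baseline depth 50, dispersion φ = 0.1 (biological coefficient of variation
≈ 0.32, appropriate for inbred-mouse replicates), 3 treated vs 3 control.
Site methylation levels are bimodal (35% low, 0.02–0.15; 65% high,
0.5–1.0) with log-normal capture efficiency (σ = 1 natural log),
reproducing the long-tailed depth distributions of real MethylRAD
libraries. The background sequence is motif-scrubbed, so the digestion
catalog of the emitted genome equals the planted site set exactly — this
is what makes ground-truth round-trip tests exact. qPCR Ct values are
coupled to the planted methylation truth (ΔCt = base + slope × true
log₂FC for treated samples), so hypermethylated genes come out repressed
~4-fold at the defaults.

Known limits:

- Sites are drawn independently within genes, so gene-level counts have
  less extra-Poisson spread than real data, where sample-level effects
  correlate sites of the same gene; gene-level dispersion estimated from
  simulated data is accordingly deflated.
- At ~300 sites, one read corresponds to thousands of RPM units, so
  log-RPM correlations between replicates land near 0.7–0.85 rather than
  the 0.89–0.99 seen at genome scale; the correlation property tests
  therefore simulate counts at a realistic 50,000-site scale.
- The planted fold changes are applied to the NB mean, so recovered RPM
  fold changes are mildly compressed (≈ 1.4–2.2 against planted ±2) by
  library-composition effects, as in real data.
- Reads are error-free except for uniform substitutions at rate 0.002 and
  deliberately failing QC reads (5% of the library, labelled in the read
  ids); there is no adapter contamination, indel error, or mappability
  structure.

## Reproducibility

Every stochastic component takes an explicit seed (the generator derives
per-stage seeds as seed, seed+1, seed+2 for genome, reads and qPCR). The
pipeline writes a manifest with tool version, seed, parameter set, config
hash, SHA-256 input checksums and per-stage record counts; identical
config and inputs reproduce every output byte for byte.
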