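# Methods

## Study design and data model

The pipeline analyses reciprocal crosses between two breeds, A and B. F0
purebreds provide between-breed expression; F1 hybrids (cross directions
A♂×B♀, written `AxB` with the sire's breed first, and `BxA`) provide
within-individual allele-specific expression. Three transcript classes are
carried throughout — protein-coding genes (PCG), lncRNAs, and transcripts
of unknown coding potential (TUCP) — with expression thresholds of mean
TPM > 0.5 (PCG) and > 0.1 (lncRNA/TUCP), strict inequalities, means taken
over the libraries under consideration. All variant and annotation
coordinates are 1-based closed; only exported BED is 0-based half-open.

## Variant handling

Variants are restricted to biallelic autosomal sites. The GATK-style hard
filter rejects a site iff any clause fires: QD < 10, FS > 60, MQ < 40,
MQRankSum < −12.5, ReadPosRankSum < −8, GQ < 30 (strict comparisons, so
boundary values survive; absent annotations never fire a clause, matching
GATK semantics). Extreme-depth sites are removed either by percentile
(outside the 1st–99th) or by z-score (|z| > 2.58); both modes are provided
because either rule is defensible, and with zero depth variance the
z-score mode keeps everything (no information to reject on).

## Trio phasing

A child-heterozygous SNV is phased when at least one parent is homozygous
and exactly one transmission explains the child: the homozygous parent can
only have transmitted its single allele. Both-heterozygous sites are
*ambiguous* (either orientation is Mendelian-consistent) and sites with no
legal transmission — including alleles absent from both parents — are
*Mendelian errors*. Both classes are excluded from downstream allele
assignment and counted in the phasing summary, which also reports the
phased fraction and the phased-SNV density per kb for a given genome size.
Indels are not phased; read assignment uses SNVs only.

## N-masking and read assignment

Phased SNV positions are replaced by `N` in the reference so that neither
allele has a mapping advantage. Each aligned read (or read pair) is then
assigned by the bases it carries at phased SNVs, interrogating only
match/mismatch-aligned bases: all votes maternal → `allele1`, all paternal
→ `allele2`, votes for both → `conflicting`, no informative base →
`unassignable`. Disagreeing mates make the pair conflicting; pairs count
once. Conflicting reads are excluded from allele counts and reported.

Counting is deterministic exon-union overlap — a read increments every
transcript whose exons its aligned blocks touch on the same chromosome
(strand ignored; multi-gene reads count toward each). The original study
quantified allele-split reads by pseudoalignment; overlap counting
replaces it here so that counts are exactly checkable against simulation
truth. This is the one deliberate methodological substitution in the
pipeline and does not affect the statistical machinery downstream.

## The negative-binomial Wald test

Counts are modelled as NB with variance μ + φμ². Library size factors are
median-of-ratios (genes with all-positive counts, factors rescaled to
geometric mean 1; column-total fallback with a warning when no gene
qualifies). For two groups with nₐ and n_b libraries:

* normalized means μ̂ₐ, μ̂_b, shifted by half a normalized count per
  library (0.5/n) so the statistic stays defined when a group is all zero;
* pooled method-of-moments dispersion
  φ̂ = Σ(n−1)(v − μ̂) / Σ(n−1)μ̂², floored at 10⁻⁸;
* Wald statistic z = (ln μ̂ₐ − ln μ̂_b) / SE with
  SE² = (1/μ̂ₐ + φ̂)/nₐ + (1/μ̂_b + φ̂)/n_b, referred two-sided to a t
  distribution with **max(nₐ + n_b − 4, 1)** degrees of freedom.

The df choice discounts two degrees beyond the group means for the
estimated dispersion and is deliberately conservative. The asymmetry is
intentional: in the category assignment a spurious significance flag
re-routes a transcript into a wrong category outright, whereas a missed
flag mostly lands it in *ambiguous*; with thousands of strongly divergent
genes in a BH family, the step-up threshold is generous and extreme-tail
false positives propagate directly into misclassification. On null NB
simulations (φ = 0.1, 6 vs 6 libraries) the rejection rate at α = 0.05 is
≈ 0.047 — near nominal, slightly below it by design. Displayed
log2 fold-changes use a pseudocount of 0.5 on the normalized scale; the
test statistic does not. Groups with a single library fall back to an
exact conditional (binomial) Poisson test. No information is shared across
genes: dispersion shrinkage and GLM covariates are out of scope.

## Imprinting calls

Within a tissue, breed-allele counts map to parental origin through each
library's cross direction (`AxB`: allele A is paternal). Transcripts pass
a detectability filter (maternal+paternal ≥ 10 in at least half the
libraries — the threshold is a package default, exposed as a parameter),
are tested maternal vs paternal with the NB Wald test (both matrices share
the library size factors, so depth cancels), and BH correction runs across
the tested transcripts of that tissue. Adjusted p < 0.05 calls imprinting;
the parent is the sign of the maternal/paternal log2 fold-change. The
allelic ratio is maternal/(maternal+paternal): 0 means fully paternal
expression, 1 fully maternal. Because totals are shared between the two
alleles of a library, treating them as independent groups slightly
overstates the variance — the test is conservative in the direction that
protects the null. A per-direction ratio diagnostic is reported but not
used for calling; requiring both cross directions is a warning rather than
an error so exploratory single-direction runs remain possible, flagged as
confounding parent with breed.

Tissue specificity counts, per transcript of the union set (imprinted in
≥ 1 tissue), the number of tissues with a call. Clusters chain imprinted
transcripts whose consecutive TSS positions (the representative position,
a package choice) lie within 1 Mb on a chromosome; chains of ≥ 2 are
reported with the clustered fraction.

## cis/trans classification

Eligible transcripts (expressed, allele-informative, not imprinted in that
tissue — imprinted input is rejected, since parent-of-origin bias would
masquerade as allelic divergence) get three tests:

* **P**: NB Wald, F0 breed A vs breed B;
* **F**: NB Wald, allele A vs allele B across F1 libraries, reciprocal
  directions pooled;
* **T**: Fisher's exact test (two-sided, point-probability rule) on a 2×2
  table, rows F0/F1, columns breed A/B.

The T table is built from size-factor-normalized, group-summed counts,
with each generation row divided by 1 + φ̂·μ_h before half-to-even
rounding, where μ_h is the harmonic mean of the row's two per-library cell
means and φ̂ = max(φ̂_P, φ̂_F). Rationale: Fisher's test assumes
count-level (hypergeometric) sampling, but replicated NB counts carry
overdispersion φμ² that grows with expression; unscaled sums make the test
reject wildly for well-expressed genes with identical true ratios. By the
delta method, Var(ln ratio) per row is Σ_g (1 + φμ_g)/(nμ_g), and dividing
both cells by 1 + φ·2μₐμ_b/(μₐ+μ_b) equates the table's implied variance
to it while preserving the ratio. The larger of the two generations'
dispersion estimates is used because each has few degrees of freedom and
an underestimate would inflate the effective counts. The construction is
isolated in `build_ratio_table` for substitution; with φ = 0 it reduces to
plain normalized sums.

P, F, and T p-values are BH-corrected independently within the tissue and
thresholded at 0.05. The flag triple plus fold-change directions map to
the seven categories (see README table); the (1,1,1) pattern with an
exactly zero direction is degenerate and classified ambiguous. The mapping
is total and mutually exclusive over the flag/direction space, and
relabeling the breeds flips both directions jointly, leaving every
category invariant.

## Downstream statistics

Promoter windows are the 2,000 bp immediately upstream of the TSS,
strand-aware, abutting but excluding the TSS base, truncated (and flagged)
at the chromosome start. Variant burden counts SNVs and indels whose
position falls in the window (indel length |len(alt) − len(ref)|, mean 0
when none) — computed per F1 individual and averaged per gene when
multiple individuals are provided. Burden, conservation-score tables
(accepted precomputed), and |log2FC| divergence comparisons use the
two-sided rank-sum test (exact for ≤ 20 observations without ties, normal
approximation with tie and continuity corrections otherwise).
Cross-tissue/cross-generation concordance is the Pearson correlation of
log2 fold-changes over transcripts sharing a regulatory status (≥ 3
shared required). Cell-type marker enrichment uses score =
observed/expected overlap with expected = |set|·|markers|/|background| and
an upper-tail hypergeometric p; the score formula is a package choice,
isolated for substitution, and marker sets are inputs — single-cell
clustering and marker discovery are out of scope.

## The synthetic-data generator

Per gene g with baseline λ_g ~ 2^N(baseline_log2_mean, baseline_log2_sd)
(defaults 8 and 2 → median ≈ 256 counts):

* F0 breed-A mean λ·2^(c+t), breed-B mean λ;
* F1 allele-A mean (λ/2)·2^c, allele-B mean λ/2 — the halving keeps summed
  F1 expression on the F0 scale (a simplification; real libraries are
  depth-normalized anyway);
* counts ~ NB(μ·s_j, φ) with per-library size factors s_j ~ U[0.7, 1.3]
  (per library, not per gene) and φ = 0.05 by default;
* categories map to effects as cis (c = ±e, t = 0), trans (c = 0,
  t = ±e), cis+trans (t = c), cis×trans (t = −2c, chosen so the F0 and F1
  ratios have equal magnitude and opposite sign; other choices are
  possible and parameterizable), compensatory (t = −c), conserved
  (c = t = 0). The effect magnitude e defaults to 2 log2 units and may be
  a set from which each gene draws uniformly.

The imprinting experiment draws per-library totals ~ NB(λ·s_j, φ) and
splits maternal ~ Binomial(total, ρ), with ρ = 0.5 for unbiased genes and
ρ = maternal_bias (default 0.9) or 1 − maternal_bias for maternally or
paternally imprinted ones; the parental origin maps to a breed allele via
the library's cross direction, so the biased *breed* allele swaps between
reciprocal directions while the parental bias does not.

Trio genotypes draw parental alleles from breed frequencies (fixed
difference with probability p_divergent, shared frequency otherwise) and
transmit one allele per parent uniformly. Read simulation emits spliced,
exon-consistent reads carrying the originating haplotype's bases at
phased SNVs, each base independently replaced by a uniformly chosen
different base with the error rate (so a diagnostic base turns into the
other allele with probability ε/3 and into a dead third base with 2ε/3).

All randomness flows from one seeded `numpy` generator per call; fixture
bundles are byte-identical under a fixed seed. What the generator does
*not* emulate: positional/GC coverage bias, isoform mixtures, mapping
errors, reference bias beyond what N-masking removes, correlated
biological replicates, and library-preparation artefacts. Passing tests
demonstrate the statistical machinery is correct under the stated model,
not that real-data preprocessing upstream of it is solved.

## Benchmark problem sizes

The end-to-end benchmarks use 2,400 genes (400 per category) for category
recovery, 2,000 genes for the all-conserved null and for imprinting
(~25% biased), 10,000 trio sites (2% corrupted to create illegal
transmissions, which Mendelian-consistent simulation cannot produce
naturally), 16,000 reads per error-model check, exhaustive enumeration of
all 2×2 tables with margins ≤ 12 for the Fisher oracle, and 1,000 random
vectors for the BH oracle. These sizes give stable estimates (binomial
SE ≲ 1%) while the whole benchmark suite completes in well under a
minute. The cis-concordance benchmark reads the correlation on genes with
baseline ≥ 100 counts, where fold-change estimates are informative rather
than shot-noise limited, and mixes effect magnitudes {0.5, 1, 2} within
one experiment — an all-cis gene set violates the median-of-ratios
assumption that most genes are unchanged, and simulating the magnitudes
separately would give each batch a different constant fold-change offset,
an artefact of the benchmark design rather than of the method.

## Known limitations

* The NB test estimates dispersion per gene from few replicates; with
  n < 4 per group its power is limited and its conservatism grows.
* The T test's effective-count scaling is a first-order variance match;
  extremely skewed tables (one cell near zero) remain approximate.
* Exon-union counting ignores isoform structure and assigns multi-gene
  reads to every overlapped transcript (flagged, not resolved).
* Phasing covers only sites with a homozygous parent; linkage-based
  recovery of both-het sites is deliberately not attempted.
* The imprinting test pools cross directions; a direction-consistency
  diagnostic is reported but not enforced.
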