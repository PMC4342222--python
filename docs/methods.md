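# Methods

## The measurement problem

Whole seed sampled a few days after pollination is a mixture of three
transcript pools: maternal sporophyte tissue (seed coat; entirely maternal),
triploid endosperm (2 maternal : 1 paternal genome dose) and embryo (1:1).
RNA-seq reads aligned to the reference cDNA can be assigned to a parent only
at positions where the two parental genotypes differ.  The analysis therefore
has two halves: build a reliable catalogue of parent-diagnostic SNPs from
parental sequencing, then use it to measure each gene's maternal/paternal
transcript fractions in the hybrid and test them against dosage expectations.

## Diagnostic SNP discovery

A position is accepted as diagnostic for a parent when, in that parent's
pileup, the most frequent non-reference base accounts for ≥ 95% of ≥ 5 reads
(both thresholds closed, configurable).  The purity rule exists chiefly to
reject heterozygous sites of the outcrossing parent, which emit ~50:50 base
mixes.  Exact ties between two non-reference bases are rejected as ambiguous
(the conservative choice; ties are not otherwise adjudicated).  Two further
filters remove positions that cannot separate the parents of a cross:
positions carrying the *same* SNP base in both non-reference genotypes, and
positions where the reference-matched parent itself deviates from the
reference.  Same-start reads are deduplicated before pileup summarisation
(key: gene, strand, start; single-end semantics — each mate is an independent
record) so PCR duplicates do not inflate coverage.

## Allelic quantification

At a diagnostic position, hybrid reads carrying the SNP base count for the
diagnostic parent and reads carrying the reference base for the other
lineage; any third base is excluded from both counts and from the informative
depth (it is uninformative about parentage, and counting it in the
denominator would deflate both fractions).  Positions need ≥ 5 informative
reads.  Per gene, the paternal percentage P_p is the **unweighted mean of
per-position fractions** and C the mean informative depth, following the
mean-percent-SNP convention; a read-pooled (coverage-weighted) alternative is
available via `profile_genes(weighted=True)` for sensitivity analysis.
Approximate parental read counts are N_m = C·P_m/100 and N_p = C·P_p/100.

**Pseudocounts.** Ratio tests need positive cells.  The default adds one read
to each of N_m and N_p (symmetric, and actually removes zero cells); the
literal alternative — one read added to the coverage, split by the observed
fractions — is provided as `pseudocount_mode="coverage"` but leaves a zero
cell whenever one fraction is 0 and is therefore not the default.

**Mapping bias.** Reads from the genome more divergent from the alignment
reference are preferentially lost, inflating the reference parent's apparent
fraction.  `estimate_mapping_bias` reports the mean reference-parent fraction
over a known 50:50 control mix as a QC diagnostic.  No correction is applied
to the fractions by default (an optional bias-aware null exists only through
the configurable null share of the goodness-of-fit test), mirroring how such
controls are used in practice.

## Classification

A gene is **maternal (MEG)** when P_m > 66 — above what the 2m:1p endosperm
dose explains — and the Pearson 1-df goodness-of-fit of (n_m, n_p) against a
2:1 expectation is significant; **paternal (PEG)** when P_p > 50 with a
significant departure from 1:1; otherwise **biparental**.  Thresholds are
strict inequalities and configurable (66, 50, α = 0.05 defaults).  P-values
are Benjamini–Hochberg adjusted per test family across all profiled genes of
the cross.  The within-cross goodness-of-fit is the gating test because the
thresholds are within-cross quantities; the 2×2 between-cross chi-square
(rows = crosses, columns = parental counts, no continuity correction) is
computed and reported separately so either convention can be reproduced.  For
comparisons between libraries of very different depth, `downsampled_chisq`
first rescales both profiles deterministically (half-up rounding, totals
preserved) to the lower coverage.

Distribution-level comparisons use the paired Wilcoxon signed-rank test
(zero differences dropped) on per-gene paternal fractions and OLS simple
regression (R², slope, slope p) between crosses.

Literature annotation: a known PEG that is paternal in the hybrid is
*confirmed*; maternal, *reverted_to_maternal*; a paternal hybrid call with no
literature record and no paternal call in the control is a *de novo PEG*;
genes without informative SNP coverage are *not informative*.

## Endosperm specificity

From a seed-compartment expression matrix (preglobular/globular stages), per
gene: max over endosperm compartments, max over non-endosperm compartments
(seed coat, suspensor, embryo), and the score
log₁₀((max_endo − 2.3)/(max_non − 2.3)).  The floor 2.3 is the level treated
as zero on the source scale; subtracted terms are clamped below at ε = 0.01
so floor-level denominators yield finite, capped scores rather than
discarding exactly the "high in endosperm, absent elsewhere" genes the score
exists to find.  Low expressors are removed by
log₁₀(max_endo + max_non) ≥ 1.8 (the log-sum uses the same two maxima; with
base-10 logs the threshold corresponds to a linear-scale sum of ~63, which is
why base 10 is the default — both base and threshold are configurable).
Endosperm-specific genes are those above the upper Tukey fence
Q3 + 1.5·(Q3 − Q1) of the filtered log-ratio distribution; quartiles use
linear interpolation between order statistics (the common default), with
Tukey hinges available (`method="hinges"`).

## Overlap testing

`hypergeometric_overlap(k, n, K, N)` reports the expected overlap n·K/N and
the exact one-sided enrichment tail P(X ≥ k), summed in log space with
log-gamma binomial coefficients (a ~15,000-gene universe overflows naive
factorials).  A full-enumeration oracle over all n-subsets (N ≤ 25) provides
an independent check used in the tests.

## The synthetic generator

`poex.simulate` draws a reference transcriptome (uniform bases), plants fixed
differences per site at the divergence rate (defaults: 0.5% intraspecific,
5% interspecific), heterozygous sites of the outcrossing parent at its
heterozygosity rate, and optional reference-parent self-SNPs.  Per-gene read
depth is negative binomial (parent default mean 27 / SD 23 per position;
hybrid default mean 50), with 0.5%/base sequencing error (uniform
substitution).

**Coverage model.** Each simulated read is assigned a parent (and haplotype)
once and observes every position of its transcript.  Within a gene the
per-position fractions therefore describe the same reads — the correlation
structure that real transcript-covering reads induce — which is exactly what
makes the per-gene statistic (mean percent with mean coverage as effective
count) correctly calibrated: simulating every position as an independent
binomial would make the test conservative by roughly the number of SNPs per
gene.  The flip side is that a gene's depth is constant across its positions;
positional coverage variation within transcripts is not modelled.

**Heterozygote emission.** A heterozygous parent's reads split between its
two haplotypes as evenly as integers allow (floor/ceil), the idealised 50:50
allelic balance.  This makes rejection of het sites by the 95% purity filter
deterministic at ≥ 5 reads; a binomial allele split would let a small
fraction of low-depth het sites through (≈3% at depth 5), which is a property
of the filter worth knowing about on real data.

**Mixtures and bias.** A cross's per-gene maternal fraction is
f_mat·1 + f_endo·dose(gene) + f_emb·(1/2), with endosperm doses MEG → 1,
biparental → 2/3, PEG → 0.1 (i.e. 90% paternal) and reverted-PEG → 0.1 in the
intraspecific design but 1.0 in the interspecific design.  The whole-seed
default mixture (0.5 maternal tissue / 0.4 endosperm / 0.1 embryo) is a
stated assumption — the maternal RNA fraction at this stage is not measured —
and is configurable; `ENDOSPERM_ONLY` and `EVEN_MIX` presets cover dissected
endosperm and 50:50 control designs.  Mapping bias is per-read loss of
non-reference-parent reads with probability q = 2 − 1/t, parameterised by the
observed reference fraction t at a true 50:50 mix (t = 0.6 reproduces the
~60:40 allopolyploid control; t = 0.5 is no distortion).  Crosses in which
*both* parents differ from the reference (e.g. an accession mother with an
outcrossing father) emit maternal reads from the second divergent genotype;
bias then applies to the more divergent side only — a simplification of the
differential bias a real double-divergent cross would show.

The LCM-style matrix generator plants endosperm-specific genes by elevating
their endosperm compartments 20-fold (default) over a log-normal background
with floor 2.3, and writes the planted set as truth.

**What passing tests do not show.** The generator has no positional coverage
variation, no alignment artefacts beyond the single bias parameter, no
isoforms, no gene-length or GC effects, and independent genes; recovery rates
measured on it are upper bounds on real-data performance, not estimates of it.

## Verification scenario sizes

The bundled verification runs (tests and `scripts/acceptance.py`) use:
200 genes × 1 kb at 5% divergence / 0.5% heterozygosity for SNP-caller oracle
equivalence; 500 genes at depth 50 for the mixture closed form and the
mapping-bias calibration; 2,000 genes at depth 50 for type-I/FDR calibration
(expected window 3–7% raw, ≤ 1% after BH); 1,000 genes (10% MEG, 5% PEG at
90% paternal dose, 3% reverted) at depth 50 on a dissected-endosperm design
for class recovery — whole-seed mixtures deliberately mask PEGs (a planted
90%-paternal PEG sits at P_p ≈ 41% under the default 0.5/0.4/0.1 mixture),
which is itself the maternal-dilution effect the classifier's users must keep
in mind; and ≥ 1,000 random instances per statistical kernel against
independent oracles (tolerance 1e-9; full enumeration grid at N ≤ 12 at
1e-12).

## Numerical and design notes

- Pearson chi-squares carry no continuity correction (configurable in spirit:
  the 2×2 statistic is the standard uncorrected one; a corrected variant can
  be had from scipy directly).
- BH adjustment delegates to statsmodels' `multipletests(method="fdr_bh")`;
  chi-square and Wilcoxon tails come from scipy.  The goodness-of-fit and
  contingency statistics themselves are computed from the expected-count
  formulas and cross-checked against scipy in the test suite.
- Library-size normalization defaults to smallest-library total-count scaling
  (size factor = total/min total, so the smallest library is unchanged); the
  DESeq-style median-of-ratios estimator is available as
  `method="median-ratios"`.
- All generators are bit-reproducible under a fixed seed; the pipeline writes
  a manifest with seeds and thresholds, and reruns are byte-identical.
- Degenerate inputs fail loudly: zero-total libraries, sub-floor expression
  values, missing reference bases, diagnostic SNPs equal to the reference
  base, < 4 values for a Tukey fence, < 5 reads for a downsampled test.

## Known limitations

- Transcript-isoform resolution, indels and genotype-likelihood models are
  out of scope; the SNP caller is a threshold rule, not a caller with error
  model.
- The mapping-bias estimate is a diagnostic; fractions are not corrected.
- With the per-gene test applied to mean counts, genes whose positions are
  *not* fully correlated (short reads over long transcripts) are tested
  conservatively; the weighted profile mode partially addresses this.
- The reverse reading of the pseudocount rule, and between-cross gating of
  the MEG/PEG call, are provided but not default; published analyses of this
  design are ambiguous on both points, and both readings are reproducible
  here.
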