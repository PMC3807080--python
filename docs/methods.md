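# Methods

## Problem and scope

Published genetic associations for rheumatoid arthritis come from studies of
very different power and design, and many reported signals fail to replicate.
ravarkit implements a curation chain that (1) re-grades each reported result
under a unified significance policy, (2) reduces redundant follow-up reports
to one representative result per variant and geographical population,
(3) classifies variants by whether their evidence reproduces across or within
populations, and (4) converts a panel of confirmed markers into per-individual
risk indices. Literature retrieval, cohort-level genotype analysis and
meta-analytic pooling are out of scope: the tool classifies reported results,
it does not combine them.

## Significance regimes

Two threshold pairs are used, keyed to what a study assayed. A study of
genome-wide SNPs (or a meta-analysis of GWAS, or a combined GWAS + replication
analysis, regardless of its nominal SNP panel) is graded at genome-wide
thresholds: strong below 5×10⁻⁸, moderate up to 10⁻⁵. A follow-up study of a
few selected SNPs is graded at nominal thresholds: strong below 0.01,
moderate up to 0.05. Boundary handling is not fully determined by the
published prose, which states only that values *between* the two cutoffs are
moderate and values *above* the weak cutoff are not significant; we take
"strong" as strictly below the stringent cutoff and include both endpoints in
the moderate band, which keeps "not significant" strictly above the weak
cutoff. P-values are taken as published; one- vs two-sided testing is not
distinguished and nothing is recomputed from counts.

Regime selection consults study design before coverage. A meta-analysis of
*follow-up* data therefore stays in the follow-up regime even though it pools
many samples; in the packaged fixture such rows (printed as "Selected (Meta)"
in the source) are encoded `design=followup, coverage=selected`, which is the
only encoding under which every confirmed row in the fixture actually grades
significant.

## Representative selection and reproducibility

Populations are the nine canonical groups (European, East Asian, West Asian,
South Asian, South American, Central American, North African, South African,
African American); reported sub-labels resolve through a shipped synonym
table (data, not code, so users can extend it), and unknown labels are hard
errors. "East Asian" absorbs "South-East Asian"; no finer subdivision is
attempted, and no label may map to two groups.

The representative for a (variant, population) is the result from the study
with the most cases. The tie-break chain — smaller P, then more controls,
then lexicographic study ID — is our own determinism choice; the primary key
(case count) is the published rule. Selection is therefore
permutation-invariant and idempotent.

Direction harmonization compares two reports of one variant: a report's
allele equal to the other's reverse-strand complement is treated as the same
allele; two different non-complementary alleles are assumed to be the two
alleles of a biallelic marker, so their odds ratios must fall on *opposite*
sides of 1 to agree. A/T and C/G palindromic markers cannot be disambiguated
by complementation — for them complementation coincides with the
other-allele case and the opposite-side rule governs; this is a documented
ambiguity of strand-free literature data. Reports lacking an odds ratio, or
with OR exactly 1, are direction-indeterminate: they can support a
classification but never veto one.

Inter-population reproduction requires significant (strong or moderate)
representatives in ≥ 2 populations with no conflicting pair; any conflict
excludes the variant outright. Intra-population reproduction requires a
significant representative plus ≥ 1 significant report from a distinct
publication in the same population. Direction consistency is enforced for the
intra class too — the published rule states the exclusion only across
populations, but an opposite-direction "replication" is not a replication.
"Independent study" means distinct publication; cohort overlap between
publications is undetectable from these inputs and is a known limitation. A
variant may hold both classes; calls are reported independently. Any reported
significant association (not only representative-eligible ones) may serve as
the intra replication, and a multi-population meta-analysis record counts
only toward its labeled population.

## Risk model

Panels are pruned to one marker per LD locus (smallest association P,
lexicographic variant ID on ties) so linked markers cannot double-count one
signal. For pruned markers with allelic odds ratio rᵢ, control risk-allele
frequency pᵢ and risk-allele copy number Xᵢ:

- GRS = Σᵢ Xᵢ ln rᵢ. The natural log is our choice (the construction is
  stated only as "log-OR"); the base rescales GRS uniformly and affects
  nothing else.
- sᵢ = rᵢ^Xᵢ and aᵢ = pᵢ²rᵢ² + 2pᵢ(1−pᵢ)rᵢ + (1−pᵢ)², giving RGRᵢ = sᵢ/aᵢ
  and overall RGR = Πᵢ RGRᵢ (empty product = 1). The published equations are
  rendered as figures in the source, so these forms are reconstructed from
  the accompanying prose (multiplicative allelic risk with the risk factor
  equal to the allelic OR, normalized by the population-average risk under
  Hardy–Weinberg equilibrium). The reconstruction is pinned by its defining
  identity, Σ_X HWE(X; p)·RGR(X) = 1, which the test suite checks to 1e-12
  on an (r, p) grid, and by the exact symmetry RGR(r, p, X) =
  RGR(1/r, 1−p, 2−X) under relabeling of the risk and non-risk alleles.
- lifetime risk = min(RGR × prevalence, 1). Plain multiplication matches the
  published worked example (RGR 2.6 × 1% → 2.6%); the cap is ours and is far
  from any realistic operating point. The shipped default prevalence is 0.01
  for Europeans (the baseline the worked example states); other populations
  require an explicit value.

Degenerate inputs: p = 0 with X > 0 and p = 1 with X < 2 are rejected (the
genotype is impossible at the stated frequency and the normalizer
degenerates); r = 1 markers contribute exactly 1 (RGR) and 0 (GRS). Missing
genotypes are skipped, never imputed — no imputation model is described for
this construction — and `n_markers_used` reports how many markers actually
contributed. Panel rows reported in the protective orientation are
re-expressed for the risk allele (r → 1/r, p → 1−p) when the other allele is
named; otherwise they are scored as given, which the relabeling symmetry
makes numerically equivalent.

## Synthetic data

The generator emulates a multi-study, multi-population association
literature with planted reproducibility classes: cross-population
replication, within-population replication, lone significant reports, never
significant variants, direction conflicts, and the small-study pattern in
which a significant small study is displaced by a larger non-significant
representative. Planted P-values sit one order of magnitude beyond the
decision thresholds (10⁻⁹ vs 5×10⁻⁸ genome-wide; 10⁻³ vs 0.01 follow-up) so
recovery tests never ride a boundary — boundary behavior is tested separately
in the grading unit tests. Odds ratios are log-uniform on [1.05, 2.5]
(inverted for the conflicting arm), matching the magnitude range of confirmed
associations in the packaged table. Case counts are drawn so the intended
representative always wins selection. Everything is a deterministic function
of the seed.

What the generator does *not* emulate — and hence what passing recovery tests
cannot show about real data: P-values are planted, not sampled from simulated
cohorts, so there is no sampling noise around the thresholds; no LD structure
exists (each variant is its own locus); alleles are single bases with no
strand ambiguity; study populations are clean labels with no admixture or
mislabeling. Genotypes for risk-math calibration are drawn from exact
Hardy–Weinberg proportions, which is the model's own assumption, not a test
of it.

## Test and calibration sizes

The classifier-vs-oracle equivalence runs on 150 randomized tables of ≤ 6
records per variant (the brute-force oracle enumerates all record pairs);
planted-label recovery runs across 50 randomized generator specifications;
the Monte-Carlo calibration of the mean overall RGR uses 100 000
Hardy–Weinberg genotypes of a five-marker panel and accepts a deviation of up
to three standard errors. These sizes make the full suite run in a few
seconds while keeping the Monte-Carlo standard error near 10⁻³.

## Known limitations

Variant IDs are opaque keys: merging synonymous rsIDs, HLA-allele
nomenclature and cross-SNP "same signal" pairing are not attempted, so two
different SNPs of one locus are two variants (the locus count, not the
variant count, deduplicates them). The fixture transcribes printed values
verbatim, including a P-value of 1×10⁻²⁹⁹, which is parsed as-is without
underflow clamping. Confidence intervals on RGR, marker–marker interaction
and liability-threshold modeling are out of scope.
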