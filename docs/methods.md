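# Methods

## Variant and catalog model

A variant is a strict single-base substitution keyed by
`(chrom, pos, ref, alt)` on hg38; indels and multi-base alleles are
rejected at the boundary, matching the single-base scope of the analysis.
Positions are 1-based (VCF convention) externally; gene coding intervals
are 0-based half-open internally, and chromosome names are stored without
the `chr` prefix. Where a literature table identifies variants only by
cDNA change, a fallback key `(gene, hgvs_c)` is used; the two key spaces
are never mixed within one comparison.

Gene assignment finds the catalog gene whose merged coding intervals
contain the site. Overlapping genes are resolved by smallest total coding
span, then lexicographic symbol — a deterministic stand-in for the
transcript-priority rules annotation tools apply, verified against a
brute-force interval scan in the tests.

Clinical significance collapses by case-insensitive keyword: any
"conflicting" label dominates; "pathogenic" without "benign" is a PV;
"benign" without "pathogenic" a BV; "uncertain" a VUS. Variants with
conflicting assertions are excluded from PV sets — the conservative
reading of a Pathogenic/Likely-Pathogenic inclusion rule. Cohort presence
means allele count ≥ 1 by default (configurable): the variants analyzed
are rare, so set membership rather than a frequency floor is the right
semantics.

## Sharing classification

The ancient-intermediate classifier is a pure function of membership: an
ancient-observed variant maps to `AFRICAN_ONLY`, `BOTH`,
`NONAFRICAN_ONLY` or `UNSHARED` by its presence in the modern African and
non-African cohorts. `UNSHARED` variants are retained in all outputs, and
summaries report percentages on both denominators (all classified
variants, and the shared subset only), because the two bases differ and
published figures have used each; the report notes this explicitly.
"Earliest" carrier dates are maxima over years-BP values (larger = older);
undated carriers are skipped, and a variant with no dated carrier has an
absent date, never zero.

## Statistics

- **Two-proportion z**: pooled variance, two-sided, with the Yates
  continuity correction ½(1/n₁+1/n₂) subtracted from |p̂₁−p̂₂| and clamped
  at zero. This is the variant that reproduces the published p = 0.01404
  for the 54/169 vs 77/169 gene-ratio comparison; the uncorrected pooled z
  gives 0.0102. The tests cross-check against an erfc-based normal tail.
- **t-test**: Welch (unequal variance) with Welch–Satterthwaite degrees of
  freedom, the safer default when cohort variances differ.
- **Prevalence correlation**: Pearson r over the union of genes with
  zeros imputed for absent genes, plus a least-squares line whose largest
  absolute residuals flag discordant genes.
- **Group clustering**: binary presence/absence profiles, Jaccard
  distance, average linkage. Rows are sorted by label before clustering
  and sibling subtrees ordered lexicographically in the Newick output, so
  the tree is invariant to input order. The distance/linkage pair is
  configurable and recorded in the tree's method tag; a frequency-weighted
  profile mode can be obtained by passing a non-binary matrix with another
  metric.
- Percentages round half-up to one decimal (whole percents for the
  ethnic shared-fraction statistic), matching the reporting style of the
  tables being reproduced.

## Synthetic out-of-Africa studies

The generator emulates the demography the inference presumes: an ancestral
diploid population; a bottlenecked split at 60,000 years BP (30-year
generations, hence 2,000 generations) where a small founder group starts
the non-African branch while the African branch continues the ancestral
population; no migration after the split; no selection (the variants
modelled are too young for selection to act appreciably). New PVs arise as
a Poisson process per branch and drift as neutral Wright–Fisher binomial
resampling with absorbing loss/fixation. Modern cohorts are binomial
samples of terminal branch frequencies with unequal subgroup sizes; ancient
individuals are diploid draws from the non-African branch at their dated
generations with per-call missingness, mimicking incomplete ancient-DNA
coverage. A truth table records each variant's arising generation and
lineage (`ANCESTRAL`, `AFRICAN_BRANCH`, `NONAFRICAN_BRANCH`).

Default parameters are illustrative desk-scale choices, not estimates:
ancestral N = 800, founders = 120, African growth to 2,000 (after 10,000
BP), non-African growth to 1,200 then 4,000 (after 2,000 BP), 1 new PV per
generation per branch, an 800-generation ancestral epoch, cohorts of 2,000
African and 9,200 non-African individuals in three subgroups, and 204
ancient samples whose dates follow the empirical profile of published
ancient Eurasian genomes (~80% within the last 6,000 years, ~3% beyond
10,000 BP) with 30% per-call missingness. Populations are hundreds to
thousands rather than the real tens of thousands so that drift, founder
loss and fixation play out within seconds of compute; this preserves the
qualitative regime (founder effect, African-private ancestral variants,
post-split variants confined to one branch) while inflating per-variant
drift relative to the real demography.

`init_frequency` optionally overrides the 1/(2N) entry frequency of new
variants. Setting it high while making branch sizes huge yields the
idealized no-drift regime in which every ancient-observed variant remains
detectable in its modern cohorts; there the epoch-recovery accuracy of the
sharing classifier is exactly 1.0, which the tests assert. Under the
default drifting regime accuracy is ~0.7–0.8: the dominant error modes are
ancestral variants lost from one branch (misread as branch-private) and
variants drifted out of the modern cohorts (`UNSHARED`). Accuracy
improves on average with modern cohort size, checked across seeds at two
sizes.

What the generator does **not** emulate: recombination and linkage,
archaic admixture, post-split migration, selection, sequencing error and
ancient-DNA damage (inputs are assumed post-recalibration calls), or
realistic site-frequency spectra at genome scale. Passing tests therefore
validate the pipeline's logic and the classifier's behaviour under an
explicit neutral demography — not the historical claim itself, which
rests on the real cohorts.

## Reproducibility and numerical choices

All simulator randomness flows through one `numpy` generator seeded from
`SimulationParams.seed`; identical parameters produce byte-identical study
bundles. Epoch bins use inclusive lower bounds with an open top bin
(default <2000, 2,000–3,999, ..., ≥10,000 years BP) and report undated
samples as an `NA` row with percentages over the grand total. Duplicate
clinical assertions with identical labels collapse; contradictory labels
become `CONFLICTING` with a logged warning. Degenerate statistical inputs
(zero variance, empty groups, zero denominators) raise typed errors rather
than returning NaN.

## Known limitations

- The packaged DDR catalog is synthetic: per-pathway counts and
  literature-named genes are faithful, but the full roster and every
  coding interval are constructed. Analyses of real data must supply a
  real interval catalog. (The published pathway table's header total of
  166 genes differs from the text's 169; the catalog follows the text.)
- Carrier counts approximate carriers by allele count (heterozygosity
  assumption), appropriate for rare variants only.
- The HGVS fallback key assumes one transcript per gene; no liftover or
  transcript-level HGVS computation is performed.
- The simulator tracks variants independently; allele-frequency
  trajectories are uncorrelated across variants even within a branch.
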