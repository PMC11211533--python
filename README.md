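# pvarch

Sharing analysis of pathogenic variants (PVs) in DNA damage repair (DDR)
genes across modern African, modern non-African and ancient human cohorts.

## The scientific problem

Pathogenic and likely-pathogenic variants in the ~169 genes of the DNA
damage repair system (base excision repair, mismatch repair, homologous
recombination, Fanconi anemia, ...) underlie much of the inherited risk for
cancer. When did these variants arise? The latest out-of-Africa migration
(~50,000–60,000 years BP, roughly 2,000 generations ago) is a natural
cut-point: a variant that arose *after* the migration should be present in
modern non-Africans (and in ancient Eurasians, who descend from the
migrants) but absent from modern Africans, while a variant inherited from
the ancestral African population should be found on both sides of the
split.

`pvarch` implements this inference as a tested pipeline:

1. **PV extraction** — select single-base substitutions inside DDR coding
   intervals with a Pathogenic/Likely-Pathogenic clinical assertion, from
   cohort VCF/TSV tables with per-population allele counts.
2. **Ancient-intermediate classification** — classify each PV observed in
   ancient genomes by its membership in the two modern cohorts:

   | in African | in non-African | pattern          | reading                |
   |-----------:|---------------:|------------------|------------------------|
   | yes        | yes            | `BOTH`           | pre-migration origin   |
   | yes        | no             | `AFRICAN_ONLY`   | pre-migration origin   |
   | no         | yes            | `NONAFRICAN_ONLY`| post-migration origin  |
   | no         | no             | `UNSHARED`       | undetermined           |

3. **Statistics** — pooled two-proportion z-test with Yates continuity
   correction, Welch's t, Pearson prevalence correlation, and Jaccard
   distance / average-linkage clustering of ethnic-group PV profiles.
4. **Synthetic studies** — a forward Wright–Fisher simulator of the
   bottlenecked out-of-Africa split that generates complete study bundles
   with known variant arising epochs, used to validate that the classifier
   recovers those epochs.

The two-proportion statistic for comparing the PV-containing gene ratio
x₁/n vs x₂/n is the pooled z

    z = (|p̂₁ − p̂₂| − ½(1/n₁ + 1/n₂)) / √(p̂(1−p̂)(1/n₁ + 1/n₂)),

with p̂ the pooled proportion and a two-sided normal tail.

## Worked example

Classify the packaged table of ancient TP53/BRCA PVs (57 variants observed
in ancient Eurasian genomes, flagged for presence in the modern African and
non-African cohorts):

```
$ python analysis/03_ancient_sharing.py
TP53 (19 ancient PVs): non-African only 13, both 4, African only 2
BRCA (38 ancient PVs): non-African only 30, both 7, African only 1
oldest dated BRCA carrier: 37,470 BP; oldest TP53 carrier private to non-African: 34,425 BP
ancient cohort: 5,031 samples, 2.5% older than 10,000 BP
```

Of the 19 ancient TP53 PVs, 13 are private to non-Africans — consistent
with a post-migration origin — and the 4 shared with Africans are exactly
the TP53 hotspot variants. The two-proportion test on PV-containing gene
ratios (54 of 169 in African vs 77 of 169 in non-African):

```
$ python analysis/02_direct_comparison.py
African-only 86 (33.1% of African), non-African-only 800 (82.1% of non-African), shared 174
PV-containing gene ratios 54/169 vs 77/169: z = -2.4562, p = 0.01404 (two-proportion z, pooled, Yates continuity)
```

And the simulator's epoch-recovery validation:

```
$ python analysis/04_simulation.py
[default] 4869 variants arose; 23 observed in ancient samples; recovery accuracy 0.78
[idealized] 216 variants arose; 105 observed in ancient samples; recovery accuracy 1.00
```

Under realistic drift and sampling the classifier recovers ~78% of arising
epochs; in the no-drift, fully sampled limit recovery is exact.

A CLI wraps the same pipeline (`pvarch report --config cfg.yaml`,
`pvarch simulate --seed 3`); see `pvarch --help`.

## Input formats

- **Cohort variants**: VCF v4.x (INFO `AC`/`AN`) or TSV with columns
  `chrom, pos, ref, alt, allele_count, allele_number[, consequence]`.
- **Gene catalog**: TSV `gene, pathway, chrom, start, end`, one row per
  coding interval, 0-based half-open coordinates, hg38.
- **Clinical assertions**: TSV `chrom, pos, ref, alt, significance`.
- **Ancient manifest**: TSV `sample_id, date_bp[, lat, lon, variants]`,
  with inline variants as comma-separated `chrom:pos:ref>alt` tokens.

The packaged DDR catalog (`pvarch.fixtures.load_ddr_catalog`) is a
synthetic stand-in: literature-named genes sit in their true pathways, but
the full roster and all intervals are constructed, since no public roster
with intervals accompanies the published per-pathway counts.

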