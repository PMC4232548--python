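# genomescan

Genome characterization toolkit for whole-genome variant call sets,
built around the analysis of the chicken DT40 bursal-lymphoma cell line
— a workhorse model system for DNA-repair genetics whose genome was
shaped by avian leukosis virus (ALV) transformation.  Given per-sample
VCFs called against a reference genome, plus gene models, a coverage
track, and de novo assembly scaffolds, the pipeline answers the
questions a cell-line characterization asks:

* **Mutation spectrum** — counts and percentages over the six
  strand-collapsed substitution classes (CG>AT, CG>GC, CG>TA, TA>AT,
  TA>CG, TA>GC), for all SNVs and for sample-unique SNVs.
* **Unique/shared partitioning** — allele-aware intersection of ≥ 2
  samples on (chrom, pos, ref, alt) after indel left-normalization,
  and the unique-indel/unique-SNV ratio that flags excess indel
  formation.
* **Copy-neutral LOH** — heterozygous/homozygous SNV tallies in 100-kb
  blocks; a block is LOH when het < 0.1 × hom and hom ≥ 50; consecutive
  LOH blocks merge into regions with a size distribution.
* **Tandem-repeat indels** — deletions that precisely remove one unit of
  a ≥ 2-unit tandem repeat and insertions that precisely duplicate an
  adjacent segment, per indel length, with Poisson error bars
  (√k / N) and test-vs-control enrichment curves.
* **Coding impact** — strand-aware codon projection against CDS gene
  models; synonymous / nonsynonymous (Grantham-graded, radical > 150) /
  stop-gain / frameshift / in-frame calls, aggregated into candidate
  inactivated-gene lists (unique homozygous damaging hits, and
  heteroallelic combinations of ≥ 2 damaging hits).
* **Chromosome copy number** — length-weighted mean coverage scaled
  against a disomic baseline, rounded to an integer copy number, with
  B-allele-frequency modes distinguishing a trisomy (modes near 1/3 and
  2/3) from a 2+2 tetrasomy (single mode near 0.5 at doubled coverage).
* **Viral integration sites** — mixed host/viral assembly scaffolds and
  read pairs with one fully viral mate; junction zygosity from spanning
  reads (a junction with no spanning reads is carried by every allele).

A first-class synthetic-data generator (`genomescan.sim`) produces a
desk-scale multi-chromosome genome with planted truth for every signal
— spectrum weights, zygosity structure, LOH tracts, repeat indels,
aneuploidies, proviral junctions — so each stage is validated by truth
recovery rather than fixtures.

## Worked example

The published whole-genome tallies for DT40 and the L2 and Silkie
domestic-breed genomes are bundled as inputs; pushing them through the
package's operations reproduces the printed summary statistics:

```python
>>> from genomescan.published import ALL_SNV_COUNTS, UNIQUE_INDEL_ZYGOSITY
>>> from genomescan.spectrum import MutationSpectrum
>>> from genomescan.variants import ZygosityCounts
>>> MutationSpectrum.from_counts(ALL_SNV_COUNTS["DT40"]).percentages["CG>TA"]
35.31
>>> ZygosityCounts(*UNIQUE_INDEL_ZYGOSITY["DT40"]).hom_fraction_pct
52.3
>>> from genomescan.multisample import unique_indel_snv_ratio
>>> unique_indel_snv_ratio(239_924, 1_846_365)
0.13
```

35.31 is the percentage of all DT40 SNVs in the CG>TA transition class
(the dominant class, as C>T deamination-driven changes dominate most
genomes); 52.3 is the homozygous percentage of DT40-unique indels; and
0.130 is the DT40 unique-indel to unique-SNV ratio, elevated relative
to the control genomes (0.0919 and 0.0864).

End-to-end on synthetic data:

```
genomescan simulate --out-dir demo --seed 1
genomescan run-all demo/pipeline.yaml
```

writes a results directory with the spectrum tables, zygosity and
unique-variant summaries, per-block LOH calls and merged regions,
repeat-indel fraction/enrichment curves, coding effects and gene lists,
per-chromosome copy-number calls, and integration sites — each TSV with
a `#` header recording the thresholds used.

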