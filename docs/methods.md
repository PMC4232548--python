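# Methods

This note records the models, rules and numerical choices behind each
analysis stage, what the synthetic generator does and does not emulate,
and the design decisions taken where more than one reasonable choice
existed.

## Variant ingestion and filtering

VCF rows are split into one record per alternate allele so that all set
arithmetic is allele-aware; genotype 1/1 maps to `hom_alt`, any genotype
carrying the allele together with a different allele (0/1, 1/0, 1/2)
maps to `het`, and anything else — including a missing GT — to `other`.
The call-set filter keeps records with depth ≥ 3 and quality ≥ 30, both
inclusive; depth is read from the sample-level DP field with INFO/DP as
fallback (site-level depth is assumed where the two could differ).
Coordinates are 1-based only in VCF records; all internal interval
arithmetic is 0-based half-open, converted at I/O boundaries.  Indels
longer than 50 bp are flagged out-of-range and excluded from all
downstream tallies, matching the ≤ 50 bp call set the analysis is
defined on.

## Mutation spectrum

Each substitution is collapsed with its reverse complement into six
classes reported in a fixed order (CG>AT, CG>GC, CG>TA, TA>AT, TA>CG,
TA>GC).  Percentages are rounded half-up to two decimals, as in
published tables; counts are never rounded.  An empty spectrum reports
undefined (NaN) percentages rather than zeros.

## Unique/shared partitioning

Variants are keyed on (chrom, pos, ref, alt); indels are left-normalized
first so two VCF encodings of the same physical edit share a key.  A key
is unique to a sample iff absent from every other sample; zygosity is
ignored for uniqueness (hom in one sample, het in another is still
shared).  The unique-indel/unique-SNV ratio is reported to three
significant figures.

## LOH scan

Blocks of 100 kb (configurable) are anchored at position 0 of each
chromosome, non-overlapping, with a possibly short final block.  Only
SNVs with genotype hom_alt/het are tallied.  The classification rule is:
unclassifiable if hom < 50; otherwise LOH iff het < 0.1 × hom with a
strict inequality.  The two published phrasings of the rule disagree at
the exact boundaries (hom "more than 50" vs "fewer than 50 … not used";
"at least 10-times greater" vs "ratio less than 0.1"); the ratio-rule
form is used because it is the one stated twice, and hom = 50 counts as
classifiable.  Consecutive LOH blocks merge into maximal regions; region
size is quantized at block width, which bounds boundary error at one
block.  At the emulated SNV density (~5.8/kb, i.e. ~580 SNVs per 100-kb
block against the reported averages of 322 homozygous plus 306
heterozygous) every block is classifiable, so planted tracts of ≥ 3
blocks are recovered with ≤ 1 block of boundary error; tracts below one
block width are not detectable by construction.

## Tandem-repeat indels

Indels are left-aligned by shifting the edit leftward while the edited
sequence is unchanged; the result is canonical, unique and idempotent.
A deletion is a repeat-unit deletion iff the deleted segment D is
immediately preceded or followed in the reference by an identical copy
of D (≥ 2 tandem copies, one removed exactly); homopolymer contractions
are the unit-length-1 case.  An insertion is a tandem duplication iff
the inserted sequence equals the adjacent reference segment on either
side.  Both flanks are examined after normalization so the verdict is
representation-independent; "at least two repeat units" is evaluated on
the reference (pre-deletion) state, and partial-unit matches never
count.  Per length L, fraction = k/N with k events at repeats of N
total; the error bar is √k / N, the Poisson counting error of the
numerator (the published error-bar phrasing is ambiguous between √k/N
and √N/N; the numerator reading is used and recorded here).  Enrichment
at L is the test-sample fraction over the mean of the control fractions,
flagged undefined when any control fraction is zero.

## Coding impact

SNVs are projected into codon space through the spliced CDS; on the
minus strand the CDS coordinate is mirrored and alleles complemented.
Codon changes classify via the standard genetic code (synonymous /
nonsynonymous / stop-gain / stop-loss); nonsynonymous changes are graded
with the embedded published Grantham distance matrix using the
conventional bands — ≤ 50 conservative, 51–100 moderately conservative,
101–150 moderately radical, > 150 radical.  Indels overlapping the CDS
are frameshift when length mod 3 ≠ 0; length-divisible-by-3 indels are
in-frame only when fully inside one coding exon — an exon-boundary
straddle is called frameshift with a boundary flag, since the true
effect would need transcript evidence the pipeline lacks.  For gene
aggregation, "damaging" means radical nonsynonymous, frameshift,
in-frame indel, or stop-gain (in-frame indels are included because whole
coding-region indel counts are tallied and an in-frame deletion is the
documented inactivating lesion of PIK3R1 in this system).  List A
collects genes with ≥ 1 damaging hit that is both sample-unique and
homozygous; list B collects genes with ≥ 2 distinct damaging hits whose
heteroallelic combination may disrupt both alleles.  Splice-site and
UTR effects are not modeled.

## Copy number and BAF

Per-chromosome mean depth is length-weighted over a contiguous tiling
track (gaps are rejected).  The disomic baseline is the length-weighted
mean over a configured set of chromosomes assumed disomic; copy number
is round(2 × depth / baseline) with ties rounding up and a floor of one.
Calls on chromosomes shorter than 5 Mb are emitted but flagged
unreliable, reflecting the observed coverage bias against
microchromosomes.  BAF analysis histograms heterozygous-site alt-allele
fractions in (0.1, 0.9) at bin width 0.05; local maxima holding ≥ 10% of
the intermediate sites are modes, modes closer than 0.08 are merged, and
≥ 50 heterozygous sites are required for a call.  One mode near 0.5
reads disomic-like — or tetrasomic 2+2 when coverage says four copies —
and modes near 1/3 and 2/3 read trisomic-like.

## Viral integration

Alignment hits arrive in 12-column tabular form (BLAST outfmt-6 column
order).  For synthetic data an exact k-mer matcher (k = 31, seeds
chained on diagonals into maximal exact matches) produces equivalent
hits, so tests need no external aligner; with real data any aligner
emitting the tabular format can be used upstream.  Scaffolds are
classified after discarding hits below 200 bp or 90% identity: mixed
(host + viral), viral-only, host-only; a scaffold whose sole viral
evidence was a discarded short match keeps an excluded-short annotation
(the short-phage-match exclusion), and endogenous-retrovirus records can
be removed via a user-supplied exclusion list of viral sequence ids.
On a mixed scaffold the junction is the host genomic coordinate where
the host alignment meets the viral segment; a gap of > 50 unexplained
bases flags the candidate unresolved.  Orientation compares host and
viral subject strands.  Independently, read pairs with exactly one
fully viral mate (≥ 80% of 25-mers in the viral index) contribute their
exactly-placed host mate; positions cluster within 1000 bp and clusters
with ≥ 3 pairs become sites positioned at the cluster boundary nearest
the viral side.  Sites from both evidence paths within 1000 bp merge as
`both`.  Zygosity: a junction with support ≥ 3 and zero reads spanning
the uninserted coordinate is present on all alleles; support ≥ 3 with
≥ 3 spanning reads is partial; anything less is no-call.  The numeric
thresholds in this stage are not published values; they are exposed as
configuration and recorded in output headers.

## Synthetic data generator

The generator emulates the statistical structure of the study system at
desk scale: 4 chromosomes totalling 5.5 Mb (0.5–2 Mb each, vs 1.07 Gb
real) with ploidies {2, 3, 4, 1} — including a monosomic W-like
chromosome, a trisomy and a 2+2 tetrasomy; SNVs at 5.8/kb with the
genome-wide six-class weights (35.31% CG>TA etc., normalized); a
heterozygous fraction of 0.47 (the reported call set is ~53%
homozygous); indels at 0.66/kb; planted LOH tracts of 300–500 kb;
mean coverage 52×; and two proviral insertions (one all-allele, one
partial, one per orientation).  Depth and quality fields are drawn
uniformly on 1–60 and 10–60, straddling the filter thresholds so the
filter is genuinely exercised.  Coverage is Poisson per 1-kb window
around mean × ploidy/2 and heterozygous allele depths are binomial at
the planted B-allele fraction — the simplest noise model consistent
with read-depth/BAF profiles.  Monosomic chromosomes carry homozygous
variants only.  A configured fraction of indels is planted at catalog
tandem repeats (removing or duplicating exactly one unit); the
remainder are rejection-sampled until they fail the repeat tests, so
planted truth and classifier verdicts are exactly comparable.  In
cohort mode a shared pool is planted once and per-sample private sets
are planted disjointly (one global occupancy map), with the test
sample's private repeat-indel fraction raised (0.5 vs 0.3) to emulate
the repeat-deletion excess.  The generator does not emulate read-level
sequencing error, mapping artifacts, quality recalibration, GC bias, or
the SNP-array platform — so passing tests demonstrate correctness of
the analysis logic under the stated noise models, not robustness to
real-data artifacts.

## Problem sizes and determinism

Tests run the generator at 0.2–5 Mb per genome; the acceptance script
uses the 5.5-Mb default genome, a 5-Mb genome for LOH recovery, a
3.45-Mb genome for the 20,000-SNV spectrum recovery, an exhaustive
binary-alphabet reference enumeration (length ≤ 12, ~459k edits) for
the repeat oracle, and ≥ 1000 fuzzed variants for the coding oracle.
All randomness flows through seeded numpy Generators; identical config
and seed give byte-identical files, which the pipeline preserves by
writing only parameter (never timestamp) metadata.

## Known limitations

Multi-nucleotide and complex substitutions are counted but not
decomposed; phasing is not attempted, so heteroallelic gene hits may
coincide on one allele; BAF mode detection is a fixed-bin histogram
heuristic rather than a mixture model; the exact k-mer matcher does not
tolerate mismatches and stands in for a real aligner only on synthetic
data; and sub-chromosomal CNV segmentation is out of scope.
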