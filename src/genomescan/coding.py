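"""Coding-impact classification of variants against CDS gene models.

SNVs inside coding exons are projected into codon space (strand-aware),
classified as synonymous / nonsynonymous / stop-gain / stop-loss, and
nonsynonymous changes are graded by Grantham chemical dissimilarity.
Indels overlapping coding exons are frameshift (length not divisible by
three, or spanning an exon boundary) or in-frame.  Gene-level
aggregation flags candidate inactivated genes: those with a unique
homozygous damaging hit, and those with two or more damaging hits whose
heteroallelic combination may disrupt both alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from ._util import complement
from .genes import GeneModel
from .grantham import grantham_severity
from .repeats import NormalizedIndel, normalize_indel
from .variants import HOM_ALT, VariantRecord, classify_variant

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"
FRAMESHIFT_INDEL = "frameshift_indel"
INFRAME_INDEL = "inframe_indel"
NONCODING = "noncoding"

#: Categories treated as gene-damaging for aggregation (radical
#: nonsynonymous hits qualify via their severity, handled separately).
DAMAGING_INDEL_OR_STOP = frozenset({FRAMESHIFT_INDEL, INFRAME_INDEL, STOP_GAIN})


@dataclass(frozen=True)
class CodonChange:
    codon_index: int  # 0-based codon number in the spliced CDS
    ref_codon: str
    alt_codon: str


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    variant_key: tuple
    category: str
    grantham_score: int | None = None
    severity: str | None = None
    zygosity: str = "other"
    boundary: bool = False  # indel spans a CDS/intron boundary

    def __post_init__(self):
        if (self.category == NONSYNONYMOUS) != (self.grantham_score is not None):
            raise ValueError("grantham_score present iff nonsynonymous")

    @property
    def damaging(self) -> bool:
        if self.category in DAMAGING_INDEL_OR_STOP:
            return True
        return self.category == NONSYNONYMOUS and self.severity == "radical"


def project_variant(gene: GeneModel, variant: VariantRecord,
                    chrom_seq: str) -> CodonChange | None:
    """Project an SNV into codon space; None when outside the CDS.

    Reverse-strand genes see complemented alleles at the mirrored CDS
    coordinate.  The reference codon is read from the spliced CDS, so a
    reference/gene inconsistency is rejected loudly.
    """
    if gene.chrom != variant.chrom:
        raise ValueError("gene and variant on different chromosomes")
    vc = classify_variant(variant)
    if vc.kind != "snv":
        raise ValueError("project_variant handles SNVs only")
    pos0 = variant.pos - 1
    cds_pos = gene.cds_position(pos0)
    if cds_pos is None:
        return None
    spliced = gene.spliced_cds(chrom_seq)
    ref_base = variant.ref.upper() if gene.strand == "+" else complement(variant.ref.upper())
    alt_base = variant.alt.upper() if gene.strand == "+" else complement(variant.alt.upper())
    if spliced[cds_pos] != ref_base:
        raise ValueError(
            f"reference/gene inconsistency in {gene.gene_id} at CDS position {cds_pos}: "
            f"spliced CDS has {spliced[cds_pos]!r}, variant REF implies {ref_base!r}"
        )
    idx = cds_pos // 3
    ref_codon = spliced[idx * 3:idx * 3 + 3]
    within = cds_pos % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    return CodonChange(codon_index=idx, ref_codon=ref_codon, alt_codon=alt_codon)


def classify_snv_effect(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon change via the standard genetic code."""
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon.upper()):
            raise ValueError(f"invalid codon {codon!r}")
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return SYNONYMOUS
    if aa_alt == "*":
        return STOP_GAIN
    if aa_ref == "*":
        return STOP_LOSS
    return NONSYNONYMOUS


def classify_indel_effect(gene: GeneModel, indel: NormalizedIndel) -> tuple[str, bool]:
    """Classify an indel overlapping the CDS; returns (category, boundary flag).

    Length not divisible by three shifts the reading frame; a length
    divisible by three is in-frame only when the edit lies fully inside
    one coding exon — indels spanning a CDS boundary are called
    frameshift with the boundary flag set, since the true effect would
    need transcript evidence.
    """
    if indel.kind == "deletion":
        lo, hi = indel.pos0, indel.pos0 + indel.length
        overlapping = [(s, e) for s, e in gene.cds if lo < e and hi > s]
        if not overlapping:
            return NONCODING, False
        fully_within = any(s <= lo and hi <= e for s, e in gene.cds)
    else:
        p = indel.pos0  # insertion lands between p-1 and p
        overlapping = [(s, e) for s, e in gene.cds if s < p < e]
        if not overlapping:
            return NONCODING, False
        fully_within = True
    if indel.length % 3 != 0:
        return FRAMESHIFT_INDEL, not fully_within
    if fully_within:
        return INFRAME_INDEL, False
    return FRAMESHIFT_INDEL, True


def classify_coding_effect(gene: GeneModel, variant: VariantRecord,
                           chrom_seq: str) -> CodingEffect:
    """Full per-variant effect call against one gene model."""
    vc = classify_variant(variant)
    if vc.kind == "snv":
        change = project_variant(gene, variant, chrom_seq)
        if change is None:
            return CodingEffect(gene.gene_id, variant.key, NONCODING,
                                zygosity=variant.genotype)
        category = classify_snv_effect(change.ref_codon, change.alt_codon)
        score = sev = None
        if category == NONSYNONYMOUS:
            aa_from = str(Seq(change.ref_codon).translate())
            aa_to = str(Seq(change.alt_codon).translate())
            score, sev = grantham_severity(aa_from, aa_to)
        return CodingEffect(gene.gene_id, variant.key, category,
                            grantham_score=score, severity=sev,
                            zygosity=variant.genotype)
    if vc.kind in ("insertion", "deletion"):
        indel = normalize_indel(chrom_seq, variant)
        category, boundary = classify_indel_effect(gene, indel)
        return CodingEffect(gene.gene_id, variant.key, category,
                            zygosity=variant.genotype, boundary=boundary)
    return CodingEffect(gene.gene_id, variant.key, NONCODING,
                        zygosity=variant.genotype)


def annotate_effects(variants: Iterable[VariantRecord],
                     genes: Sequence[GeneModel],
                     sequences: Mapping[str, str]) -> list[CodingEffect]:
    """Classify every variant against every overlapping gene model."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    effects = []
    for var in variants:
        for gene in by_chrom.get(var.chrom, ()):
            lo, hi = gene.span
            pos0 = var.pos - 1
            if pos0 + len(var.ref) + 1 < lo or pos0 > hi:
                continue
            eff = classify_coding_effect(gene, var, sequences[var.chrom])
            if eff.category != NONCODING:
                effects.append(eff)
    return effects


@dataclass
class GeneHitLists:
    unique_homozygous: list[str]  # genes with >= 1 unique homozygous damaging hit
    heteroallelic: list[str]  # genes with >= 2 distinct damaging hits


def aggregate_gene_hits(effects: Iterable[CodingEffect],
                        unique_keys: set) -> GeneHitLists:
    """Candidate inactivated genes from damaging coding hits.

    List A: genes carrying at least one damaging hit that is both unique
    to the sample and homozygous.  List B: genes carrying two or more
    distinct damaging hits, whose heteroallelic combination may disrupt
    both alleles even when no single hit is homozygous.
    """
    a_hits: dict[str, int] = {}
    b_hits: dict[str, set] = {}
    for eff in effects:
        if not eff.damaging:
            continue
        b_hits.setdefault(eff.gene_id, set()).add(eff.variant_key)
        if eff.zygosity == HOM_ALT and eff.variant_key in unique_keys:
            a_hits[eff.gene_id] = a_hits.get(eff.gene_id, 0) + 1
    return GeneHitLists(
        unique_homozygous=sorted(a_hits),
        heteroallelic=sorted(g for g, keys in b_hits.items() if len(keys) >= 2),
    )
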