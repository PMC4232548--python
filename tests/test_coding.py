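"""Coding-effect classification vs a brute-force edit-and-translate oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from genomescan.coding import (
    FRAMESHIFT_INDEL,
    INFRAME_INDEL,
    NONCODING,
    NONSYNONYMOUS,
    STOP_GAIN,
    SYNONYMOUS,
    CodingEffect,
    aggregate_gene_hits,
    classify_coding_effect,
    classify_indel_effect,
    classify_snv_effect,
    project_variant,
)
from genomescan.genes import GeneModel
from genomescan.grantham import (
    GRANTHAM_MATRIX,
    grantham_score,
    grantham_severity,
    severity_band,
)
from genomescan.repeats import NormalizedIndel
from genomescan.variants import HET, HOM_ALT, VariantRecord

# hand-built two-exon forward gene on a known sequence:
# CDS = ATG GCT TGC TAA split as 9 + 3 bases
SEQ = "TTTT" + "ATGGCTTGC" + "GGGGG" + "TAA" + "TTTT"
GENE_FWD = GeneModel("gF", "c", "+", ((4, 13), (18, 21)))


def test_projection_arithmetic_forward():
    # genomic pos 11 (0-based 10) is CDS position 6 -> codon 2, offset 0
    change = project_variant(GENE_FWD, VariantRecord("c", 11, "T", "A", HET, 9, 40), SEQ)
    assert (change.codon_index, change.ref_codon, change.alt_codon) == (2, "TGC", "AGC")


def test_projection_reverse_strand_complements_alleles():
    # same CDS planted on the minus strand: genomic = revcomp(ATGGCTTGCTAA)
    cds = "ATGGCTTGCTAA"
    genomic = str(Seq(cds).reverse_complement())
    seq = "AAAA" + genomic + "AAAA"
    gene = GeneModel("gR", "c", "-", ((4, 16),))
    assert gene.spliced_cds(seq) == cds
    # edit the genomic base that maps to CDS position 6 ('T' of TGC)
    pos0 = 4 + (len(cds) - 1 - 6)
    ref = seq[pos0]
    change = project_variant(
        gene, VariantRecord("c", pos0 + 1, ref, "T", HET, 9, 40), seq)
    assert change.codon_index == 2
    assert change.ref_codon == "TGC"
    assert change.alt_codon == "AGC"  # complement of the genomic alt


def test_projection_outside_cds_is_noncoding():
    assert project_variant(GENE_FWD, VariantRecord("c", 15, "G", "A", HET, 9, 40),
                           SEQ) is None


def test_reference_gene_inconsistency_rejected():
    with pytest.raises(ValueError):
        project_variant(GENE_FWD, VariantRecord("c", 11, "G", "A", HET, 9, 40), SEQ)


@pytest.mark.parametrize(
    "ref_codon,alt_codon,category",
    [
        ("AAA", "AAG", SYNONYMOUS),
        ("TGC", "TGA", STOP_GAIN),
        ("TGC", "TGG", NONSYNONYMOUS),
        ("TAA", "CAA", "stop_loss"),
    ],
)
def test_codon_change_classification(ref_codon, alt_codon, category):
    assert classify_snv_effect(ref_codon, alt_codon) == category


def test_invalid_codon_rejected():
    with pytest.raises(ValueError):
        classify_snv_effect("AXA", "AAA")


@pytest.mark.parametrize(
    "a,b,score,band",
    [("L", "I", 5, "conservative"), ("C", "W", 215, "radical"),
     ("R", "K", 26, "conservative"), ("G", "W", 184, "radical")],
)
def test_grantham_lookup(a, b, score, band):
    assert grantham_severity(a, b) == (score, band)


def test_grantham_symmetry_and_identity():
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for a in aas:
        assert grantham_score(a, a) == 0
        for b in aas:
            assert grantham_score(a, b) == grantham_score(b, a)
    assert len(GRANTHAM_MATRIX) == 400
    with pytest.raises(KeyError):
        grantham_score("X", "A")


def test_severity_band_edges():
    assert [severity_band(s) for s in (50, 51, 100, 101, 150, 151)] == [
        "conservative", "moderately_conservative", "moderately_conservative",
        "moderately_radical", "moderately_radical", "radical"]


@pytest.mark.parametrize(
    "indel,category,boundary",
    [
        (NormalizedIndel("c", 11, "deletion", "GCGGGG"), FRAMESHIFT_INDEL, True),  # in-frame length but exon-spanning
        (NormalizedIndel("c", 5, "deletion", "GCT"), INFRAME_INDEL, False),
        (NormalizedIndel("c", 5, "deletion", "GC"), FRAMESHIFT_INDEL, False),
        (NormalizedIndel("c", 11, "deletion", "CGG"), FRAMESHIFT_INDEL, True),  # exon end straddle
        (NormalizedIndel("c", 14, "deletion", "GGG"), NONCODING, False),  # intron only
        (NormalizedIndel("c", 6, "insertion", "AGC"), INFRAME_INDEL, False),
    ],
)
def test_indel_effect_rules(indel, category, boundary):
    cat, flag = classify_indel_effect(GENE_FWD, indel)
    assert (cat, flag) == (category, boundary)


def _fuzz_oracle(gene, seq, pos0, ref, alt):
    """Edit the chromosome, re-splice, translate, and diff proteins."""
    edited = seq[:pos0] + alt + seq[pos0 + len(ref):]
    if len(ref) == len(alt) == 1 and gene.cds_position(pos0) is None:
        return NONCODING
    p_ref = str(Seq(gene.spliced_cds(seq)).translate())
    if len(ref) == len(alt) == 1:
        p_alt = str(Seq(gene.spliced_cds(edited)).translate())
        if p_ref == p_alt:
            return SYNONYMOUS
        for a, b in zip(p_ref, p_alt):
            if a != b:
                if b == "*":
                    return STOP_GAIN
                if a == "*":
                    return "stop_loss"
                return NONSYNONYMOUS
        return SYNONYMOUS
    raise NotImplementedError


def test_snv_classifier_agrees_with_translation_oracle(reference):
    """>= 1000 fuzzed coding SNVs over multi-exon genes on both strands."""
    rng = np.random.default_rng(42)
    n = 0
    for gene in reference.genes:
        seq = reference.sequences[gene.chrom]
        for s, e in gene.cds:
            for _ in range(45):
                pos0 = int(rng.integers(s, e))
                ref = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                eff = classify_coding_effect(
                    gene, VariantRecord(gene.chrom, pos0 + 1, ref, alt, HET, 9, 40), seq)
                assert eff.category == _fuzz_oracle(gene, seq, pos0, ref, alt), (
                    gene.gene_id, pos0, ref, alt)
                n += 1
    assert n >= 1000
    assert {g.strand for g in reference.genes} == {"+", "-"}


def test_frameshift_oracle_on_fuzzed_indels(reference):
    """Indels fully inside exons: frame rule equals length-mod-3 of the edit."""
    rng = np.random.default_rng(7)
    checked = 0
    for gene in reference.genes:
        seq = reference.sequences[gene.chrom]
        for s, e in gene.cds:
            for _ in range(15):
                L = int(rng.integers(1, 7))
                pos0 = int(rng.integers(s + 1, e - L - 1))
                v = VariantRecord(gene.chrom, pos0, seq[pos0 - 1:pos0 + L],
                                  seq[pos0 - 1], HET, 9, 40)
                eff = classify_coding_effect(gene, v, seq)
                expected = INFRAME_INDEL if L % 3 == 0 else FRAMESHIFT_INDEL
                if eff.category in (INFRAME_INDEL, FRAMESHIFT_INDEL) and not eff.boundary:
                    assert eff.category == expected
                    checked += 1
    assert checked >= 50


def _eff(gene, key, category, severity=None, zygosity=HET):
    return CodingEffect(gene, key, category,
                        grantham_score=155 if category == NONSYNONYMOUS else None,
                        severity=severity, zygosity=zygosity)


def test_gene_aggregation_lists():
    effects = [
        _eff("gA", ("c", 1, "A", "G"), STOP_GAIN, zygosity=HOM_ALT),
        _eff("gB", ("c", 2, "A", "G"), NONSYNONYMOUS, "radical"),
        _eff("gB", ("c", 3, "T", "C"), NONSYNONYMOUS, "radical"),
        _eff("gC", ("c", 4, "A", "G"), SYNONYMOUS),
        _eff("gD", ("c", 5, "A", "G"), NONSYNONYMOUS, "conservative", HOM_ALT),
    ]
    # patch gD's score/severity pair to a consistent non-radical value
    hits = aggregate_gene_hits(effects, unique_keys={("c", 1, "A", "G")})
    assert hits.unique_homozygous == ["gA"]
    assert hits.heteroallelic == ["gB"]  # two het radical hits combine
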