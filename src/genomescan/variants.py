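"""Variant record I/O, filtering and basic classification.

VCF positions stay 1-based as in the format; all internal interval
arithmetic elsewhere in the package is 0-based half-open, converted only
at I/O boundaries.  Multi-allelic rows are split into one record per
alternate allele so that downstream set arithmetic is allele-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

HOM_ALT = "hom_alt"
HET = "het"
OTHER = "other"

#: Indels longer than this are flagged and excluded from downstream tallies.
MAX_INDEL_LEN = 50

DEFAULT_MIN_DEPTH = 3
DEFAULT_MIN_QUALITY = 30


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based reference position of the VCF row
    ref: str
    alt: str
    genotype: str  # hom_alt | het | other
    depth: int
    quality: float

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")
        if self.depth < 0:
            raise ValueError(f"negative depth at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantClass:
    kind: str  # snv | insertion | deletion | mnv_or_complex
    length: int  # signed: insertions positive, deletions negative, 0 for SNV
    out_of_range: bool = False  # |length| > 50 for an indel


def _genotype_label(gt: tuple, alt_index: int) -> str:
    """Map a genotype tuple to hom_alt/het/other for the alt_index-th alt."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return OTHER
    target = alt_index + 1
    if all(a == target for a in alleles) and len(alleles) >= 2:
        return HOM_ALT
    if target in alleles:
        return HET
    return OTHER


def read_vcf(path) -> Iterator[VariantRecord]:
    """Stream records from a VCF file in file order.

    Multi-allelic rows are split into one record per alternate allele;
    genotype 1/1 maps to hom_alt, 0/1 or 1/0 (or any mixed pair carrying
    the allele) to het, everything else — including a missing GT — to
    ``other``.  Depth is taken from the sample-level DP field, falling
    back to INFO/DP, then 0.
    """
    with pysam.VariantFile(str(path)) as vf:
        for row in vf:
            alts = row.alts or ()
            qual = float(row.qual) if row.qual is not None else 0.0
            depth = None
            gt = None
            if len(row.samples) > 0:
                sample = row.samples[0]
                depth = sample.get("DP")
                gt = sample.get("GT")
            if depth is None:
                depth = row.info.get("DP", 0)
            for i, alt in enumerate(alts):
                if alt is None or alt.startswith("<"):
                    continue  # symbolic alleles carry no sequence to analyze
                genotype = _genotype_label(gt, i) if gt is not None else OTHER
                yield VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=row.ref,
                    alt=alt,
                    genotype=genotype,
                    depth=int(depth) if depth is not None else 0,
                    quality=qual,
                )


def write_vcf(records: Iterable[VariantRecord], path,
              contigs: Mapping[str, int], sample: str = "SAMPLE") -> None:
    """Write records as a minimal single-sample VCF 4.2 with GT and DP."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.quality,
            )
            gt = (1, 1) if rec.genotype == HOM_ALT else (0, 1) if rec.genotype == HET else (None, None)
            row.samples[sample]["GT"] = gt
            row.samples[sample]["DP"] = rec.depth
            out.write(row)


@dataclass
class FilterResult:
    records: list
    n_kept: int
    n_dropped: int


def filter_variants(records: Iterable[VariantRecord],
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    min_quality: float = DEFAULT_MIN_QUALITY) -> FilterResult:
    """Keep records with depth >= min_depth and quality >= min_quality.

    Both thresholds are inclusive (coverage at least 3, quality at least
    30 by default — the call-set filter the analysis is built on).
    Input order is preserved.
    """
    if min_depth < 0 or min_quality < 0:
        raise ValueError("filter thresholds must be non-negative")
    kept, dropped = [], 0
    for rec in records:
        if rec.depth >= min_depth and rec.quality >= min_quality:
            kept.append(rec)
        else:
            dropped += 1
    return FilterResult(records=kept, n_kept=len(kept), n_dropped=dropped)


def classify_variant(record: VariantRecord) -> VariantClass:
    """Classify by allele lengths: snv, insertion, deletion or complex.

    Signed length is +inserted bases / -deleted bases; indels longer
    than 50 bp are flagged out-of-range (the analysis considers indels
    up to 50 bp only).
    """
    lr, la = len(record.ref), len(record.alt)
    if lr == 1 and la == 1:
        return VariantClass("snv", 0)
    if lr == 1 and la > 1:
        n = la - 1
        return VariantClass("insertion", n, out_of_range=n > MAX_INDEL_LEN)
    if la == 1 and lr > 1:
        n = lr - 1
        return VariantClass("deletion", -n, out_of_range=n > MAX_INDEL_LEN)
    return VariantClass("mnv_or_complex", 0)


@dataclass
class ZygosityCounts:
    hom: int
    het: int

    @property
    def hom_fraction_pct(self) -> float | None:
        """Homozygous percentage over classifiable records, one decimal.

        None when no record is hom_alt or het (explicitly undefined).
        """
        from ._util import round_half_up

        total = self.hom + self.het
        if total == 0:
            return None
        return round_half_up(100.0 * self.hom / total, 1)


def zygosity_counts(records: Iterable[VariantRecord] | Sequence) -> ZygosityCounts:
    hom = het = 0
    for rec in records:
        if rec.genotype == HOM_ALT:
            hom += 1
        elif rec.genotype == HET:
            het += 1
    return ZygosityCounts(hom=hom, het=het)
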