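"""Block-based copy-neutral loss-of-heterozygosity scanning.

The genome is tiled with non-overlapping 100-kb blocks anchored at
position 0 of each chromosome.  Within every block the homozygous and
heterozygous SNVs are counted; a block is called LOH when heterozygous
SNVs are nearly absent (het < ratio_threshold x hom, default 0.1) and is
left unclassified when it carries too few homozygous SNVs to judge
(hom < min_hom, default 50).  Consecutive LOH blocks merge into maximal
regions whose size distribution summarizes the LOH landscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import HET, HOM_ALT, VariantRecord, classify_variant

DEFAULT_BLOCK_SIZE = 100_000
DEFAULT_MIN_HOM = 50
DEFAULT_RATIO_THRESHOLD = 0.1

LOH = "loh"
NON_LOH = "non_loh"
UNCLASSIFIED = "unclassified"


@dataclass
class LohBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    hom_count: int = 0
    het_count: int = 0
    status: str = UNCLASSIFIED

    @property
    def het_hom_ratio(self) -> float | None:
        if self.hom_count == 0:
            return None
        return self.het_count / self.hom_count


@dataclass
class LohRegion:
    chrom: str
    start: int
    end: int
    n_blocks: int

    @property
    def size(self) -> int:
        return self.end - self.start


def block_counts(records: Iterable[VariantRecord],
                 chrom_lengths: Mapping[str, int],
                 block_size: int = DEFAULT_BLOCK_SIZE) -> list[LohBlock]:
    """Tile each chromosome and tally hom/het SNVs per block.

    Every genomic position belongs to exactly one block; the last block
    of a chromosome may be shorter.  Only SNV records with genotype
    hom_alt or het contribute to the tallies.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    blocks: dict[str, list[LohBlock]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        chrom_blocks = []
        for start in range(0, length, block_size):
            chrom_blocks.append(
                LohBlock(chrom=chrom, start=start, end=min(start + block_size, length))
            )
        blocks[chrom] = chrom_blocks
    for rec in records:
        if rec.chrom not in blocks:
            raise ValueError(f"record on unknown chromosome {rec.chrom}")
        pos0 = rec.pos - 1
        if pos0 >= chrom_lengths[rec.chrom]:
            raise ValueError(
                f"record at {rec.chrom}:{rec.pos} beyond chromosome length"
            )
        if classify_variant(rec).kind != "snv":
            continue
        if rec.genotype not in (HOM_ALT, HET):
            continue
        block = blocks[rec.chrom][pos0 // block_size]
        if rec.genotype == HOM_ALT:
            block.hom_count += 1
        else:
            block.het_count += 1
    out = []
    for chrom in chrom_lengths:
        out.extend(blocks[chrom])
    return out


def classify_block(hom_count: int, het_count: int,
                   min_hom: int = DEFAULT_MIN_HOM,
                   ratio_threshold: float = DEFAULT_RATIO_THRESHOLD) -> str:
    """Classify one block: unclassified / loh / non_loh.

    Blocks with fewer than ``min_hom`` homozygous SNVs carry too little
    signal and are left unclassified; otherwise LOH requires the
    heterozygous count to be strictly below ratio_threshold x hom.
    """
    if hom_count < 0 or het_count < 0:
        raise ValueError("negative SNV count")
    if hom_count < min_hom:
        return UNCLASSIFIED
    return LOH if het_count < ratio_threshold * hom_count else NON_LOH


def classify_blocks(blocks: Sequence[LohBlock],
                    min_hom: int = DEFAULT_MIN_HOM,
                    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD) -> list[LohBlock]:
    for b in blocks:
        b.status = classify_block(b.hom_count, b.het_count, min_hom, ratio_threshold)
    return list(blocks)


def merge_loh_regions(blocks: Sequence[LohBlock]) -> list[LohRegion]:
    """Merge maximal runs of consecutive LOH blocks into regions.

    Blocks must be ordered by chromosome and start (as produced by
    :func:`block_counts`); a region ends at a chromosome boundary or at
    the first non-LOH block.
    """
    regions: list[LohRegion] = []
    current: LohRegion | None = None
    prev: LohBlock | None = None
    for b in blocks:
        contiguous = (
            current is not None
            and prev is not None
            and b.chrom == prev.chrom
            and b.start == prev.end
        )
        if b.status == LOH:
            if contiguous:
                current.end = b.end
                current.n_blocks += 1
            else:
                current = LohRegion(b.chrom, b.start, b.end, 1)
                regions.append(current)
        else:
            current = None
        prev = b
    return regions


@dataclass
class LohSummary:
    n_blocks: int
    loh_fraction: float
    unclassified_fraction: float
    size_histogram: dict[int, int]  # region size (bp, block-width bins) -> count


def loh_summary(blocks: Sequence[LohBlock], regions: Sequence[LohRegion],
                block_size: int = DEFAULT_BLOCK_SIZE) -> LohSummary:
    """Genome-level fractions of LOH and unclassified blocks plus region sizes.

    The size histogram bins regions at block-width granularity (a region
    of n blocks lands in the n x block_size bin, truncated final blocks
    rounded up to the bin).
    """
    if not blocks:
        raise ValueError("no blocks to summarize")
    n = len(blocks)
    n_loh = sum(1 for b in blocks if b.status == LOH)
    n_unc = sum(1 for b in blocks if b.status == UNCLASSIFIED)
    hist: dict[int, int] = {}
    for r in regions:
        bin_bp = r.n_blocks * block_size
        hist[bin_bp] = hist.get(bin_bp, 0) + 1
    return LohSummary(
        n_blocks=n,
        loh_fraction=n_loh / n,
        unclassified_fraction=n_unc / n,
        size_histogram=dict(sorted(hist.items())),
    )


def blocks_to_frame(blocks: Sequence[LohBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "hom": [b.hom_count for b in blocks],
            "het": [b.het_count for b in blocks],
            "het_hom_ratio": [
                float("nan") if b.het_hom_ratio is None else b.het_hom_ratio
                for b in blocks
            ],
            "status": [b.status for b in blocks],
        }
    )


def regions_to_bed(regions: Sequence[LohRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tloh\t{r.n_blocks}\n")
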