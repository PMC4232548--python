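"""Sample-unique vs shared variant partitioning across call sets.

Variants are matched on the (chrom, pos, ref, alt) four-tuple after indel
left-normalization, so representation differences cannot break matching.
Zygosity is deliberately ignored for uniqueness: a site homozygous in one
sample and heterozygous in another counts as shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from ._util import sig3


class VariantKey(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class Partition:
    unique: dict[str, set]  # sample -> keys present in that sample only
    shared: set  # keys present in >= 2 samples

    @property
    def union(self) -> set:
        out = set(self.shared)
        for s in self.unique.values():
            out |= s
        return out


def partition_unique_shared(sample_variants: Mapping[str, Iterable]) -> Partition:
    """Split variant keys into per-sample unique sets and a shared set.

    A key is unique to sample *s* iff present in *s* and absent from all
    other samples; everything seen in two or more samples is shared.
    Duplicate keys within one sample are deduplicated with a warning.
    """
    if len(sample_variants) < 2:
        raise ValueError("partitioning requires at least two samples")
    sets: dict[str, set] = {}
    for name, keys in sample_variants.items():
        keys = list(keys)
        dedup = set(keys)
        if len(dedup) != len(keys):
            warnings.warn(
                f"sample {name}: {len(keys) - len(dedup)} duplicate variant keys removed"
            )
        sets[name] = dedup
    unique: dict[str, set] = {}
    shared: set = set()
    for name, keys in sets.items():
        others = set().union(*(s for n, s in sets.items() if n != name))
        unique[name] = keys - others
        shared |= keys & others
    return Partition(unique=unique, shared=shared)


def unique_indel_snv_ratio(unique_indel_count: int, unique_snv_count: int) -> float:
    """Ratio of sample-unique indels to sample-unique SNVs, 3 significant figures.

    An elevated ratio relative to control genomes indicates excess indel
    formation (the DT40 hallmark); undefined for a zero SNV denominator.
    """
    if unique_snv_count <= 0:
        raise ZeroDivisionError("unique SNV count must be positive")
    if unique_indel_count < 0:
        raise ValueError("negative indel count")
    return sig3(unique_indel_count / unique_snv_count)
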