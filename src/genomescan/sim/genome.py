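"""Reference-genome synthesis: sequence, tandem-repeat catalog, gene models.

Chromosome sequences are uniform random DNA into which two kinds of
structure are planted: multi-exon CDS gene models (two or more per
chromosome, on both strands, with valid start and stop codons) and a
catalog of tandem repeats (unit length 1-15, at least two copies) used
downstream to plant slippage-style indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .._util import revcomp
from ..genes import GeneModel
from .config import SimulationConfig

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

#: Default gene shape: exon lengths (sum divisible by 3) and intron lengths.
_EXON_LENGTHS = (120, 90, 63)
_INTRON_LENGTHS = (150, 200)


@dataclass
class Reference:
    sequences: dict[str, str]
    repeat_catalog: pd.DataFrame  # chrom, start, unit, unit_len, copies, end
    genes: list[GeneModel]

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _find_free(rng: np.random.Generator, occupied: IntervalTree, length: int,
               span: int, margin: int = 200, tries: int = 200) -> int:
    for _ in range(tries):
        start = int(rng.integers(margin, length - span - margin))
        if not occupied.overlap(start - margin, start + span + margin):
            return start
    raise RuntimeError("could not place a feature; genome too crowded")


def _plant_gene(rng: np.random.Generator, seq: list, occupied: IntervalTree,
                chrom: str, gene_id: str, strand: str) -> GeneModel:
    exon_lens, intron_lens = _EXON_LENGTHS, _INTRON_LENGTHS
    span = sum(exon_lens) + sum(intron_lens)
    start = _find_free(rng, occupied, len(seq), span)
    cds_seq = _random_cds(rng, sum(exon_lens) // 3)
    genomic = cds_seq if strand == "+" else revcomp(cds_seq)
    intervals = []
    pos = start
    offset = 0
    for i, ex_len in enumerate(exon_lens):
        intervals.append((pos, pos + ex_len))
        seq[pos:pos + ex_len] = list(genomic[offset:offset + ex_len])
        offset += ex_len
        pos += ex_len
        if i < len(intron_lens):
            pos += intron_lens[i]
    occupied[start:start + span] = ("gene", gene_id)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, cds=tuple(intervals))


def _plant_repeats(rng: np.random.Generator, seq: list, occupied: IntervalTree,
                   chrom: str, n_repeats: int) -> list[dict]:
    unit_lens = np.arange(1, 16)
    weights = 0.75 ** unit_lens
    weights /= weights.sum()
    catalog = []
    for j in range(n_repeats):
        unit_len = int(rng.choice(unit_lens, p=weights))
        copies = int(rng.integers(2, 7))
        unit = "".join(rng.choice(_BASES, size=unit_len))
        tract = unit * copies
        start = _find_free(rng, occupied, len(seq), len(tract), margin=60)
        seq[start:start + len(tract)] = list(tract)
        occupied[start:start + len(tract)] = ("repeat", j)
        catalog.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + len(tract),
                "unit": unit,
                "unit_len": unit_len,
                "copies": copies,
            }
        )
    return catalog


def generate_reference(config: SimulationConfig, genes_per_chrom: int = 2,
                       repeat_spacing: int = 1500) -> Reference:
    """Build the synthetic reference deterministically from the config seed.

    Plants ``genes_per_chrom`` multi-exon CDS genes per chromosome
    (alternating strands) and roughly one tandem repeat per
    ``repeat_spacing`` bp.  Every catalog entry is an exact substring
    of the emitted sequence (unit repeated ``copies`` times).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    catalog_rows: list[dict] = []
    for chrom, length in config.chromosome_lengths:
        seq = list(rng.choice(_BASES, size=length))
        occupied = IntervalTree()
        for g in range(genes_per_chrom):
            strand = "+" if g % 2 == 0 else "-"
            genes.append(
                _plant_gene(rng, seq, occupied, chrom, f"{chrom}_g{g + 1}", strand)
            )
        catalog_rows.extend(
            _plant_repeats(rng, seq, occupied, chrom, max(4, length // repeat_spacing))
        )
        sequences[chrom] = "".join(seq)
    catalog = pd.DataFrame(
        catalog_rows, columns=["chrom", "start", "end", "unit", "unit_len", "copies"]
    )
    return Reference(sequences=sequences, repeat_catalog=catalog, genes=genes)
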