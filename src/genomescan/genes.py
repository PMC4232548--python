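"""CDS gene models and GFF3 I/O.

Models are read from GFF3 (1-based inclusive coordinates, gene/mRNA/CDS
rows) via gffutils and stored 0-based half-open.  Reading frame is
anchored at the CDS start; multi-exon genes on either strand are
supported, and the spliced CDS of a valid model translates from a start
codon to a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import gffutils

from ._util import revcomp


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]  # 0-based half-open, genomic ascending

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for s, e in self.cds:
            if s >= e:
                raise ValueError(f"empty CDS interval in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted CDS in {self.gene_id}")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds)

    def genomic_cds_offset(self, pos0: int) -> int | None:
        """Offset of a genomic position within the genomic-order spliced CDS."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                return off + (pos0 - s)
            off += e - s
        return None

    def cds_position(self, pos0: int) -> int | None:
        """Transcript-direction CDS coordinate of a genomic position."""
        off = self.genomic_cds_offset(pos0)
        if off is None:
            return None
        return off if self.strand == "+" else self.cds_length - 1 - off

    def spliced_cds(self, chrom_seq: str) -> str:
        """Coding sequence in translation order."""
        s = "".join(chrom_seq[a:b] for a, b in self.cds).upper()
        return s if self.strand == "+" else revcomp(s)


def read_gff(path) -> list[GeneModel]:
    """Load gene models from a GFF3 file (CDS rows grouped per gene)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if not cds:
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds=tuple(cds),
            )
        )
    return models


def write_gff(models: Sequence[GeneModel], path) -> None:
    """Write gene/mRNA/CDS rows as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.chrom}\tgenomescan\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tgenomescan\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            # phase of each CDS piece relative to translation order
            pieces = list(m.cds) if m.strand == "+" else list(m.cds)[::-1]
            consumed = 0
            phases = {}
            for s, e in pieces:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for i, (s, e) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.chrom}\tgenomescan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}.t1\n"
                )


def genes_by_chrom(models: Sequence[GeneModel]) -> Mapping[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for m in models:
        out.setdefault(m.chrom, []).append(m)
    return out
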