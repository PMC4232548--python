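"""FASTA and interleaved read-pair I/O (thin wrappers over Biopython)."""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_pairs_fasta(pairs: Iterable[tuple[str, str, str]], path) -> None:
    """Write read pairs as interleaved FASTA (name/1 then name/2)."""
    with open(path, "w") as fh:
        for name, seq1, seq2 in pairs:
            fh.write(f">{name}/1\n{seq1}\n>{name}/2\n{seq2}\n")


def read_pairs_fasta(path) -> list[tuple[str, str, str]]:
    """Read interleaved paired FASTA back into (name, seq1, seq2) tuples."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError("interleaved pair file holds an odd number of reads")
    pairs = []
    for r1, r2 in zip(records[0::2], records[1::2]):
        n1, n2 = r1.id.rsplit("/", 1)[0], r2.id.rsplit("/", 1)[0]
        if n1 != n2:
            raise ValueError(f"unpaired reads {r1.id} / {r2.id}")
        pairs.append((n1, str(r1.seq).upper(), str(r2.seq).upper()))
    return pairs
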