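"""Proviral-insertion simulation: chimeric scaffolds and junction read pairs.

Each planted site yields one mixed scaffold (host flank followed by part
of a viral LTR, reverse-complemented for reverse-orientation insertions)
plus viral-only and host-only decoy scaffolds, and read pairs in which
one mate is fully viral while the other maps to the host within one
fragment length of the junction.  Sites flagged ``all_alleles`` emit no
read spanning the uninserted junction — the signature used to call an
insertion present on every allele — while ``partial`` sites do.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import revcomp
from .genome import Reference

DEFAULT_READ_LENGTH = 100
DEFAULT_FRAGMENT_SIZE = 350
DEFAULT_LTR_LENGTH = 300


def make_viral_genome(rng: np.random.Generator, internal_length: int = 4400,
                      ltr_length: int = DEFAULT_LTR_LENGTH) -> str:
    """Random retrovirus-like genome: identical LTRs flanking an internal body."""
    bases = np.array(list("ACGT"))
    ltr = "".join(rng.choice(bases, size=ltr_length))
    internal = "".join(rng.choice(bases, size=internal_length))
    return ltr + internal + ltr


def plant_viral_insertions(reference: Reference, viral_genome: str,
                           sites: list[tuple], rng: np.random.Generator,
                           read_length: int = DEFAULT_READ_LENGTH,
                           fragment_size: int = DEFAULT_FRAGMENT_SIZE,
                           ltr_length: int = DEFAULT_LTR_LENGTH,
                           host_flank: int = 500,
                           pairs_per_site: int = 10,
                           spanning_pairs: int = 5,
                           n_host_decoys: int = 2,
                           n_background_pairs: int = 20
                           ) -> tuple[dict[str, str], list[tuple[str, str, str]], pd.DataFrame]:
    """Emit (scaffolds, read pairs, truth) for the planted sites.

    Site tuples are (chrom, pos, orientation[, zygosity]); ``pos`` is the
    0-based host coordinate immediately after which the provirus sits,
    so the reported 1-based junction coordinate equals ``pos``.
    """
    if len(viral_genome) < 2 * read_length:
        raise ValueError("viral genome shorter than two read lengths")
    ltr = viral_genome[:ltr_length]
    scaffolds: dict[str, str] = {}
    pairs: list[tuple[str, str, str]] = []
    truth_rows = []
    exclusion: dict[str, list[tuple[int, int]]] = {}
    for i, site in enumerate(sites, 1):
        chrom, pos, orientation = site[0], site[1], site[2]
        zygosity = site[3] if len(site) > 3 else "all_alleles"
        host = reference.sequences[chrom]
        if pos < host_flank or pos + host_flank > len(host):
            raise ValueError(
                f"viral site {chrom}:{pos} too close to the chromosome end"
            )
        vpart = ltr if orientation == "forward" else revcomp(ltr)
        scaffolds[f"mixed_{i}"] = host[pos - host_flank:pos] + vpart
        for j in range(pairs_per_site):
            offset = int(rng.integers(0, fragment_size - 2 * read_length + 1))
            start = pos - read_length - offset
            host_read = host[start:start + read_length]
            vstart = int(rng.integers(0, len(ltr) - read_length + 1))
            viral_read = ltr[vstart:vstart + read_length]
            name = f"junc_{i}_{j}"
            if rng.random() < 0.5:
                pairs.append((name, host_read, viral_read))
            else:
                pairs.append((name, viral_read, host_read))
        if zygosity == "partial":
            for j in range(spanning_pairs):
                jitter = int(rng.integers(-20, 21))
                s1 = pos - read_length // 2 + jitter
                span_read = host[s1:s1 + read_length]
                mate = host[s1 - fragment_size + read_length:
                            s1 - fragment_size + 2 * read_length]
                pairs.append((f"span_{i}_{j}", mate, span_read))
        else:
            exclusion.setdefault(chrom, []).append((pos - 2 * read_length,
                                                    pos + 2 * read_length))
        truth_rows.append(dict(chrom=chrom, pos=pos, orientation=orientation,
                               zygosity=zygosity))
    # decoy scaffolds exercise the scaffold classifier's other categories
    body = viral_genome[ltr_length:-ltr_length] or viral_genome
    scaffolds["viral_only_1"] = body[:min(800, len(body))]
    chroms = list(reference.sequences)
    for d in range(n_host_decoys):
        chrom = chroms[d % len(chroms)]
        host = reference.sequences[chrom]
        start = int(rng.integers(0, len(host) - 800))
        scaffolds[f"host_only_{d + 1}"] = host[start:start + 800]
    for b in range(n_background_pairs):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        host = reference.sequences[chrom]
        for _ in range(50):
            start = int(rng.integers(0, len(host) - fragment_size))
            bad = any(lo <= start + fragment_size and start <= hi
                      for lo, hi in exclusion.get(chrom, ()))
            if not bad:
                break
        pairs.append(
            (f"bg_{b}", host[start:start + read_length],
             host[start + fragment_size - read_length:start + fragment_size])
        )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "orientation", "zygosity"])
    return scaffolds, pairs, truth
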