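"""Coverage-track and allele-depth simulation.

Window depths are Poisson around mean_coverage x ploidy/2 — the simplest
noise model consistent with read-depth CNV profiles.  Heterozygous-site
allele depths are binomial with success probability equal to the planted
B-allele fraction: 1/2 on disomic and 2+2 tetrasomic chromosomes, 1/3 or
2/3 (per site) on trisomic ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..variants import HET
from .genome import Reference


def simulate_coverage(reference: Reference, ploidy_map: dict[str, int],
                      mean_coverage: float, rng: np.random.Generator,
                      window: int = 1000) -> pd.DataFrame:
    """Tiled bedGraph-like coverage track (chrom, start, end, depth)."""
    rows = []
    for chrom, seq in reference.sequences.items():
        length = len(seq)
        ploidy = ploidy_map[chrom]
        lam = mean_coverage * ploidy / 2
        starts = np.arange(0, length, window)
        depths = rng.poisson(lam, size=len(starts))
        for start, depth in zip(starts, depths):
            rows.append((chrom, int(start), int(min(start + window, length)), float(depth)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


def simulate_allele_depths(truth_variants: pd.DataFrame,
                           ploidy_map: dict[str, int],
                           mean_coverage: float,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-site allele depths for heterozygous SNVs (BAF input).

    Returns chrom, pos, total_depth, alt_depth, alt_fraction.
    """
    het = truth_variants[(truth_variants["kind"] == "snv")
                         & (truth_variants["zygosity"] == HET)]
    rows = []
    for _, row in het.iterrows():
        chrom = row["chrom"]
        ploidy = ploidy_map[chrom]
        lam = mean_coverage * ploidy / 2
        total = max(int(rng.poisson(lam)), 4)
        if ploidy == 3:
            p_alt = float(rng.choice([1 / 3, 2 / 3]))
        else:  # disomic and 2+2 tetrasomic states both sit at 1/2
            p_alt = 0.5
        alt = int(rng.binomial(total, p_alt))
        rows.append((chrom, int(row["pos"]), total, alt, alt / total))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "total_depth", "alt_depth", "alt_fraction"]
    )


def write_coverage_tsv(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, header=False, float_format="%.1f")
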