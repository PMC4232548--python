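"""Whole-chromosome copy-number estimation from read depth plus BAF states.

Chromosome mean coverage scaled against a disomic baseline gives an
integer copy-number estimate (rounded, minimum one); coverage of
chromosomes shorter than ~5 Mb is unreliable and such calls are flagged.
B-allele frequency (BAF) histograms at heterozygous sites distinguish
allelic states that share a coverage ratio: a trisomy shows modes near
1/3 and 2/3, while a 2+2 tetrasomy keeps a single mode near 0.5 with a
doubled coverage ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RELIABLE_MIN_LENGTH = 5_000_000

DISOMIC_LIKE = "disomic-like"
TRISOMIC_LIKE = "trisomic-like"
TETRASOMIC_2_2 = "tetrasomic-2+2"
NO_CALL = "no_call"


@dataclass
class ChromosomeCoverage:
    chrom: str
    length: int
    mean_depth: float

    @property
    def reliable(self) -> bool:
        return self.length >= RELIABLE_MIN_LENGTH


@dataclass
class CopyNumberCall:
    chrom: str
    copy_number: int
    coverage_ratio: float
    reliable: bool
    baf_modes: list[float] = field(default_factory=list)
    allelic_state: str = NO_CALL


def read_coverage_track(path) -> pd.DataFrame:
    """Read a bedGraph-like coverage TSV (chrom, start, end, depth)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": float},
    )
    return df


def chromosome_mean_coverage(track: pd.DataFrame) -> list[ChromosomeCoverage]:
    """Length-weighted mean depth per chromosome from a tiling track.

    Windows must tile each chromosome contiguously from 0; a gap or
    overlap in the tiling is rejected.
    """
    out = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"coverage windows do not tile chromosome {chrom}")
        spans = ends - starts
        mean = float(np.average(sub["depth"].to_numpy(), weights=spans))
        out.append(ChromosomeCoverage(chrom=str(chrom), length=int(ends[-1]), mean_depth=mean))
    return out


def disomic_baseline(coverages: Sequence[ChromosomeCoverage],
                     baseline_chroms: Sequence[str]) -> float:
    """Length-weighted mean depth over chromosomes assumed disomic."""
    if not baseline_chroms:
        raise ValueError("baseline chromosome set is empty")
    by_name = {c.chrom: c for c in coverages}
    missing = [c for c in baseline_chroms if c not in by_name]
    if missing:
        raise ValueError(f"baseline chromosomes missing from track: {missing}")
    chosen = [by_name[c] for c in baseline_chroms]
    weights = [c.length for c in chosen]
    return float(np.average([c.mean_depth for c in chosen], weights=weights))


def copy_number_estimate(mean_depth: float, baseline: float,
                         chrom_length: int) -> tuple[int, float, bool]:
    """Integer copy number from the coverage ratio vs the disomic baseline.

    copy number = round(2 x depth / baseline), floored at one; ties round
    up.  Returns (copy_number, ratio, reliable).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    ratio = mean_depth / baseline
    cn = max(1, math.floor(2 * ratio + 0.5))
    return cn, ratio, chrom_length >= RELIABLE_MIN_LENGTH


def baf_profile(alt_fractions: Sequence[float], copy_number: int | None = None,
                min_sites: int = 50, bin_width: float = 0.05,
                min_peak_mass: float = 0.1,
                merge_distance: float = 0.08) -> tuple[list[float], str]:
    """Modal intermediate allele fractions and the implied allelic state.

    Alt-allele fractions in the open interval (0.1, 0.9) are histogrammed
    at fixed bin width; local maxima carrying at least ``min_peak_mass``
    of the intermediate sites are modes, and modes closer than
    ``merge_distance`` are merged.  One mode near 0.5 is disomic-like
    (or the 2+2 tetrasomic state when coverage says four copies); modes
    near 1/3 and 2/3 are trisomic-like.
    """
    fracs = np.asarray([f for f in alt_fractions if 0.1 < f < 0.9], dtype=float)
    if fracs.size < min_sites:
        return [], NO_CALL
    edges = np.arange(0.1, 0.9 + bin_width / 2, bin_width)
    hist, _ = np.histogram(fracs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    peaks = []
    for i in range(len(hist)):
        left = hist[i - 1] if i > 0 else -1
        right = hist[i + 1] if i < len(hist) - 1 else -1
        if hist[i] >= left and hist[i] >= right and hist[i] >= min_peak_mass * total:
            peaks.append((centers[i], hist[i]))
    # merge nearby peaks, mass-weighted
    peaks.sort()
    modes: list[tuple[float, float]] = []
    for center, mass in peaks:
        if modes and center - modes[-1][0] <= merge_distance:
            pc, pm = modes[-1]
            tot = pm + mass
            modes[-1] = ((pc * pm + center * mass) / tot, tot)
        else:
            modes.append((center, mass))
    mode_pos = [round(float(m[0]), 3) for m in modes]
    label = NO_CALL
    near = lambda x, t: abs(x - t) <= 0.08
    if len(mode_pos) == 1 and near(mode_pos[0], 0.5):
        label = TETRASOMIC_2_2 if copy_number == 4 else DISOMIC_LIKE
    elif len(mode_pos) == 2 and near(mode_pos[0], 1 / 3) and near(mode_pos[1], 2 / 3):
        label = TRISOMIC_LIKE
    return mode_pos, label


def call_chromosomes(track: pd.DataFrame, baseline_chroms: Sequence[str],
                     baf_by_chrom: Mapping[str, Sequence[float]] | None = None
                     ) -> list[CopyNumberCall]:
    """End-to-end per-chromosome calls: coverage ratio, CN and BAF state."""
    coverages = chromosome_mean_coverage(track)
    baseline = disomic_baseline(coverages, baseline_chroms)
    calls = []
    for cov in coverages:
        cn, ratio, reliable = copy_number_estimate(cov.mean_depth, baseline, cov.length)
        modes: list[float] = []
        state = NO_CALL
        if baf_by_chrom is not None and cov.chrom in baf_by_chrom:
            modes, state = baf_profile(baf_by_chrom[cov.chrom], copy_number=cn)
        calls.append(
            CopyNumberCall(chrom=cov.chrom, copy_number=cn, coverage_ratio=ratio,
                           reliable=reliable, baf_modes=modes, allelic_state=state)
        )
    return calls


def calls_to_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "coverage_ratio": [c.coverage_ratio for c in calls],
            "reliable": [c.reliable for c in calls],
            "baf_modes": [",".join(f"{m:.3f}" for m in c.baf_modes) for c in calls],
            "allelic_state": [c.allelic_state for c in calls],
        }
    )
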