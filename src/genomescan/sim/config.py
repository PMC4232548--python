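"""Simulation configuration and planted-truth containers.

The generator's defaults mirror the reported magnitudes of the DT40
study system at desk scale: a few chromosomes of 0.1-2 Mb, ~5.8 SNVs
and ~0.66 indels per kb, a slight homozygous excess (~53%), the
genome-wide six-class substitution spectrum, planted copy-neutral LOH
tracts, aneuploid chromosomes (including a monosomic W-like chromosome)
and proviral insertion sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..spectrum import SPECTRUM_CLASSES

#: Genome-wide six-class fractions observed for the DT40 call set, in
#: SPECTRUM_CLASSES order (normalized: the printed percentages sum to
#: 100.01% because of rounding).
_RAW_WEIGHTS = (0.0735, 0.0713, 0.3531, 0.0777, 0.3529, 0.0716)
DEFAULT_SPECTRUM_WEIGHTS = tuple(w / sum(_RAW_WEIGHTS) for w in _RAW_WEIGHTS)


@dataclass
class SimulationConfig:
    chromosome_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 2_000_000),
            ("chr2", 1_200_000),
            ("chr3", 800_000),
            ("chrW", 500_000),
        ]
    )
    snv_rate: float = 5.8  # SNVs per kb
    spectrum_weights: tuple[float, ...] = DEFAULT_SPECTRUM_WEIGHTS
    het_fraction: float = 0.47
    loh_tracts: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("chr1", 300_000, 800_000),
            ("chr2", 100_000, 400_000),
        ]
    )
    indel_rate: float = 0.66  # indels per kb
    repeat_indel_fraction: float = 0.5
    ploidy_map: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2, "chr2": 3, "chr3": 4, "chrW": 1}
    )
    mean_coverage: float = 52.0
    viral_sites: list[tuple] = field(
        default_factory=lambda: [
            ("chr1", 1_500_000, "forward", "all_alleles"),
            ("chr3", 400_000, "reverse", "partial"),
        ]
    )
    seed: int = 1
    # depth/quality are drawn uniformly across ranges straddling the
    # default call-set filter (depth >= 3, quality >= 30)
    depth_range: tuple[int, int] = (1, 60)
    quality_range: tuple[int, int] = (10, 60)

    def validate(self) -> None:
        lengths = dict(self.chromosome_lengths)
        if len(lengths) != len(self.chromosome_lengths):
            raise ValueError("chromosome_lengths: duplicate chromosome names")
        for name, length in self.chromosome_lengths:
            if length <= 0:
                raise ValueError(f"chromosome_lengths: non-positive length for {name}")
        if len(self.spectrum_weights) != len(SPECTRUM_CLASSES):
            raise ValueError("spectrum_weights: six weights required")
        if any(w < 0 for w in self.spectrum_weights):
            raise ValueError("spectrum_weights: negative weight")
        if abs(sum(self.spectrum_weights) - 1.0) > 1e-9:
            raise ValueError("spectrum_weights: must sum to 1")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction: must be within [0, 1]")
        if not 0 <= self.repeat_indel_fraction <= 1:
            raise ValueError("repeat_indel_fraction: must be within [0, 1]")
        if self.snv_rate < 0 or self.indel_rate < 0:
            raise ValueError("snv_rate/indel_rate: must be non-negative")
        for chrom, start, end in self.loh_tracts:
            if chrom not in lengths:
                raise ValueError(f"loh_tracts: unknown chromosome {chrom}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"loh_tracts: tract {chrom}:{start}-{end} outside chromosome bounds"
                )
        for chrom, ploidy in self.ploidy_map.items():
            if ploidy < 1:
                raise ValueError(f"ploidy_map: ploidy < 1 for {chrom}")
        missing = set(lengths) - set(self.ploidy_map)
        if missing:
            raise ValueError(f"ploidy_map: missing chromosomes {sorted(missing)}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage: must be positive")
        for site in self.viral_sites:
            chrom, pos = site[0], site[1]
            if chrom not in lengths:
                raise ValueError(f"viral_sites: unknown chromosome {chrom}")
            if not 0 < pos < lengths[chrom]:
                raise ValueError(f"viral_sites: position {pos} outside {chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosome_lengths)


@dataclass
class TruthSet:
    """Planted ground truth, serializable losslessly as plain TSVs."""

    variants: pd.DataFrame | None = None  # chrom,pos,ref,alt,kind,zygosity,class,at_repeat,repeat_unit
    loh_tracts: pd.DataFrame | None = None  # chrom,start,end (0-based half-open)
    ploidy: pd.DataFrame | None = None  # chrom,copy_number
    integrations: pd.DataFrame | None = None  # chrom,pos,orientation,zygosity

    _FILES = {
        "variants": "truth_variants.tsv",
        "loh_tracts": "truth_loh_tracts.tsv",
        "ploidy": "truth_ploidy.tsv",
        "integrations": "truth_integrations.tsv",
    }

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            df = getattr(self, attr)
            if df is not None:
                df.to_csv(d / fname, sep="\t", index=False)

    @classmethod
    def read(cls, directory) -> "TruthSet":
        from pathlib import Path

        d = Path(directory)
        kwargs = {}
        for attr, fname in cls._FILES.items():
            p = d / fname
            if p.exists():
                kwargs[attr] = pd.read_csv(p, sep="\t")
        return cls(**kwargs)
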