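"""Six-class strand-collapsed single-nucleotide substitution spectra.

Every base substitution is merged with its reverse complement, giving six
classes named by the reference base pair and the resulting base pair
(e.g. C>T and G>A both belong to CG>TA).  This is the standard collapsed
spectrum used to compare mutational processes between whole-genome SNV
call sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import complement, round_half_up

#: Fixed class order used in all tables and serialized output.
SPECTRUM_CLASSES: tuple[str, ...] = (
    "CG>AT", "CG>GC", "CG>TA", "TA>AT", "TA>CG", "TA>GC",
)

_PYRIMIDINE_KEY = {
    ("C", "A"): "CG>AT",
    ("C", "G"): "CG>GC",
    ("C", "T"): "CG>TA",
    ("T", "A"): "TA>AT",
    ("T", "C"): "TA>CG",
    ("T", "G"): "TA>GC",
}


def collapse_substitution(ref_base: str, alt_base: str) -> str:
    """Map a single-base substitution to its strand-collapsed class.

    A substitution and its reverse complement map to the same class:
    C>T and G>A are both CG>TA.
    """
    ref = ref_base.upper()
    alt = alt_base.upper()
    if ref not in {"A", "C", "G", "T"} or alt not in {"A", "C", "G", "T"}:
        raise ValueError(f"non-ACGT base in substitution {ref_base}>{alt_base}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref_base}")
    if ref in "GA":  # collapse onto the pyrimidine-reference strand
        ref, alt = complement(ref), complement(alt)
    return _PYRIMIDINE_KEY[(ref, alt)]


@dataclass
class MutationSpectrum:
    """Counts and percentages over the six collapsed substitution classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SPECTRUM_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float] | None:
        """Per-class percentages to two decimals; None for an empty spectrum."""
        t = self.total
        if t == 0:
            return None
        return {c: round_half_up(100.0 * n / t, 2) for c, n in self.counts.items()}

    @property
    def fractions(self) -> dict[str, float] | None:
        t = self.total
        if t == 0:
            return None
        return {c: n / t for c, n in self.counts.items()}

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MutationSpectrum":
        unknown = set(counts) - set(SPECTRUM_CLASSES)
        if unknown:
            raise ValueError(f"unknown spectrum classes: {sorted(unknown)}")
        full = {c: int(counts.get(c, 0)) for c in SPECTRUM_CLASSES}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative class count")
        return cls(counts=full)

    def add(self, ref_base: str, alt_base: str) -> None:
        self.counts[collapse_substitution(ref_base, alt_base)] += 1


def compute_spectrum(snv_records: Iterable) -> MutationSpectrum:
    """Tally the collapsed spectrum of an SNV record stream.

    Records need ``ref`` and ``alt`` attributes holding single bases
    (``VariantRecord`` works; any duck-typed object does too).
    """
    spec = MutationSpectrum()
    for rec in snv_records:
        if len(rec.ref) != 1 or len(rec.alt) != 1:
            raise ValueError(
                f"non-SNV record at {rec.chrom}:{rec.pos} ({rec.ref}>{rec.alt})"
            )
        spec.add(rec.ref, rec.alt)
    return spec


def spectrum_table(named_spectra: Mapping[str, MutationSpectrum]) -> pd.DataFrame:
    """Side-by-side comparison table: six class rows plus a total row.

    For each sample there is a count column and a percentage column; an
    empty spectrum yields NA percentages (flagged, never fabricated).
    """
    if not named_spectra:
        raise ValueError("at least one spectrum is required")
    rows = list(SPECTRUM_CLASSES) + ["Total"]
    data: dict[str, list] = {}
    for name, spec in named_spectra.items():
        pct = spec.percentages
        data[f"{name}_count"] = [spec.counts[c] for c in SPECTRUM_CLASSES] + [spec.total]
        if pct is None:
            data[f"{name}_pct"] = [float("nan")] * 6 + [float("nan")]
        else:
            data[f"{name}_pct"] = [pct[c] for c in SPECTRUM_CLASSES] + [
                round_half_up(sum(pct.values()), 2)
            ]
    return pd.DataFrame(data, index=pd.Index(rows, name="class"))


def write_spectrum_table(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Serialize a spectrum table as TSV with optional ``#`` metadata lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", float_format="%.2f")
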