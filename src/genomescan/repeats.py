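"""Tandem-repeat indel classification and length-resolved instability curves.

Deletions that precisely remove one unit of a tandem repeat (>= 2 units
in the reference), and insertions that precisely duplicate an adjacent
sequence to create a tandem repeat, are the signature of replication
slippage at repeats.  Indels are left-normalized first so the test is
independent of the VCF representation chosen by the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import VariantRecord, classify_variant


@dataclass(frozen=True)
class NormalizedIndel:
    chrom: str
    pos0: int  # 0-based: deletion = start of deleted segment; insertion = point before which seq is inserted
    kind: str  # insertion | deletion
    seq: str  # inserted or deleted bases

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Canonical VCF-style key (anchored at the base before the edit)."""
        return (self.chrom, self.pos0, self.kind, self.seq)


@dataclass(frozen=True)
class RepeatIndelCall:
    indel: NormalizedIndel
    at_repeat: bool
    repeat_unit: str = ""

    def __post_init__(self):
        if self.at_repeat and len(self.repeat_unit) != self.indel.length:
            raise ValueError("repeat unit length must equal indel length")


def normalize_indel(refseq: str, variant: VariantRecord) -> NormalizedIndel:
    """Left-align an insertion or deletion against the reference sequence.

    The edit is shifted left base by base while the edited sequence stays
    identical; the result is canonical and unique, so two VCF encodings
    of the same physical edit normalize to the same key.  Idempotent.
    """
    vc = classify_variant(variant)
    if vc.kind not in ("insertion", "deletion"):
        raise ValueError(f"not an indel: {variant.ref}>{variant.alt}")
    pos0 = variant.pos - 1
    if refseq[pos0:pos0 + len(variant.ref)].upper() != variant.ref.upper():
        raise ValueError(
            f"REF allele mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref!r}, reference has "
            f"{refseq[pos0:pos0 + len(variant.ref)]!r}"
        )
    ref = refseq.upper()
    if vc.kind == "deletion":
        # deleted segment is ref[p:p+L] with p = pos0+1 (VCF anchor convention)
        p = pos0 + 1
        L = len(variant.ref) - 1
        while p > 0 and ref[p - 1] == ref[p + L - 1]:
            p -= 1
        return NormalizedIndel(variant.chrom, p, "deletion", ref[p:p + L])
    # insertion: seq inserted before position p = pos0+1
    p = pos0 + 1
    seq = variant.alt[1:].upper()
    while p > 0 and ref[p - 1] == seq[-1]:
        seq = ref[p - 1] + seq[:-1]
        p -= 1
    return NormalizedIndel(variant.chrom, p, "insertion", seq)


def is_repeat_unit_deletion(refseq: str, indel: NormalizedIndel) -> tuple[bool, str]:
    """Does this deletion precisely remove one unit of a tandem repeat?

    True iff the deleted segment D is immediately preceded or followed in
    the reference by an identical copy of D, i.e. the locus holds >= 2
    tandem copies and the deletion removes exactly one.  Homopolymer
    contractions are the unit-length-1 case.
    """
    if indel.kind != "deletion":
        raise ValueError("expected a deletion")
    ref = refseq.upper()
    p, L, d = indel.pos0, indel.length, indel.seq
    if p + 2 * L <= len(ref) and ref[p + L:p + 2 * L] == d:
        return True, d
    if p - L >= 0 and ref[p - L:p] == d:
        return True, d
    return False, ""


def is_tandem_duplication_insertion(refseq: str, indel: NormalizedIndel) -> tuple[bool, str]:
    """Does this insertion precisely duplicate an adjacent reference segment?

    True iff the inserted sequence equals the reference segment
    immediately preceding or following the insertion point (creating a
    tandem repeat where there was at least one copy).
    """
    if indel.kind != "insertion":
        raise ValueError("expected an insertion")
    ref = refseq.upper()
    p, L, s = indel.pos0, indel.length, indel.seq
    if p - L >= 0 and ref[p - L:p] == s:
        return True, s
    if p + L <= len(ref) and ref[p:p + L] == s:
        return True, s
    return False, ""


def classify_repeat_indel(refseq: str, variant: VariantRecord) -> RepeatIndelCall:
    """Normalize one indel and test its tandem-repeat status."""
    indel = normalize_indel(refseq, variant)
    if indel.kind == "deletion":
        hit, unit = is_repeat_unit_deletion(refseq, indel)
    else:
        hit, unit = is_tandem_duplication_insertion(refseq, indel)
    return RepeatIndelCall(indel=indel, at_repeat=hit, repeat_unit=unit)


def repeat_fraction_curve(calls: Iterable[RepeatIndelCall], sample: str,
                          kind: str = "deletion", max_len: int = 50) -> pd.DataFrame:
    """Per-length fraction of indels at tandem repeats, with Poisson errors.

    fraction(L) = n_at_repeat(L) / n_total(L);
    error(L) = sqrt(n_at_repeat(L)) / n_total(L), the Poisson counting
    error of the numerator.  Lengths with no events are omitted.
    """
    totals: dict[int, int] = {}
    at_rep: dict[int, int] = {}
    for call in calls:
        if call.indel.kind != kind:
            continue
        L = call.indel.length
        if L < 1 or L > max_len:
            continue
        totals[L] = totals.get(L, 0) + 1
        if call.at_repeat:
            at_rep[L] = at_rep.get(L, 0) + 1
    rows = []
    for L in sorted(totals):
        n, k = totals[L], at_rep.get(L, 0)
        rows.append(
            {
                "sample": sample,
                "length": L,
                "n_total": n,
                "n_at_repeat": k,
                "fraction": k / n,
                "error": math.sqrt(k) / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "length", "n_total", "n_at_repeat", "fraction", "error"]
    )


def enrichment_curve(test_curve: pd.DataFrame,
                     control_curves: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-length enrichment of the test sample over the control mean.

    enrichment(L) = test fraction(L) / mean(control fractions(L)).
    A length is flagged undefined when any control fraction is zero, and
    omitted (with a warning) when absent from some control.
    """
    if not control_curves:
        raise ValueError("at least one control curve is required")
    ctrl = [c.set_index("length") for c in control_curves]
    rows = []
    for _, row in test_curve.iterrows():
        L = int(row["length"])
        if any(L not in c.index for c in ctrl):
            warnings.warn(f"length {L} absent from a control curve; omitted")
            continue
        fracs = [float(c.loc[L, "fraction"]) for c in ctrl]
        undefined = any(f == 0.0 for f in fracs)
        mean_ctrl = sum(fracs) / len(fracs)
        rows.append(
            {
                "length": L,
                "test_fraction": float(row["fraction"]),
                "control_mean_fraction": mean_ctrl,
                "enrichment": float("nan") if undefined else float(row["fraction"]) / mean_ctrl,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["length", "test_fraction", "control_mean_fraction", "enrichment", "undefined"],
    )


def indel_length_histogram(indels: Iterable[NormalizedIndel],
                           max_len: int = 50) -> dict[int, int]:
    """Signed-length histogram: insertions positive, deletions negative."""
    hist: dict[int, int] = {}
    for indel in indels:
        if indel.length < 1 or indel.length > max_len:
            continue
        L = indel.length if indel.kind == "insertion" else -indel.length
        hist[L] = hist.get(L, 0) + 1
    return dict(sorted(hist.items()))
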