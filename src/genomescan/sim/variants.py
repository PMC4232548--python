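"""Variant planting: SNVs with a chosen spectrum, indels with and without
tandem-repeat context, zygosity structure and planted LOH tracts.

SNV classes are drawn multinomially from the configured six-class
weights; heterozygous/homozygous status follows the het fraction except
inside planted LOH tracts and on monosomic chromosomes, which carry
homozygous variants only.  A configurable fraction of deletions exactly
removes one unit of a catalog tandem repeat, and the same fraction of
insertions exactly duplicates a unit; the remaining indels are verified
NOT to pass the tandem-repeat tests, so planted truth and classifier
verdicts are exactly comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .._util import complement
from ..repeats import (
    is_repeat_unit_deletion,
    is_tandem_duplication_insertion,
    normalize_indel,
)
from ..spectrum import SPECTRUM_CLASSES
from ..variants import HET, HOM_ALT, VariantRecord
from .config import SimulationConfig
from .genome import Reference

_MAX_TRIES = 200


def _class_alt(spectrum_class: str, ref_base: str) -> str:
    ref_pair, alt_pair = spectrum_class.split(">")
    return alt_pair[0] if ref_base == ref_pair[0] else complement(alt_pair[0])


def _zygosity(rng, chrom: str, pos0: int, config: SimulationConfig) -> str:
    if config.ploidy_map.get(chrom, 2) == 1:
        return HOM_ALT
    for t_chrom, start, end in config.loh_tracts:
        if t_chrom == chrom and start <= pos0 < end:
            return HOM_ALT
    return HET if rng.random() < config.het_fraction else HOM_ALT


def _depth_quality(rng, config: SimulationConfig) -> tuple[int, int]:
    d0, d1 = config.depth_range
    q0, q1 = config.quality_range
    return int(rng.integers(d0, d1 + 1)), int(rng.integers(q0, q1 + 1))


def plant_variants(reference: Reference, config: SimulationConfig,
                   rng: np.random.Generator, *, scale: float = 1.0,
                   repeat_indel_fraction: float | None = None,
                   occupied: dict[str, set] | None = None
                   ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Plant SNVs and indels on the reference; returns (records, truth).

    ``scale`` multiplies both rates (used to split shared/private pools
    in cohort simulation); ``occupied`` is a mutable per-chromosome set
    of reserved positions shared across calls so separately planted sets
    never collide.  Records come back sorted by chromosome and position.
    """
    config.validate()
    rep_frac = (config.repeat_indel_fraction
                if repeat_indel_fraction is None else repeat_indel_fraction)
    if occupied is None:
        occupied = {chrom: set() for chrom in reference.sequences}
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    weights = np.asarray(config.spectrum_weights, dtype=float)
    weights = weights / weights.sum()
    for chrom, seq in reference.sequences.items():
        length = len(seq)
        occ = occupied.setdefault(chrom, set())
        n_snv = int(round(config.snv_rate * length / 1000 * scale))
        n_indel = int(round(config.indel_rate * length / 1000 * scale))
        classes = rng.choice(len(SPECTRUM_CLASSES), size=n_snv, p=weights)
        for ci in classes:
            cls = SPECTRUM_CLASSES[ci]
            ref_pair = cls.split(">")[0]
            ok = False
            for _ in range(_MAX_TRIES):
                pos0 = int(rng.integers(1, length - 1))
                base = seq[pos0]
                if pos0 in occ or base not in ref_pair:
                    continue
                ok = True
                break
            if not ok:
                warnings.warn(f"could not place SNV of class {cls} on {chrom}; skipped")
                continue
            alt = _class_alt(cls, base)
            zyg = _zygosity(rng, chrom, pos0, config)
            depth, qual = _depth_quality(rng, config)
            occ.add(pos0)
            records.append(VariantRecord(chrom, pos0 + 1, base, alt, zyg, depth, qual))
            truth_rows.append(
                dict(chrom=chrom, pos=pos0 + 1, ref=base, alt=alt, kind="snv",
                     zygosity=zyg, spectrum_class=cls, at_repeat=False, repeat_unit="")
            )
        n_repeat = int(round(n_indel * rep_frac))
        n_plain = n_indel - n_repeat
        cat = reference.repeat_catalog
        cat_chrom = cat[cat["chrom"] == chrom]
        order = rng.permutation(len(cat_chrom))
        taken = 0
        for idx in order:
            if taken >= n_repeat:
                break
            row = cat_chrom.iloc[idx]
            p, unit = int(row["start"]), str(row["unit"])
            lu = len(unit)
            span = set(range(p - 1, p + lu + 1))
            if p < 1 or span & occ:
                continue
            anchor = seq[p - 1]
            if rng.random() < 0.5:  # deletion of one unit
                ref_allele, alt_allele, kind = anchor + seq[p:p + lu], anchor, "deletion"
            else:  # insertion duplicating one unit
                ref_allele, alt_allele, kind = anchor, anchor + unit, "insertion"
            zyg = _zygosity(rng, chrom, p, config)
            depth, qual = _depth_quality(rng, config)
            occ.update(span)
            records.append(
                VariantRecord(chrom, p, ref_allele, alt_allele, zyg, depth, qual)
            )
            truth_rows.append(
                dict(chrom=chrom, pos=p, ref=ref_allele, alt=alt_allele, kind=kind,
                     zygosity=zyg, spectrum_class="", at_repeat=True, repeat_unit=unit)
            )
            taken += 1
        if taken < n_repeat:
            warnings.warn(
                f"only {taken}/{n_repeat} repeat indels placed on {chrom} "
                "(catalog exhausted)"
            )
        len_weights = 0.7 ** np.arange(1, 16)
        len_weights /= len_weights.sum()
        for _ in range(n_plain):
            placed = False
            for _try in range(_MAX_TRIES):
                ilen = int(rng.choice(np.arange(1, 16), p=len_weights))
                pos0 = int(rng.integers(1, length - ilen - 2))
                span = set(range(pos0, pos0 + ilen + 2))
                if span & occ:
                    continue
                anchor = seq[pos0]
                if rng.random() < 0.5:
                    ref_allele = seq[pos0:pos0 + 1 + ilen]
                    alt_allele, kind = anchor, "deletion"
                else:
                    ins = "".join(rng.choice(list("ACGT"), size=ilen))
                    ref_allele, alt_allele, kind = anchor, anchor + ins, "insertion"
                cand = VariantRecord(chrom, pos0 + 1, ref_allele, alt_allele,
                                     HET, 10, 40)
                norm = normalize_indel(seq, cand)
                if kind == "deletion":
                    hit, _ = is_repeat_unit_deletion(seq, norm)
                else:
                    hit, _ = is_tandem_duplication_insertion(seq, norm)
                if hit:
                    continue  # must stay a non-repeat indel
                zyg = _zygosity(rng, chrom, pos0, config)
                depth, qual = _depth_quality(rng, config)
                occ.update(span)
                records.append(
                    VariantRecord(chrom, pos0 + 1, ref_allele, alt_allele,
                                  zyg, depth, qual)
                )
                truth_rows.append(
                    dict(chrom=chrom, pos=pos0 + 1, ref=ref_allele, alt=alt_allele,
                         kind=kind, zygosity=zyg, spectrum_class="",
                         at_repeat=False, repeat_unit="")
                )
                placed = True
                break
            if not placed:
                warnings.warn(f"could not place a non-repeat indel on {chrom}; skipped")
    chrom_order = {c: i for i, c in enumerate(reference.sequences)}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.pos))
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "kind", "zygosity",
                 "spectrum_class", "at_repeat", "repeat_unit"],
    )
    truth["_c"] = truth["chrom"].map(chrom_order)
    truth = (truth.sort_values(["_c", "pos"], kind="stable")
             .drop(columns="_c").reset_index(drop=True))
    return records, truth


def simulate_cohort(reference: Reference, config: SimulationConfig,
                    sample_names: list[str],
                    shared_fraction: float = 0.5,
                    overrides: dict[str, dict] | None = None
                    ) -> dict[str, tuple[list[VariantRecord], pd.DataFrame]]:
    """Plant a multi-sample cohort: one shared pool plus private sets.

    The shared pool (present in every sample) gets ``shared_fraction``
    of the configured rates; each sample's private set gets the rest.
    A single occupancy map guarantees private sets are disjoint across
    samples, so downstream unique/shared partitioning can be checked
    against planted truth exactly.  ``overrides`` may adjust
    ``repeat_indel_fraction`` per sample (private variants only).
    """
    if not 0 <= shared_fraction < 1:
        raise ValueError("shared_fraction must be in [0, 1)")
    overrides = overrides or {}
    rng = np.random.default_rng(config.seed + 1)
    occupied: dict[str, set] = {chrom: set() for chrom in reference.sequences}
    shared_records, shared_truth = plant_variants(
        reference, config, rng, scale=shared_fraction, occupied=occupied
    )
    shared_truth = shared_truth.assign(private_to="")
    out: dict[str, tuple[list[VariantRecord], pd.DataFrame]] = {}
    private_scale = (1 - shared_fraction) / max(len(sample_names), 1)
    for name in sample_names:
        rep_frac = overrides.get(name, {}).get("repeat_indel_fraction")
        priv_records, priv_truth = plant_variants(
            reference, config, rng, scale=private_scale,
            repeat_indel_fraction=rep_frac, occupied=occupied,
        )
        priv_truth = priv_truth.assign(private_to=name)
        records = shared_records + priv_records
        chrom_order = {c: i for i, c in enumerate(reference.sequences)}
        records.sort(key=lambda r: (chrom_order[r.chrom], r.pos))
        truth = pd.concat([shared_truth, priv_truth], ignore_index=True)
        out[name] = (records, truth)
    return out
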