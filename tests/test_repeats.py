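"""Indel normalization and tandem-repeat classification vs brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from genomescan.repeats import (
    NormalizedIndel,
    classify_repeat_indel,
    enrichment_curve,
    indel_length_histogram,
    is_repeat_unit_deletion,
    is_tandem_duplication_insertion,
    normalize_indel,
    repeat_fraction_curve,
)
from genomescan.sim import SimulationConfig, generate_reference, plant_variants
from genomescan.variants import HET, VariantRecord


def _del_record(ref, p, L, chrom="c"):
    """VCF encoding of 'delete ref[p:p+L]' anchored at the previous base."""
    return VariantRecord(chrom, p, ref[p - 1] + ref[p:p + L], ref[p - 1], HET, 10, 40)


def _ins_record(ref, p, seq, chrom="c"):
    """VCF encoding of 'insert seq before ref[p]' anchored at ref[p-1]."""
    return VariantRecord(chrom, p, ref[p - 1], ref[p - 1] + seq, HET, 10, 40)


# ---------------------------------------------------------------- normalization

def test_left_alignment_of_homopolymer_deletion():
    ref = "CAAAT"
    norm = normalize_indel(ref, _del_record(ref, 3, 1))  # delete the last A
    assert (norm.pos0, norm.seq) == (1, "A")  # shifted to the first A


def test_insertion_without_repeat_context_is_unchanged():
    ref = "GATTC"
    norm = normalize_indel(ref, _ins_record(ref, 3, "CG"))
    assert (norm.pos0, norm.kind, norm.seq) == (3, "insertion", "CG")


def test_normalization_is_idempotent_and_rejects_ref_mismatch():
    ref = "GACACACT"
    v = _del_record(ref, 5, 2)
    n1 = normalize_indel(ref, v)
    v2 = _del_record(ref, n1.pos0, 2)
    assert normalize_indel(ref, v2).key == n1.key
    with pytest.raises(ValueError):
        normalize_indel(ref, VariantRecord("c", 2, "TT", "T", HET, 10, 40))


def test_equivalent_encodings_share_one_normalized_key():
    """All VCF positions inside a repeat run encode the same physical edit."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        flank1 = "".join(rng.choice(list("ACGT"), size=20))
        flank2 = "".join(rng.choice(list("ACGT"), size=20))
        unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        copies = int(rng.integers(2, 5))
        ref = flank1 + unit * copies + flank2
        L = len(unit)
        keys = set()
        edited = set()
        for c in range(copies):
            p = len(flank1) + c * L
            edited.add(ref[:p] + ref[p + L:])
            keys.add(normalize_indel(ref, _del_record(ref, p, L)).key)
        assert len(edited) == 1  # all encodings produce the same sequence
        assert len(keys) == 1


# ------------------------------------------------------- brute-force oracles

def _edited_by_deletion(ref, p, L):
    return ref[:p] + ref[p + L:]


def _oracle_repeat_deletion(ref, p, L):
    """True iff some >= 2-unit tandem run loses exactly one unit."""
    target = _edited_by_deletion(ref, p, L)
    n = len(ref)
    for i in range(n - 2 * L + 1):
        unit = ref[i:i + L]
        if ref[i + L:i + 2 * L] != unit:
            continue
        if ref[:i] + ref[i + L:] == target:
            return True
    return False


def _oracle_tandem_insertion(ref, p, seq):
    """True iff the edited string holds a 2-unit tandem whose removal
    restores the reference."""
    edited = ref[:p] + seq + ref[p:]
    L = len(seq)
    for i in range(len(edited) - 2 * L + 1):
        if edited[i:i + L] == edited[i + L:i + 2 * L]:
            if edited[:i] + edited[i + L:] == ref:
                return True
    return False


def test_worked_examples_match_figure_definitions():
    ref = "GACACT"
    hit, unit = is_repeat_unit_deletion(ref, NormalizedIndel("c", 1, "deletion", "AC"))
    assert (hit, unit) == (True, "AC")
    ref2 = "GACGTT"
    assert is_repeat_unit_deletion(ref2, NormalizedIndel("c", 2, "deletion", "CG"))[0] is False
    assert is_tandem_duplication_insertion("GAC", NormalizedIndel("c", 3, "insertion", "AC"))[0] is True
    assert is_tandem_duplication_insertion("GAC", NormalizedIndel("c", 3, "insertion", "TT"))[0] is False


def test_deletion_classifier_equals_oracle_exhaustively():
    """Every single-unit deletion on every binary reference up to length 12."""
    for n in range(2, 13):
        for bits in itertools.product("AC", repeat=n):
            ref = "".join(bits)
            for p in range(1, n):
                for L in range(1, n - p + 1):
                    call = classify_repeat_indel(ref, _del_record(ref, p, L))
                    assert call.at_repeat == _oracle_repeat_deletion(
                        ref, call.indel.pos0, L
                    ), (ref, p, L)


def test_insertion_classifier_equals_oracle_exhaustively():
    for n in range(1, 10):
        for bits in itertools.product("AC", repeat=n):
            ref = "".join(bits)
            for p in range(1, n + 1):
                for L in (1, 2):
                    for seq_bits in itertools.product("AC", repeat=L):
                        seq = "".join(seq_bits)
                        call = classify_repeat_indel(ref, _ins_record(ref, p, seq))
                        assert call.at_repeat == _oracle_tandem_insertion(
                            ref, call.indel.pos0, call.indel.seq
                        ), (ref, p, seq)


# ------------------------------------------------------------ curves, counts

def test_fraction_curve_formula():
    calls = (
        [classify_repeat_indel("GAACT", _del_record("GAACT", 2, 1))]  # homopolymer hit
        + [classify_repeat_indel("GACTT", _del_record("GACTT", 2, 1))] * 3  # miss
    )
    curve = repeat_fraction_curve(calls, "s")
    row = curve.iloc[0]
    assert (row["n_total"], row["n_at_repeat"]) == (4, 1)
    assert row["fraction"] == pytest.approx(0.25)
    assert row["error"] == pytest.approx(1 / 4)
    # integer conservation
    assert row["fraction"] * row["n_total"] == row["n_at_repeat"]


def _curve(rows):
    return pd.DataFrame(rows, columns=["sample", "length", "n_total",
                                       "n_at_repeat", "fraction", "error"])


def test_enrichment_published_worked_example():
    test = _curve([("DT40", 10, 100, 28, 0.28, 0.05)])
    ctrl = [_curve([("L2", 10, 100, 16, 0.16, 0.04)]),
            _curve([("S", 10, 100, 17, 0.17, 0.04)])]
    enr = enrichment_curve(test, ctrl)
    assert enr.iloc[0]["enrichment"] == pytest.approx(28 / 16.5)


def test_enrichment_identity_and_zero_control():
    same = _curve([("x", 1, 10, 5, 0.5, 0.1), ("x", 2, 10, 2, 0.2, 0.1)])
    enr = enrichment_curve(same, [same.copy()])
    assert (enr["enrichment"] == 1.0).all()
    zero = _curve([("c", 1, 10, 0, 0.0, 0.0), ("c", 2, 10, 2, 0.2, 0.1)])
    enr2 = enrichment_curve(same, [zero])
    assert bool(enr2.iloc[0]["undefined"]) is True
    with pytest.warns(UserWarning):
        enrichment_curve(same, [_curve([("c", 1, 10, 1, 0.1, 0.1)])])


def test_signed_length_histogram():
    indels = ([NormalizedIndel("c", 5, "insertion", "A")] * 3
              + [NormalizedIndel("c", 9, "deletion", "AT")] * 2)
    assert indel_length_histogram(indels) == {-2: 2, 1: 3}
    assert indel_length_histogram([]) == {}


# ------------------------------------------------------------- planted truth

def test_classifier_reproduces_planted_repeat_status(reference, planted):
    records, truth = planted
    indels = truth[truth["kind"] != "snv"]
    assert len(indels) > 200
    for _, row in indels.iterrows():
        v = VariantRecord(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                          HET, 10, 40)
        call = classify_repeat_indel(reference.sequences[row["chrom"]], v)
        assert call.at_repeat == bool(row["at_repeat"]), dict(row)


def test_zero_repeat_fraction_plants_no_repeat_indels():
    cfg = SimulationConfig(
        chromosome_lengths=[("chr1", 150_000)], ploidy_map={"chr1": 2},
        loh_tracts=[], viral_sites=[], repeat_indel_fraction=0.0, seed=5,
    )
    ref = generate_reference(cfg)
    records, truth = plant_variants(ref, cfg, np.random.default_rng(5))
    indels = truth[truth["kind"] != "snv"]
    assert len(indels) > 50
    for _, row in indels.iterrows():
        v = VariantRecord(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                          HET, 10, 40)
        assert classify_repeat_indel(ref.sequences[row["chrom"]], v).at_repeat is False
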