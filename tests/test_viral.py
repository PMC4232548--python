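"""Scaffold classification, junction location, read-pair clustering, zygosity."""

import numpy as np
import pytest

from genomescan._util import revcomp
from genomescan.pipeline import detect_integrations
from genomescan.sim import (
    SimulationConfig,
    generate_reference,
    make_viral_genome,
    plant_viral_insertions,
)
from genomescan.viral import (
    ALL_ALLELES,
    HOST_ONLY,
    MIXED,
    NO_CALL,
    PARTIAL,
    VIRAL_ONLY,
    AlignmentHit,
    classify_scaffold,
    exact_hits,
    is_viral_read,
    junction_zygosity,
    locate_integration,
    readpair_integration,
    viral_kmer_index,
)


def _hit(qseqid, length, sstart=1, send=None, pident=100.0, sseqid="s"):
    send = send if send is not None else sstart + length - 1
    return AlignmentHit(qseqid, sseqid, pident, length, 0, 0, 1, length,
                        sstart, send)


def test_scaffold_categories():
    assert classify_scaffold([_hit("a", 500)], [_hit("a", 400)], 1000).category == MIXED
    assert classify_scaffold([_hit("b", 500)], [], 1000).category == VIRAL_ONLY
    assert classify_scaffold([], [_hit("c", 400)], 1000).category == HOST_ONLY


def test_short_viral_match_excluded_on_long_scaffold():
    call = classify_scaffold([_hit("d", 60)], [_hit("d", 5000)], 30_000)
    assert call.category == HOST_ONLY
    assert call.excluded_short_viral is True


def test_no_hits_is_zero_evidence_host_only():
    call = classify_scaffold([], [], 500)
    assert call.category == HOST_ONLY and call.zero_evidence is True


def test_low_identity_hits_discarded():
    call = classify_scaffold([_hit("e", 500, pident=80.0)], [_hit("e", 400)], 1000)
    assert call.category == HOST_ONLY and call.excluded_short_viral is True


def test_exact_hits_forward_and_reverse():
    rng = np.random.default_rng(0)
    subject = "".join(rng.choice(list("ACGT"), size=4000))
    q_fwd = subject[1000:1400]
    q_rev = revcomp(subject[2000:2500])
    hits = exact_hits({"f": q_fwd, "r": q_rev}, {"s": subject}, min_len=100)
    f = [h for h in hits if h.qseqid == "f"]
    r = [h for h in hits if h.qseqid == "r"]
    assert any(h.sstart == 1001 and h.send == 1400 and h.subject_strand == "+"
               for h in f)
    assert any(h.sstart == 2500 and h.send == 2001 and h.subject_strand == "-"
               for h in r)


def _mixed_dataset(sites, seed=21):
    cfg = SimulationConfig(
        chromosome_lengths=[("chr1", 300_000), ("chr2", 200_000)],
        ploidy_map={"chr1": 2, "chr2": 2}, loh_tracts=[],
        viral_sites=sites, seed=seed,
    )
    ref = generate_reference(cfg)
    rng = np.random.default_rng(seed + 9000)  # independent of the genome stream
    viral = make_viral_genome(rng)
    scaffolds, pairs, truth = plant_viral_insertions(ref, viral, sites, rng)
    return ref, viral, scaffolds, pairs, truth


def test_junction_located_exactly_on_synthetic_scaffolds():
    sites = [("chr1", 250_000, "forward", "all_alleles"),
             ("chr2", 100_000, "reverse", "partial")]
    ref, viral, scaffolds, pairs, truth = _mixed_dataset(sites)
    found = detect_integrations(scaffolds, {"v": viral}, ref.sequences, pairs)
    by_chrom = {s.chrom: s for s in found}
    assert len(found) == 2
    assert by_chrom["chr1"].pos == 250_000
    assert by_chrom["chr1"].orientation == "forward"
    assert by_chrom["chr1"].zygosity == ALL_ALLELES
    assert by_chrom["chr2"].pos == 100_000
    assert by_chrom["chr2"].orientation == "reverse"
    assert by_chrom["chr2"].zygosity == PARTIAL


def test_unexplained_spacer_flags_candidate_unresolved():
    rng = np.random.default_rng(5)
    host = "".join(rng.choice(list("ACGT"), size=10_000))
    viral = "".join(rng.choice(list("ACGT"), size=2_000))
    spacer = "".join(rng.choice(list("ACGT"), size=200))
    scaffold = host[4000:4500] + spacer + viral[:400]
    hits_v = exact_hits({"m": scaffold}, {"v": viral}, min_len=200)
    hits_h = exact_hits({"m": scaffold}, {"chr1": host}, min_len=200)
    call = classify_scaffold(hits_v, hits_h, len(scaffold))
    assert call.category == MIXED
    site = locate_integration(call)
    assert site.resolved is False


def test_readpair_clustering_thresholds():
    sites = [("chr1", 150_000, "forward", "all_alleles")]
    ref, viral, scaffolds, pairs, truth = _mixed_dataset(sites, seed=8)
    kmers = viral_kmer_index(viral)
    junction = [p for p in pairs if p[0].startswith("junc")]
    background = [p for p in pairs if p[0].startswith("bg")]
    found = readpair_integration(junction + background, kmers, ref.sequences)
    assert len(found) == 1
    assert found[0].chrom == "chr1"
    assert abs(found[0].pos - 150_000) <= 350  # within one fragment length
    assert found[0].support == len(junction)
    # background-only pairs yield nothing
    assert readpair_integration(background, kmers, ref.sequences) == []
    # two supporting pairs are below the reporting threshold
    assert readpair_integration(junction[:2] + background, kmers, ref.sequences) == []


def test_viral_read_membership():
    rng = np.random.default_rng(3)
    viral = make_viral_genome(rng)
    kmers = viral_kmer_index(viral)
    assert is_viral_read(viral[50:150], kmers) is True
    assert is_viral_read(revcomp(viral[50:150]), kmers) is True
    host_like = "".join(rng.choice(list("ACGT"), size=100))
    assert is_viral_read(host_like, kmers) is False


@pytest.mark.parametrize(
    "spanning,support,expected",
    [(0, 20, ALL_ALLELES), (10, 10, PARTIAL), (1, 2, NO_CALL), (2, 5, NO_CALL)],
)
def test_junction_zygosity_rules(spanning, support, expected):
    assert junction_zygosity(spanning, support) == expected


def test_no_sites_on_insertion_free_genomes():
    """Decoy scaffolds and background pairs never produce a site."""
    for seed in range(4):
        cfg = SimulationConfig(
            chromosome_lengths=[("chr1", 120_000)], ploidy_map={"chr1": 2},
            loh_tracts=[], viral_sites=[], seed=100 + seed,
        )
        ref = generate_reference(cfg)
        rng = np.random.default_rng(9100 + seed)
        viral = make_viral_genome(rng)
        scaffolds, pairs, _ = plant_viral_insertions(ref, viral, [], rng)
        assert not any(n.startswith("mixed") for n in scaffolds)
        sites = detect_integrations(scaffolds, {"v": viral}, ref.sequences, pairs)
        assert sites == []
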