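"""Synthetic-data generator: determinism, validation, planted structure."""

import numpy as np
import pandas as pd
import pytest

from genomescan.fastaio import read_fasta, read_pairs_fasta
from genomescan.genes import read_gff
from genomescan.sim import (
    SimulationConfig,
    TruthSet,
    generate_reference,
    make_viral_genome,
    plant_variants,
    plant_viral_insertions,
    simulate_dataset,
)
from genomescan.variants import HET, read_vcf
from Bio.Seq import Seq


def _tiny_config(seed=1, **kw):
    base = dict(
        chromosome_lengths=[("chr1", 100_000)], ploidy_map={"chr1": 2},
        loh_tracts=[], viral_sites=[], seed=seed,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_reference_is_deterministic_under_seed():
    a = generate_reference(_tiny_config(seed=4))
    b = generate_reference(_tiny_config(seed=4))
    c = generate_reference(_tiny_config(seed=5))
    assert a.sequences == b.sequences
    assert len(a.sequences["chr1"]) == 100_000
    assert a.sequences != c.sequences
    pd.testing.assert_frame_equal(a.repeat_catalog, b.repeat_catalog)


@pytest.mark.parametrize(
    "kw,field",
    [
        (dict(chromosome_lengths=[("chr1", 0)]), "chromosome_lengths"),
        (dict(spectrum_weights=(0.5, 0.5, 0, 0, 0, 0.1)), "spectrum_weights"),
        (dict(het_fraction=1.5), "het_fraction"),
        (dict(loh_tracts=[("chr1", 50, 200_000)]), "loh_tracts"),
        (dict(ploidy_map={"chr1": 0}), "ploidy_map"),
        (dict(viral_sites=[("chrX", 10, "forward")]), "viral_sites"),
        (dict(mean_coverage=0), "mean_coverage"),
    ],
)
def test_invalid_config_rejected_naming_the_field(kw, field):
    with pytest.raises(ValueError, match=field):
        _tiny_config(**kw).validate()


def test_repeat_catalog_entries_are_exact_substrings(reference):
    for _, row in reference.repeat_catalog.iterrows():
        seq = reference.sequences[row["chrom"]]
        assert seq[row["start"]:row["end"]] == row["unit"] * row["copies"]
        assert 1 <= row["unit_len"] <= 15 and row["copies"] >= 2


def test_gene_models_are_translatable_on_both_strands(reference):
    per_chrom = {}
    for g in reference.genes:
        per_chrom.setdefault(g.chrom, []).append(g)
        cds = g.spliced_cds(reference.sequences[g.chrom])
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        protein = str(Seq(cds).translate())
        assert protein.endswith("*") and protein.count("*") == 1
        assert len(g.cds) >= 2  # multi-exon
    for chrom, genes in per_chrom.items():
        assert len(genes) >= 2
        assert {g.strand for g in genes} == {"+", "-"}


def test_loh_tracts_contain_no_heterozygous_variants(config, planted):
    _, truth = planted
    for chrom, start, end in config.loh_tracts:
        inside = truth[(truth["chrom"] == chrom)
                       & (truth["pos"] - 1 >= start) & (truth["pos"] - 1 < end)]
        assert len(inside) > 100
        assert (inside["zygosity"] != HET).all()


def test_monosomic_chromosome_is_fully_homozygous(planted):
    _, truth = planted
    w = truth[truth["chrom"] == "chrW"]
    assert len(w) > 100 and (w["zygosity"] != HET).all()


def test_depth_and_quality_straddle_the_filter_thresholds(planted):
    records, _ = planted
    depths = np.array([r.depth for r in records])
    quals = np.array([r.quality for r in records])
    assert depths.min() >= 1 and depths.max() <= 60
    assert quals.min() >= 10 and quals.max() <= 60
    assert (depths < 3).any() and (quals < 30).any()  # filter is exercised


def test_vcf_and_truth_round_trip(dataset, truth_variants):
    for sample in dataset["samples"]:
        records = list(read_vcf(dataset["vcfs"][sample]))
        truth = truth_variants[sample]
        assert len(records) == len(truth)
        got = {(r.chrom, r.pos, r.ref, r.alt, r.genotype) for r in records}
        expected = set(zip(truth["chrom"], truth["pos"], truth["ref"],
                           truth["alt"], truth["zygosity"]))
        assert got == expected


def test_truth_set_serialization_lossless(tmp_path, dataset):
    truth = TruthSet.read(dataset["truth_dir"])
    truth.write(tmp_path)
    back = TruthSet.read(tmp_path)
    for attr in ("loh_tracts", "ploidy", "integrations"):
        pd.testing.assert_frame_equal(getattr(truth, attr), getattr(back, attr))


def test_emitted_files_are_parseable_by_the_readers(dataset):
    genome = read_fasta(dataset["reference"])
    assert set(genome) == {"chr1", "chr2", "chr3", "chrW"}
    models = read_gff(dataset["genes"])
    assert len(models) == 8
    pairs = read_pairs_fasta(dataset["readpairs"])
    assert all(len(p) == 3 for p in pairs)
    scaffolds = read_fasta(dataset["scaffolds"])
    assert any(n.startswith("mixed") for n in scaffolds)


def test_viral_site_too_close_to_chromosome_end_rejected():
    cfg = _tiny_config()
    ref = generate_reference(cfg)
    rng = np.random.default_rng(0)
    viral = make_viral_genome(rng)
    with pytest.raises(ValueError, match="too close"):
        plant_viral_insertions(ref, viral, [("chr1", 100, "forward")], rng)


def test_dataset_generation_is_byte_deterministic(tmp_path, config):
    a = tmp_path / "a"
    b = tmp_path / "b"
    small = SimulationConfig(
        chromosome_lengths=[("chr1", 150_000), ("chr2", 100_000)],
        ploidy_map={"chr1": 2, "chr2": 3},
        loh_tracts=[("chr1", 20_000, 80_000)],
        viral_sites=[("chr1", 120_000, "forward", "all_alleles")],
        seed=33,
    )
    simulate_dataset(small, a)
    simulate_dataset(small, b)
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel
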