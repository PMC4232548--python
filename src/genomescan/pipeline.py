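"""End-to-end pipeline orchestration over a flat YAML config.

Stages run in a fixed order — filter, spectrum, unique, loh,
repeat_indels, coding, cnv, integrations — each writing TSV/BED outputs
whose ``#`` metadata headers record the exact parameters used, so a
report bundle is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import loh as loh_mod
from . import repeats as rep_mod
from . import viral as viral_mod
from .coding import aggregate_gene_hits, annotate_effects
from .fastaio import read_fasta, read_pairs_fasta
from .genes import read_gff
from .multisample import partition_unique_shared, unique_indel_snv_ratio
from .spectrum import MutationSpectrum, compute_spectrum, spectrum_table
from .variants import (
    classify_variant,
    filter_variants,
    read_vcf,
    zygosity_counts,
)

logger = logging.getLogger("genomescan")

ALL_STAGES = ("filter", "spectrum", "unique", "loh", "repeat_indels",
              "coding", "cnv", "integrations")

DEFAULT_PARAMS = {
    "min_depth": 3,
    "min_quality": 30,
    "block_size": 100_000,
    "min_hom": 50,
    "ratio_threshold": 0.1,
    "baseline_chroms": ["chr1"],
    "min_hit_len": 200,
    "min_identity": 90.0,
    "cluster_window": 1000,
    "min_support": 3,
    "max_junction_gap": 50,
}


@dataclass
class PipelineConfig:
    samples: dict[str, str]  # sample name -> VCF path
    reference: str
    output_dir: str
    test_sample: str = ""
    genes: str = ""
    coverage: str = ""
    allele_depths: str = ""
    viral: str = ""
    scaffolds: str = ""
    readpairs: str = ""
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    params: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self):
        if not self.test_sample:
            self.test_sample = next(iter(self.samples))
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_inputs(self) -> None:
        def need(stage: str, path: str, what: str):
            if stage in self.stages and (not path or not Path(path).exists()):
                raise FileNotFoundError(f"stage {stage}: missing input {what} ({path!r})")

        for name, p in self.samples.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"sample {name}: VCF not found ({p})")
        if not Path(self.reference).exists():
            raise FileNotFoundError(f"reference not found ({self.reference})")
        need("coding", self.genes, "gene models")
        need("cnv", self.coverage, "coverage track")
        need("integrations", self.scaffolds, "scaffolds FASTA")
        need("integrations", self.viral, "viral FASTA")
        need("integrations", self.readpairs, "read pairs")


def _write_tsv(df: pd.DataFrame, path: Path, params: Mapping, stage: str,
               index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genomescan stage={stage}\n")
        for key in sorted(params):
            fh.write(f"# {key}={params[key]}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages; returns a map of output name -> path."""
    config.validate_inputs()
    params = config.params
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    sequences = read_fasta(config.reference)
    lengths = {c: len(s) for c, s in sequences.items()}

    # ingest + filter
    filtered: dict[str, list] = {}
    filter_rows = []
    for name, path in config.samples.items():
        records = list(read_vcf(path))
        if "filter" in config.stages:
            res = filter_variants(records, params["min_depth"], params["min_quality"])
            filtered[name] = res.records
            filter_rows.append(dict(sample=name, input=len(records),
                                    kept=res.n_kept, dropped=res.n_dropped))
        else:
            filtered[name] = records
            filter_rows.append(dict(sample=name, input=len(records),
                                    kept=len(records), dropped=0))
    if "filter" in config.stages:
        outputs["filter_summary"] = out / "filter_summary.tsv"
        _write_tsv(pd.DataFrame(filter_rows), outputs["filter_summary"],
                   {k: params[k] for k in ("min_depth", "min_quality")}, "filter")
    for row in filter_rows:
        logger.info("sample %s: %d records in, %d kept", row["sample"],
                    row["input"], row["kept"])

    snvs = {n: [r for r in recs if classify_variant(r).kind == "snv"]
            for n, recs in filtered.items()}
    indels = {n: [r for r in recs
                  if classify_variant(r).kind in ("insertion", "deletion")
                  and not classify_variant(r).out_of_range]
              for n, recs in filtered.items()}

    if "spectrum" in config.stages:
        spectra = {n: compute_spectrum(v) for n, v in snvs.items()}
        outputs["spectrum_all"] = out / "spectrum_all.tsv"
        _write_tsv(spectrum_table(spectra), outputs["spectrum_all"], {}, "spectrum",
                   index=True)
        zyg_rows = []
        for name in config.samples:
            zs = zygosity_counts(snvs[name])
            zi = zygosity_counts(indels[name])
            zyg_rows.append(dict(sample=name,
                                 snv_hom=zs.hom, snv_het=zs.het,
                                 snv_hom_pct=zs.hom_fraction_pct,
                                 indel_hom=zi.hom, indel_het=zi.het,
                                 indel_hom_pct=zi.hom_fraction_pct))
        outputs["zygosity"] = out / "zygosity.tsv"
        _write_tsv(pd.DataFrame(zyg_rows), outputs["zygosity"], {}, "spectrum")

    # multisample partition (needed by unique/repeat_indels/coding)
    partition = None
    norm_keys: dict[str, dict] = {}
    if len(config.samples) >= 2:
        key_map: dict[str, dict] = {}
        for name in config.samples:
            keys = {}
            for rec in snvs[name]:
                keys[rec.key] = rec
            for rec in indels[name]:
                norm = rep_mod.normalize_indel(sequences[rec.chrom], rec)
                keys[norm.key] = rec
            key_map[name] = keys
        norm_keys = key_map
        partition = partition_unique_shared({n: k.keys() for n, k in key_map.items()})

    if "unique" in config.stages:
        if partition is None:
            raise ValueError("stage unique: needs at least two samples")
        uniq_rows = []
        unique_spectra = {}
        for name in config.samples:
            uniq = [norm_keys[name][k] for k in partition.unique[name]]
            u_snv = [r for r in uniq if classify_variant(r).kind == "snv"]
            u_ind = [r for r in uniq if classify_variant(r).kind != "snv"]
            unique_spectra[name] = compute_spectrum(u_snv)
            zi = zygosity_counts(u_ind)
            ratio = (unique_indel_snv_ratio(len(u_ind), len(u_snv))
                     if u_snv else float("nan"))
            uniq_rows.append(dict(sample=name, unique_snvs=len(u_snv),
                                  unique_indels=len(u_ind),
                                  unique_indel_hom_pct=zi.hom_fraction_pct,
                                  indel_snv_ratio=ratio))
        outputs["unique_summary"] = out / "unique_summary.tsv"
        _write_tsv(pd.DataFrame(uniq_rows), outputs["unique_summary"], {}, "unique")
        outputs["spectrum_unique"] = out / "spectrum_unique.tsv"
        _write_tsv(spectrum_table(unique_spectra), outputs["spectrum_unique"], {},
                   "unique", index=True)

    test = config.test_sample

    if "loh" in config.stages:
        blocks = loh_mod.block_counts(snvs[test], lengths, params["block_size"])
        loh_mod.classify_blocks(blocks, params["min_hom"], params["ratio_threshold"])
        regions = loh_mod.merge_loh_regions(blocks)
        summary = loh_mod.loh_summary(blocks, regions, params["block_size"])
        loh_params = {k: params[k] for k in ("block_size", "min_hom", "ratio_threshold")}
        outputs["loh_blocks"] = out / "loh_blocks.tsv"
        _write_tsv(loh_mod.blocks_to_frame(blocks), outputs["loh_blocks"],
                   loh_params, "loh")
        outputs["loh_regions"] = out / "loh_regions.bed"
        loh_mod.regions_to_bed(regions, outputs["loh_regions"])
        outputs["loh_summary"] = out / "loh_summary.tsv"
        _write_tsv(
            pd.DataFrame([dict(n_blocks=summary.n_blocks,
                               loh_fraction=summary.loh_fraction,
                               unclassified_fraction=summary.unclassified_fraction)]),
            outputs["loh_summary"], loh_params, "loh")

    if "repeat_indels" in config.stages:
        if partition is None:
            raise ValueError("stage repeat_indels: needs at least two samples")
        curves_del: dict[str, pd.DataFrame] = {}
        all_curves = []
        for name in config.samples:
            uniq = [norm_keys[name][k] for k in partition.unique[name]]
            u_ind = [r for r in uniq if classify_variant(r).kind != "snv"]
            calls = [rep_mod.classify_repeat_indel(sequences[r.chrom], r)
                     for r in u_ind]
            for kind in ("deletion", "insertion"):
                curve = rep_mod.repeat_fraction_curve(calls, name, kind=kind)
                curve.insert(1, "kind", kind)
                all_curves.append(curve)
                if kind == "deletion":
                    curves_del[name] = curve
        outputs["repeat_curves"] = out / "repeat_curves.tsv"
        _write_tsv(pd.concat(all_curves, ignore_index=True),
                   outputs["repeat_curves"], {}, "repeat_indels")
        controls = [curves_del[n] for n in config.samples if n != test]
        if controls:
            enr = rep_mod.enrichment_curve(curves_del[test], controls)
            outputs["repeat_enrichment"] = out / "repeat_enrichment.tsv"
            _write_tsv(enr, outputs["repeat_enrichment"],
                       {"test_sample": test}, "repeat_indels")
        hist = rep_mod.indel_length_histogram(
            [rep_mod.normalize_indel(sequences[r.chrom], r) for r in indels[test]]
        )
        outputs["indel_length_hist"] = out / "indel_length_hist.tsv"
        _write_tsv(pd.DataFrame(sorted(hist.items()), columns=["length", "count"]),
                   outputs["indel_length_hist"], {"sample": test}, "repeat_indels")

    if "coding" in config.stages:
        genes = read_gff(config.genes)
        effects = annotate_effects(filtered[test], genes, sequences)
        eff_df = pd.DataFrame(
            [dict(gene=e.gene_id, chrom=e.variant_key[0], pos=e.variant_key[1],
                  ref=e.variant_key[2], alt=e.variant_key[3], category=e.category,
                  grantham=e.grantham_score if e.grantham_score is not None else "",
                  severity=e.severity or "", zygosity=e.zygosity,
                  boundary=e.boundary)
             for e in effects],
            columns=["gene", "chrom", "pos", "ref", "alt", "category",
                     "grantham", "severity", "zygosity", "boundary"],
        )
        outputs["coding_effects"] = out / "coding_effects.tsv"
        _write_tsv(eff_df, outputs["coding_effects"], {}, "coding")
        unique_keys = partition.unique[test] if partition else set()
        hits = aggregate_gene_hits(effects, unique_keys)
        gene_rows = ([dict(gene=g, list="unique_homozygous") for g in hits.unique_homozygous]
                     + [dict(gene=g, list="heteroallelic") for g in hits.heteroallelic])
        outputs["gene_hits"] = out / "gene_hits.tsv"
        _write_tsv(pd.DataFrame(gene_rows, columns=["gene", "list"]),
                   outputs["gene_hits"], {}, "coding")

    if "cnv" in config.stages:
        track = cnv_mod.read_coverage_track(config.coverage)
        baf = None
        if config.allele_depths and Path(config.allele_depths).exists():
            ad = pd.read_csv(config.allele_depths, sep="\t")
            baf = {c: sub["alt_fraction"].tolist()
                   for c, sub in ad.groupby("chrom")}
        calls = cnv_mod.call_chromosomes(track, params["baseline_chroms"], baf)
        outputs["cnv_calls"] = out / "cnv_calls.tsv"
        _write_tsv(cnv_mod.calls_to_frame(calls), outputs["cnv_calls"],
                   {"baseline_chroms": ",".join(params["baseline_chroms"])}, "cnv")

    if "integrations" in config.stages:
        scaffolds = read_fasta(config.scaffolds)
        viral_seqs = read_fasta(config.viral)
        pairs = read_pairs_fasta(config.readpairs)
        sites = detect_integrations(
            scaffolds, viral_seqs, sequences, pairs,
            min_hit_len=params["min_hit_len"], min_identity=params["min_identity"],
            cluster_window=params["cluster_window"], min_support=params["min_support"],
            max_junction_gap=params["max_junction_gap"],
        )
        site_df = pd.DataFrame(
            [dict(chrom=s.chrom, pos=s.pos, orientation=s.orientation,
                  evidence=s.evidence, support=s.support, zygosity=s.zygosity,
                  resolved=s.resolved, scaffold=s.scaffold)
             for s in sites],
            columns=["chrom", "pos", "orientation", "evidence", "support",
                     "zygosity", "resolved", "scaffold"],
        )
        outputs["integration_sites"] = out / "integration_sites.tsv"
        _write_tsv(site_df, outputs["integration_sites"],
                   {k: params[k] for k in ("min_hit_len", "min_identity",
                                           "cluster_window", "min_support")},
                   "integrations")
        outputs["junctions_bed"] = out / "junctions.bed"
        with open(outputs["junctions_bed"], "w") as fh:
            for s in sites:
                fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.evidence}\t{s.support}\n")
    return outputs


@dataclass
class SampleSummary:
    """Per-sample stage outputs fed into the cross-sample report."""

    spectrum: MutationSpectrum
    unique_spectrum: MutationSpectrum
    unique_snvs: int
    unique_indels: int
    deletion_curve: pd.DataFrame
    params: dict = field(default_factory=dict)


def compare_samples_report(summaries: Mapping[str, SampleSummary],
                           test_sample: str) -> dict[str, pd.DataFrame]:
    """Cross-sample report: spectrum tables, ratios, repeat enrichment.

    All samples must have been processed with identical stage parameters;
    a single sample cannot be compared.
    """
    if len(summaries) < 2:
        raise ValueError("cross-sample comparison requires at least two samples")
    if test_sample not in summaries:
        raise ValueError(f"unknown test sample {test_sample!r}")
    param_sets = {yaml.dump(s.params, sort_keys=True) for s in summaries.values()}
    if len(param_sets) > 1:
        raise ValueError("samples were processed with mismatched parameters")
    ratios = pd.DataFrame(
        [dict(sample=n, unique_snvs=s.unique_snvs, unique_indels=s.unique_indels,
              indel_snv_ratio=unique_indel_snv_ratio(s.unique_indels, s.unique_snvs))
         for n, s in summaries.items()]
    )
    controls = [s.deletion_curve for n, s in summaries.items() if n != test_sample]
    enrichment = rep_mod.enrichment_curve(
        summaries[test_sample].deletion_curve, controls
    )
    return {
        "spectrum_all": spectrum_table({n: s.spectrum for n, s in summaries.items()}),
        "spectrum_unique": spectrum_table(
            {n: s.unique_spectrum for n, s in summaries.items()}
        ),
        "ratios": ratios,
        "repeat_enrichment": enrichment,
    }


def detect_integrations(scaffolds: Mapping[str, str],
                        viral_seqs: Mapping[str, str],
                        host_sequences: Mapping[str, str],
                        pairs: Sequence[tuple[str, str, str]],
                        min_hit_len: int = 200, min_identity: float = 90.0,
                        cluster_window: int = 1000, min_support: int = 3,
                        max_junction_gap: int = 50,
                        merge_distance: int = 1000) -> list:
    """Combine scaffold and read-pair evidence into integration-site calls."""
    viral_hits = viral_mod.exact_hits(scaffolds, viral_seqs)
    host_hits = viral_mod.exact_hits(scaffolds, host_sequences)
    by_scaffold_v: dict[str, list] = {}
    by_scaffold_h: dict[str, list] = {}
    for h in viral_hits:
        by_scaffold_v.setdefault(h.qseqid, []).append(h)
    for h in host_hits:
        by_scaffold_h.setdefault(h.qseqid, []).append(h)
    scaffold_sites = []
    for name, seq in scaffolds.items():
        call = viral_mod.classify_scaffold(
            by_scaffold_v.get(name, []), by_scaffold_h.get(name, []),
            len(seq), min_hit_len, min_identity,
        )
        if call.category == viral_mod.MIXED:
            scaffold_sites.append(viral_mod.locate_integration(call, max_junction_gap))
    kmers = viral_mod.viral_kmer_index(dict(viral_seqs))
    pair_sites = viral_mod.readpair_integration(
        pairs, kmers, host_sequences,
        cluster_window=cluster_window, min_support=min_support,
    )
    merged = list(scaffold_sites)
    for ps in pair_sites:
        matched = False
        for s in merged:
            if s.chrom == ps.chrom and abs(s.pos - ps.pos) <= merge_distance:
                s.evidence = "both"
                s.support += ps.support
                matched = True
                break
        if not matched:
            merged.append(ps)
    for s in merged:
        if not s.resolved:
            continue
        spanning = viral_mod.count_spanning_reads(pairs, host_sequences, s.chrom, s.pos)
        s.zygosity = viral_mod.junction_zygosity(spanning, s.support)
    merged.sort(key=lambda s: (s.chrom, s.pos))
    return merged
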