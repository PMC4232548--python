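"""Synthetic-dataset generation with planted ground truth.

``simulate_dataset`` writes a complete desk-scale input bundle — a
multi-chromosome reference with gene models and a tandem-repeat catalog,
per-sample VCFs (one test sample plus controls), a coverage track,
heterozygous-site allele depths, a viral genome, chimeric scaffolds and
junction read pairs — together with TSV truth tables for every planted
signal, so each pipeline stage can be validated against known truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..fastaio import write_fasta, write_pairs_fasta
from ..genes import write_gff
from ..variants import write_vcf
from .config import SimulationConfig, TruthSet
from .coverage import simulate_allele_depths, simulate_coverage, write_coverage_tsv
from .genome import Reference, generate_reference
from .variants import plant_variants, simulate_cohort
from .viral import make_viral_genome, plant_viral_insertions

__all__ = [
    "SimulationConfig", "TruthSet", "Reference", "generate_reference",
    "plant_variants", "simulate_cohort", "simulate_coverage",
    "simulate_allele_depths", "make_viral_genome", "plant_viral_insertions",
    "simulate_dataset",
]

#: Per-sample private repeat-indel fractions emulating the test sample's
#: excess of slippage deletions over the control genomes.
DEFAULT_COHORT_REPEAT_FRACTIONS = {"DT40": 0.5, "L2": 0.3, "Silkie": 0.3}


def simulate_dataset(config: SimulationConfig, out_dir,
                     samples: tuple[str, ...] = ("DT40", "L2", "Silkie"),
                     shared_fraction: float = 0.5,
                     repeat_fractions: dict[str, float] | None = None) -> dict:
    """Generate and write the full synthetic input bundle; returns paths.

    The first sample is the test sample: it receives the coverage track,
    allele depths and viral insertions.  All outputs are deterministic
    functions of (config, samples).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)

    reference = generate_reference(config)
    write_fasta(reference.sequences, out / "reference.fa")
    write_gff(reference.genes, out / "genes.gff3")
    reference.repeat_catalog.to_csv(out / "repeat_catalog.tsv", sep="\t", index=False)

    fracs = dict(DEFAULT_COHORT_REPEAT_FRACTIONS)
    if repeat_fractions:
        fracs.update(repeat_fractions)
    overrides = {s: {"repeat_indel_fraction": fracs.get(s)} for s in samples}
    cohort = simulate_cohort(reference, config, list(samples),
                             shared_fraction=shared_fraction, overrides=overrides)
    lengths = reference.chrom_lengths()
    vcf_paths = {}
    for name, (records, truth) in cohort.items():
        vcf_paths[name] = out / f"{name}.vcf"
        write_vcf(records, vcf_paths[name], lengths, sample=name)
        truth.to_csv(truth_dir / f"truth_variants_{name}.tsv", sep="\t", index=False)

    test_sample = samples[0]
    rng_cov = np.random.default_rng(config.seed + 101)
    track = simulate_coverage(reference, config.ploidy_map, config.mean_coverage, rng_cov)
    write_coverage_tsv(track, out / "coverage.tsv")
    allele_depths = simulate_allele_depths(
        cohort[test_sample][1], config.ploidy_map, config.mean_coverage, rng_cov
    )
    allele_depths.to_csv(out / "allele_depths.tsv", sep="\t", index=False)

    rng_vir = np.random.default_rng(config.seed + 202)
    viral_genome = make_viral_genome(rng_vir)
    write_fasta({"ALV_like": viral_genome}, out / "viral.fa")
    scaffolds, pairs, viral_truth = plant_viral_insertions(
        reference, viral_genome, config.viral_sites, rng_vir
    )
    write_fasta(scaffolds, out / "scaffolds.fa")
    write_pairs_fasta(pairs, out / "readpairs.fa")

    truth = TruthSet(
        variants=cohort[test_sample][1],
        loh_tracts=pd.DataFrame(config.loh_tracts,
                                columns=["chrom", "start", "end"]),
        ploidy=pd.DataFrame(sorted(config.ploidy_map.items()),
                            columns=["chrom", "copy_number"]),
        integrations=viral_truth,
    )
    truth.write(truth_dir)

    return {
        "out_dir": out,
        "reference": out / "reference.fa",
        "genes": out / "genes.gff3",
        "repeat_catalog": out / "repeat_catalog.tsv",
        "vcfs": vcf_paths,
        "coverage": out / "coverage.tsv",
        "allele_depths": out / "allele_depths.tsv",
        "viral": out / "viral.fa",
        "scaffolds": out / "scaffolds.fa",
        "readpairs": out / "readpairs.fa",
        "truth_dir": truth_dir,
        "samples": list(samples),
    }
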