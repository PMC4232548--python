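"""Published whole-genome variant tallies for DT40 and two domestic breeds.

These are the raw counts reported for the DT40 bursal-lymphoma cell line
and the Taiwanese L2 and Silkie breed genomes, each called against the
Gallus gallus reference: the six-class SNV spectra (all and sample-unique
SNVs), the homozygous/heterozygous indel splits (all and sample-unique
indels), and coding-region mutation tallies.  Only counts are stored;
every percentage or ratio derived from them is recomputed through the
package's own operations.
"""

from __future__ import annotations

SAMPLES = ("DT40", "L2", "Silkie")

#: All SNVs vs the reference genome, per collapsed substitution class.
ALL_SNV_COUNTS = {
    "DT40": {
        "CG>AT": 459_364, "CG>GC": 445_483, "CG>TA": 2_207_538,
        "TA>AT": 485_466, "TA>CG": 2_206_210, "TA>GC": 447_492,
    },
    "L2": {
        "CG>AT": 455_653, "CG>GC": 446_463, "CG>TA": 2_249_362,
        "TA>AT": 478_766, "TA>CG": 2_181_601, "TA>GC": 443_900,
    },
    "Silkie": {
        "CG>AT": 459_896, "CG>GC": 451_513, "CG>TA": 2_276_302,
        "TA>AT": 481_672, "TA>CG": 2_211_668, "TA>GC": 448_589,
    },
}

#: SNVs found in exactly one of the three samples.
UNIQUE_SNV_COUNTS = {
    "DT40": {
        "CG>AT": 152_918, "CG>GC": 132_424, "CG>TA": 733_718,
        "TA>AT": 148_064, "TA>CG": 556_837, "TA>GC": 122_404,
    },
    "L2": {
        "CG>AT": 125_881, "CG>GC": 112_578, "CG>TA": 631_195,
        "TA>AT": 125_262, "TA>CG": 467_746, "TA>GC": 100_442,
    },
    "Silkie": {
        "CG>AT": 153_238, "CG>GC": 135_442, "CG>TA": 758_788,
        "TA>AT": 145_251, "TA>CG": 572_208, "TA>GC": 121_206,
    },
}

#: All indels (<= 50 bp): homozygous / heterozygous counts.
ALL_INDEL_ZYGOSITY = {
    "DT40": (441_245, 267_647),
    "L2": (389_374, 220_838),
    "Silkie": (370_100, 223_594),
}

#: Sample-unique indels: homozygous / heterozygous counts.
UNIQUE_INDEL_ZYGOSITY = {
    "DT40": (125_420, 114_504),
    "L2": (71_472, 72_201),
    "Silkie": (78_273, 84_728),
}

#: Tandem-repeat deletion percentages at length 10 (DT40 vs the two
#: breed controls) — the published point used for the enrichment
#: worked example.
REPEAT_DELETION_PCT_LEN10 = {"DT40": 28.0, "L2": 16.0, "Silkie": 17.0}

#: Coding-region mutation tallies.
CODING_COUNTS = {
    "nonsynonymous_snvs": {"DT40": 23_184, "L2": 22_906, "Silkie": 21_851},
    "radical_nonsynonymous_snvs": {"DT40": 1_251, "L2": 1_285, "Silkie": 1_128},
    "coding_region_indels": {"DT40": 1_505, "L2": 1_235, "Silkie": 1_074},
    "stop_gain_mutations": {"DT40": 175, "L2": 167, "Silkie": 157},
}


def unique_snv_total(sample: str) -> int:
    return sum(UNIQUE_SNV_COUNTS[sample].values())


def unique_indel_total(sample: str) -> int:
    hom, het = UNIQUE_INDEL_ZYGOSITY[sample]
    return hom + het
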