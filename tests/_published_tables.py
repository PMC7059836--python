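"""Published per-chromosome evaluation figures for the GRCh38 1000 Genomes
consensus call set, used as fixed inputs for report-arithmetic checks."""

# Site concordance against the NA12878 gold standard, chromosome 1 (GRCh38):
# (shared/TP, gold-only/FN, query-only/FP) and the printed derived values.
CHR1_CONCORDANCE_COUNTS = (238_323, 8_965, 1_347)
CHR1_CONCORDANCE_PRINTED = {
    "pct_shared": 96.37,
    "pct_gold_only": 3.63,
    "pct_query_only": 0.56,
    "total_gold": 247_288,
    "total_query": 239_670,
}

# False-negative attribution per autosome: (false negatives, count removed in
# the 99.5-99.9 recalibration tranche, count removed in the 99.9-100 tranche).
FN_ATTRIBUTION_COUNTS = {
    "chr1": (5224, 3666, 138),
    "chr2": (5071, 3476, 75),
    "chr3": (4635, 3198, 92),
    "chr4": (4592, 3274, 98),
    "chr5": (3949, 2808, 66),
    "chr6": (4916, 3489, 123),
    "chr7": (3462, 2338, 78),
    "chr8": (3246, 2155, 65),
    "chr9": (2652, 1750, 42),
    "chr10": (2893, 1870, 64),
    "chr11": (3896, 2768, 91),
    "chr12": (2802, 1937, 69),
    "chr13": (2024, 1261, 32),
    "chr14": (2177, 1463, 48),
    "chr15": (1643, 1028, 33),
    "chr16": (977, 528, 17),
    "chr17": (1359, 835, 37),
    "chr18": (1261, 821, 25),
    "chr19": (1401, 929, 38),
    "chr20": (1051, 623, 18),
    "chr21": (728, 477, 10),
    "chr22": (628, 477, 10),
}
TRANCHE_LABELS = ("VQSRTrancheSNP99.50to99.90", "VQSRTrancheSNP99.90to100.00")

# Biallelic SNV counts on novel GRCh38 contigs vs pre-existing sequence for
# the de novo call set and the lift-over call set.
NOVEL_REGION_COUNTS = {
    "novel": {"this_work": 1_019_976, "liftover": 811_817},
    "existing": {"this_work": 70_809_835, "liftover": 76_588_820},
}

# Per-autosome switch-error rates (percent) of the de novo call set.
SWITCH_ERROR_SNV_RATES = [
    0.99, 0.53, 0.48, 0.50, 0.51, 1.40, 0.74, 0.61, 0.43, 0.89, 0.57,
    0.44, 0.44, 0.44, 0.61, 1.17, 1.62, 0.53, 0.37, 0.46, 0.44, 1.52,
]
SWITCH_ERROR_INDEL_RATES = [
    2.55, 0.66, 0.44, 0.56, 0.57, 4.67, 2.26, 0.95, 0.40, 2.91, 0.71,
    0.43, 0.52, 0.51, 0.58, 5.56, 6.35, 0.56, 0.62, 0.86, 0.73, 5.83,
]
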