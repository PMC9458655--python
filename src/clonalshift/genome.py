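"""GRCh38 reference constants used across the pipeline.

Only autosome lengths and the handful of JAK2-region landmarks the analysis
needs are kept here; no sequence data is required anywhere in the package.
"""

from __future__ import annotations

# Autosome lengths, GRCh38 primary assembly (1-based inclusive coordinates).
GRCH38_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
}

#: Somatic JAK2 V617F site (GRCh38, 1-based).
V617F_CHROM = "chr9"
V617F_POS = 5_073_770

#: Germline SNPs tagging the JAK2 46/1 risk haplotype, in haplotype-string order.
HAPLOTYPE_SNPS = ("rs3780367", "rs10974944", "rs12343867")

#: Risk and major non-risk allele strings over HAPLOTYPE_SNPS.
RISK_HAPLOTYPE = "GGC"
NONRISK_HAPLOTYPE = "TCT"

#: Per-site allele alphabets (risk allele first).
SNP_ALLELES = (("G", "T"), ("G", "C"), ("C", "T"))

#: Margin defining "telomeric" events (distance from either chromosome end).
TELOMERE_MARGIN = 1_000_000
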