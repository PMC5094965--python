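"""Versioned hg19 constants: primary-chromosome sizes, centromere (acen
cytoband) coordinates, and the prostate-cancer gene loci used by the locus
analysis.

All coordinates are 0-based half-open. Embedding these as constants removes
any download dependency; alternate assemblies can be supplied as chrom-sizes
files instead.
"""

from __future__ import annotations

# UCSC hg19 primary chromosome lengths (chr1..chr22, chrX, chrY).
CHROM_SIZES: list[tuple[str, int]] = [
    ("chr1", 249250621),
    ("chr2", 243199373),
    ("chr3", 198022430),
    ("chr4", 191154276),
    ("chr5", 180915260),
    ("chr6", 171115067),
    ("chr7", 159138663),
    ("chr8", 146364022),
    ("chr9", 141213431),
    ("chr10", 135534747),
    ("chr11", 135006516),
    ("chr12", 133851895),
    ("chr13", 115169878),
    ("chr14", 107349540),
    ("chr15", 102531392),
    ("chr16", 90354753),
    ("chr17", 81195210),
    ("chr18", 78077248),
    ("chr19", 59128983),
    ("chr20", 63025520),
    ("chr21", 48129895),
    ("chr22", 51304566),
    ("chrX", 155270560),
    ("chrY", 59373566),
]

# Centromere span per chromosome: union of the two UCSC cytoBand "acen" bands.
CENTROMERES: dict[str, tuple[int, int]] = {
    "chr1": (121535434, 124535434),
    "chr2": (92326171, 95326171),
    "chr3": (90504854, 93504854),
    "chr4": (49660117, 52660117),
    "chr5": (46405641, 49405641),
    "chr6": (58830166, 61830166),
    "chr7": (58054331, 61054331),
    "chr8": (43838887, 46838887),
    "chr9": (47367679, 50367679),
    "chr10": (39254935, 42254935),
    "chr11": (51644205, 54644205),
    "chr12": (34856694, 37856694),
    "chr13": (16000000, 19000000),
    "chr14": (16000000, 19000000),
    "chr15": (17000000, 20000000),
    "chr16": (35335801, 38335801),
    "chr17": (22263006, 25263006),
    "chr18": (15460898, 18460898),
    "chr19": (24681782, 27681782),
    "chr20": (26369569, 29369569),
    "chr21": (11288129, 14288129),
    "chr22": (13000000, 16000000),
    "chrX": (58632012, 61632012),
    "chrY": (10104553, 13104553),
}

# Core prostate-cancer genes (RefSeq hg19 gene spans).
GENE_LOCI: list[tuple[str, str, int, int]] = [
    ("AR", "chrX", 66764465, 66950461),
    ("PTEN", "chr10", 89623195, 89728532),
    ("TMPRSS2", "chr21", 42836478, 42903043),
    ("ERG", "chr21", 39751949, 40033704),
    ("NOTCH1", "chr9", 139388896, 139440238),
    ("MYCL", "chr1", 40361098, 40367687),
]

# Treatment-change genes, coordinates as published in the source locus table.
TREATMENT_GENE_LOCI: list[tuple[str, str, int, int]] = [
    ("ZNRF3", "chr22", 29427573, 29453476),
    ("RNF43", "chr17", 56431037, 56494931),
    ("LGR4", "chr11", 27387508, 27494338),
    ("NCOR1", "chr17", 15933864, 16101195),
    ("ZBTB16", "chr11", 113933133, 114126702),
    ("MYC", "chr8", 128748449, 128753674),
    ("FGFR1", "chr7", 55177416, 55279262),
    ("KRAS", "chr12", 25358180, 25403854),
    ("STK11", "chr19", 1205798, 1228434),
]

# T-cell receptor alpha locus: lymphocyte gDNA controls carry somatic
# deletions here, so cfDNA/gDNA ratios show pseudo-amplification. Excluded
# from cross-sample minimal-overlap analysis by default.
TCRA_LOCUS: tuple[str, str, int, int] = ("TCRA", "chr14", 22090057, 23021075)
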