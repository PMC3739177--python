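"""Published reference values for the *Treponema caldaria* H1 genome project.

These are the printed summary statistics of the H1 chromosome (INSDC
CP002868) and its pairwise genome comparisons against *Spirochaeta
africana* (CP003282) and *Treponema primitia* (CP001843).  They serve as
fixed inputs for report generation and as expected values in the test
suite; nothing here is computed by this package.
"""

from __future__ import annotations

#: Gene counts per single-letter COG functional category for the H1 genome.
#: Keys follow the canonical 25-category order used throughout the package.
H1_COG_COUNTS: dict[str, int] = {
    "J": 158,
    "A": 0,
    "K": 156,
    "L": 125,
    "B": 2,
    "D": 33,
    "Y": 0,
    "V": 40,
    "T": 228,
    "M": 142,
    "N": 86,
    "Z": 0,
    "W": 0,
    "U": 50,
    "O": 91,
    "C": 134,
    "G": 296,
    "E": 188,
    "F": 67,
    "H": 77,
    "I": 60,
    "P": 77,
    "Q": 26,
    "R": 293,
    "S": 182,
}

#: Genes of the H1 genome without any COG assignment.
H1_NOT_IN_COGS: int = 658

#: Chromosome-level summary counts for H1 (all in bp or gene counts).
H1_GENOME_STATS: dict[str, int] = {
    "genome_size": 3_239_340,
    "coding_bases": 2_965_950,
    "gc_bases": 1_476_358,
    "total_genes": 2_928,
    "protein_coding_genes": 2_869,
    "rna_genes": 59,
    "pseudo_genes": 80,
}

#: Published pairwise distance components (coverage %, within-HSP identity %)
#: from the genome-to-genome comparisons of the three study genomes.
GGD_COMPONENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("S. caldaria", "S. africana"): (1.62, 84.50),
    ("S. caldaria", "T. primitia"): (6.04, 81.92),
    ("T. primitia", "S. africana"): (1.34, 83.99),
}
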