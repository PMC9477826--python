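"""Shared paths and study conditions for the analysis scripts.

The study stand-in: 10 alpha + 10 beta synthetic isolates (50-kb
mini-genomes, planted marker identity 0.6) and 20 simulated lake
metagenomes of 10,000 x 150-bp reads each, mixed at a summed alpha:beta
abundance of 7:1 with a 1% substitution error rate. Bulky intermediates
(FASTA/FASTQ) live under scratch/; tables under results/.
"""
from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 2022
N_ALPHA = 10
N_BETA = 10
GENOME_LENGTH = 50_000
PLANTED_IDENTITY = 0.6
N_METAGENOMES = 20
N_READS = 10_000
READ_LENGTH = 150
ERROR_RATE = 0.01
ALPHA_TO_BETA = 7.0
#: genomes included in the recruitment reference set (2 alpha + 2 beta)
RECRUIT_REFS = ("alpha_00", "alpha_01", "beta_10", "beta_11")

GENOMES_DIR = SCRATCH / "genomes"
READS_DIR = SCRATCH / "reads"
TRUTH_TSV = RESULTS / "planted_loci.tsv"
GENE_MATRIX_TSV = RESULTS / "gene_matrix.tsv"
CALLS_TSV = RESULTS / "genotype_calls.tsv"
RPKG_TSV = RESULTS / "rpkg_matrix.tsv"
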