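"""Shared fixtures: the packaged panel and a session-scoped synthetic cohort.

The cohort (10 alpha + 10 beta genomes, 50 kb, planted marker identity 0.6,
fixed seeds) is the workhorse for end-to-end genotype-recovery checks; it is
generated once per session because marker search over 20 proteomes is the
most expensive step in the suite.
"""
from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from picoccm.genotyping import build_gene_matrix, extract_orfs
from picoccm.panel import MarkerPanel
from picoccm.synthetic import (
    GenotypeSpec,
    alpha_marker_set,
    beta_marker_set,
    generate_genome,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COHORT_IDENTITY = 0.6
COHORT_GENOME_LENGTH = 50_000
COHORT_SEED_BASE = 7000


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return MarkerPanel.default()


@dataclasses.dataclass
class Cohort:
    genomes: list  # GenomeRecord with proteomes
    truths: dict  # genome_id -> list[PlantedLocus]
    classes: dict  # genome_id -> alpha|beta
    matrix: "object"  # GeneMatrix


def build_cohort(panel: MarkerPanel, n_alpha: int = 10, n_beta: int = 10) -> Cohort:
    genomes, truths, classes = [], {}, {}
    for i in range(n_alpha + n_beta):
        ccm_class = "alpha" if i < n_alpha else "beta"
        markers = (
            alpha_marker_set(COHORT_IDENTITY)
            if ccm_class == "alpha"
            else beta_marker_set(COHORT_IDENTITY)
        )
        spec = GenotypeSpec(
            label=f"{ccm_class}_{i:02d}",
            ccm_class=ccm_class,
            markers=markers,
            genome_length=COHORT_GENOME_LENGTH,
        )
        genome, loci = generate_genome(spec, seed=COHORT_SEED_BASE + i, panel=panel)
        genome = extract_orfs(genome, min_len_codons=60)
        genomes.append(genome)
        truths[genome.genome_id] = loci
        classes[genome.genome_id] = ccm_class
    matrix = build_gene_matrix(genomes, panel)
    return Cohort(genomes=genomes, truths=truths, classes=classes, matrix=matrix)


@pytest.fixture(scope="session")
def cohort(panel) -> Cohort:
    return build_cohort(panel)
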