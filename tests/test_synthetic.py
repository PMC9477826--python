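"""Synthetic genomes, marker variants and metagenomes: parameter recovery."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from picoccm.align import local_align
from picoccm.genotyping import extract_orfs
from picoccm.io import InputError
from picoccm.ordination import kulczynski_binary, pco
from picoccm.synthetic import (
    CommunitySpec,
    GenotypeSpec,
    alpha_marker_set,
    generate_genome,
    generate_marker_variant,
    generate_pa_fixture,
    simulate_metagenome,
)


class TestMarkerVariant:
    def test_identity_one_returns_reference(self):
        assert generate_marker_variant("MKTAYIAKQR", 1.0, seed=1) == "MKTAYIAKQR"

    def test_measured_identity_tracks_target(self, panel):
        ref = panel["rbcL_1A"].representative[:100]
        variant = generate_marker_variant(ref, 0.40, seed=7)
        assert len(variant) == len(ref)
        hit = local_align(variant, ref)
        assert hit.identity == pytest.approx(40.0, abs=2.0)

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7, 0.9])
    def test_realized_identity_within_two_points(self, panel, target):
        ref = panel["csoS2"].representative  # length >= 50
        for seed in (1, 2, 3):
            variant = generate_marker_variant(ref, target, seed=seed)
            hit = local_align(variant, ref)
            assert abs(hit.identity - 100 * target) <= 2.0

    def test_deterministic_given_seed(self):
        ref = "M" + "ACDEFGHIKL" * 10
        assert generate_marker_variant(ref, 0.5, 42) == generate_marker_variant(ref, 0.5, 42)
        assert generate_marker_variant(ref, 0.5, 42) != generate_marker_variant(ref, 0.5, 43)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            generate_marker_variant("", 0.5, 1)
        with pytest.raises(InputError):
            generate_marker_variant("MK", 0.0, 1)
        with pytest.raises(InputError):
            generate_marker_variant("MK", 1.5, 1)


class TestGenerateGenome:
    def test_planted_orfs_recovered_at_recorded_coordinates(self, panel):
        spec = GenotypeSpec(
            label="g1", ccm_class="alpha",
            markers=[("rbcL_1A", 1, 0.9), ("csoS1", 2, 0.8), ("ccmK", 1, 1.0)],
            genome_length=20_000,
        )
        genome, loci = generate_genome(spec, seed=11, panel=panel)
        assert genome.genome_length_bp == 20_000
        assert len(loci) == 4  # csoS1 planted twice
        extracted = extract_orfs(genome, min_len_codons=60)
        by_coord = {extracted.orf_coords[pid]: seq for pid, seq in extracted.proteome}
        for locus in loci:
            key = (locus.contig, locus.start, locus.end, locus.strand)
            assert key in by_coord, f"planted {locus.family_id} not recovered"
            assert by_coord[key] == locus.protein

    def test_spacing_and_strand_conventions(self, panel):
        spec = GenotypeSpec(
            label="g2", ccm_class="beta",
            markers=[("ccmK", 1, 0.9), ("ccmL", 1, 0.9), ("ccmM", 1, 0.9)],
            genome_length=15_000,
        )
        _, loci = generate_genome(spec, seed=3, panel=panel)
        loci = sorted(loci, key=lambda l: l.start)
        for prev, cur in zip(loci, loci[1:]):
            assert cur.start - prev.end >= 100 - 3  # guard codons sit inside the gap
        assert all(l.strand in "+-" for l in loci)

    def test_deterministic_given_seed(self, panel):
        spec = GenotypeSpec(
            label="g3", ccm_class="alpha", markers=alpha_marker_set(0.7),
            genome_length=30_000,
        )
        g1, _ = generate_genome(spec, seed=5, panel=panel)
        g2, _ = generate_genome(spec, seed=5, panel=panel)
        assert g1.contigs == g2.contigs

    def test_markers_exceeding_genome_length_rejected(self, panel):
        spec = GenotypeSpec(
            label="g4", ccm_class="alpha", markers=alpha_marker_set(0.9),
            genome_length=2_000,
        )
        with pytest.raises(InputError):
            generate_genome(spec, seed=1, panel=panel)

    def test_unknown_family_rejected(self):
        with pytest.raises(InputError):
            GenotypeSpec(label="g", ccm_class="alpha", markers=[("nonsense", 1, 0.9)])


def _toy_genomes(panel, lengths=(8_000, 8_000), seed0=50):
    genomes = []
    for i, length in enumerate(lengths):
        spec = GenotypeSpec(
            label=f"t{i}", ccm_class="alpha", markers=[("rbcS", 1, 0.9)],
            genome_length=length,
        )
        g, _ = generate_genome(spec, seed=seed0 + i, panel=panel)
        genomes.append(g)
    return genomes


class TestSimulateMetagenome:
    def test_error_free_reads_are_exact_substrings(self, panel):
        (genome,) = _toy_genomes(panel, lengths=(8_000,))
        community = CommunitySpec(members=[(genome.genome_id, 1.0)], n_reads=200, read_length=100, seed=4)
        read_set = simulate_metagenome(community, [genome])
        sequence = genome.contigs[0][1]
        assert read_set.total_bases == 200 * 100
        for _, seq, source, start in read_set.reads:
            assert source == genome.genome_id
            assert sequence[start : start + 100] == seq

    def test_source_fractions_match_binomial(self, panel):
        """Weights (0.875, 0.125) on equal-length genomes: the fraction of
        reads from genome 1 sits within 3 binomial standard deviations."""
        genomes = _toy_genomes(panel)
        community = CommunitySpec(
            members=[(genomes[0].genome_id, 0.875), (genomes[1].genome_id, 0.125)],
            n_reads=40_000, read_length=100, seed=3,
        )
        read_set = simulate_metagenome(community, genomes)
        frac = np.mean([r[2] == genomes[0].genome_id for r in read_set.reads])
        se = np.sqrt(0.875 * 0.125 / 40_000)
        assert abs(frac - 0.875) <= 3 * se

    def test_weights_are_normalized(self, panel):
        genomes = _toy_genomes(panel)
        community = CommunitySpec(
            members=[(genomes[0].genome_id, 2.0), (genomes[1].genome_id, 2.0)],
            n_reads=10, read_length=100, seed=1,
        )
        assert [w for _, w in community.normalized_weights] == [0.5, 0.5]

    def test_length_weighted_sampling_chi_square(self, panel):
        """Empirical source counts fit weight_i * length_i / sum at alpha=0.01."""
        genomes = _toy_genomes(panel, lengths=(6_000, 12_000), seed0=60)
        weights = np.array([0.7, 0.3])
        lengths = np.array([6_000.0, 12_000.0])
        community = CommunitySpec(
            members=[(genomes[0].genome_id, 0.7), (genomes[1].genome_id, 0.3)],
            n_reads=10_000, read_length=100, seed=9,
        )
        read_set = simulate_metagenome(community, genomes)
        observed = np.array(
            [sum(1 for r in read_set.reads if r[2] == g.genome_id) for g in genomes]
        )
        expected = weights * lengths
        expected = expected / expected.sum() * observed.sum()
        assert chisquare(observed, expected).pvalue > 0.01

    def test_reproducible_given_seed(self, panel):
        genomes = _toy_genomes(panel)
        community = CommunitySpec(
            members=[(g.genome_id, 1.0) for g in genomes], n_reads=50,
            read_length=80, error_rate=0.05, seed=13,
        )
        assert simulate_metagenome(community, genomes).reads == simulate_metagenome(community, genomes).reads

    def test_invalid_inputs_rejected(self, panel):
        genomes = _toy_genomes(panel)
        with pytest.raises(InputError):
            CommunitySpec(members=[("t0", 1.0)], n_reads=0)
        with pytest.raises(InputError):
            CommunitySpec(members=[("t0", 0.0)], n_reads=10)
        community = CommunitySpec(members=[("missing", 1.0)], n_reads=10)
        with pytest.raises(InputError):
            simulate_metagenome(community, genomes)


class TestPaFixture:
    def test_clean_fixture_separates_groups_on_axis_one(self, panel):
        matrix = generate_pa_fixture(5, 5, 0.0, seed=1, panel=panel)
        ordination = pco(kulczynski_binary(matrix))
        axis1 = dict(zip(ordination.labels, ordination.coordinates[:, 0]))
        alpha_scores = [v for k, v in axis1.items() if k.startswith("alpha")]
        beta_scores = [v for k, v in axis1.items() if k.startswith("beta")]
        assert max(alpha_scores) < 0 < min(beta_scores) or max(beta_scores) < 0 < min(alpha_scores)

    def test_single_group_rows_are_identical(self, panel):
        matrix = generate_pa_fixture(3, 0, 0.0, seed=1, panel=panel)
        D = kulczynski_binary(matrix)
        assert np.allclose(D.values, 0.0)

    def test_heavy_noise_still_behaves(self, panel):
        matrix = generate_pa_fixture(5, 5, 0.45, seed=2, panel=panel)
        assert matrix.df.shape == (10, len(panel))
        assert set(np.unique(matrix.df.to_numpy())) <= {0, 1}

    def test_invalid_inputs_rejected(self, panel):
        with pytest.raises(InputError):
            generate_pa_fixture(1, 1, 0.0, seed=1, panel=panel)
        with pytest.raises(InputError):
            generate_pa_fixture(5, 5, 0.5, seed=1, panel=panel)
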