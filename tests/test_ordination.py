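"""Dissimilarities, PCO, nMDS and the Wilcoxon signed-rank test."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import wilcoxon as scipy_wilcoxon

from picoccm.io import InputError
from picoccm.ordination import (
    DissimilarityMatrix,
    axis_gene_association,
    bray_curtis,
    kulczynski_binary,
    nmds,
    pco,
    wilcoxon_signed_rank,
)
from picoccm.synthetic import generate_pa_fixture

from oracles import bray_curtis_oracle, kulczynski_oracle


def _euclidean_dm(points: np.ndarray, labels=None) -> DissimilarityMatrix:
    D = squareform(pdist(points))
    D = D / max(D.max(), 1.0)
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DissimilarityMatrix(labels=labels, values=D, metric_name="euclidean")


class TestKulczynski:
    def test_hand_example(self):
        df = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["x", "y"])
        assert kulczynski_binary(df).values[0, 1] == pytest.approx(0.5)

    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["x", "y"])
        assert kulczynski_binary(df).values[0, 1] == 0.0

    def test_degenerate_rows(self):
        df = pd.DataFrame([[0, 0, 0], [1, 1, 0], [0, 0, 0]], index=["z1", "x", "z2"])
        D = kulczynski_binary(df).values
        assert D[0, 1] == 1.0  # one all-zero row
        assert D[0, 2] == 0.0  # both all-zero

    def test_matches_oracle_on_all_three_feature_vectors(self):
        vectors = list(itertools.product([0, 1], repeat=3))
        df = pd.DataFrame(vectors, index=[f"v{i}" for i in range(8)])
        D = kulczynski_binary(df).values
        for i, j in itertools.combinations(range(8), 2):
            assert D[i, j] == pytest.approx(kulczynski_oracle(vectors[i], vectors[j]))

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            kulczynski_binary(pd.DataFrame([[1, 0]]))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((2, 0), (0, 2), 1.0), ((1, 1), (1, 1), 0.0), ((3, 1), (1, 1), 1 / 3)],
    )
    def test_hand_examples(self, x, y, expected):
        df = pd.DataFrame([x, y], index=["x", "y"])
        assert bray_curtis(df).values[0, 1] == pytest.approx(expected)

    def test_matches_scipy_and_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 20, size=(6, 5)).astype(float)
        D = bray_curtis(pd.DataFrame(X)).values
        for i, j in itertools.combinations(range(6), 2):
            assert D[i, j] == pytest.approx(scipy_braycurtis(X[i], X[j]))
            assert D[i, j] == pytest.approx(bray_curtis_oracle(X[i], X[j]))

    def test_negative_values_rejected(self):
        with pytest.raises(InputError):
            bray_curtis(pd.DataFrame([[1, -1], [0, 1]]))


@given(
    st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
        min_size=2,
        max_size=6,
    )
)
def test_dissimilarities_are_bounded_and_symmetric(rows):
    df = pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))])
    for metric in (kulczynski_binary, bray_curtis):
        D = metric(df).values
        assert np.allclose(D, D.T)
        assert D.min() >= 0.0 and D.max() <= 1.0
        assert np.allclose(np.diag(D), 0.0)


class TestPco:
    def test_two_point_closed_form(self):
        D = DissimilarityMatrix(labels=["a", "b"], values=np.array([[0.0, 0.8], [0.8, 0.0]]), metric_name="d")
        result = pco(D)
        assert sorted(result.coordinates[:, 0]) == pytest.approx([-0.4, 0.4])
        assert result.eigenvalues[0] == pytest.approx(0.8**2 / 2)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(42)
        for n, d in [(3, 2), (8, 3), (10, 4)]:
            X = rng.normal(size=(n, d))
            dm = _euclidean_dm(X)
            result = pco(dm)
            recon = squareform(pdist(result.coordinates))
            assert np.abs(recon - dm.values).max() < 1e-9
            # eigenvalue sum equals total squared centered norm
            Xc = result.coordinates - result.coordinates.mean(axis=0)
            assert result.eigenvalues[result.eigenvalues > 0].sum() == pytest.approx(
                np.sum(Xc**2), rel=1e-9
            )

    def test_matches_skbio_eigenvalues(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 3))
        dm = _euclidean_dm(X)
        ours = pco(dm)
        theirs = pcoa(DistanceMatrix(dm.values, ids=dm.labels))
        assert np.allclose(
            np.sort(theirs.eigvals.values)[::-1][:6], ours.eigenvalues[:6], atol=1e-10
        )

    def test_variance_explained_sums_to_one(self):
        matrix = generate_pa_fixture(4, 4, 0.2, seed=5)
        result = pco(kulczynski_binary(matrix))
        assert result.variance_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(InputError):
            DissimilarityMatrix(labels=["a", "b"], values=np.array([[0.0, 0.5], [0.4, 0.0]]), metric_name="d")


class TestAxisGeneAssociation:
    def test_diagnostic_genes_outrank_shared_genes(self, panel):
        from picoccm.panel import ALPHA_DIAGNOSTIC, SHARED_FAMILIES

        matrix = generate_pa_fixture(5, 5, 0.0, seed=1, panel=panel)
        result = pco(kulczynski_binary(matrix))
        ranking = axis_gene_association(matrix, result, axis=0, top_n=len(panel))
        r_by_gene = dict(zip(ranking["gene"], ranking["r"].abs()))
        worst_diag = min(r_by_gene[g] for g in ALPHA_DIAGNOSTIC)
        best_shared = max(r_by_gene[g] for g in SHARED_FAMILIES)
        assert worst_diag > best_shared

    def test_constant_gene_has_zero_correlation(self, panel):
        matrix = generate_pa_fixture(3, 3, 0.0, seed=1, panel=panel)
        result = pco(kulczynski_binary(matrix))
        ranking = axis_gene_association(matrix, result, axis=0, top_n=len(panel))
        shared_rows = ranking[ranking["gene"] == "bicA"]
        assert shared_rows["r"].iloc[0] == 0.0

    def test_top_n_clamped_to_gene_count(self, panel):
        matrix = generate_pa_fixture(3, 3, 0.0, seed=1, panel=panel)
        result = pco(kulczynski_binary(matrix))
        ranking = axis_gene_association(matrix, result, axis=0, top_n=10_000)
        assert len(ranking) == len(panel)


class TestNmds:
    def test_near_zero_stress_on_euclidean_2d_input(self):
        rng = np.random.default_rng(6)
        dm = _euclidean_dm(rng.normal(size=(9, 2)))
        result = nmds(dm, dims=2, seed=1)
        assert result.stress < 0.01

    def test_fixture_groups_separable_in_two_dims(self, panel):
        matrix = generate_pa_fixture(5, 5, 0.0, seed=1, panel=panel)
        result = nmds(kulczynski_binary(matrix), dims=2, seed=4)
        axis1 = dict(zip(result.labels, result.coordinates[:, 0]))
        alpha = [v for k, v in axis1.items() if k.startswith("alpha")]
        beta = [v for k, v in axis1.items() if k.startswith("beta")]
        assert max(alpha) < min(beta) or max(beta) < min(alpha)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        dm = _euclidean_dm(rng.normal(size=(7, 3)))
        r1 = nmds(dm, seed=11)
        r2 = nmds(dm, seed=11)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_stress_not_worse_than_pco_start(self):
        from picoccm.ordination import _monotone_fit, _stress1

        rng = np.random.default_rng(15)
        dm = _euclidean_dm(rng.normal(size=(8, 4)))  # 4-D cloud into 2-D: nonzero stress
        result = nmds(dm, dims=2, seed=0)
        pco_coords = pco(dm).coordinates[:, :2]
        delta = squareform(dm.values, checks=False)
        order = np.argsort(delta, kind="stable")
        d = pdist(pco_coords)
        pco_stress = _stress1(d, _monotone_fit(d, order))
        assert result.stress <= pco_stress + 1e-12

    def test_configuration_is_centered_and_unit_rms(self):
        rng = np.random.default_rng(8)
        dm = _euclidean_dm(rng.normal(size=(6, 2)))
        result = nmds(dm, seed=5)
        X = result.coordinates
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-9)
        assert np.sqrt(np.mean(np.sum(X**2, axis=1))) == pytest.approx(1.0)


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        result = wilcoxon_signed_rank([(1, 0), (2, 0), (3, 0), (4, 0), (5, 0)])
        assert result.method == "exact"
        assert result.W == 0.0
        assert result.p == pytest.approx(2 / 2**5)

    def test_antisymmetry(self):
        pairs = [(3.0, 1.0), (0.5, 2.0), (4.0, 1.0), (2.0, 2.5)]
        fwd = wilcoxon_signed_rank(pairs)
        rev = wilcoxon_signed_rank([(y, x) for x, y in pairs])
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p == pytest.approx(fwd.p)

    def test_all_zero_differences(self):
        result = wilcoxon_signed_rank([(1.0, 1.0)] * 4)
        assert result.n_effective == 0
        assert result.p == 1.0

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            d = rng.normal(size=12)
            ours = wilcoxon_signed_rank([(x, 0.0) for x in d])
            ref = scipy_wilcoxon(d, method="exact")
            assert ours.p == pytest.approx(ref.pvalue)
            assert ours.W == pytest.approx(ref.statistic)

    def test_matches_scipy_normal_with_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0, -2.0, 4.0] * 4)
        ours = wilcoxon_signed_rank([(x, 0.0) for x in d])
        ref = scipy_wilcoxon(d, correction=True, method="approx")
        assert ours.method == "normal"
        assert ours.p == pytest.approx(ref.pvalue)
        plain = wilcoxon_signed_rank([(x, 0.0) for x in d], continuity_correction=False)
        ref_plain = scipy_wilcoxon(d, correction=False, method="approx")
        assert plain.p == pytest.approx(ref_plain.pvalue)

    def test_exact_and_normal_agree_at_boundary(self):
        """|p_exact - p_normal| < 0.01 at n_effective = 25."""
        rng = np.random.default_rng(31)
        for _ in range(5):
            d = rng.normal(size=25)
            exact = wilcoxon_signed_rank([(x, 0.0) for x in d])
            assert exact.method == "exact"
            ref = scipy_wilcoxon(d, correction=True, method="approx")
            assert abs(exact.p - ref.pvalue) < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_signed_rank([])
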