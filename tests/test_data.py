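"""Standardization, BRM, PCs, smoothing and file round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertexlmm import (
    MEAS_TYPES,
    CohortMatrix,
    VertexAtlas,
    compute_brm,
    compute_pcs,
    smooth_graph,
    standardize_columns,
)
from vertexlmm import io as vio
from vertexlmm.simulate import lattice_edges


def _cohort_from(values, covariates=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return CohortMatrix(
        subject_id=[f"S{i}" for i in range(n)],
        values=values,
        covariates=covariates
        if covariates is not None
        else pd.DataFrame(index=range(n)),
    )


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


class TestStandardize:
    def test_closed_form_three_points(self):
        out = standardize_columns(_cohort_from([[1.0], [2.0], [3.0]]))
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-8)
        # population variance (denominator N) is exactly 1
        assert abs(out.values[:, 0].var() - 1.0) < 1e-12

    def test_already_standardized_column_unchanged(self):
        col = np.array([-1.22474487, 0.0, 1.22474487])
        out = standardize_columns(_cohort_from(col[:, None]))
        np.testing.assert_allclose(out.values[:, 0], col, atol=1e-12)

    def test_constant_column_errors_with_vertex_id(self):
        vals = np.random.default_rng(0).normal(size=(10, 3))
        vals[:, 2] = 5.0
        with pytest.raises(ValueError, match="constant vertex.*2"):
            standardize_columns(_cohort_from(vals))

    def test_double_standardization_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="already standardized"):
            standardize_columns(tiny_cohort)

    def test_records_reusable_statistics(self, tiny_raw, tiny_cohort):
        raw, _ = tiny_raw
        back = tiny_cohort.values * tiny_cohort.col_sds + tiny_cohort.col_means
        np.testing.assert_allclose(back, raw.values, atol=1e-10)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_have_zero_mean_unit_variance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(11, 4)) * rng.uniform(0.5, 3.0, size=4) + rng.normal(
            size=4
        )
        out = standardize_columns(_cohort_from(vals))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.var(axis=0), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# BRM
# ---------------------------------------------------------------------------


class TestBRM:
    def test_single_vertex_outer_product(self):
        data = standardize_columns(_cohort_from([[1.0], [2.0], [4.0]]))
        b = compute_brm(data, subset=[0])
        x = data.values[:, 0]
        np.testing.assert_allclose(b.matrix, np.outer(x, x), atol=1e-12)
        assert b.p_used == 1

    def test_hand_multiplied_two_column_example(self):
        data = standardize_columns(_cohort_from([[1, -1], [-1, 1], [0, 0]]))
        b = compute_brm(data)
        expected = np.array([[1.5, -1.5, 0.0], [-1.5, 1.5, 0.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(b.matrix, expected, atol=1e-12)

    def test_mean_diagonal_is_one(self, tiny_cohort):
        b = compute_brm(tiny_cohort)
        assert abs(np.mean(np.diag(b.matrix)) - 1.0) < 1e-10

    def test_positive_semidefinite(self, tiny_cohort):
        b = compute_brm(tiny_cohort)
        vals = np.linalg.eigvalsh(b.matrix)
        assert vals.min() >= -1e-8

    def test_global_is_weighted_average_of_types(self, tiny_cohort, tiny_atlas):
        b_global = compute_brm(tiny_cohort)
        acc = np.zeros_like(b_global.matrix)
        for t in MEAS_TYPES:
            bt = compute_brm(tiny_cohort, subset=t, atlas=tiny_atlas)
            acc += bt.matrix * (bt.p_used / tiny_cohort.n_vertices)
        np.testing.assert_allclose(b_global.matrix, acc, atol=1e-10)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 100))
        perm = rng.permutation(100)
        b1 = compute_brm(standardize_columns(_cohort_from(vals)))
        b2 = compute_brm(standardize_columns(_cohort_from(vals[:, perm])))
        np.testing.assert_allclose(b1.matrix, b2.matrix, atol=1e-10)

    def test_empty_subset_errors(self, tiny_cohort):
        with pytest.raises(ValueError, match="empty"):
            compute_brm(tiny_cohort, subset=[])

    def test_requires_standardized(self, tiny_raw):
        raw, _ = tiny_raw
        with pytest.raises(ValueError, match="standardized"):
            compute_brm(raw)


# ---------------------------------------------------------------------------
# PCs
# ---------------------------------------------------------------------------


class TestPCs:
    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        vvec = np.linspace(1, 2, 6)
        vals = np.outer(u, vvec)
        vals = vals - vals.mean(axis=0)
        vals = vals / vals.std(axis=0)
        data = _cohort_from(vals)
        data.standardized = True
        pcs = compute_pcs(data, 1)
        assert pcs.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_match_gram_eigendecomposition(self):
        rng = np.random.default_rng(11)
        data = standardize_columns(_cohort_from(rng.normal(size=(50, 200))))
        pcs = compute_pcs(data, 5)
        gram = data.values @ data.values.T
        w, u = np.linalg.eigh(gram)
        top = np.sort(w)[::-1][:5]
        np.testing.assert_allclose(
            np.einsum("ij,ij->j", pcs.scores, pcs.scores), top, rtol=1e-8
        )
        # scores are orthogonal and variance_explained is non-increasing
        off = pcs.scores.T @ pcs.scores - np.diag(top)
        assert np.abs(off).max() < 1e-6
        assert np.all(np.diff(pcs.variance_explained) <= 1e-12)

    def test_k_bounds(self, tiny_cohort, tiny_atlas):
        with pytest.raises(ValueError):
            compute_pcs(tiny_cohort, 0)
        with pytest.raises(ValueError, match="exceeds"):
            compute_pcs(tiny_cohort, tiny_cohort.n_subjects)

    def test_per_type_concatenates_blocks(self, tiny_cohort, tiny_atlas):
        pcs = compute_pcs(tiny_cohort, 3, scope="per_type", atlas=tiny_atlas)
        assert pcs.scores.shape == (tiny_cohort.n_subjects, 12)
        assert pcs.loadings.shape == (tiny_cohort.n_vertices, 12)
        # each loading block is confined to its own measurement type
        for i, t in enumerate(MEAS_TYPES):
            ids = tiny_atlas.vertex_ids_of_type(t)
            other = np.setdiff1d(np.arange(tiny_cohort.n_vertices), ids)
            assert np.abs(pcs.loadings[other, 3 * i : 3 * (i + 1)]).max() == 0.0


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class TestSmoothing:
    def test_zero_rounds_is_identity(self, tiny_raw, tiny_atlas):
        raw, _ = tiny_raw
        out = smooth_graph(raw, tiny_atlas, 0)
        assert np.array_equal(out.values, raw.values)

    def test_constant_field_is_preserved(self, tiny_atlas):
        vals = np.full((5, tiny_atlas.n_vertices), 3.25)
        data = _cohort_from(vals, pd.DataFrame(index=range(5)))
        out = smooth_graph(data, tiny_atlas, 4)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_neighbor_correlation_increases(self, tiny_raw, tiny_atlas):
        raw, _ = tiny_raw

        def mean_neighbor_corr(values):
            c = np.corrcoef(values.T)
            e = tiny_atlas.edges
            return np.abs(c[e[:, 0], e[:, 1]]).mean()

        base = mean_neighbor_corr(raw.values)
        smoothed = smooth_graph(raw, tiny_atlas, 3)
        assert mean_neighbor_corr(smoothed.values) > base

    def test_rejects_standardized_input(self, tiny_cohort, tiny_atlas):
        with pytest.raises(ValueError, match="raw"):
            smooth_graph(tiny_cohort, tiny_atlas, 1)


# ---------------------------------------------------------------------------
# atlas structure
# ---------------------------------------------------------------------------


class TestAtlas:
    def test_lattice_edge_count(self):
        # 2x2 lattice: 4 vertices, 4 edges
        assert lattice_edges(2, 2).shape == (4, 2)
        # r x c lattice has r(c-1) + c(r-1) edges
        assert lattice_edges(3, 5).shape == (3 * 4 + 5 * 2, 2)

    def test_validation_rejects_cross_type_edges(self, tiny_atlas):
        bad = VertexAtlas(
            table=tiny_atlas.table.copy(),
            edges=np.array([[0, tiny_atlas.n_vertices - 1]]),
        )
        with pytest.raises(ValueError, match="meas_type"):
            bad.validate()

    def test_every_vertex_has_one_type(self, tiny_atlas):
        counts = sum(
            len(tiny_atlas.vertex_ids_of_type(t)) for t in MEAS_TYPES
        )
        assert counts == tiny_atlas.n_vertices


# ---------------------------------------------------------------------------
# file round trips
# ---------------------------------------------------------------------------


class TestIO:
    def test_h5_round_trip(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.h5"
        vio.write_cohort_h5(tiny_cohort, path)
        back = vio.read_cohort_h5(path)
        np.testing.assert_array_equal(back.values, tiny_cohort.values)
        assert back.subject_id == tiny_cohort.subject_id
        assert back.standardized
        np.testing.assert_array_equal(back.col_means, tiny_cohort.col_means)
        assert list(back.covariates.columns) == list(tiny_cohort.covariates.columns)

    def test_tsv_round_trip(self, tiny_raw, tmp_path):
        raw, _ = tiny_raw
        vpath, cpath = tmp_path / "values.tsv", tmp_path / "covars.tsv"
        vio.write_cohort_tsv(raw, vpath, cpath)
        back = vio.read_cohort_tsv(vpath, cpath)
        np.testing.assert_allclose(back.values, raw.values, atol=1e-12)
        assert back.subject_id == raw.subject_id

    def test_atlas_round_trip(self, tiny_atlas, tmp_path):
        vp, ep = tmp_path / "vertices.tsv", tmp_path / "edges.tsv"
        vio.write_atlas(tiny_atlas, vp, ep)
        back = vio.read_atlas(vp, ep)
        assert back.table.equals(tiny_atlas.table)
        np.testing.assert_array_equal(back.edges, tiny_atlas.edges)

    def test_phenotype_round_trip_with_missing(self, tmp_path):
        path = tmp_path / "trait.phen"
        y = np.array([0.5, np.nan, -1.25])
        vio.write_phenotype(y, ["A", "B", "C"], path)
        back = vio.read_phenotype(path, ["A", "B", "C", "D"])
        np.testing.assert_allclose(back[[0, 2]], y[[0, 2]])
        assert np.isnan(back[1]) and np.isnan(back[3])
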