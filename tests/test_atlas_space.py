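"""Developmental-space construction: readers, binarization, coordinate grid."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dprule.atlas_space import (
    ExpressionAtlas,
    assign_coordinates,
    binarize_activity,
    build_developmental_matrix,
    read_atlas,
    stage_profile,
)
from conftest import write_atlas_files


def make_atlas(counts, cell_types, times):
    counts = sp.csr_matrix(np.asarray(counts))
    return ExpressionAtlas(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        gene_ids=[f"g{j}" for j in range(counts.shape[1])],
        cell_type=np.asarray(cell_types, dtype=object),
        embryo_time=np.asarray(times, dtype=float),
    )


class TestReadAtlas:
    def test_roundtrip_shape_and_ids(self, tmp_path):
        paths = write_atlas_files(
            tmp_path,
            [[0, 3], [1, 0], [2, 2]],
            [("c1", "neuron", 50.0), ("c2", "muscle", 150.0), ("c3", "neuron", 250.0)],
            ["gA", "gB"],
        )
        atlas = read_atlas(*paths)
        assert (atlas.n_cells, atlas.n_genes) == (3, 2)
        assert atlas.gene_ids == ["gA", "gB"]
        assert atlas.counts.toarray().tolist() == [[0, 3], [1, 0], [2, 2]]
        assert atlas.annotated.all()

    def test_dimension_mismatch_names_files(self, tmp_path):
        matrix, cells, genes = write_atlas_files(
            tmp_path,
            [[0, 3], [1, 0], [2, 2]],
            [("c1", "a", 1), ("c2", "a", 1), ("c3", "a", 1), ("c4", "a", 1)],
            ["gA", "gB"],
        )
        with pytest.raises(ValueError, match="dimension mismatch") as err:
            read_atlas(matrix, cells, genes)
        for path in (matrix, cells, genes):
            assert str(path) in str(err.value)

    def test_negative_count_rejected(self, tmp_path):
        matrix, cells, genes = write_atlas_files(
            tmp_path, [[0, -1], [1, 0]], [("c1", "a", 1), ("c2", "a", 2)], ["gA", "gB"]
        )
        with pytest.raises(ValueError, match="negative"):
            read_atlas(matrix, cells, genes)

    def test_unparseable_time_reports_row(self, tmp_path):
        matrix, cells, genes = write_atlas_files(
            tmp_path, [[1], [1]], [("c1", "a", 10.0), ("c2", "a", "tenish")], ["gA"]
        )
        with pytest.raises(ValueError, match="row 3"):
            read_atlas(matrix, cells, genes)

    def test_missing_annotations_kept_but_flagged(self, tmp_path):
        matrix, cells, genes = write_atlas_files(
            tmp_path, [[1], [2]], [("c1", "", 10.0), ("c2", "a", "")], ["gA"]
        )
        atlas = read_atlas(matrix, cells, genes)
        assert atlas.n_cells == 2
        assert not atlas.annotated.any()


class TestBinarize:
    @pytest.mark.parametrize(
        "counts,min_count,expected",
        [
            ([[0, 3], [1, 0]], 1, [[0, 1], [1, 0]]),
            ([[0, 0], [0, 0]], 1, [[0, 0], [0, 0]]),
            ([[2]], 3, [[0]]),
        ],
    )
    def test_thresholding(self, counts, min_count, expected):
        out = binarize_activity(sp.csr_matrix(np.array(counts)), min_count)
        assert out.toarray().tolist() == expected

    def test_min_count_must_be_positive(self):
        with pytest.raises(ValueError):
            binarize_activity(sp.csr_matrix(np.eye(2)), 0)

    @given(
        counts=hnp.arrays(np.int64, (4, 3), elements=st.integers(0, 5)),
        low=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, counts, low):
        a = binarize_activity(sp.csr_matrix(counts), low).toarray()
        b = binarize_activity(sp.csr_matrix(counts), low + 1).toarray()
        assert (b <= a).all()


class TestAssignCoordinates:
    edges = [0.0, 100.0, 200.0, 300.0]

    def test_half_open_binning(self):
        atlas = make_atlas([[1], [1]], ["a", "a"], [150.0, 100.0])
        coords = assign_coordinates(atlas, self.edges)
        assert coords.stage.tolist() == [1, 1]  # 100 belongs to [100, 200)

    def test_missing_type_gives_null_coordinate(self):
        atlas = make_atlas([[1], [1]], [None, "a"], [50.0, 50.0])
        coords = assign_coordinates(atlas, self.edges)
        assert coords.stage[0] == -1 and coords.stage[1] == 0
        assert coords.valid.tolist() == [False, True]

    def test_out_of_range_clamped_with_counts(self):
        atlas = make_atlas([[1], [1], [1]], ["a", "a", "a"], [-5.0, 300.0, 150.0])
        coords = assign_coordinates(atlas, self.edges)
        assert coords.stage.tolist() == [0, 2, 1]
        assert (coords.n_below, coords.n_above) == (1, 1)

    def test_edges_must_increase(self):
        atlas = make_atlas([[1]], ["a"], [1.0])
        with pytest.raises(ValueError):
            assign_coordinates(atlas, [0.0, 0.0, 10.0])


class TestBuildDevelopmentalMatrix:
    def test_direct_fraction(self):
        # 4 cells at one coordinate, gene active in 3 -> 0.75
        atlas = make_atlas([[1], [1], [1], [0]], ["a"] * 4, [10.0] * 4)
        coords = assign_coordinates(atlas, [0.0, 100.0])
        dev = build_developmental_matrix(binarize_activity(atlas), coords)
        assert dev.values.tolist() == [[0.75]]

    def test_always_active_gene_row_of_ones(self):
        counts = np.ones((6, 2), dtype=int)
        counts[:, 1] = [1, 0, 1, 0, 1, 0]
        atlas = make_atlas(counts, ["a", "a", "b", "b", "a", "b"], [10, 10, 10, 150, 150, 150])
        coords = assign_coordinates(atlas, [0.0, 100.0, 200.0])
        dev = build_developmental_matrix(binarize_activity(atlas), coords)
        assert np.allclose(dev.values[0], 1.0)

    def test_matches_bruteforce_tallies(self, rng):
        n_cells, n_genes = 200, 50
        active = sp.csr_matrix((rng.random((n_cells, n_genes)) < 0.3).astype(np.int8))
        types = rng.choice(["a", "b", "c"], size=n_cells)
        times = rng.uniform(0, 300, size=n_cells)
        atlas = make_atlas(active.toarray(), types, times)
        coords = assign_coordinates(atlas, [0.0, 100.0, 200.0, 300.0])
        dev = build_developmental_matrix(active, coords)
        dense = active.toarray()
        for j, (ct, s) in enumerate(dev.coordinates):
            members = [
                i for i in range(n_cells)
                if types[i] == ct and coords.stage[i] == s
            ]
            expected = dense[members].sum(axis=0) / len(members)
            assert np.allclose(dev.values[:, j], expected)
            assert dev.n_cells_per_coordinate[j] == len(members)

    def test_invariant_under_cell_permutation(self, rng):
        n_cells, n_genes = 80, 10
        active = (rng.random((n_cells, n_genes)) < 0.4).astype(np.int8)
        types = rng.choice(["a", "b"], size=n_cells)
        times = rng.uniform(0, 200, size=n_cells)
        perm = rng.permutation(n_cells)
        dev1 = build_developmental_matrix(
            sp.csr_matrix(active),
            assign_coordinates(make_atlas(active, types, times), [0, 100, 200]),
        )
        dev2 = build_developmental_matrix(
            sp.csr_matrix(active[perm]),
            assign_coordinates(make_atlas(active[perm], types[perm], times[perm]), [0, 100, 200]),
        )
        assert dev1.coordinates == dev2.coordinates
        assert np.allclose(dev1.values, dev2.values)

    def test_min_cells_filter_and_fatal(self):
        atlas = make_atlas([[1], [1], [1]], ["a", "a", "b"], [10, 10, 10])
        coords = assign_coordinates(atlas, [0.0, 100.0])
        dev = build_developmental_matrix(binarize_activity(atlas), coords, min_cells=2)
        assert dev.coordinates == [("a", 0)]
        with pytest.raises(ValueError, match="min_cells=5"):
            build_developmental_matrix(binarize_activity(atlas), coords, min_cells=5)

    def test_deterministic_column_order(self):
        atlas = make_atlas(
            np.ones((4, 1), dtype=int), ["b", "a", "b", "a"], [150, 150, 10, 10]
        )
        coords = assign_coordinates(atlas, [0.0, 100.0, 200.0])
        dev = build_developmental_matrix(binarize_activity(atlas), coords)
        assert dev.coordinates == [("a", 0), ("a", 1), ("b", 0), ("b", 1)]


class TestStageProfile:
    def build(self, active, types, times, edges):
        atlas = make_atlas(active, types, times)
        coords = assign_coordinates(atlas, edges)
        return build_developmental_matrix(binarize_activity(atlas), coords)

    def test_fraction_of_types(self):
        # gene active in 2 of 4 cell types present at one stage
        active = np.array([[1], [1], [0], [0]])
        dev = self.build(active, ["a", "b", "c", "d"], [10] * 4, [0.0, 100.0])
        prof = stage_profile(dev)
        assert prof.values.tolist() == [[0.5]]

    def test_silent_gene_all_zero(self):
        active = np.array([[0, 1], [0, 1]])
        dev = self.build(active, ["a", "b"], [10, 10], [0.0, 100.0])
        assert (stage_profile(dev).values[0] == 0).all()

    def test_matches_per_stage_hand_tally(self, rng):
        n_cells, n_genes = 90, 8
        active = (rng.random((n_cells, n_genes)) < 0.5).astype(np.int8)
        types = rng.choice(["a", "b", "c"], size=n_cells)
        times = rng.uniform(0, 300, size=n_cells)
        dev = self.build(active, types, times, [0, 100, 200, 300])
        prof = stage_profile(dev)
        for s in dev.stages:
            cols = [(i, t) for i, (t, st_) in enumerate(dev.coordinates) if st_ == s]
            for g in range(n_genes):
                expect = sum(dev.values[g, i] > 0 for i, _ in cols) / len(cols)
                assert prof.loc[dev.gene_ids[g], s] == pytest.approx(expect)
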