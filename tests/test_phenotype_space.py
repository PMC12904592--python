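"""Ontology parsing, ancestor closure, NMF factorization, pleiotropy sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dprule.phenotype_space import (
    NMFModel,
    Ontology,
    ancestor_closure,
    annotate_component,
    factorize,
    pleiotropy_scores,
    read_ontology,
)


def write_obo(tmp_path, stanzas: str):
    path = tmp_path / "test.obo"
    path.write_text("format-version: 1.2\nontology: test\n\n" + stanzas)
    return path


class TestReadOntology:
    def test_chain_roots(self, tmp_path):
        path = write_obo(
            tmp_path,
            "[Term]\nid: T:A\nname: a\nis_a: T:B\n\n"
            "[Term]\nid: T:B\nname: b\nis_a: T:C\n\n"
            "[Term]\nid: T:C\nname: c\n\n",
        )
        onto = read_ontology(path)
        assert onto.roots == frozenset({"T:C"})
        assert onto.ancestors("T:A") == frozenset({"T:B", "T:C"})

    def test_obsolete_terms_excluded(self, tmp_path):
        path = write_obo(
            tmp_path,
            "[Term]\nid: T:A\nname: a\n\n"
            "[Term]\nid: T:OLD\nname: old\nis_obsolete: true\n\n",
        )
        onto = read_ontology(path)
        assert "T:OLD" not in onto.term_ids and "T:A" in onto.term_ids

    def test_cycle_is_fatal(self, tmp_path):
        path = write_obo(
            tmp_path,
            "[Term]\nid: T:A\nname: a\nis_a: T:B\n\n"
            "[Term]\nid: T:B\nname: b\nis_a: T:A\n\n",
        )
        with pytest.raises(ValueError, match="cycle"):
            read_ontology(path)

    def test_missing_parent_is_fatal(self):
        with pytest.raises(ValueError, match="unknown parent"):
            Ontology.from_parents({"T:A": {"T:GONE"}})


def random_dag(rng, n_terms=20):
    """Random DAG where each term may have parents among earlier terms."""
    terms = [f"T:{i:02d}" for i in range(n_terms)]
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = rng.integers(0, min(3, i) + 1)
        parents[terms[i]] = set(rng.choice(terms[:i], size=k, replace=False))
    return Ontology.from_parents(parents)


def bfs_ancestors(onto, term):
    seen, frontier = set(), [term]
    while frontier:
        t = frontier.pop()
        for p in onto.parents[t]:
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return seen


class TestAncestorClosure:
    def chain(self):
        return Ontology.from_parents({"L": {"M"}, "M": {"R"}, "R": set()})

    def test_chain_propagation(self):
        direct = pd.DataFrame([[1, 0, 0]], index=["g1"], columns=["L", "M", "R"])
        closed = ancestor_closure(self.chain(), direct)
        assert closed.frame.loc["g1"].tolist() == [1, 1, 1]

    def test_root_annotation_is_fixed_point(self):
        direct = pd.DataFrame([[0, 0, 1]], index=["g1"], columns=["L", "M", "R"])
        closed = ancestor_closure(self.chain(), direct)
        assert closed.frame.loc["g1", "R"] == 1
        assert closed.frame.loc["g1"].sum() == 1

    def test_matches_graph_reachability_oracle(self, rng):
        onto = random_dag(rng)
        genes = [f"g{i}" for i in range(5)]
        direct = pd.DataFrame(
            (rng.random((5, len(onto.term_ids))) < 0.15).astype(int),
            index=genes, columns=onto.term_ids,
        )
        direct.iloc[:, 0] = 1  # avoid empty rows being dropped
        closed = ancestor_closure(onto, direct)
        for g in genes:
            expect = set()
            for t in onto.term_ids:
                if direct.loc[g, t]:
                    expect.add(t)
                    expect |= bfs_ancestors(onto, t)
            got = {t for t in onto.term_ids if closed.frame.loc[g, t]}
            assert got == expect

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        onto = random_dag(rng, n_terms=12)
        direct = pd.DataFrame(
            (rng.random((4, len(onto.term_ids))) < 0.2).astype(int),
            index=[f"g{i}" for i in range(4)], columns=onto.term_ids,
        )
        direct.iloc[:, 0] = 1
        once = ancestor_closure(onto, direct)
        twice = ancestor_closure(onto, once.frame)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_unknown_terms_dropped_with_warning(self, caplog):
        direct = pd.DataFrame([[1, 1]], index=["g1"], columns=["L", "T:NOPE"])
        with caplog.at_level("WARNING"):
            closed = ancestor_closure(self.chain(), direct)
        assert "unknown term" in caplog.text
        assert "T:NOPE" not in closed.frame.columns


def annotation_from(matrix, genes, terms):
    from dprule.phenotype_space import PhenotypeAnnotation

    return PhenotypeAnnotation(
        frame=pd.DataFrame(np.asarray(matrix, dtype=np.uint8), index=genes, columns=terms)
    )


class TestFactorize:
    def rank1(self):
        u = np.array([1, 1, 0, 1, 0, 1])
        v = np.array([0, 1, 1, 1])
        V = np.outer(u, v)
        return annotation_from(V, [f"g{i}" for i in range(6)], [f"t{j}" for j in range(4)])

    def test_exact_rank1_recovery(self):
        model = factorize(self.rank1(), k=1, seed=0, min_term_genes=1)
        assert model.reconstruction_error < 1e-6
        assert (model.W.values >= 0).all() and (model.H.values >= 0).all()

    def test_error_monotone_in_k(self):
        ann = self.rank1()
        e1 = factorize(ann, k=1, seed=0, min_term_genes=1).reconstruction_error
        e2 = factorize(ann, k=2, seed=0, min_term_genes=1).reconstruction_error
        assert e2 <= e1 + 1e-9

    def test_block_diagonal_recovery(self, rng):
        # two disjoint blocks of genes x terms; each component's H row should
        # concentrate >= 95% of its mass on a single block's terms
        blockA = (rng.random((15, 6)) < 0.9).astype(int)
        blockB = (rng.random((12, 5)) < 0.9).astype(int)
        V = np.zeros((27, 11), dtype=int)
        V[:15, :6] = blockA
        V[15:, 6:] = blockB
        ann = annotation_from(V, [f"g{i}" for i in range(27)], [f"t{j}" for j in range(11)])
        model = factorize(ann, k=2, seed=0, min_term_genes=1)
        for _, row in model.H.iterrows():
            total = row.values.sum()
            share_a = row.values[:6].sum() / total
            assert max(share_a, 1 - share_a) >= 0.95

    def test_reconstruction_error_recomputable(self):
        ann = self.rank1()
        model = factorize(ann, k=2, seed=3, min_term_genes=1)
        # compare on the pruned matrix the model was actually fitted to
        V = ann.frame.loc[model.gene_ids, model.term_ids].values.astype(float)
        recomputed = float(np.linalg.norm(V - model.W.values @ model.H.values))
        assert model.reconstruction_error == pytest.approx(recomputed, abs=1e-9)

    def test_k_out_of_bounds(self):
        with pytest.raises(ValueError, match="k="):
            factorize(self.rank1(), k=10, seed=0, min_term_genes=1)

    def test_deterministic_given_seed(self):
        ann = self.rank1()
        m1 = factorize(ann, k=2, seed=7, min_term_genes=1)
        m2 = factorize(ann, k=2, seed=7, min_term_genes=1)
        assert np.array_equal(m1.W.values, m2.W.values)
        assert np.array_equal(m1.H.values, m2.H.values)

    def test_rare_term_filter(self):
        V = np.array([[1, 1], [1, 0], [1, 0]])
        ann = annotation_from(V, ["g0", "g1", "g2"], ["common", "rare"])
        model = factorize(ann, k=1, seed=0, min_term_genes=2)
        assert list(model.H.columns) == ["common"]


def model_from(W, genes):
    W = pd.DataFrame(W, index=genes, columns=[f"c{i}" for i in range(np.shape(W)[1])])
    H = pd.DataFrame(
        np.ones((W.shape[1], 3)), index=W.columns, columns=["t0", "t1", "t2"]
    )
    return NMFModel(W=W, H=H, k=W.shape[1], seed=0, n_restarts=1, reconstruction_error=0.0)


class TestPleiotropy:
    def test_zero_row_scores_zero(self):
        model = model_from([[0.0, 0.0], [1.0, 2.0]], ["g0", "g1"])
        res = pleiotropy_scores(model)
        assert res.scores["g0"] == 0.0 and res.scores["g1"] == 3.0

    def test_degenerate_ties_give_empty_sets(self):
        model = model_from(np.eye(3), ["g0", "g1", "g2"])
        res = pleiotropy_scores(model, 95, 5)
        assert res.pleiotropic == [] and res.non_pleiotropic == []

    def test_percentile_sets_match_sorting_oracle(self):
        scores = np.arange(1, 101, dtype=float)
        model = model_from(scores[:, None], [f"g{i:03d}" for i in range(100)])
        res = pleiotropy_scores(model, 95, 5)
        assert sorted(res.pleiotropic) == [f"g{i:03d}" for i in range(95, 100)]  # scores 96..100
        assert sorted(res.non_pleiotropic) == [f"g{i:03d}" for i in range(4)]  # scores 1..4

    def test_score_invariant_to_term_order_and_equals_row_sums(self, rng):
        W = rng.random((20, 5))
        genes = [f"g{i}" for i in range(20)]
        res1 = pleiotropy_scores(model_from(W, genes))
        res2 = pleiotropy_scores(model_from(W[:, ::-1], genes))
        naive = [sum(row) for row in W]
        assert np.allclose(res1.scores.values, naive)
        assert np.allclose(res1.scores.values, res2.scores.values)


class TestAnnotateComponent:
    def test_single_support_ranks_first(self):
        model = model_from([[1.0], [2.0]], ["g0", "g1"])
        model.H.loc["c0"] = [0.0, 5.0, 0.0]
        assert annotate_component(model, 0, top_n=2) == [("t1", 5.0)]

    def test_all_zero_row_degenerate(self, caplog):
        model = model_from([[1.0], [2.0]], ["g0", "g1"])
        model.H.loc["c0"] = 0.0
        with caplog.at_level("WARNING"):
            assert annotate_component(model, 0) == []
        assert "all-zero" in caplog.text

    def test_ordering_matches_sort_oracle(self, rng):
        model = model_from(rng.random((4, 1)), [f"g{i}" for i in range(4)])
        weights = rng.random(3)
        model.H.loc["c0"] = weights
        got = annotate_component(model, 0, top_n=3)
        expect = sorted(zip(["t0", "t1", "t2"], weights), key=lambda tw: (-tw[1], tw[0]))
        assert [t for t, _ in got] == [t for t, _ in expect]
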