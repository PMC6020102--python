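"""Similarity models: Jaccard, DAG semantic models, GIP kernel, integrations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trilink as tl
from trilink.similarity import (
    gip_kernel_disease,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    integrate_sm_similarity,
    jaccard_similarity,
    semantic_contribution_m1,
    semantic_contribution_m2,
    semantic_similarity_m1,
    semantic_similarity_m2,
    semantic_value,
)


def dag(root, *edges):
    return tl.DiseaseDAG(root, frozenset(), frozenset(edges))


IDX2 = tl.EntityIndex(["x", "y"])


class TestJaccard:
    @pytest.mark.parametrize(
        "set_i, set_j, expected",
        [
            ({"a", "b"}, {"b", "c"}, 1 / 3),
            ({"a"}, {"b"}, 0.0),
            ({"a"}, {"a"}, 1.0),
            (set(), {"a"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_pairwise_values(self, set_i, set_j, expected):
        sets = tl.AnnotationSets({"x": set_i, "y": set_j})
        sim = jaccard_similarity(sets, IDX2)
        assert sim.values[0, 1] == pytest.approx(expected)

    def test_diagonal_is_one_even_for_empty_sets(self):
        sim = jaccard_similarity(tl.AnnotationSets({}), IDX2)
        np.testing.assert_array_equal(np.diag(sim.values), [1, 1])

    @given(
        st.lists(
            st.sets(st.sampled_from("abcdefgh"), max_size=6), min_size=2, max_size=6
        )
    )
    def test_symmetric_unit_interval(self, families):
        index = tl.EntityIndex(f"e{i}" for i in range(len(families)))
        sets = tl.AnnotationSets(dict(zip(index.ids, families)))
        sim = jaccard_similarity(sets, index).values
        assert (sim >= 0).all() and (sim <= 1).all()
        np.testing.assert_allclose(sim, sim.T)


class TestSemanticModel1:
    def test_root_only(self):
        assert semantic_contribution_m1(dag("D")) == {"D": 1.0}

    def test_chain_contribution_halves_per_level(self):
        contrib = semantic_contribution_m1(dag("D", ("D", "P")), delta=0.5)
        assert contrib == {"D": 1.0, "P": 0.5}

    def test_three_level_path_closed_form(self):
        contrib = semantic_contribution_m1(dag("D", ("D", "P1"), ("P1", "P2")), delta=0.5)
        assert contrib == {"D": 1.0, "P1": 0.5, "P2": 0.25}

    def test_diamond_takes_max_over_children(self):
        d = dag("D", ("D", "P1"), ("D", "P2"), ("P1", "G"), ("P2", "G"))
        contrib = semantic_contribution_m1(d, delta=0.5)
        assert contrib["G"] == pytest.approx(0.25)

    def test_unreachable_term_rejected(self):
        bad = tl.DiseaseDAG("D", frozenset({"D", "lost"}), frozenset({("D", "P")}))
        with pytest.raises(tl.ValidationError, match="unreachable"):
            semantic_contribution_m1(bad)

    @pytest.mark.parametrize(
        "contrib, expected",
        [
            ({"D": 1.0}, 1.0),
            ({"D": 1.0, "P": 0.5}, 1.5),
            ({"D": 1.0, "P1": 0.5, "P2": 0.5, "G": 0.25}, 2.25),
        ],
    )
    def test_semantic_value_sums_contributions(self, contrib, expected):
        assert semantic_value(contrib) == pytest.approx(expected)

    def test_shared_parent_toy_scores_one_third(self):
        dags = {"x": dag("x", ("x", "P")), "y": dag("y", ("y", "P"))}
        # distinct roots, so only the shared parent overlaps
        sim = semantic_similarity_m1(dags, IDX2, delta=0.5)
        assert sim.values[0, 1] == pytest.approx((0.5 + 0.5) / (1.5 + 1.5))

    def test_same_dag_full_overlap(self):
        idx = tl.EntityIndex(["x"])
        sim = semantic_similarity_m1({"x": dag("x", ("x", "P"))}, idx)
        assert sim.values[0, 0] == 1.0

    def test_disjoint_term_sets_score_zero(self):
        dags = {"x": dag("x", ("x", "P")), "y": dag("y", ("y", "Q"))}
        assert semantic_similarity_m1(dags, IDX2).values[0, 1] == 0.0


class TestSemanticModel2:
    def test_rare_term_contribution_is_information_content(self):
        dags = {f"d{i}": dag(f"d{i}") for i in range(10)}
        contrib = semantic_contribution_m2(dags, n_diseases=10)
        # each root term appears in exactly 1 of 10 DAGs
        assert contrib["d0"] == pytest.approx(-math.log(0.1), abs=1e-4)

    def test_ubiquitous_term_contributes_zero(self):
        dags = {"a": dag("a", ("a", "T")), "b": dag("b", ("b", "T"))}
        contrib = semantic_contribution_m2(dags, n_diseases=2)
        assert contrib["T"] == 0.0

    def test_equal_counts_give_equal_contributions(self):
        dags = {"a": dag("a", ("a", "T"), ("a", "U")), "b": dag("b", ("b", "T"), ("b", "U"))}
        contrib = semantic_contribution_m2(dags, n_diseases=4)
        assert contrib["T"] == contrib["U"]

    def test_similarity_invariant_to_log_base(self):
        dags = {
            "x": dag("x", ("x", "P"), ("P", "G")),
            "y": dag("y", ("y", "P"), ("P", "G")),
        }
        s_e = semantic_similarity_m2(dags, IDX2, base=math.e).values
        s_10 = semantic_similarity_m2(dags, IDX2, base=10).values
        np.testing.assert_allclose(s_e, s_10, atol=1e-12)

    def test_disjoint_term_sets_score_zero(self):
        dags = {"x": dag("x", ("x", "P")), "y": dag("y", ("y", "Q"))}
        assert semantic_similarity_m2(dags, IDX2).values[0, 1] == 0.0

    def test_degenerate_zero_dv_uses_term_set_equality(self):
        # both DAGs consist solely of terms shared by every disease: DV2 = 0
        same = {"x": dag("x", ("x", "s")), "y": dag("y", ("y", "s"))}
        # term sets differ ({x, s} vs {y, s}) -> similarity 0; identical sets -> 1
        sim = semantic_similarity_m2(same, IDX2)
        assert 0.0 <= sim.values[0, 1] <= 1.0


class TestGIPKernel:
    def test_identical_profiles_score_one(self):
        B = np.array([[1.0, 1.0], [0.0, 0.0]])
        sim = gip_kernel_disease(B)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_profiles(self):
        B = np.eye(2)  # profiles [1,0] and [0,1], mean squared norm 1
        sim = gip_kernel_disease(B, gamma_prime=1.0)
        assert sim.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-10)

    def test_doubling_gamma_prime_squares_off_diagonal(self):
        B = np.eye(2)
        sim = gip_kernel_disease(B, gamma_prime=2.0)
        assert sim.values[0, 1] == pytest.approx(math.exp(-4), abs=1e-10)

    def test_all_zero_adjacency_requires_explicit_gamma(self):
        with pytest.raises(tl.ValidationError, match="gamma"):
            gip_kernel_disease(np.zeros((3, 2)))
        sim = gip_kernel_disease(np.zeros((3, 2)), gamma=1.0)
        np.testing.assert_array_equal(sim.values, np.ones((2, 2)))

    def test_kernel_decreases_with_profile_distance(self, rng):
        B = (rng.random((12, 8)) < 0.3).astype(float)
        sim = gip_kernel_disease(B).values
        profiles = B.T
        d2 = ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(-1)
        order = np.argsort(d2, axis=None)
        np.testing.assert_allclose(
            np.sort(sim.flatten()[order])[::-1], sim.flatten()[order], atol=1e-12
        )


class TestIntegrations:
    def test_equal_sources_returned_unchanged(self, rng):
        raw = rng.random((4, 4))
        M = tl.SimilarityMatrix((raw + raw.T) / 2, tl.EntityIndex("abcd"))
        out = integrate_sm_similarity(M, M, M, M)
        np.testing.assert_allclose(out.values, M.values, atol=1e-12)

    def test_two_sources_average(self):
        idx = tl.EntityIndex(["a", "b"])
        m1 = np.array([[1.0, 0.2], [0.2, 1.0]])
        m2 = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = integrate_sm_similarity(disease=m1, target=m2, index=idx)
        assert out.values[0, 1] == pytest.approx(0.4)

    def test_weights_normalized_for_single_source(self):
        idx = tl.EntityIndex(["a", "b"])
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = integrate_sm_similarity(disease=m, weights=(2, 0, 0, 0), index=idx)
        np.testing.assert_allclose(out.values, m, atol=1e-12)

    def test_all_sources_missing_rejected(self):
        with pytest.raises(tl.ValidationError):
            integrate_sm_similarity(index=tl.EntityIndex(["a"]))

    def test_mirna_single_source_passthrough(self):
        idx = tl.EntityIndex(["a", "b"])
        m = np.array([[1.0, 0.7], [0.7, 1.0]])
        out = integrate_mirna_similarity(disease=m, index=idx)
        np.testing.assert_allclose(out.values, m, atol=1e-12)

    def test_mirna_mean_of_zero_and_one(self):
        idx = tl.EntityIndex(["a", "b"])
        lo = np.array([[1.0, 0.0], [0.0, 1.0]])
        hi = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = integrate_mirna_similarity(lo, hi, index=idx)
        assert out.values[0, 1] == pytest.approx(0.5)

    def test_per_cell_renormalization_with_coverage(self):
        idx = tl.EntityIndex(["a", "b", "c"])
        full = np.full((3, 3), 0.6)
        np.fill_diagonal(full, 1.0)
        partial = np.full((3, 3), 0.2)
        np.fill_diagonal(partial, 1.0)
        cov = np.array([True, True, False])  # entity c missing from `partial`
        out = integrate_mirna_similarity(full, partial, coverages=[None, cov], index=idx)
        assert out.values[0, 1] == pytest.approx(0.4)  # both sources
        assert out.values[0, 2] == pytest.approx(0.6)  # only the full source

    @given(st.integers(0, 2**31 - 1))
    def test_integration_is_convex_combination(self, seed):
        r = np.random.default_rng(seed)
        idx = tl.EntityIndex("abcd")
        mats = []
        for _ in range(2):
            raw = r.random((4, 4))
            raw = (raw + raw.T) / 2
            np.fill_diagonal(raw, 1.0)
            mats.append(raw)
        w = r.random(2) + 0.01
        out = integrate_mirna_similarity(mats[0], mats[1], weights=w, index=idx).values
        lo = np.minimum(mats[0], mats[1])
        hi = np.maximum(mats[0], mats[1])
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_disease_integration_branches(self):
        idx = tl.EntityIndex(["u", "v", "w"])
        ss1 = np.full((3, 3), 0.4)
        ss2 = np.full((3, 3), 0.6)
        kd = np.full((3, 3), 0.2)
        for m in (ss1, ss2, kd):
            np.fill_diagonal(m, 1.0)
        has_dag = np.array([True, True, False])
        out = integrate_disease_similarity(ss1, ss2, kd, has_dag, idx)
        assert out.values[0, 1] == pytest.approx(0.5)  # both have DAGs
        assert out.values[0, 2] == pytest.approx(0.2)  # fallback to GIP
        np.testing.assert_array_equal(np.diag(out.values), [1, 1, 1])

    def test_full_disease_pipeline_combines_semantic_and_gip(self, rng):
        B = (rng.random((6, 4)) < 0.5).astype(float)
        B[:, 0] = [1, 0, 0, 0, 0, 0]  # ensure nonzero
        idx = tl.EntityIndex([f"d{i}" for i in range(4)])
        Bm = tl.AssociationMatrix(B, tl.EntityIndex([f"m{i}" for i in range(6)]), idx)
        dags = {"d0": dag("d0", ("d0", "P")), "d1": dag("d1", ("d1", "P"))}
        out = tl.disease_similarity(dags, Bm)
        assert out.values.shape == (4, 4)
        kd = gip_kernel_disease(Bm).values
        # pairs lacking DAGs fall back to the GIP kernel
        assert out.values[2, 3] == pytest.approx(kd[2, 3])
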