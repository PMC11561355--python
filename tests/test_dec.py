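import itertools
import math

import numpy as np
import pytest

import stygotrace as st
from stygotrace.dec import (
    CladogenesisSpec,
    DECModel,
    DECParams,
    GeographyData,
    RangeStateSpace,
    StratifiedDispersalModel,
    build_anagenetic_Q,
    cladogenesis_distribution,
    read_dispersal_model,
    read_geography,
    write_dispersal_model,
    write_geography,
)
from stygotrace.treeio import Stratification

from oracles import brute_dec


def fs(*labels):
    return frozenset(labels)


class TestStateSpace:
    def test_two_areas_full_enumeration(self, uni2):
        states = st.enumerate_range_states(uni2, 2)
        assert states == [fs(), fs("A"), fs("B"), fs("A", "B")]

    def test_five_areas_counts(self):
        u = st.AreaUniverse()
        assert len(st.enumerate_range_states(u, 5)) == 32
        assert len(st.enumerate_range_states(u, 1)) == 6

    def test_cap_below_one_rejected(self, uni2):
        with pytest.raises(ValueError):
            st.enumerate_range_states(uni2, 0)


class TestAnageneticQ:
    def test_rates_by_hand(self, space2):
        Q = build_anagenetic_Q(DECParams(0.1, 0.05), np.ones((2, 2)), space2)
        iA, iB, iAB = space2.index[1], space2.index[2], space2.index[3]
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iA, 0] == pytest.approx(0.05)
        assert Q[iAB, iA] == pytest.approx(0.05)
        assert Q[iAB, iB] == pytest.approx(0.05)

    def test_forbidden_sink_gets_zero_gain(self, space2):
        m = np.ones((2, 2))
        m[0, 1] = 0.0  # A -> B closed
        Q = build_anagenetic_Q(DECParams(0.1, 0.05), m, space2)
        assert Q[space2.index[1], space2.index[3]] == 0.0

    def test_null_process_is_zero_matrix(self, space2):
        Q = build_anagenetic_Q(DECParams(0.0, 0.0), np.ones((2, 2)), space2)
        assert np.all(Q == 0)

    @pytest.mark.parametrize("n_areas,cap", [(2, 2), (3, 2), (3, 3), (5, 5)])
    def test_rows_sum_to_zero_and_offdiagonals_nonnegative(self, n_areas, cap):
        u = st.AreaUniverse(tuple("ABCDE"[:n_areas]))
        space = RangeStateSpace(u, cap)
        rng = np.random.default_rng(n_areas * 10 + cap)
        m = rng.random((n_areas, n_areas))
        Q = build_anagenetic_Q(DECParams(0.3, 0.2, w=1.7), m, space)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-12
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_w_one_leaves_multipliers_unchanged(self, space2):
        m = np.array([[1.0, 0.4], [0.7, 1.0]])
        Q1 = build_anagenetic_Q(DECParams(0.2, 0.1, w=1.0), m, space2)
        Q2 = build_anagenetic_Q(DECParams(0.2, 0.1), m, space2)
        np.testing.assert_allclose(Q1, Q2)

    def test_w_never_reopens_zero_multipliers(self, space2):
        m = np.array([[1.0, 0.0], [0.5, 1.0]])
        for w in (0.0, 0.5, 2.0):
            Q = build_anagenetic_Q(DECParams(0.2, 0.1, w=w), m, space2)
            assert Q[space2.index[1], space2.index[3]] == 0.0


class TestCladogenesis:
    def test_singleton_pure_sympatry(self, space2):
        d = cladogenesis_distribution(
            fs("A"), CladogenesisSpec("DEC"), DECParams(0.1, 0.05), np.ones((2, 2)), space2
        )
        assert d == {(fs("A"), fs("A")): pytest.approx(1.0)}

    def test_widespread_dec_six_equal_outcomes(self, space2):
        d = cladogenesis_distribution(
            fs("A", "B"),
            CladogenesisSpec("DEC", y=1, s=1, v=1),
            DECParams(0.1, 0.05),
            np.ones((2, 2)),
            space2,
        )
        expected = {
            (fs("A"), fs("B")),
            (fs("B"), fs("A")),
            (fs("A", "B"), fs("A")),
            (fs("A"), fs("A", "B")),
            (fs("A", "B"), fs("B")),
            (fs("B"), fs("A", "B")),
        }
        assert set(d) == expected
        assert all(p == pytest.approx(1 / 6) for p in d.values())

    def test_jump_weight_normalization(self, space2):
        d = cladogenesis_distribution(
            fs("A"),
            CladogenesisSpec("DEC", y=1, s=1, v=1),
            DECParams(0.1, 0.05, j=0.5),
            np.ones((2, 2)),
            space2,
        )
        assert d[(fs("A"), fs("A"))] == pytest.approx(2 / 3)
        assert d[(fs("A"), fs("B"))] == pytest.approx(1 / 3)

    def test_null_ancestor_rejected(self, space2):
        with pytest.raises(ValueError):
            cladogenesis_distribution(
                fs(), CladogenesisSpec("DEC"), DECParams(0.1, 0.05), np.ones((2, 2)), space2
            )

    def test_bayarealike_copies_ancestor(self):
        u = st.AreaUniverse(("A", "B", "C"))
        space = RangeStateSpace(u, 3)
        d = cladogenesis_distribution(
            fs("A", "B"), CladogenesisSpec("BAYAREALIKE"), DECParams(0.1, 0.05),
            np.ones((3, 3)), space,
        )
        assert d == {(fs("A", "B"), fs("A", "B")): pytest.approx(1.0)}

    def test_divalike_has_no_subset_sympatry(self):
        u = st.AreaUniverse(("A", "B", "C"))
        space = RangeStateSpace(u, 3)
        d = cladogenesis_distribution(
            fs("A", "B", "C"), CladogenesisSpec("DIVALIKE"), DECParams(0.1, 0.05),
            np.ones((3, 3)), space,
        )
        for (d1, d2) in d:
            assert d1 | d2 == fs("A", "B", "C") and not (d1 & d2)

    @pytest.mark.parametrize("family", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    def test_distributions_sum_to_one_for_every_ancestor(self, family):
        u = st.AreaUniverse(("A", "B", "C"))
        space = RangeStateSpace(u, 3)
        rng = np.random.default_rng(5)
        m = rng.random((3, 3))
        params = DECParams(0.1, 0.05, j=0.7)
        for mask in space.states[1:]:
            d = cladogenesis_distribution(mask, CladogenesisSpec(family), params, m, space)
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)

    def test_jump_scaled_by_mean_multiplier(self, space2):
        m = np.array([[1.0, 0.2], [1.0, 1.0]])
        d = cladogenesis_distribution(
            fs("A"),
            CladogenesisSpec("DEC", y=1, s=1, v=1, jump_scaled_by_multiplier=True),
            DECParams(0.1, 0.05, j=1.0),
            m,
            space2,
        )
        # jump weight 1 * 0.2 against sympatry weight 1
        assert d[(fs("A"), fs("B"))] == pytest.approx(0.2 / 1.2)


class TestLikelihood:
    def test_cherry_matches_brute_force(self, cherry, uni2):
        geog = GeographyData.from_sets(uni2, {"x": {"A"}, "y": {"A"}})
        disp = StratifiedDispersalModel.uniform(uni2)
        spec = CladogenesisSpec("DEC")
        params = DECParams(0.1, 0.05)
        ll = st.dec_loglik(cherry, geog, params, disp, spec)
        expected, _ = brute_dec(cherry, geog, params, disp, spec)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_plus_j_at_zero_equals_pure_dec(self, balanced4, uni2):
        geog = GeographyData.from_sets(
            uni2, {"a": {"A"}, "b": {"B"}, "c": {"A", "B"}, "d": {"B"}}
        )
        disp = StratifiedDispersalModel.uniform(uni2)
        ll0 = st.dec_loglik(balanced4, geog, DECParams(0.2, 0.1, j=0.0), disp,
                            CladogenesisSpec("DEC"))
        ll1 = st.dec_loglik(balanced4, geog, DECParams(0.2, 0.1), disp,
                            CladogenesisSpec("DEC"))
        assert ll0 == pytest.approx(ll1, abs=1e-10)

    def test_frozen_process_with_singleton_cap_is_impossible(self, cherry, uni2):
        geog = GeographyData.from_sets(uni2, {"x": {"A"}, "y": {"B"}})
        ll = st.dec_loglik(cherry, geog, DECParams(0.0, 0.0),
                           StratifiedDispersalModel.uniform(uni2),
                           CladogenesisSpec("DEC"), max_range_size=1)
        assert ll == -math.inf

    def test_frozen_process_with_widespread_root_uses_vicariance(self, cherry, uni2):
        # a widespread root can still split {A,B} -> {A}|{B} cladogenetically
        geog = GeographyData.from_sets(uni2, {"x": {"A"}, "y": {"B"}})
        ll = st.dec_loglik(cherry, geog, DECParams(0.0, 0.0),
                           StratifiedDispersalModel.uniform(uni2),
                           CladogenesisSpec("DEC"))
        assert ll == pytest.approx(math.log(1 / 18), abs=1e-10)

    def test_oversized_tip_range_rejected(self, cherry, uni3):
        geog = GeographyData.from_sets(uni3, {"x": {"A", "B", "C"}, "y": {"A"}})
        with pytest.raises(ValueError, match="max_range_size"):
            st.dec_loglik(cherry, geog, DECParams(0.1, 0.05),
                          StratifiedDispersalModel.uniform(uni3),
                          CladogenesisSpec("DEC"), max_range_size=2)

    def test_stratified_with_identical_matrices_equals_unstratified(self):
        tree, _ = st.simulate_bd_tree(1.0, 0.0, 12, seed=11)
        u = st.AreaUniverse(("A", "B", "C"))
        rng = np.random.default_rng(0)
        m = rng.random((3, 3))
        geog, _ = st.simulate_dec_tips(
            tree, DECParams(0.3, 0.1), StratifiedDispersalModel(u, [m]),
            CladogenesisSpec("DEC"), {"A"}, seed=5,
        )
        strat = Stratification((tree.root_age * 0.7, tree.root_age * 0.3))
        layered = StratifiedDispersalModel(u, [m, m, m], strat)
        flat = StratifiedDispersalModel(u, [m])
        params = DECParams(0.25, 0.12, j=0.4)
        spec = CladogenesisSpec("DEC")
        assert st.dec_loglik(tree, geog, params, layered, spec) == pytest.approx(
            st.dec_loglik(tree, geog, params, flat, spec), abs=1e-10
        )

    def test_likelihood_continuous_in_w_on_positive_multipliers(self):
        tree, _ = st.simulate_bd_tree(1.0, 0.0, 8, seed=2)
        u = st.AreaUniverse(("A", "B"))
        m = np.array([[1.0, 0.35], [0.6, 1.0]])
        disp = StratifiedDispersalModel(u, [m])
        geog, _ = st.simulate_dec_tips(
            tree, DECParams(0.3, 0.1), disp, CladogenesisSpec("DEC"), {"A"}, seed=3
        )
        base = st.dec_loglik(tree, geog, DECParams(0.2, 0.1, w=1.0), disp,
                             CladogenesisSpec("DEC"))
        for eps in (1e-4, 1e-6):
            near = st.dec_loglik(tree, geog, DECParams(0.2, 0.1, w=1.0 + eps), disp,
                                 CladogenesisSpec("DEC"))
            assert abs(near - base) < 1e-2


class TestMarginals:
    def test_distributions_sum_to_one(self, balanced4, uni2):
        geog = GeographyData.from_sets(
            uni2, {"a": {"A"}, "b": {"B"}, "c": {"A"}, "d": {"A", "B"}}
        )
        marg, _, _ = st.ancestral_range_marginals(
            balanced4, geog, DECParams(0.2, 0.1),
            StratifiedDispersalModel.uniform(uni2), CladogenesisSpec("DEC"),
        )
        for v, dist in marg.items():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_problem_gives_symmetric_root(self, cherry, uni2, space2):
        geog = GeographyData.from_sets(uni2, {"x": {"A"}, "y": {"B"}})
        marg, _, _ = st.ancestral_range_marginals(
            cherry, geog, DECParams(0.2, 0.1),
            StratifiedDispersalModel.uniform(uni2), CladogenesisSpec("DEC"),
        )
        root = marg[cherry.root]
        assert root[space2.index[1]] == pytest.approx(root[space2.index[2]], rel=1e-9)

    def test_three_tip_marginals_match_enumeration(self, uni2):
        tree = st.parse_newick("((p:1,q:1):1,r:2);")
        geog = GeographyData.from_sets(uni2, {"p": {"A"}, "q": {"B"}, "r": {"B"}})
        disp = StratifiedDispersalModel.uniform(uni2)
        spec = CladogenesisSpec("DEC")
        params = DECParams(0.3, 0.15, j=0.6)
        model = DECModel(tree, geog, disp, spec)
        marg = model.marginals(params)
        _, expected = brute_dec(tree, geog, params, disp, spec)
        for v in marg:
            np.testing.assert_allclose(marg[v], expected[v], atol=1e-9)

    def test_root_areas_summary_minimal_cover(self, cherry, uni2):
        geog = GeographyData.from_sets(uni2, {"x": {"A"}, "y": {"A"}})
        model = DECModel(cherry, geog, StratifiedDispersalModel.uniform(uni2),
                         CladogenesisSpec("DEC"))
        marg = model.marginals(DECParams(0.05, 0.02))
        states, union = model.root_areas_summary(marg[cherry.root])
        assert "A" in union
        cum = sum(
            marg[cherry.root][model.space.labels().index(s)] for s in states
        )
        assert cum >= 0.95


class TestFileFormats:
    def test_geography_round_trip(self, uni3):
        geog = GeographyData.from_sets(
            uni3, {"sp1": {"A"}, "sp2": {"B", "C"}, "sp3": {"A", "B", "C"}}
        )
        again = read_geography(write_geography(geog))
        assert again.ranges == geog.ranges
        assert again.universe.labels == uni3.labels

    def test_geography_header_and_rows_validated(self):
        with pytest.raises(ValueError, match="presence"):
            read_geography("1 2 (A B)\nsp1\t21\n")
        with pytest.raises(ValueError, match="declares"):
            read_geography("2 2 (A B)\nsp1\t10\n")

    def test_dispersal_model_round_trip(self, uni2):
        strat = Stratification((23.0,))
        m0 = np.array([[1.0, 0.0], [0.5, 1.0]])
        m1 = np.array([[1.0, 0.8], [0.8, 1.0]])
        model = StratifiedDispersalModel(uni2, [m0, m1], strat)
        again = read_dispersal_model(write_dispersal_model(model), uni2)
        assert again.stratification.boundary_ages == (23.0,)
        np.testing.assert_allclose(again.matrices[0], m0)
        np.testing.assert_allclose(again.matrices[1], m1)

    def test_unavailable_area_helper_zeroes_incoming(self, uni2):
        model = StratifiedDispersalModel.uniform(uni2).with_area_unavailable("B", [0])
        assert np.all(model.matrices[0][:, 1] == 0)
        assert np.all(model.matrices[0][:, 0] == 1)

    def test_multiplier_range_validated(self, uni2):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            StratifiedDispersalModel(uni2, [np.full((2, 2), 1.5)])
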