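import numpy as np
import pytest

from hostphylo.dec import (
    AncestralEstimate,
    DECParams,
    ancestral_states,
    anagenetic_rate_matrix,
    build_state_space,
    cladogenesis_table,
    dec_loglik,
    fit_dec,
    transition_probabilities,
)
from hostphylo.synthetic import simulate_dec_history, simulate_yule_tree
from hostphylo.trees import parse_newick

from _oracles import dec_brute_loglik, dec_brute_marginals


@pytest.fixture
def space3():
    return build_state_space(["X", "Y", "Z"])


@pytest.fixture
def four_tip_tree():
    return parse_newick("((a:1,b:1):1,(c:0.5,d:0.5):1.5);")


class TestStateSpace:
    def test_two_families(self):
        sp = build_state_space(["A", "B"], 2)
        assert [sorted(s) for s in sp.states] == [["A"], ["B"], ["A", "B"]]

    @pytest.mark.parametrize(
        "n, m, expected", [(9, 9, 511), (9, 2, 45), (3, 3, 7), (12, 1, 12)]
    )
    def test_state_counts(self, n, m, expected):
        sp = build_state_space([f"F{i}" for i in range(n)], m)
        assert sp.n_states == expected

    def test_too_many_families_refused(self):
        with pytest.raises(ValueError, match="capped"):
            build_state_space([f"F{i}" for i in range(13)])

    def test_null_range_absent(self, space3):
        assert frozenset() not in space3.states
        with pytest.raises(KeyError):
            space3.state_index([])


class TestRateMatrix:
    def test_two_family_entries(self):
        sp = build_state_space(["A", "B"], 2)
        Q = anagenetic_rate_matrix(sp, DECParams(0.1, 0.05))
        iA, iB, iAB = sp.state_index(["A"]), sp.state_index(["B"]), sp.state_index(["A", "B"])
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iAB, iA] == pytest.approx(0.05)
        assert Q[iA, iB] == 0.0
        assert Q[iA, iA] == pytest.approx(-0.1)
        # DEC*: no extirpation out of single-family ranges
        assert Q[iA].sum() == pytest.approx(0.0)

    def test_zero_rates_zero_matrix(self, space3):
        assert np.all(anagenetic_rate_matrix(space3, DECParams(0, 0)) == 0)

    def test_rows_sum_to_zero(self, space3):
        Q = anagenetic_rate_matrix(space3, DECParams(0.3, 0.2))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, space3):
        Q = anagenetic_rate_matrix(space3, DECParams(0.2, 0.1))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(space3.n_states))

    def test_matches_analytic_two_state_chain(self):
        # the {A} <-> {A,B} subsystem with d = gain, e = loss is a standard
        # two-state chain with closed-form exponential
        sp = build_state_space(["A"], 1)
        d, e, t = 0.4, 0.7, 1.3
        Q = np.array([[-d, d], [e, -e]])
        P = transition_probabilities(Q, t)
        s = d + e
        p01 = d / s * (1 - np.exp(-s * t))
        assert P[0, 1] == pytest.approx(p01, abs=1e-10)
        assert P[1, 0] == pytest.approx(e / s * (1 - np.exp(-s * t)), abs=1e-10)

    def test_semigroup_property(self, space3):
        Q = anagenetic_rate_matrix(space3, DECParams(0.35, 0.15))
        P1 = transition_probabilities(Q, 0.8)
        P2 = transition_probabilities(Q, 1.6)
        assert np.allclose(P1 @ P1, P2, atol=1e-8)

    def test_negative_time_rejected(self, space3):
        Q = anagenetic_rate_matrix(space3, DECParams(0.1, 0.1))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


class TestCladogenesis:
    def test_single_family_identity_event(self):
        sp = build_state_space(["A", "B"], 2)
        events = [e for e in cladogenesis_table(sp) if e[0] == frozenset({"A"})]
        assert events == [(frozenset({"A"}), frozenset({"A"}), frozenset({"A"}), 1.0)]

    def test_two_family_parent_has_six_equiprobable_pairs(self):
        sp = build_state_space(["A", "B"], 2)
        AB = frozenset({"A", "B"})
        events = [e for e in cladogenesis_table(sp) if e[0] == AB]
        assert len(events) == 6
        assert all(w == pytest.approx(1 / 6) for *_, w in events)
        pairs = {(l, r) for _, l, r, _ in events}
        A, B = frozenset({"A"}), frozenset({"B"})
        assert pairs == {(A, AB), (AB, A), (B, AB), (AB, B), (A, B), (B, A)}

    def test_probabilities_sum_to_one_per_parent(self, space3):
        table = cladogenesis_table(space3)
        for parent in space3.states:
            total = sum(w for p, *_ , w in table if p == parent)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_no_widespread_sympatry_or_jumps(self, space3):
        # both daughters equal to a parent of size >= 2 is excluded, and no
        # daughter may contain families absent from the parent
        for parent, left, right, _ in cladogenesis_table(space3):
            if len(parent) >= 2:
                assert not (left == parent and right == parent)
            assert left <= parent and right <= parent


class TestLoglik:
    def test_frozen_states_at_zero_rates(self):
        tree = parse_newick("(a:1,b:1);")
        sp = build_state_space(["A", "B"], 2)
        tips = {"a": {"A"}, "b": {"A"}}
        ll = dec_loglik(tree, tips, DECParams(0, 0), sp)
        assert ll == pytest.approx(np.log(1 / sp.n_states), abs=1e-12)

    def test_pruning_equals_enumeration(self, four_tip_tree, space3):
        tips = {"a": {"X"}, "b": {"X", "Y"}, "c": {"Z"}, "d": {"Y", "Z"}}
        rng = np.random.default_rng(1)
        for _ in range(10):
            params = DECParams(rng.uniform(0.01, 1.5), rng.uniform(0.01, 1.5))
            assert dec_loglik(four_tip_tree, tips, params, space3) == pytest.approx(
                dec_brute_loglik(four_tip_tree, tips, params, space3), abs=1e-8
            )

    def test_family_relabeling_invariance(self, four_tip_tree):
        params = DECParams(0.3, 0.2)
        sp1 = build_state_space(["X", "Y", "Z"])
        sp2 = build_state_space(["Z", "X", "Y"])
        tips1 = {"a": {"X"}, "b": {"X", "Y"}, "c": {"Z"}, "d": {"Y", "Z"}}
        assert dec_loglik(four_tip_tree, tips1, params, sp1) == pytest.approx(
            dec_loglik(four_tip_tree, tips1, params, sp2), abs=1e-10
        )

    def test_loglik_decreases_with_extirpation(self, four_tip_tree, space3):
        # tips holding multi-family ranges become unreachable as e grows
        tips = {"a": {"X", "Y"}, "b": {"X", "Y"}, "c": {"Y", "Z"}, "d": {"Y", "Z"}}
        lls = [
            dec_loglik(four_tip_tree, tips, DECParams(0.2, e), space3)
            for e in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_non_ultrametric_rejected(self, space3):
        tree = parse_newick("((a:1,b:1):1,c:5);")
        tips = {"a": {"X"}, "b": {"X"}, "c": {"X"}}
        with pytest.raises(ValueError, match="ultrametric"):
            dec_loglik(tree, tips, DECParams(0.1, 0.1), space3)

    def test_polytomy_rejected(self, space3):
        tree = parse_newick("(a:1,b:1,c:1);")
        tips = {"a": {"X"}, "b": {"X"}, "c": {"X"}}
        with pytest.raises(ValueError, match="polytom"):
            dec_loglik(tree, tips, DECParams(0.1, 0.1), space3)

    def test_empty_tip_range_rejected(self, four_tip_tree, space3):
        tips = {"a": set(), "b": {"X"}, "c": {"X"}, "d": {"X"}}
        with pytest.raises(ValueError, match="empty range"):
            dec_loglik(four_tip_tree, tips, DECParams(0.1, 0.1), space3)

    def test_restricted_range_size_loglik_nondecreasing_in_m(self, four_tip_tree):
        tips = {"a": {"X"}, "b": {"Y"}, "c": {"Z"}, "d": {"Y"}}
        params = DECParams(0.05, 0.02)
        lls = []
        for m in (2, 3):
            sp = build_state_space(["X", "Y", "Z"], m)
            lls.append(dec_loglik(four_tip_tree, tips, params, sp))
        # the larger state space adds paths without removing any
        assert np.isfinite(lls[0])
        assert lls[0] <= lls[1] + 1e-9

    def test_frozen_space_with_conflicting_tips_has_zero_likelihood(self, four_tip_tree):
        # max range size 1 disables every DEC* move, so unequal tips are
        # impossible and the engine reports log-likelihood -inf
        sp = build_state_space(["X", "Y", "Z"], 1)
        tips = {"a": {"X"}, "b": {"Y"}, "c": {"Z"}, "d": {"Y"}}
        assert dec_loglik(four_tip_tree, tips, DECParams(0.05, 0.02), sp) == -np.inf


class TestFitAndAncestral:
    def test_uniform_tips_drive_dispersal_to_bound(self):
        tree = simulate_yule_tree(n_tips=8, seed=1)
        sp = build_state_space(["A", "B"], 2)
        tips = {l: {"A"} for l in tree.tip_labels}
        fit = fit_dec(tree, tips, sp)
        assert fit.params.d == pytest.approx(1e-9, rel=10)
        assert fit.at_bound

    def test_ml_beats_truth_on_simulated_data(self):
        sp = build_state_space(["A", "B", "C"])
        truth = DECParams(0.15, 0.05)
        tree = simulate_yule_tree(n_tips=40, seed=60)
        hist = simulate_dec_history(tree, sp, truth, seed=61)
        fit = fit_dec(tree, hist.tips, sp)
        assert fit.loglik >= dec_loglik(tree, hist.tips, truth, sp) - 1e-6

    def test_marginals_match_enumeration(self, four_tip_tree, space3):
        tips = {"a": {"X"}, "b": {"X", "Y"}, "c": {"Z"}, "d": {"Y", "Z"}}
        params = DECParams(0.3, 0.1)
        est = ancestral_states(four_tip_tree, tips, params, space3)
        brute = dec_brute_marginals(four_tip_tree, tips, params, space3)
        post = four_tip_tree.postorder_index()
        for node, vec in brute.items():
            row = est.probs[est.node_ids.index(post[node])]
            assert np.allclose(row, vec, atol=1e-8)

    def test_marginals_normalised(self, four_tip_tree, space3):
        tips = {"a": {"X"}, "b": {"Y"}, "c": {"Z"}, "d": {"X", "Z"}}
        est = ancestral_states(four_tip_tree, tips, DECParams(0.4, 0.3), space3)
        assert np.allclose(est.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(est.probs >= 0)

    def test_symmetric_cherry_reconstructs_shared_family(self):
        tree = parse_newick("(a:1,b:1);")
        sp = build_state_space(["Cucurbitaceae", "Rutaceae"], 2)
        tips = {"a": {"Cucurbitaceae"}, "b": {"Cucurbitaceae"}}
        est = ancestral_states(tree, tips, DECParams(0.05, 0.02), sp)
        assert est.most_probable()[est.node_ids[0]] == frozenset({"Cucurbitaceae"})
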