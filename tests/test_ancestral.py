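"""Ancestral reconstruction (parsimony, ML-Brownian) and selection gradients."""

import numpy as np
import pytest

from macroqg import (AncestralStates, CovMatrix, SimConfig, Pulse,
                     branch_delta_z, branch_selection_gradients,
                     compare_reconstructions, extend_matrix, make_within_cov,
                     pic, read_newick, reconstruct_ml_bm,
                     reconstruct_parsimony, selection_gradient,
                     selection_profile, simulate_means, simulate_tree)
from conftest import bm_on_tree, brute_force_parsimony_cost


class TestParsimony:
    def test_constant_tips_reconstruct_constant(self, three_tip_tree):
        st = reconstruct_parsimony(three_tip_tree, {t: [5.0] for t in "ABC"})
        assert all(v[0] == 5.0 for v in st.states.values())
        assert np.all(st.cost == 0.0)

    def test_majority_tree_interval_and_cost(self):
        # ((A,B),C) with 0, 0, 10: the A-B node is exactly 0 (unique
        # optimum), the root optimum is the whole interval [0, 10] with
        # minimal total change 10; the point estimate is the midpoint
        tree = read_newick("((A:1,B:1):1,C:1);")
        st = reconstruct_parsimony(tree, {"A": [0.0], "B": [0.0], "C": [10.0]})
        internal = next(n.label for n in tree.internal_nodes()
                        if n.parent is not None)
        root = tree.root.label
        assert st.states[internal][0] == 0.0
        assert st.intervals[internal][0][0] == 0.0
        assert st.intervals[internal][1][0] == 0.0
        assert (st.intervals[root][0][0], st.intervals[root][1][0]) == (0.0, 10.0)
        assert st.states[root][0] == 5.0
        assert st.cost[0] == 10.0

    def test_point_estimates_inside_intervals(self):
        cfg = SimConfig(seed=2, n_tips=12, p=3)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(0)
        values = {t: rng.integers(0, 10, 3).astype(float)
                  for t in tree.tip_labels}
        st = reconstruct_parsimony(tree, values)
        for label, vec in st.states.items():
            lo, hi = st.intervals[label]
            assert np.all(lo <= vec) and np.all(vec <= hi)

    def test_tip_values_reproduced_exactly(self):
        cfg = SimConfig(seed=3, n_tips=9, p=2)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(1)
        values = {t: rng.normal(size=2) for t in tree.tip_labels}
        st = reconstruct_parsimony(tree, values)
        for t, v in values.items():
            assert np.array_equal(st.states[t], v)

    def test_cost_matches_bruteforce_on_random_tree(self):
        cfg = SimConfig(seed=4, n_tips=6)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(2)
        values = {t: float(rng.integers(0, 10)) for t in tree.tip_labels}
        st = reconstruct_parsimony(tree, {t: [v] for t, v in values.items()})
        oracle = brute_force_parsimony_cost(tree, values, np.arange(10.0))
        assert st.cost[0] == pytest.approx(oracle, abs=1e-12)


class TestMlBrownian:
    def test_two_tip_symmetric_average(self):
        tree = read_newick("(A:1,B:1);")
        st = reconstruct_ml_bm(tree, {"A": [4.0], "B": [8.0]})
        assert st.states[tree.root.label][0] == pytest.approx(6.0)

    def test_three_tip_matches_gls_oracle(self, three_tip_tree):
        # root = (1' C^-1 x)/(1' C^-1 1) with C = [[2,1,0],[1,2,0],[0,0,2]]
        st = reconstruct_ml_bm(three_tip_tree,
                               {"A": [0.0], "B": [2.0], "C": [6.0]})
        assert st.states[three_tip_tree.root.label][0] == pytest.approx(
            3.142857142857143, rel=1e-12)

    def test_constant_tips_reconstruct_constant(self, three_tip_tree):
        st = reconstruct_ml_bm(three_tip_tree, {t: [3.0, 1.0] for t in "ABC"})
        for v in st.states.values():
            assert np.allclose(v, [3.0, 1.0])

    def test_root_equals_pic_root_value(self):
        for seed in range(5):
            cfg = SimConfig(seed=100 + seed, n_tips=14, p=2)
            tree = simulate_tree(cfg)
            rng = np.random.default_rng(seed)
            values = bm_on_tree(tree, np.eye(2), rng)
            tip_values = {t: values[t] for t in tree.tip_labels}
            st = reconstruct_ml_bm(tree, tip_values)
            cs = pic(tree, tip_values)
            assert np.allclose(st.states[tree.root.label], cs.root_value,
                               rtol=1e-12, atol=1e-12)

    def test_internal_node_matches_rerooted_pic(self):
        cfg = SimConfig(seed=6, n_tips=10, p=1)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(3)
        values = bm_on_tree(tree, np.eye(1), rng)
        tip_values = {t: values[t] for t in tree.tip_labels}
        st = reconstruct_ml_bm(tree, tip_values)
        # independent GLS oracle: for each internal node, solve the full
        # GLS problem with the node as the tree's root
        node = next(n for n in tree.internal_nodes() if n.parent is not None)
        est = _gls_state_at_node(tree, node, tip_values)
        assert st.states[node.label][0] == pytest.approx(est, rel=1e-9)


def _gls_state_at_node(tree, target, tip_values):
    """Independent GLS oracle: estimate the state at ``target`` as the GLS
    mean of the tips with covariance C[i,j] = shared path length between
    tips i and j measured from ``target`` (the re-rooted tree covariance),
    computed from plain patristic distances:
    C[i,j] = (d(v,i) + d(v,j) - d(i,j)) / 2 with v = target."""
    depths = tree.depths()

    def chain(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def dist(a, b):
        ca, cb = chain(a), set(chain(b))
        mrca = next(n for n in ca if n in cb)
        return (depths[a.label] + depths[b.label] - 2 * depths[mrca.label])

    tips = [tree.node(t) for t in tree.tip_labels]
    n = len(tips)
    c = np.empty((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            c[i, j] = (dist(target, a) + dist(target, b) - dist(a, b)) / 2.0
    x = np.array([tip_values[t.label][0] for t in tips])
    ci = np.linalg.inv(c + 1e-12 * np.eye(n))
    one = np.ones(n)
    return float(one @ ci @ x / (one @ ci @ one))


class TestCompareReconstructions:
    def _states(self, values):
        return AncestralStates(method="x", states=values, tips=("A", "B"))

    def test_identical_states_correlate_one(self):
        a = self._states({"A": np.array([1.0]), "B": np.array([2.0]),
                          "n1": np.array([3.0]), "n2": np.array([1.0])})
        assert compare_reconstructions(a, a) == pytest.approx(1.0)

    def test_sign_flip_correlates_minus_one(self):
        a = self._states({"A": np.array([1.0]), "B": np.array([2.0]),
                          "n1": np.array([3.0]), "n2": np.array([1.0])})
        b = self._states({k: -v for k, v in a.states.items()})
        assert compare_reconstructions(a, b) == pytest.approx(-1.0)

    def test_methods_agree_on_brownian_data(self):
        cfg = SimConfig(seed=8, n_tips=30, p=5)
        tree = simulate_tree(cfg)
        means = simulate_means(tree, cfg).tip_means(tree)
        pars = reconstruct_parsimony(tree, means)
        ml = reconstruct_ml_bm(tree, means)
        assert compare_reconstructions(pars, ml) > 0.8


class TestBranchDeltaZ:
    def test_sign_convention_and_count(self, three_tip_tree):
        tree = three_tip_tree
        st = reconstruct_ml_bm(tree, {"A": [0.0], "B": [0.0], "C": [9.0]})
        dz = branch_delta_z(st, tree)
        assert len(dz) == len(tree.branches())
        parent, child = tree.branches()[0]
        expected = st.states[child.label] - st.states[parent.label]
        assert np.allclose(dz[(parent.label, child.label)], expected)

    def test_identical_states_give_zero(self, three_tip_tree):
        st = reconstruct_ml_bm(three_tip_tree, {t: [4.0] for t in "ABC"})
        dz = branch_delta_z(st, three_tip_tree)
        assert all(np.allclose(v, 0.0) for v in dz.values())


class TestSelectionGradient:
    def test_zero_response_gives_zero_gradient(self):
        w = CovMatrix(make_within_cov(6), role="W")
        est = selection_gradient(np.zeros(6), w, mean=np.ones(6))
        assert np.allclose(est.beta, 0.0) and est.magnitude == 0.0

    def test_identity_w_returns_delta_z(self):
        dz = np.array([1.0, -2.0, 0.5, 0.0, 1.0])
        est = selection_gradient(dz, CovMatrix(np.eye(5), role="W"),
                                 extend=False, mean=np.ones(5))
        assert np.allclose(est.beta, dz)
        assert est.magnitude == pytest.approx(np.linalg.norm(dz))

    def test_exact_recovery_without_extension(self):
        rng = np.random.default_rng(10)
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        lam = np.geomspace(1.0, 1.0 / 500.0, 8)  # condition number < 1e3
        w = CovMatrix((q * lam) @ q.T, role="W")
        beta_true = rng.normal(size=8)
        dz = w.values @ beta_true
        est = selection_gradient(dz, w, extend=False)
        assert np.linalg.norm(est.beta - beta_true) / np.linalg.norm(beta_true) < 1e-8

    def test_unit_change_equivariance(self):
        # scaling traits by c scales beta by 1/c; mean-standardized
        # magnitude is dimensionless and unchanged
        rng = np.random.default_rng(11)
        w = CovMatrix(make_within_cov(7), role="W")
        dz = rng.normal(size=7)
        mean = np.full(7, 20.0)
        est1 = selection_gradient(dz, w, mean=mean)
        c = 3.5
        w_scaled = CovMatrix(c ** 2 * w.values, role="W")
        est2 = selection_gradient(c * dz, w_scaled, mean=c * mean)
        assert np.allclose(est2.beta, est1.beta / c)
        assert est2.magnitude == pytest.approx(est1.magnitude, rel=1e-10)

    def test_singular_w_raises(self):
        w = CovMatrix(np.zeros((3, 3)), role="W")
        with pytest.raises(Exception):
            selection_gradient(np.ones(3), w, extend=False)


class TestSelectionProfile:
    def test_zero_everywhere(self, three_tip_tree):
        tree = three_tip_tree
        st = reconstruct_ml_bm(tree, {t: [4.0, 2.0] for t in "ABC"})
        w = {n.label: CovMatrix(np.eye(2), role="W") for n in tree.postorder()}
        grads = branch_selection_gradients(tree, st, w, extend=False)
        profile = selection_profile(tree, grads)
        assert len(profile) == len(tree.branches())
        assert np.allclose(profile["magnitude"], 0.0)

    def test_pulsed_branch_has_maximum_magnitude(self):
        cfg = SimConfig(seed=12, n_tips=30, p=10,
                        pulses=(Pulse(branch="random", intensity=8.0),))
        tree = simulate_tree(cfg)
        means = simulate_means(tree, cfg)
        st = reconstruct_parsimony(tree, means.tip_means(tree))
        w = CovMatrix(make_within_cov(10), role="W")
        wmap = {n.label: w for n in tree.postorder()}
        grads = branch_selection_gradients(tree, st, wmap)
        profile = selection_profile(tree, grads)
        (pl, cl, _), = means.pulse_branches
        top = profile.loc[profile["magnitude"].idxmax()]
        assert (top["parent"], top["child"]) == (pl, cl)

    def test_clade_subsetting(self):
        cfg = SimConfig(seed=13, n_tips=12, p=4)
        tree = simulate_tree(cfg)
        means = simulate_means(tree, cfg)
        st = reconstruct_parsimony(tree, means.tip_means(tree))
        w = CovMatrix(make_within_cov(4), role="W")
        wmap = {n.label: w for n in tree.postorder()}
        grads = branch_selection_gradients(tree, st, wmap)
        node = next(n for n in tree.internal_nodes() if n.parent is not None)
        sub = selection_profile(tree, grads, clade=node.label)
        n_sub_branches = len(tree.subtree(node).branches())
        assert len(sub) == n_sub_branches
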