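"""P-matrix estimation, pooling into node W-matrices, eigenvalue extension."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from macroqg import (CovMatrix, MatrixError, average_replicates,
                     estimate_p_matrix, extend_matrix, pool_w_matrices,
                     pool_w_matrix, read_newick, repeatability)
from macroqg.simulate import trait_names


def _table(rows):
    return pd.DataFrame(rows)


def _specimen_rows(species, specimen, traits, replicate=1, **factors):
    row = {"species": species, "specimen": specimen, "replicate": replicate}
    row.update(factors)
    row.update({f"tr{i+1:02d}": v for i, v in enumerate(traits)})
    return row


class TestAverageReplicates:
    def test_mean_of_two_replicates(self):
        t = _table([
            _specimen_rows("sp1", "a", [10.0], replicate=1),
            _specimen_rows("sp1", "a", [12.0], replicate=2),
        ])
        out = average_replicates(t)
        assert len(out) == 1 and out["tr01"].iloc[0] == 11.0

    def test_single_replicate_passes_through(self):
        t = _table([_specimen_rows("sp1", "a", [10.0])])
        assert average_replicates(t)["tr01"].iloc[0] == 10.0

    def test_one_row_per_specimen(self):
        rows = []
        for k in range(3):
            for rep in (1, 2):
                rows.append(_specimen_rows("sp1", f"s{k}", [float(k)], rep))
        assert len(average_replicates(_table(rows))) == 3


class TestRepeatability:
    def test_identical_replicates_give_one(self):
        rows = [_specimen_rows("sp1", f"s{k}", [float(k), 2.0 * k], rep)
                for k in range(4) for rep in (1, 2)]
        icc = repeatability(_table(rows))
        assert np.allclose(icc.to_numpy(), 1.0)

    def test_no_among_specimen_variance_gives_near_zero(self):
        rng = np.random.default_rng(0)
        rows = [_specimen_rows("sp1", f"s{k}", [rng.normal()], rep)
                for k in range(200) for rep in (1, 2)]
        assert repeatability(_table(rows)).iloc[0] < 0.15

    def test_nine_to_one_variance_ratio_gives_icc_point_nine(self):
        # among-specimen variance 9, replicate variance 1, k = 2:
        # expected ICC = 9 / (9 + 1) = 0.9
        rng = np.random.default_rng(1)
        rows = []
        for k in range(500):
            mu = rng.normal(0, 3.0)
            for rep in (1, 2):
                rows.append(_specimen_rows("sp1", f"s{k}", [mu + rng.normal()], rep))
        icc = repeatability(_table(rows)).iloc[0]
        assert icc == pytest.approx(0.9, abs=0.03)

    def test_unreplicated_table_raises(self):
        rows = [_specimen_rows("sp1", f"s{k}", [1.0]) for k in range(5)]
        with pytest.raises(MatrixError):
            repeatability(_table(rows))


class TestEstimatePMatrix:
    def test_no_factors_is_sample_covariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        rows = [_specimen_rows("sp1", f"s{i}", x[i]) for i in range(30)]
        p = estimate_p_matrix(_table(rows))
        assert np.allclose(p.values, np.cov(x, rowvar=False))
        assert p.role == "P" and p.n == 30

    def test_identical_specimens_give_zero_matrix(self):
        rows = [_specimen_rows("sp1", "s1", [1.0, 2.0]),
                _specimen_rows("sp1", "s2", [1.0, 2.0])]
        assert np.allclose(estimate_p_matrix(_table(rows)).values, 0.0)

    def test_sex_effect_removed_from_residual_matrix(self):
        # specimens shifted by +-delta/2 per sex: raw covariance is inflated
        # by the between-sex term delta delta'/4 (law of total covariance),
        # while the MANOVA-controlled residual P recovers the true sigma
        rng = np.random.default_rng(3)
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        delta = np.array([2.0, 2.0])
        chol = np.linalg.cholesky(sigma)
        rows = []
        for i in range(400):
            sex = "M" if i % 2 else "F"
            center = (0.5 if sex == "M" else -0.5) * delta
            rows.append(_specimen_rows("sp1", f"s{i}",
                                       center + chol @ rng.standard_normal(2),
                                       sex=sex))
        table = _table(rows)
        p_ctrl = estimate_p_matrix(table, factors=["sex"])
        p_raw = estimate_p_matrix(table)
        assert np.linalg.norm(p_ctrl.values - sigma) / np.linalg.norm(sigma) < 0.15
        inflation = p_raw.values - p_ctrl.values
        expected = np.outer(delta, delta) / 4.0
        assert np.linalg.norm(inflation - expected) / np.linalg.norm(expected) < 0.3

    def test_uninformative_factor_ignored(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 2))
        rows = [_specimen_rows("sp1", f"s{i}", x[i],
                               sex="M" if rng.random() < 0.5 else "F")
                for i in range(60)]
        p_with = estimate_p_matrix(_table(rows), factors=["sex"])
        p_without = estimate_p_matrix(_table(rows))
        # sex explains nothing: the term is not retained, estimates coincide
        assert np.allclose(p_with.values, p_without.values)

    def test_single_specimen_raises(self):
        with pytest.raises(MatrixError):
            estimate_p_matrix(_table([_specimen_rows("sp1", "s1", [1.0])]))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_trait_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(25, 4))
        rows = [_specimen_rows("sp1", f"s{i}", x[i],
                               sex="M" if i % 2 else "F") for i in range(25)]
        table = _table(rows)
        perm = rng.permutation(4)
        traits = trait_names(4)
        renamed = table.rename(columns={traits[perm[k]]: traits[k]
                                        for k in range(4)})
        renamed = renamed[list(table.columns)]
        p1 = estimate_p_matrix(table, factors=["sex"]).values
        p2 = estimate_p_matrix(renamed, factors=["sex"]).values
        assert np.allclose(p2, p1[np.ix_(perm, perm)])


class TestPoolWMatrices:
    tree = None

    def setup_method(self):
        self.tree = read_newick("((A:1,B:1):1,C:2);")

    def test_identical_p_pools_to_itself(self):
        p = CovMatrix(np.array([[2.0, 0.5], [0.5, 1.0]]), role="P")
        w = pool_w_matrix(self.tree, self.tree.root,
                          {t: p for t in "ABC"}, {t: 50 for t in "ABC"})
        assert np.allclose(w.values, p.values) and w.role == "W"

    def test_weighted_average_arithmetic(self):
        # (100 * I + 50 * 3I) / 150 = (5/3) I
        tree = read_newick("(A:1,B:1);")
        mats = {"A": CovMatrix(np.eye(2)), "B": CovMatrix(3 * np.eye(2))}
        w = pool_w_matrix(tree, tree.root, mats, {"A": 101, "B": 51})
        assert np.allclose(w.values, (5.0 / 3.0) * np.eye(2))

    def test_small_species_takes_ancestral_node_matrix(self):
        # C has n = 10 < 35: its own (absurd) P must be ignored in favour of
        # its ancestral node's pooled matrix
        mats = {"A": CovMatrix(np.eye(2)), "B": CovMatrix(3 * np.eye(2)),
                "C": CovMatrix(99 * np.eye(2))}
        sizes = {"A": 101, "B": 51, "C": 10}
        ws = pool_w_matrices(self.tree, mats, sizes, min_n=35)
        root_w = ws[self.tree.root.label]
        assert root_w.values[0, 0] < 5  # the 99 never enters
        # C's substitute is the root pool of A and B = (5/3) I, so the root
        # re-pool is unchanged: ((5/3)*150 + (5/3)*9)/159 = 5/3
        assert np.allclose(root_w.values, (5.0 / 3.0) * np.eye(2))

    def test_equal_sizes_pool_to_unweighted_mean(self):
        rng = np.random.default_rng(5)
        mats = {}
        for t in "ABC":
            a = rng.normal(size=(3, 3))
            mats[t] = CovMatrix(a @ a.T)
        w = pool_w_matrix(self.tree, self.tree.root, mats,
                          {t: 40 for t in "ABC"})
        mean = sum(m.values for m in mats.values()) / 3.0
        assert np.allclose(w.values, mean)

    def test_no_usable_species_raises(self):
        mats = {t: CovMatrix(np.eye(2)) for t in "ABC"}
        with pytest.raises(MatrixError):
            pool_w_matrices(self.tree, mats, {t: 5 for t in "ABC"}, min_n=35)

    def test_root_w_converges_to_shared_sigma(self):
        # many species sharing one true sigma, total n = 3000
        rng = np.random.default_rng(6)
        sigma = np.array([[2.0, 0.7, 0.1], [0.7, 1.5, 0.4], [0.1, 0.4, 1.0]])
        chol = np.linalg.cholesky(sigma)
        n_species, n_each = 30, 100
        cur = "s1:1"
        for i in range(2, n_species + 1):
            cur = f"({cur},s{i}:1):1"
        tree = read_newick(cur.rsplit(":", 1)[0] + ";")
        mats, sizes = {}, {}
        for t in tree.tip_labels:
            x = (chol @ rng.standard_normal((3, n_each))).T
            mats[t] = CovMatrix(np.cov(x, rowvar=False))
            sizes[t] = n_each
        w = pool_w_matrix(tree, tree.root, mats, sizes)
        assert np.linalg.norm(w.values - sigma) / np.linalg.norm(sigma) < 0.05


class TestExtendMatrix:
    def test_flat_scree_unchanged(self):
        w = CovMatrix(2.0 * np.eye(6), role="W")
        ext = extend_matrix(w)
        assert np.allclose(ext.values, w.values) and ext.role == "W_ext"

    def test_trailing_noise_eigenvalues_raised(self):
        lam = np.array([10.0, 5.0, 2.0, 1.0, 1e-8, 1e-9, 1e-10, 1e-11])
        w = CovMatrix(np.diag(lam), role="W")
        ext = extend_matrix(w)
        lam_ext = np.sort(np.linalg.eigvalsh(ext.values))[::-1]
        assert ext.cutoff is not None
        cut_val = lam_ext[ext.cutoff - 1]
        assert np.allclose(lam_ext[ext.cutoff:], cut_val)
        cond_before = lam[0] / lam[-1]
        cond_after = lam_ext[0] / lam_ext[-1]
        assert cond_after <= cond_before / 990  # orders-of-magnitude drop

    def test_leading_subspace_preserved(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 8))
        w = CovMatrix(a @ a.T / 8 + np.diag([4, 2, 1, 0.5, 0, 0, 0, 0]), role="W")
        ext = extend_matrix(w)
        lam, vec = w.eigh()
        lam_e, vec_e = ext.eigh()
        j = ext.cutoff
        # leading eigenvalues identical up to the cutoff; the eigenspace
        # strictly above the extension level is preserved (the cutoff
        # eigenvalue itself becomes degenerate with the raised tail, so its
        # eigenvector ordering is arbitrary)
        k = j - 1
        p1 = vec[:, :k] @ vec[:, :k].T
        p2 = vec_e[:, :k] @ vec_e[:, :k].T
        assert np.linalg.norm(p1 - p2) < 1e-8
        assert np.allclose(lam_e[:j], lam[:j])
        diff = ext.values - w.values
        proj = vec[:, :j].T @ diff @ vec[:, :j]
        assert np.allclose(proj, 0.0, atol=1e-10)

    def test_min_eigenvalue_never_decreases(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(10, 10))
        w = CovMatrix(a @ a.T, role="W")
        ext = extend_matrix(w)
        assert (np.linalg.eigvalsh(ext.values).min()
                >= np.linalg.eigvalsh(w.values).min() - 1e-10)

    def test_short_scree_returned_unchanged(self):
        w = CovMatrix(np.diag([3.0, 2.0, 1.0]), role="W")
        ext = extend_matrix(w)
        assert np.allclose(ext.values, w.values) and ext.cutoff is None

    def test_manual_rank_override(self):
        w = CovMatrix(np.diag(np.geomspace(8.0, 1e-6, 8)), role="W")
        ext = extend_matrix(w, rank=4)
        lam_ext = np.sort(np.linalg.eigvalsh(ext.values))[::-1]
        assert ext.cutoff == 4 and np.allclose(lam_ext[4:], lam_ext[3])
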