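"""Shared fixtures and independent oracle helpers.

The oracle helpers (direct Brownian simulation, exhaustive tree-shape
enumeration) are deliberately written from scratch here so that tests check
the package against independent computations, not against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from macroqg import Node, Phylogeny, fixture_dataset


# ---------------------------------------------------------------------------
# small reference trees
# ---------------------------------------------------------------------------

@pytest.fixture
def three_tip_tree():
    from macroqg import read_newick
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def fixture_data():
    """Frozen small dataset: 10 species, 6 traits, 3 diet categories."""
    return fixture_dataset(seed=17)


# ---------------------------------------------------------------------------
# oracle helpers
# ---------------------------------------------------------------------------

def bm_on_tree(tree: Phylogeny, sigma: np.ndarray, rng: np.random.Generator,
               root_value: float = 0.0, rate: float = 1.0) -> dict[str, np.ndarray]:
    """Direct multivariate Brownian simulation (independent of the package
    generator): value(child) = value(parent) + MVN(0, rate * sigma * t)."""
    p = sigma.shape[0]
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    values = {tree.root.label: np.full(p, root_value, dtype=float)}
    for parent, child in tree.branches():
        step = np.sqrt(rate * child.length) * (chol @ rng.standard_normal(p))
        values[child.label] = values[parent.label] + step
    return values


def _shapes(n: int):
    """All rooted binary tree shapes with n tips, as nested tuples."""
    if n == 1:
        return [None]
    out = []
    for k in range(1, n // 2 + 1):
        left_shapes = _shapes(k)
        right_shapes = _shapes(n - k)
        for i, left in enumerate(left_shapes):
            rights = right_shapes if k != n - k else right_shapes[i:]
            for right in rights:
                out.append((left, right))
    return out


def all_tree_shapes(n_tips: int, branch_length: float = 1.0) -> list[Phylogeny]:
    """Every rooted binary topology shape with ``n_tips`` tips, unit branches."""

    def _build(shape, counter) -> Node:
        node = Node(length=branch_length)
        if shape is None:
            node.label = f"t{next(counter)}"
            return node
        node.add_child(_build(shape[0], counter))
        node.add_child(_build(shape[1], counter))
        return node

    import itertools

    trees = []
    for shape in _shapes(n_tips):
        counter = itertools.count(1)
        root = _build(shape, counter)
        root.length = 0.0
        trees.append(Phylogeny(root, resolve_polytomies=False))
    return trees


def brute_force_parsimony_cost(tree: Phylogeny, tip_values: dict[str, float],
                               grid: np.ndarray) -> float:
    """Exhaustive grid search over internal-node states, minimal L1 cost."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    g = len(grid)
    m = len(internals)
    idx = {node: i for i, node in enumerate(internals)}
    # state of internal i for combination c: grid[(c // g**i) % g]
    combos = np.arange(g ** m)
    states = grid[(combos[:, None] // g ** np.arange(m)) % g]  # (g^m, m)
    cost = np.zeros(g ** m)
    for parent, child in tree.branches():
        a = states[:, idx[parent]]
        b = states[:, idx[child]] if not child.is_tip else tip_values[child.label]
        cost += np.abs(a - b)
    return float(cost.min())


def brute_force_mk_loglik(tree: Phylogeny, tip_states: dict[str, int],
                          q: np.ndarray, prior: np.ndarray) -> float:
    """Likelihood by summing over every internal-state assignment."""
    from scipy.linalg import expm

    internals = [n for n in tree.postorder() if not n.is_tip]
    s = q.shape[0]
    pmat = {n: expm(q * n.length) for n in tree.postorder()}
    total = 0.0
    m = len(internals)
    for combo in np.ndindex(*([s] * m)):
        assign = {node: combo[i] for i, node in enumerate(internals)}
        like = prior[assign[tree.root]]
        for parent, child in tree.branches():
            a = assign[parent]
            b = assign[child] if not child.is_tip else tip_states[child.label]
            like *= pmat[child][a, b]
        total += like
    return float(np.log(total))
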