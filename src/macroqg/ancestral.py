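"""Ancestral state reconstruction and net selection gradients.

Two reconstructions of ancestral trait means are supported: linear parsimony
(minimum total absolute change, branch lengths ignored; a continuous Sankoff
dynamic program over piecewise-linear convex cost functions) and maximum
likelihood under Brownian motion (equivalently GLS; the re-rooting identity
makes every internal node's estimate the root estimate of the tree re-rooted
there). The per-branch response vector dz = child - parent is then inverted
through the (eigenvalue-extended) within-group matrix of the parent node,
following Lande's multivariate equation beta = W^-1 dz, and the magnitude of
net selection along each branch is the Euclidean norm of the
mean-standardized gradient, a dimensionless quantity comparable across
branches and trait units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .covmat import CovMatrix, MatrixError, extend_matrix
from .tree import Node, Phylogeny, TreeError, pic

logger = logging.getLogger(__name__)

__all__ = [
    "AncestralStates",
    "SelectionEstimate",
    "reconstruct_parsimony",
    "reconstruct_ml_bm",
    "compare_reconstructions",
    "branch_delta_z",
    "selection_gradient",
    "branch_selection_gradients",
    "selection_profile",
]


# ---------------------------------------------------------------------------
# Piecewise-linear convex functions (slope representation)
# ---------------------------------------------------------------------------

class _PWL:
    """Convex piecewise-linear function for the continuous Sankoff recursion.

    Stored as sorted breakpoints ``xs``, interval slopes ``slopes`` (length
    len(xs)+1, non-decreasing) and the value ``v0`` at the first breakpoint.
    """

    __slots__ = ("xs", "slopes", "v0")

    def __init__(self, xs: np.ndarray, slopes: np.ndarray, v0: float):
        self.xs = xs
        self.slopes = slopes
        self.v0 = v0

    @classmethod
    def tip(cls, value: float) -> "_PWL":
        return cls(np.array([value]), np.array([-1.0, 1.0]), 0.0)

    @classmethod
    def zero(cls) -> "_PWL":
        return cls(np.array([0.0]), np.array([0.0, 0.0]), 0.0)

    def value(self, x: float) -> float:
        xs, s = self.xs, self.slopes
        if x <= xs[0]:
            return self.v0 + s[0] * (x - xs[0])
        acc = self.v0
        for i in range(len(xs) - 1):
            if x <= xs[i + 1]:
                return acc + s[i + 1] * (x - xs[i])
            acc += s[i + 1] * (xs[i + 1] - xs[i])
        return acc + s[-1] * (x - xs[-1])

    def _slope_at(self, x: float) -> float:
        # slope on the interval containing x (breakpoints belong rightward)
        idx = int(np.searchsorted(self.xs, x, side="right"))
        return self.slopes[idx]

    def __add__(self, other: "_PWL") -> "_PWL":
        xs = np.union1d(self.xs, other.xs)
        mids = np.concatenate(([xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0, [xs[-1] + 1.0]))
        slopes = np.array([self._slope_at(m) + other._slope_at(m) for m in mids])
        v0 = self.value(xs[0]) + other.value(xs[0])
        return _PWL(xs, slopes, v0)

    def clip(self) -> "_PWL":
        """min-plus convolution with |x - y|: slopes clamped to [-1, 1].

        Where the clamped slope is unchanged the function values are
        preserved, so the value at the first surviving breakpoint can be
        read from the original function.
        """
        s = np.clip(self.slopes, -1.0, 1.0)
        keep = s[1:] != s[:-1]
        if not keep.any():
            lo, _ = self.argmin_interval()
            return _PWL(np.array([lo]), np.array([s[0], s[-1]]), self.min_value())
        xs = self.xs[keep]
        slopes = np.concatenate(([s[0]], s[1:][keep]))
        return _PWL(xs, slopes, self.value(xs[0]))

    def argmin_interval(self) -> tuple[float, float]:
        s = self.slopes
        neg = np.where(s < 0)[0]
        pos = np.where(s > 0)[0]
        lo = self.xs[neg[-1]] if neg.size else self.xs[0]
        hi = self.xs[pos[0] - 1] if pos.size else self.xs[-1]
        return float(lo), float(hi)

    def min_value(self) -> float:
        lo, _ = self.argmin_interval()
        return self.value(lo)


def _parsimony_one_trait(tree: Phylogeny, values: dict[str, float]
                         ) -> tuple[dict[str, float], dict[str, tuple[float, float]], float]:
    """Linear-parsimony states, optimal intervals and minimum cost, one trait."""
    up: dict[Node, _PWL] = {}        # subtree cost function F_u
    msg: dict[Node, _PWL] = {}       # clipped message from u to its parent
    for node in tree.postorder():
        if node.is_tip:
            f = _PWL.tip(values[node.label])
        else:
            f = msg[node.children[0]]
            for c in node.children[1:]:
                f = f + msg[c]
        up[node] = f
        msg[node] = f.clip()

    down: dict[Node, _PWL] = {tree.root: _PWL.zero()}
    for node in tree.preorder():
        for child in node.children:
            g = down[node]
            for sib in node.children:
                if sib is not child:
                    g = g + msg[sib]
            down[child] = g.clip()

    states: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = values[node.label]
            states[node.label] = v
            intervals[node.label] = (v, v)
        else:
            total = up[node] + down[node]
            lo, hi = total.argmin_interval()
            intervals[node.label] = (lo, hi)
            states[node.label] = (lo + hi) / 2.0
    cost = up[tree.root].min_value()
    return states, intervals, cost


@dataclass
class AncestralStates:
    """Reconstructed ancestral trait means for every node of a tree.

    For the parsimony method, per-trait optimal intervals [lo, hi] are kept
    (the point estimate is the interval midpoint and always lies inside);
    ``cost`` is the per-trait minimum total absolute change. Tip values are
    reproduced exactly by both methods.
    """

    method: str  # linear_parsimony | ml_brownian
    states: dict[str, np.ndarray]
    intervals: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    cost: np.ndarray | None = None
    tips: tuple[str, ...] = ()

    def to_frame(self, traits: list[str] | None = None) -> pd.DataFrame:
        labels = list(self.states)
        p = len(next(iter(self.states.values())))
        cols = traits or [f"tr{i+1:02d}" for i in range(p)]
        return pd.DataFrame(
            np.array([self.states[k] for k in labels]), index=labels, columns=cols
        ).rename_axis("node")


def _as_value_matrix(tree: Phylogeny, tip_values: Mapping[str, np.ndarray]
                     ) -> tuple[list[str], np.ndarray]:
    tips = tree.tip_labels
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise TreeError(f"missing tip value(s) for {missing}")
    mat = np.array([np.atleast_1d(np.asarray(tip_values[t], dtype=float))
                    for t in tips])
    return tips, mat


def reconstruct_parsimony(tree: Phylogeny,
                          tip_values: Mapping[str, np.ndarray]) -> AncestralStates:
    """Linear parsimony: minimize total absolute change, per trait.

    Branch lengths are ignored. Implemented as a continuous Sankoff dynamic
    program with convex piecewise-linear cost functions; the point estimate
    at each node is the midpoint of its optimal interval, and the full
    interval is retained so ambiguity can be propagated by the caller.
    """
    tips, mat = _as_value_matrix(tree, tip_values)
    p = mat.shape[1]
    labels = [n.label for n in tree.postorder()]
    states = {lab: np.empty(p) for lab in labels}
    los = {lab: np.empty(p) for lab in labels}
    his = {lab: np.empty(p) for lab in labels}
    costs = np.empty(p)
    for k in range(p):
        vals = {t: mat[i, k] for i, t in enumerate(tips)}
        st, iv, cost = _parsimony_one_trait(tree, vals)
        costs[k] = cost
        for lab in labels:
            states[lab][k] = st[lab]
            los[lab][k], his[lab][k] = iv[lab]
    intervals = {lab: (los[lab], his[lab]) for lab in labels}
    return AncestralStates(method="linear_parsimony", states=states,
                           intervals=intervals, cost=costs,
                           tips=tuple(tips))


def reconstruct_ml_bm(tree: Phylogeny,
                      tip_values: Mapping[str, np.ndarray]) -> AncestralStates:
    """Maximum-likelihood ancestral means under Brownian motion.

    Equivalent to GLS with the tree covariance; computed by two-pass message
    passing, which realizes the re-rooting identity (each node's estimate is
    the PIC root value of the tree re-rooted at that node) in linear time.
    The root estimate coincides with the PIC recursion's root value.
    """
    tips, mat = _as_value_matrix(tree, tip_values)
    p = mat.shape[1]
    eps = 1e-8 * tree.depth if tree.depth > 0 else 1e-8
    tip_index = {t: i for i, t in enumerate(tips)}

    up_val: dict[Node, np.ndarray] = {}
    up_var: dict[Node, float] = {}

    def _blen(node: Node) -> float:
        return max(node.length, eps)

    for node in tree.postorder():
        if node.is_tip:
            up_val[node] = mat[tip_index[node.label]]
            up_var[node] = _blen(node)
        else:
            prec = np.array([1.0 / up_var[c] for c in node.children])
            vals = np.array([up_val[c] for c in node.children])
            combined = (prec[:, None] * vals).sum(axis=0) / prec.sum()
            extra = 1.0 / prec.sum()
            up_val[node] = combined
            up_var[node] = (_blen(node) if node.parent is not None else 0.0) + extra

    # downward messages: estimate of the node state from everything outside
    # its subtree, with its variance
    down_val: dict[Node, np.ndarray] = {}
    down_var: dict[Node, float] = {}
    states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            down_val[node] = np.zeros(p)
            down_var[node] = np.inf
        else:
            parent = node.parent
            entries = []
            if np.isfinite(down_var[parent]):
                entries.append((down_val[parent], down_var[parent]))
            for sib in parent.children:
                if sib is not node:
                    entries.append((up_val[sib], up_var[sib]))
            prec = np.array([1.0 / v for _, v in entries])
            vals = np.array([v for v, _ in entries])
            at_parent = (prec[:, None] * vals).sum(axis=0) / prec.sum()
            down_val[node] = at_parent
            down_var[node] = 1.0 / prec.sum() + _blen(node)

        if node.is_tip:
            states[node.label] = mat[tip_index[node.label]].copy()
        else:
            entries = [(up_val[c], up_var[c]) for c in node.children]
            if np.isfinite(down_var[node]):
                entries.append((down_val[node], down_var[node]))
            prec = np.array([1.0 / v for _, v in entries])
            vals = np.array([v for v, _ in entries])
            states[node.label] = (prec[:, None] * vals).sum(axis=0) / prec.sum()

    # keep postorder key order for readability
    ordered = {n.label: states[n.label] for n in tree.postorder()}
    return AncestralStates(method="ml_brownian", states=ordered,
                           tips=tuple(tips))


def compare_reconstructions(a: AncestralStates, b: AncestralStates) -> float:
    """Pearson correlation of the two reconstructions over internal states.

    Computed across all (node, trait) pairs shared by both state sets,
    excluding tips (which both methods reproduce exactly, trivially
    inflating agreement).
    """
    if set(a.states) != set(b.states):
        raise TreeError("reconstructions cover different node sets")
    # tips have identical values in both methods by construction; restrict
    # to genuinely estimated (internal) nodes
    skip = set(a.tips) | set(b.tips)
    keys = [k for k in a.states if k not in skip]
    if not keys:
        raise TreeError("no internal nodes shared by the reconstructions")
    xa = np.concatenate([np.asarray(a.states[k], dtype=float) for k in keys])
    xb = np.concatenate([np.asarray(b.states[k], dtype=float) for k in keys])
    return float(np.corrcoef(xa, xb)[0, 1])


def branch_delta_z(states: AncestralStates, tree: Phylogeny
                   ) -> dict[tuple[str, str], np.ndarray]:
    """Response vector dz = child state - parent state, for every branch."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for parent, child in tree.branches():
        if parent.label not in states.states or child.label not in states.states:
            raise TreeError(f"states missing for branch {parent.label}->{child.label}")
        out[(parent.label, child.label)] = (
            np.asarray(states.states[child.label], dtype=float)
            - np.asarray(states.states[parent.label], dtype=float)
        )
    return out


@dataclass
class SelectionEstimate:
    """Net directional selection along one branch.

    ``beta`` solves W_ext beta = dz (Lande's equation with the extended
    within-group matrix); ``beta_mu`` is the mean-standardized gradient
    (beta_i times the ancestral mean of trait i, Hansen-Houle convention)
    whose Euclidean norm ``magnitude`` is the dimensionless strength of
    selection on the branch.
    """

    branch: tuple[str, str] | None
    delta_z: np.ndarray
    beta: np.ndarray
    beta_mu: np.ndarray | None
    magnitude: float
    w_provenance: str | None = None
    cutoff: int | None = None


def selection_gradient(delta_z: np.ndarray, w: CovMatrix, *,
                       extend: bool = True, mean: np.ndarray | None = None,
                       branch: tuple[str, str] | None = None,
                       tol: float = 1e-4) -> SelectionEstimate:
    """Net selection gradient beta = W^-1 dz for a single branch.

    Solved through the eigendecomposition of W (no explicit inverse); with
    ``extend`` the eigenvalue-extended matrix is inverted, which is the
    recommended guard against noise-dominated trailing eigenvalues. ``mean``
    is the ancestral (parent-node) trait mean used for mean-standardization;
    if omitted, ``beta_mu`` is None and the magnitude is the raw norm of
    beta.
    """
    dz = np.asarray(delta_z, dtype=float)
    w_use = extend_matrix(w, tol=tol) if extend and w.role != "W_ext" else w
    lam, vec = w_use.eigh()
    if lam[0] <= 0 or lam[-1] <= 1e-14 * lam[0]:
        raise MatrixError(
            "W is singular after extension; lower the cutoff rank or tolerance"
        )
    beta = vec @ ((vec.T @ dz) / lam)
    if mean is not None:
        beta_mu = beta * np.asarray(mean, dtype=float)
        magnitude = float(np.linalg.norm(beta_mu))
    else:
        beta_mu = None
        magnitude = float(np.linalg.norm(beta))
    return SelectionEstimate(
        branch=branch, delta_z=dz, beta=beta, beta_mu=beta_mu,
        magnitude=magnitude, w_provenance=w_use.provenance,
        cutoff=w_use.cutoff,
    )


def branch_selection_gradients(tree: Phylogeny, states: AncestralStates,
                               w_by_node: Mapping[str, CovMatrix], *,
                               extend: bool = True, tol: float = 1e-4,
                               convention: str = "parent",
                               standardize: bool = True,
                               ) -> dict[tuple[str, str], SelectionEstimate]:
    """Selection gradients for every branch of the tree.

    ``convention`` picks whose pooled W is inverted on a branch: the parent
    node's (the ancestral population whose covariance shaped the response,
    the default) or the child's. The ancestral mean used for
    mean-standardization is always the parent state.
    """
    if convention not in ("parent", "child"):
        raise ValueError(f"unknown W convention {convention!r}")
    deltas = branch_delta_z(states, tree)
    extended: dict[str, CovMatrix] = {}

    def _w(label: str) -> CovMatrix:
        if label not in extended:
            w = w_by_node[label]
            extended[label] = extend_matrix(w, tol=tol) if extend else w
        return extended[label]

    out: dict[tuple[str, str], SelectionEstimate] = {}
    for (parent, child), dz in deltas.items():
        w = _w(parent if convention == "parent" else child)
        mean = states.states[parent] if standardize else None
        out[(parent, child)] = selection_gradient(
            dz, w, extend=False, mean=mean, branch=(parent, child))
    return out


def selection_profile(tree: Phylogeny,
                      estimates: Mapping[tuple[str, str], SelectionEstimate],
                      clade: "str | None" = None) -> pd.DataFrame:
    """Tidy per-branch table of selection magnitudes.

    Columns: parent, child, branch length, midpoint time from the root, and
    the mean-standardized magnitude; suitable for tree-painted and
    magnitude-versus-time plots. ``clade`` restricts to the subtree of the
    given node.
    """
    depths = tree.depths()
    keep_tips = tree.clade_tips(clade) if clade is not None else None
    rows = []
    for parent, child in tree.branches():
        key = (parent.label, child.label)
        if key not in estimates:
            raise TreeError(f"no selection estimate for branch {key}")
        if keep_tips is not None and not (tree.clade_tips(parent) <= keep_tips):
            continue
        est = estimates[key]
        rows.append({
            "parent": parent.label,
            "child": child.label,
            "length": child.length,
            "midpoint_time": depths[parent.label] + child.length / 2.0,
            "magnitude": est.magnitude,
        })
    return pd.DataFrame(rows, columns=["parent", "child", "length",
                                       "midpoint_time", "magnitude"])
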