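"""Mk models for discrete diet categories on a phylogeny.

Feeding specialization is coded as one of eight categories per species;
continuous-time Markov (Mk) models with equal (ER), symmetric (SYM) or
all-different (ARD) transition rates are fitted by maximum likelihood
(Felsenstein pruning), compared by AIC, and marginal ancestral state
probabilities annotate branches where the most probable diet changes — the
dietary-transition branches against which selection magnitudes are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from .tree import Node, Phylogeny, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "DIET_CATEGORIES",
    "DietStateMap",
    "MkFit",
    "MarginalStates",
    "build_q",
    "n_free_rates",
    "mk_loglik",
    "mk_fit",
    "compare_mk_models",
    "mk_marginal_states",
]

DIET_CATEGORIES = (
    "insectivory",
    "strict insectivory",
    "hematophagy",
    "omnivory",
    "carnivory",
    "nectarivory",
    "frugivory",
    "obligate frugivory",
)

_MODELS = ("ER", "SYM", "ARD")


@dataclass
class DietStateMap:
    """Tip -> diet category assignment over an ordered category list."""

    categories: tuple[str, ...] = DIET_CATEGORIES
    states: dict[str, str] | None = None
    node_states: dict[str, str] | None = None  # true states when simulated

    def __post_init__(self):
        self.categories = tuple(self.categories)
        self.states = dict(self.states or {})
        for tip, cat in self.states.items():
            if cat not in self.categories:
                raise ValueError(
                    f"tip {tip!r} has state {cat!r} not in the category list"
                )

    def index_of(self, tip: str) -> int:
        return self.categories.index(self.states[tip])

    @property
    def n_states(self) -> int:
        return len(self.categories)

    def observed_categories(self) -> list[str]:
        return sorted(set(self.states.values()), key=self.categories.index)


def n_free_rates(model: str, s: int) -> int:
    """Free rate parameters: ER 1, SYM s(s-1)/2, ARD s(s-1)."""
    if model == "ER":
        return 1
    if model == "SYM":
        return s * (s - 1) // 2
    if model == "ARD":
        return s * (s - 1)
    raise ValueError(f"unknown Mk model {model!r}")


def build_q(model: str, rates: np.ndarray, s: int) -> np.ndarray:
    """Rate matrix Q from the free-rate vector; rows sum to zero."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (n_free_rates(model, s),):
        raise ValueError(
            f"{model} with {s} states needs {n_free_rates(model, s)} rates, "
            f"got {rates.shape}"
        )
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    q = np.zeros((s, s))
    if model == "ER":
        q[:] = rates[0]
    elif model == "SYM":
        iu = np.triu_indices(s, k=1)
        q[iu] = rates
        q.T[iu] = rates
    else:  # ARD
        mask = ~np.eye(s, dtype=bool)
        q[mask] = rates
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    off = q[~np.eye(q.shape[0], dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("Q off-diagonals must be non-negative")
    if np.max(np.abs(q.sum(axis=1))) > 1e-10:
        raise ValueError("Q rows must sum to zero")
    return q


def _transition_matrices(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for every branch length, via eigendecomposition.

    Falls back to scipy expm when Q is defective or badly conditioned.
    """
    s = q.shape[0]
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) < 1e10:
            e = np.exp(np.outer(lengths, w))  # (m, s)
            mats = np.einsum("ij,mj,jk->mik", v, e, vinv).real
        else:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        mats = np.array([linalg.expm(q * t) for t in lengths])
    mats = np.clip(mats, 0.0, None)
    mats /= mats.sum(axis=2, keepdims=True)
    return mats


def _pruning(tree: Phylogeny, states: DietStateMap, q: np.ndarray
             ) -> tuple[dict[Node, np.ndarray], float, dict[Node, np.ndarray]]:
    """Scaled partial likelihoods per node, total log scale, branch P matrices."""
    s = q.shape[0]
    nodes = list(tree.postorder())
    lengths = np.array([n.length for n in nodes])
    pmats = _transition_matrices(q, lengths)
    pmat_of = {n: pmats[i] for i, n in enumerate(nodes)}

    partial: dict[Node, np.ndarray] = {}
    logscale = 0.0
    for node in nodes:
        if node.is_tip:
            if node.label not in states.states:
                raise TreeError(f"no diet state for tip {node.label!r}")
            vec = np.zeros(s)
            vec[states.index_of(node.label)] = 1.0
        else:
            vec = np.ones(s)
            for c in node.children:
                vec = vec * (pmat_of[c] @ partial[c])
        top = vec.max()
        if top <= 0:
            return partial, -np.inf, pmat_of
        partial[node] = vec / top
        logscale += np.log(top)
    return partial, logscale, pmat_of


def mk_loglik(tree: Phylogeny, states: DietStateMap, q: np.ndarray,
              root_prior: np.ndarray | None = None) -> float:
    """Log-likelihood of tip states under rate matrix Q (pruning algorithm)."""
    q = _validate_q(q)
    s = q.shape[0]
    if s != states.n_states:
        raise ValueError("Q dimension does not match the category list")
    prior = (np.full(s, 1.0 / s) if root_prior is None
             else np.asarray(root_prior, dtype=float))
    if abs(prior.sum() - 1.0) > 1e-8:
        raise ValueError("root prior must sum to 1")
    partial, logscale, _ = _pruning(tree, states, q)
    if not np.isfinite(logscale):
        return -np.inf
    root_l = float(prior @ partial[tree.root])
    if root_l <= 0:
        return -np.inf
    return float(np.log(root_l) + logscale)


@dataclass
class MkFit:
    """A fitted Mk model: rates, likelihood, AIC and node marginals."""

    model: str
    q: np.ndarray
    loglik: float
    k: int
    aic: float
    rates: np.ndarray
    root_prior: np.ndarray
    categories: tuple[str, ...]
    converged: bool = True


_LOG_RATE_BOUNDS = (-12.0, 6.0)


def mk_fit(tree: Phylogeny, states: DietStateMap, model: str = "ER", *,
           n_starts: int = 5, seed: int = 0,
           root_prior: np.ndarray | None = None) -> MkFit:
    """Maximum-likelihood Mk fit by bounded quasi-Newton from multiple starts.

    Rates are optimized on the log scale with L-BFGS-B; ``n_starts`` jittered
    starting points (seeded, logged) guard against local optima. With fewer
    than two observed categories a degenerate fit at the rate lower bound is
    returned with a warning.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown Mk model {model!r}")
    s = states.n_states
    k = n_free_rates(model, s)
    prior = (np.full(s, 1.0 / s) if root_prior is None
             else np.asarray(root_prior, dtype=float))

    if len(states.observed_categories()) < 2:
        logger.warning("single observed category: degenerate %s fit at the "
                       "rate lower bound", model)
        rates = np.full(k, np.exp(_LOG_RATE_BOUNDS[0]))
        q = build_q(model, rates, s)
        ll = mk_loglik(tree, states, q, prior)
        return MkFit(model=model, q=q, loglik=ll, k=k, aic=2 * k - 2 * ll,
                     rates=rates, root_prior=prior,
                     categories=states.categories, converged=True)

    total_len = sum(n.length for n in tree.postorder() if n.parent is not None)
    base = np.log(max(len(states.states) / max(total_len, 1e-9), 1e-6))

    def negll(theta: np.ndarray) -> float:
        q = build_q(model, np.exp(theta), s)
        ll = mk_loglik(tree, states, q, prior)
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for start in range(n_starts):
        x0 = np.full(k, base) + (rng.normal(0, 1.0, k) if start else 0.0)
        x0 = np.clip(x0, *_LOG_RATE_BOUNDS)
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B",
            bounds=[_LOG_RATE_BOUNDS] * k,
        )
        logger.info("mk_fit %s start %d (seed %d): nll=%.6f success=%s",
                    model, start, seed, res.fun, res.success)
        if res.success or np.isfinite(res.fun):
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_ok == 0:
        raise RuntimeError(
            f"Mk optimizer failed in all {n_starts} starts for {model}: {best}"
        )
    rates = np.exp(best.x)
    q = build_q(model, rates, s)
    ll = float(-best.fun)
    return MkFit(model=model, q=q, loglik=ll, k=k, aic=2 * k - 2 * ll,
                 rates=rates, root_prior=prior, categories=states.categories,
                 converged=bool(best.success))


def compare_mk_models(tree: Phylogeny, states: DietStateMap, *,
                      models: Sequence[str] = _MODELS, n_starts: int = 5,
                      seed: int = 0) -> list[MkFit]:
    """Fit the requested Mk models and return them ranked by AIC."""
    fits = [mk_fit(tree, states, m, n_starts=n_starts, seed=seed)
            for m in models]
    return sorted(fits, key=lambda f: f.aic)


@dataclass
class MarginalStates:
    """Marginal ancestral state probabilities and dietary-transition flags."""

    probabilities: dict[str, np.ndarray]
    categories: tuple[str, ...]
    transitions: list[tuple[str, str]]

    def argmax(self, node: str) -> str:
        return self.categories[int(np.argmax(self.probabilities[node]))]


def mk_marginal_states(fit: MkFit, tree: Phylogeny,
                       states: DietStateMap) -> MarginalStates:
    """Marginal ancestral probabilities under a fitted Mk model.

    Downward partial likelihoods are combined with upward messages (the
    likelihood of everything outside each node's subtree), giving the exact
    marginal posterior per node; branches where the most probable state
    changes between parent and child are flagged as transitions. This is a
    deterministic summary of the same quantity stochastic character maps
    sample.
    """
    q = _validate_q(fit.q)
    partial, logscale, pmat_of = _pruning(tree, states, q)
    if not np.isfinite(logscale):
        raise RuntimeError("zero likelihood: cannot compute marginals")
    prior = fit.root_prior

    above: dict[Node, np.ndarray] = {tree.root: prior.copy()}
    probs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is not None:
            parent = node.parent
            msg = above[parent].copy()
            for sib in parent.children:
                if sib is not node:
                    msg = msg * (pmat_of[sib] @ partial[sib])
            vec = msg @ pmat_of[node]
            top = vec.max()
            above[node] = vec / top if top > 0 else vec
        post = above[node] * partial[node]
        total = post.sum()
        probs[node.label] = post / total if total > 0 else post

    transitions = [
        (p.label, c.label) for p, c in tree.branches()
        if int(np.argmax(probs[p.label])) != int(np.argmax(probs[c.label]))
    ]
    return MarginalStates(probabilities=probs, categories=fit.categories,
                          transitions=transitions)
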