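"""Within-species covariance estimation, node-wise pooling and noise control.

Specimen-level trait tables (linear cranial distances measured twice per
specimen, with nuisance factors such as sex and locality) are turned into
per-species phenotypic covariance matrices (P), controlling for significant
nuisance factors through MANOVA model selection. P-matrices stand in for the
additive-genetic matrix G under the assumption of proportionality. They are
pooled along the tree into ancestral within-group matrices (W), with a
fallback for species sampled too thinly to estimate their own matrix, and an
eigenvalue-extension step tames the trailing noise eigenvalues before W is
inverted downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import Phylogeny, Node, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "CovMatrix",
    "MatrixError",
    "ID_COLUMNS",
    "trait_columns",
    "average_replicates",
    "repeatability",
    "estimate_p_matrix",
    "pool_w_matrices",
    "pool_w_matrix",
    "extend_matrix",
]

ID_COLUMNS = ("species", "specimen", "replicate")


class MatrixError(ValueError):
    """Covariance matrix could not be estimated or is invalid."""


@dataclass
class CovMatrix:
    """A p x p symmetric PSD matrix with a role tag and provenance.

    role is one of ``P`` (within-species phenotypic), ``W`` (pooled ancestral
    within-group), ``B`` (between-species) or ``W_ext`` (eigenvalue-extended
    W). ``n`` is the sample size behind the estimate; ``cutoff`` is the
    extension cutoff rank for ``W_ext``.
    """

    values: np.ndarray
    role: str = "P"
    provenance: str | None = None
    n: int | None = None
    traits: tuple[str, ...] | None = None
    cutoff: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixError(f"expected a square matrix, got shape {v.shape}")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        scale = np.max(np.abs(v)) if v.size else 0.0
        if scale > 0 and asym > 1e-8 * scale:
            raise MatrixError(f"matrix is not symmetric (max asymmetry {asym:g})")
        self.values = (v + v.T) / 2.0
        if self.traits is not None:
            self.traits = tuple(self.traits)
            if len(self.traits) != v.shape[0]:
                raise MatrixError("trait names do not match matrix dimension")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition with eigenvalues in descending order."""
        lam, vec = np.linalg.eigh(self.values)
        order = np.argsort(lam)[::-1]
        return lam[order], vec[:, order]

    def is_psd(self, rtol: float = 1e-10) -> bool:
        lam = np.linalg.eigvalsh(self.values)
        lead = lam.max(initial=0.0)
        return bool(lam.min(initial=0.0) >= -rtol * max(lead, 1.0))

    # -- plain-text round trip -------------------------------------------

    def to_csv(self, path) -> None:
        names = self.traits or tuple(f"tr{i+1:02d}" for i in range(self.p))
        meta = f"# role={self.role} provenance={self.provenance or ''} n={self.n or ''}"
        if self.cutoff is not None:
            meta += f" cutoff={self.cutoff}"
        with open(path, "w") as fh:
            fh.write(meta + "\n")
            pd.DataFrame(self.values, index=names, columns=names).to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "CovMatrix":
        with open(path) as fh:
            meta_line = fh.readline().strip().lstrip("#").split()
            meta = dict(item.split("=", 1) for item in meta_line)
            frame = pd.read_csv(fh, index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            role=meta.get("role", "P"),
            provenance=meta.get("provenance") or None,
            n=int(meta["n"]) if meta.get("n") else None,
            traits=tuple(frame.columns),
            cutoff=int(meta["cutoff"]) if meta.get("cutoff") else None,
        )


# ---------------------------------------------------------------------------
# Specimen-table utilities
# ---------------------------------------------------------------------------

def trait_columns(table: pd.DataFrame,
                  factors: Sequence[str] = ()) -> list[str]:
    """Columns holding trait values: numeric columns that are not ids or
    factors. Non-numeric undeclared columns are treated as metadata."""
    skip = set(ID_COLUMNS) | set(factors)
    cols = [c for c in table.columns if c not in skip]
    meta = [c for c in cols if not pd.api.types.is_numeric_dtype(table[c])]
    if meta:
        logger.debug("ignoring non-numeric metadata columns %s", meta)
    return [c for c in cols if c not in meta]


def _drop_incomplete(table: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    mask = table[list(traits)].notna().all(axis=1)
    if not mask.all():
        logger.info("dropped %d rows with missing trait values", (~mask).sum())
    return table.loc[mask]


def average_replicates(table: pd.DataFrame,
                       factors: Sequence[str] = ()) -> pd.DataFrame:
    """One row per specimen: trait values averaged across replicates.

    Factor columns are carried through (first value per specimen). Specimens
    with a single replicate pass through unchanged.
    """
    traits = trait_columns(table, factors)
    table = _drop_incomplete(table, traits)
    keys = [c for c in ("species", "specimen") if c in table.columns]
    if not keys:
        raise MatrixError("table needs 'species' and/or 'specimen' columns")
    agg = {c: "mean" for c in traits}
    agg.update({c: "first" for c in factors if c in table.columns})
    out = table.groupby(keys, sort=False, as_index=False).agg(agg)
    return out


def repeatability(table: pd.DataFrame,
                  factors: Sequence[str] = ()) -> pd.Series:
    """Per-trait intraclass correlation from a one-way specimen ANOVA.

    ICC = (MS_among - MS_within) / (MS_among + (k - 1) MS_within), with k the
    (effective) number of replicates per specimen, clipped to [0, 1]. High
    values mean the double digitization of each specimen is reliable.
    """
    traits = trait_columns(table, factors)
    table = _drop_incomplete(table, traits)
    if "specimen" not in table.columns:
        raise MatrixError("repeatability needs a 'specimen' column")
    keys = [c for c in ("species", "specimen") if c in table.columns]
    groups = table.groupby(keys, sort=False)
    sizes = groups.size().to_numpy()
    replicated = sizes[sizes >= 2]
    if len(replicated) < 2:
        raise MatrixError(
            "repeatability needs >= 2 replicates for >= 2 specimens"
        )
    a = len(sizes)
    n_total = sizes.sum()
    # Effective replicates per specimen (exact k for balanced designs).
    k0 = (n_total - (sizes ** 2).sum() / n_total) / (a - 1)

    x = table[traits].to_numpy(dtype=float)
    grand = x.mean(axis=0)
    means = groups[traits].mean()
    group_means = means.to_numpy(dtype=float)
    ss_among = (sizes[:, None] * (group_means - grand) ** 2).sum(axis=0)
    centered = table[traits] - groups[traits].transform("mean")
    ss_within = (centered.to_numpy(dtype=float) ** 2).sum(axis=0)
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / max(n_total - a, 1)
    icc = (ms_among - ms_within) / (ms_among + (k0 - 1) * ms_within)
    icc = np.clip(np.where(np.isfinite(icc), icc, 0.0), 0.0, 1.0)
    return pd.Series(icc, index=traits, name="repeatability")


# ---------------------------------------------------------------------------
# P-matrix estimation with MANOVA factor screening
# ---------------------------------------------------------------------------

def _design_matrix(table: pd.DataFrame, terms: Sequence[object]) -> np.ndarray:
    """Intercept + dummy-coded columns for the given terms.

    A term is a factor name or a tuple of two factor names (interaction).
    """
    n = len(table)
    cols = [np.ones((n, 1))]
    for term in terms:
        if isinstance(term, tuple):
            combined = table[term[0]].astype(str) + "\x1f" + table[term[1]].astype(str)
            dummies = pd.get_dummies(combined, drop_first=True)
        else:
            dummies = pd.get_dummies(table[term].astype(str), drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols)


def _residual_sscp(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual cross-product matrix and the rank of the design."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.T @ resid, int(rank)


def _wilks_test(y: np.ndarray, x_full: np.ndarray,
                x_reduced: np.ndarray) -> tuple[float, float]:
    """Wilks' lambda and its Rao-F p-value for the extra term in x_full."""
    e_full, rank_full = _residual_sscp(y, x_full)
    e_red, rank_red = _residual_sscp(y, x_reduced)
    q = rank_full - rank_red
    n, p = y.shape
    v = n - rank_full
    if q <= 0 or v <= p:
        return np.nan, 1.0
    h = e_red - e_full
    sign_f, logdet_f = np.linalg.slogdet(e_full)
    sign_t, logdet_t = np.linalg.slogdet(e_full + h)
    if sign_f <= 0 or sign_t <= 0:
        return np.nan, 1.0
    lam = float(np.exp(logdet_f - logdet_t))
    # Rao's F approximation.
    pq = p * q
    denom = p ** 2 + q ** 2 - 5
    t = np.sqrt((p ** 2 * q ** 2 - 4) / denom) if denom > 0 else 1.0
    w = v - (p - q + 1) / 2.0
    df2 = w * t - (pq - 2) / 2.0
    if df2 <= 0:
        return lam, 1.0
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / pq
    pval = float(stats.f.sf(f, pq, df2))
    return lam, pval


def _usable_factors(table: pd.DataFrame, factors: Sequence[str]) -> list[str]:
    usable = []
    for f in factors:
        if f not in table.columns:
            logger.info("factor %r not in table: skipped", f)
            continue
        counts = table[f].value_counts()
        if (counts >= 2).sum() >= 2:
            usable.append(f)
        else:
            logger.info("factor %r lacks >= 2 levels with >= 2 specimens: dropped", f)
    return usable


def estimate_p_matrix(table: pd.DataFrame,
                      factors: Sequence[str] = (),
                      alpha: float = 0.05) -> CovMatrix:
    """Within-species phenotypic covariance (P), nuisance factors controlled.

    Each candidate term (factor main effects and their pairwise interactions)
    is tested by MANOVA with Wilks' lambda at ``alpha`` (Type II marginal
    tests); the retained linear model contains significant terms only, with
    an interaction kept only when both of its main effects are retained. P is
    the residual cross-product matrix of the retained model divided by
    (n - rank of design). With no significant term, P is the plain sample
    covariance (divisor n - 1).
    """
    traits = trait_columns(table, factors)
    table = average_replicates(table, factors)
    n = len(table)
    if n < 2:
        raise MatrixError(f"cannot estimate a covariance matrix from n={n}")
    species = None
    if "species" in table.columns:
        uniq = table["species"].unique()
        if len(uniq) == 1:
            species = str(uniq[0])
    y = table[traits].to_numpy(dtype=float)
    p = len(traits)

    def _raw() -> CovMatrix:
        values = np.cov(y, rowvar=False, ddof=1).reshape(p, p)
        return CovMatrix(values=values, role="P", provenance=species,
                         n=n, traits=tuple(traits))

    usable = _usable_factors(table, factors)
    if not usable:
        return _raw()
    if n <= p + 1:
        logger.warning(
            "n=%d too small relative to p=%d for MANOVA screening; "
            "falling back to raw covariance", n, p)
        return _raw()

    mains = list(usable)
    interactions = [(a, b) for i, a in enumerate(mains) for b in mains[i + 1:]]

    # Type II marginal tests: each main against the all-mains model,
    # each interaction against all mains + that interaction.
    x_mains = _design_matrix(table, mains)
    sig_mains = []
    for f in mains:
        reduced = _design_matrix(table, [g for g in mains if g != f])
        lam, pval = _wilks_test(y, x_mains, reduced)
        logger.info("MANOVA %s: Wilks lambda=%.4g p=%.4g", f, lam, pval)
        if pval < alpha:
            sig_mains.append(f)
    sig_inter = []
    for pair in interactions:
        full = _design_matrix(table, mains + [pair])
        lam, pval = _wilks_test(y, full, x_mains)
        logger.info("MANOVA %s: Wilks lambda=%.4g p=%.4g", ":".join(pair), lam, pval)
        if pval < alpha and pair[0] in sig_mains and pair[1] in sig_mains:
            sig_inter.append(pair)

    retained: list[object] = list(sig_mains) + list(sig_inter)
    if not retained:
        return _raw()
    x_ret = _design_matrix(table, retained)
    sscp, rank = _residual_sscp(y, x_ret)
    if rank >= n:
        logger.warning("design rank %d >= n=%d: falling back to raw covariance",
                       rank, n)
        return _raw()
    values = sscp / (n - rank)
    return CovMatrix(values=values, role="P", provenance=species,
                     n=n, traits=tuple(traits))


# ---------------------------------------------------------------------------
# Node-wise pooling into W-matrices
# ---------------------------------------------------------------------------

def pool_w_matrices(tree: Phylogeny,
                    p_matrices: Mapping[str, CovMatrix],
                    sample_sizes: Mapping[str, int],
                    min_n: int = 35) -> dict[str, CovMatrix]:
    """Ancestral within-group matrix (W) for every node of the tree.

    W(node) is the average of the species P-matrices over the node's clade,
    weighted by (n_k - 1). Species with fewer than ``min_n`` specimens do not
    contribute their own (unreliable) P; their slot is filled by the W of
    their immediate ancestral node, which is computed first from adequately
    sampled species (top-down fill for clades with none).
    """
    tips_all = set(tree.tip_labels)
    for t in tips_all:
        if t not in sample_sizes:
            raise MatrixError(f"no sample size for species {t!r}")
    usable = {t for t in tips_all
              if sample_sizes[t] >= min_n and t in p_matrices}
    small = tips_all - usable
    for t in small:
        if sample_sizes[t] >= min_n:
            raise MatrixError(f"no P-matrix for adequately sampled species {t!r}")
        logger.info("species %r has n=%d < %d: replaced by its ancestral node W",
                    t, sample_sizes[t], min_n)
    if not usable:
        raise MatrixError(
            f"no species with n >= {min_n}; cannot pool any W matrix"
        )

    some_p = next(iter(p_matrices.values()))
    p = some_p.p
    traits = some_p.traits

    def _pool(entries: list[tuple[np.ndarray, float]]) -> np.ndarray:
        wsum = sum(w for _, w in entries)
        acc = np.zeros((p, p))
        for m, w in entries:
            acc += w * m
        return acc / wsum

    # Pass 1: pool adequately sampled species only.
    base: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        clade = tree.clade_tips(node)
        entries = [(p_matrices[t].values, sample_sizes[t] - 1.0)
                   for t in clade if t in usable]
        if entries:
            base[node.label] = _pool(entries)
    # Top-down fill for clades with no usable species.
    for node in tree.preorder():
        if node.label not in base:
            if node.parent is None:
                raise MatrixError("root clade has no usable species")  # pragma: no cover
            base[node.label] = base[node.parent.label]

    # Pass 2: re-pool with small species contributing their parent's base W.
    def _tip_matrix(tip: str) -> np.ndarray:
        if tip in usable:
            return p_matrices[tip].values
        parent = tree.node(tip).parent
        return base[parent.label if parent is not None else tree.root.label]

    out: dict[str, CovMatrix] = {}
    for node in tree.postorder():
        clade = tree.clade_tips(node)
        entries = [(_tip_matrix(t), max(sample_sizes[t] - 1.0, 1.0))
                   for t in clade]
        n_used = int(sum(sample_sizes[t] for t in clade))
        out[node.label] = CovMatrix(values=_pool(entries), role="W",
                                    provenance=node.label, n=n_used,
                                    traits=traits)
    return out


def pool_w_matrix(tree: Phylogeny, node: "str | Node",
                  p_matrices: Mapping[str, CovMatrix],
                  sample_sizes: Mapping[str, int],
                  min_n: int = 35) -> CovMatrix:
    """W-matrix for a single node (see :func:`pool_w_matrices`)."""
    label = tree.node(node).label
    return pool_w_matrices(tree, p_matrices, sample_sizes, min_n)[label]


# ---------------------------------------------------------------------------
# Eigenvalue extension (noise control before inversion)
# ---------------------------------------------------------------------------

def extend_matrix(w: CovMatrix, tol: float = 1e-4, window: int = 4,
                  rank: int | None = None) -> CovMatrix:
    """Raise trailing noise eigenvalues of W to the last stable one.

    The scree of eigenvalues (descending) is scanned with its second
    differences d_j = lam_{j+1} - 2 lam_j + lam_{j-1}; the cutoff rank j* is
    the smallest j >= 3 for which the window of ``window`` second differences
    following j (d_{j+1}, ..., truncated at the end) has variance below
    ``tol * lam_1**2`` — i.e. the scree has stabilized beyond j. Eigenvalues
    past j* are replaced by lam_{j*} and the matrix is rebuilt with its
    original eigenvectors, which bounds the condition number before the
    inverse is taken in the selection-gradient step. ``rank`` overrides the
    automatic cutoff.
    """
    p = w.p
    if p < 5 and rank is None:
        logger.warning("extend_matrix: p=%d < 5, scree too short; returning input", p)
        return replace(w, role="W_ext", cutoff=None)
    lam, vec = w.eigh()
    lam1 = lam[0]
    if lam1 <= 0:
        raise MatrixError("extend_matrix needs a PSD matrix with lam_1 > 0")

    if rank is not None:
        if not 1 <= rank <= p:
            raise MatrixError(f"cutoff rank {rank} outside 1..{p}")
        jstar = rank
    else:
        # Second differences, 1-based index j = 2 .. p-1.
        d = lam[2:] - 2 * lam[1:-1] + lam[:-2]
        jstar = p - 1
        for j in range(3, p):  # 1-based candidate cutoffs
            seg = d[j - 1: j - 1 + window]  # d_{j+1} .. d_{j+w}, truncated
            var = float(np.var(seg)) if seg.size > 1 else 0.0
            if var < tol * lam1 ** 2:
                jstar = j
                break

    lam_ext = lam.copy()
    lam_ext[jstar:] = lam[jstar - 1]
    values = (vec * lam_ext) @ vec.T
    return CovMatrix(values=values, role="W_ext", provenance=w.provenance,
                     n=w.n, traits=w.traits, cutoff=jstar)
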