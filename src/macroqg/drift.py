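"""Neutrality tests for multivariate divergence on a phylogeny.

Under pure genetic drift the between-species covariance B is proportional to
the (ancestral) within-group covariance W. Two complementary tests probe this
at every internal node:

* the **regression test** regresses log between-group variances of species
  scores on the principal components of W against the log eigenvalues of W;
  under drift the slope is 1, and a 95% confidence interval excluding 1
  rejects drift (slopes above 1 point at diversifying selection on leading
  PCs, below 1 at divergence along minor PCs);

* the **correlation test** looks for correlations between species scores on
  distinct (orthogonal) PCs of W, computed on phylogenetic independent
  contrasts: any such correlation implies co-selection, since drift cannot
  correlate uncorrelated dimensions.

Between-group variances are computed from phylogenetic independent contrasts
of the PC scores on the subtree of the node, removing phylogenetic
pseudo-replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .covmat import CovMatrix
from .tree import Node, Phylogeny, TreeError, pic

logger = logging.getLogger(__name__)

__all__ = [
    "PcProjection",
    "DriftTestResult",
    "project_scores",
    "regression_test",
    "correlation_test",
    "size_vector_check",
]


@dataclass
class PcProjection:
    """Species scores on the principal components of a W-matrix.

    Eigenvectors are unit-norm with the sign convention that the
    largest-magnitude loading is positive; the retained PC count is
    min(p, n_species - 1).
    """

    node: str | None
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: pd.DataFrame  # species x retained PCs
    retained: int

    def species_scores(self, species: list[str]) -> pd.DataFrame:
        missing = [s for s in species if s not in self.scores.index]
        if missing:
            raise TreeError(f"species missing from projection: {missing}")
        return self.scores.loc[species]


@dataclass
class DriftTestResult:
    """Per-node outcome of the regression and/or correlation drift test."""

    node: str
    n_taxa: int
    status: str = "ok"  # ok | skipped
    # regression fields
    slope: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    intercept: float | None = None
    between_var: np.ndarray | None = None
    used_pcs: list[int] | None = None
    reject_regression: bool | None = None
    # correlation fields
    pairs: list[tuple[int, int, float, float]] | None = None
    n_pairs_tested: int | None = None
    reject_correlation: bool | None = None

    def significant_pairs(self, alpha: float = 0.01) -> list[tuple[int, int]]:
        """PC pairs (1-based) with raw p below ``alpha``."""
        if self.pairs is None:
            return []
        return [(i, j) for i, j, _, p in self.pairs if p < alpha]


def project_scores(species_means: Mapping[str, np.ndarray],
                   w: CovMatrix, node: str | None = None) -> PcProjection:
    """Project species mean phenotypes on the unit eigenvectors of W."""
    species = list(species_means)
    if len(species) < 2:
        raise TreeError("need at least two species to project scores")
    means = np.array([np.asarray(species_means[s], dtype=float) for s in species])
    lam, vec = w.eigh()
    # sign convention: largest-magnitude loading positive
    for k in range(vec.shape[1]):
        idx = np.argmax(np.abs(vec[:, k]))
        if vec[idx, k] < 0:
            vec[:, k] = -vec[:, k]
    retained = min(w.p, len(species) - 1)
    scores = means @ vec[:, :retained]
    frame = pd.DataFrame(scores, index=species,
                         columns=[f"PC{k+1}" for k in range(retained)])
    return PcProjection(node=node, eigenvalues=lam, eigenvectors=vec,
                        scores=frame, retained=retained)


def _score_contrasts(tree: Phylogeny, node: "str | Node",
                     projection: PcProjection) -> tuple[np.ndarray, int]:
    """PIC contrasts of the PC scores on the subtree of ``node``."""
    sub = tree.subtree(node)
    tips = sub.tip_labels
    scores = projection.species_scores(tips)
    values = {t: scores.loc[t].to_numpy(dtype=float) for t in tips}
    cs = pic(sub, values)
    return cs.contrasts, len(tips)


def regression_test(tree: Phylogeny, node: "str | Node",
                    projection: PcProjection, min_taxa: int = 5,
                    *, family_alpha: float = 0.05,
                    eig_rtol: float = 1e-12) -> DriftTestResult:
    """Log-linear regression of between-group PC variances on W eigenvalues.

    B_i is the variance (divisor = number of contrasts, no centering) of the
    phylogenetic independent contrasts of species scores on PC i within the
    clade of ``node``; the slope of ln(B_i) on ln(W_i) has expectation 1
    under drift, with an OLS t-based confidence interval at level
    1 - ``family_alpha``. Applied only to nodes with more than ``min_taxa``
    terminal taxa.
    """
    label = tree.node(node).label
    n_taxa = len(tree.clade_tips(node))
    if n_taxa <= min_taxa:
        return DriftTestResult(node=label, n_taxa=n_taxa, status="skipped")
    contrasts, _ = _score_contrasts(tree, node, projection)
    m_contrasts = contrasts.shape[0]
    b_var = (contrasts ** 2).sum(axis=0) / m_contrasts

    lam = projection.eigenvalues[:projection.retained]
    keep = lam > eig_rtol * projection.eigenvalues[0]
    dropped = np.where(~keep)[0]
    if dropped.size:
        logger.info("node %s: dropped near-zero eigenvalue PCs %s",
                    label, (dropped + 1).tolist())
    zero_b = b_var <= 0
    if zero_b.any():
        logger.warning("node %s: dropped PCs with zero between-group variance %s",
                       label, (np.where(zero_b)[0] + 1).tolist())
    keep = keep & ~zero_b
    used = np.where(keep)[0]
    if used.size < 3:
        logger.warning("node %s: fewer than 3 usable PCs; regression skipped", label)
        return DriftTestResult(node=label, n_taxa=n_taxa, status="skipped",
                               between_var=b_var)

    x = np.log(lam[used])
    y = np.log(b_var[used])
    m = used.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (m - 2)
    se = np.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(1 - family_alpha / 2, m - 2)
    ci_low, ci_high = slope - tcrit * se, slope + tcrit * se
    return DriftTestResult(
        node=label, n_taxa=n_taxa, slope=float(slope),
        ci_low=float(ci_low), ci_high=float(ci_high),
        intercept=float(intercept), between_var=b_var,
        used_pcs=(used + 1).tolist(),
        reject_regression=bool(ci_low > 1.0 or ci_high < 1.0),
    )


def _origin_correlation(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def correlation_test(tree: Phylogeny, node: "str | Node",
                     projection: PcProjection, min_taxa: int = 5,
                     alpha_pair: float = 0.01, *,
                     family_alpha: float = 0.05,
                     through_origin: bool = True) -> DriftTestResult:
    """Correlations between species scores on distinct PCs, via PIC.

    For every pair among the first min(n_taxa - 1, retained) PCs the Pearson
    correlation of the contrasts (through the origin by default, since
    contrasts are mean-zero with arbitrary sign) is tested with a two-sided
    t-statistic on (number of contrasts - 1) degrees of freedom. Pairs are
    reported at raw p < ``alpha_pair``; the drift-rejection flag applies the
    Bonferroni criterion at family level ``family_alpha``.
    """
    label = tree.node(node).label
    n_taxa = len(tree.clade_tips(node))
    if n_taxa < min_taxa:
        return DriftTestResult(node=label, n_taxa=n_taxa, status="skipped")
    contrasts, _ = _score_contrasts(tree, node, projection)
    m_contrasts = contrasts.shape[0]
    k = min(n_taxa - 1, projection.retained)
    df = m_contrasts - 1
    if df < 2 or k < 2:
        return DriftTestResult(node=label, n_taxa=n_taxa, status="skipped")

    variances = (contrasts[:, :k] ** 2).sum(axis=0)
    pairs: list[tuple[int, int, float, float]] = []
    n_tested = 0
    any_bonferroni = False
    all_pairs = list(combinations(range(k), 2))
    n_pairs = len(all_pairs)
    for i, j in all_pairs:
        if variances[i] == 0 or variances[j] == 0:
            logger.info("node %s: zero-variance score column in pair (%d,%d)",
                        label, i + 1, j + 1)
            continue
        xi, xj = contrasts[:, i], contrasts[:, j]
        if through_origin:
            r = _origin_correlation(xi, xj)
        else:
            r = float(np.corrcoef(xi, xj)[0, 1])
        n_tested += 1
        r_clip = min(abs(r), 1 - 1e-15)
        tstat = r_clip * np.sqrt(df / (1 - r_clip ** 2))
        pval = 2 * stats.t.sf(tstat, df)
        if pval < alpha_pair:
            pairs.append((i + 1, j + 1, r, float(pval)))
        if pval < family_alpha / n_pairs:
            any_bonferroni = True
    return DriftTestResult(
        node=label, n_taxa=n_taxa, pairs=pairs, n_pairs_tested=n_tested,
        reject_correlation=any_bonferroni,
    )


def size_vector_check(species_means: Mapping[str, np.ndarray],
                      projection: PcProjection) -> tuple[float, float]:
    """Correlation between species geometric-mean size and their PC1 score.

    A high r-squared confirms that PC1 is an allometric size axis. All trait
    values must be positive (geometric mean of linear distances).
    Returns (r, r_squared).
    """
    species = list(projection.scores.index)
    gm = np.empty(len(species))
    for idx, s in enumerate(species):
        vec = np.asarray(species_means[s], dtype=float)
        if np.any(vec <= 0):
            bad = int(np.argmin(vec))
            raise ValueError(
                f"non-positive trait value for species {s!r} (trait index {bad})"
            )
        gm[idx] = np.exp(np.mean(np.log(vec)))
    pc1 = projection.scores["PC1"].to_numpy(dtype=float)
    if np.std(gm) == 0 or np.std(pc1) == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(gm, pc1)[0, 1])
    return r, r ** 2
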