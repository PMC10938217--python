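"""Community-ecology statistics: rarefaction, α diversity, Bray-Curtis,
PCoA and PERMANOVA.

Rarefaction is true without-replacement subsampling (multivariate
hypergeometric), performed once per analysis at a fixed depth; samples
below the depth are dropped with a warning.  PCoA reports negative
eigenvalues but excludes them from the proportion-explained denominator;
no Cailliez correction is applied.  PERMANOVA uses Anderson's pseudo-F on
squared distances with the add-one permutation p estimator, switching to
exhaustive enumeration of two-group relabellings whenever that is cheaper
than the requested number of random permutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import alpha_diversity
from sklearn.base import BaseEstimator, TransformerMixin


# ---------------------------------------------------------------------------
# rarefaction

def rarefy(
    table: pd.DataFrame,
    depth: int = 6247,
    seed: int | None = None,
) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (a warning lists
    them).  A sample whose total equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    counts = table.to_numpy()
    if (counts < 0).any():
        raise ValueError("count table contains negative entries")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(table.index[~keep])
        warnings.warn(
            f"rarefy: dropping {len(dropped)} sample(s) below depth "
            f"{depth}: {dropped}", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row_idx in enumerate(np.flatnonzero(keep)):
        row = counts[row_idx]
        if totals[row_idx] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(
                row, depth, method="marginals")
    return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


class Rarefier(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`rarefy`.

    After :meth:`transform`, ``dropped_samples_`` lists the sample ids
    whose library size fell below ``depth``.
    """

    def __init__(self, depth: int = 6247, random_state: int | None = None):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        totals = X.sum(axis=1)
        self.dropped_samples_ = list(X.index[totals < self.depth])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return rarefy(X, self.depth, self.random_state)


# ---------------------------------------------------------------------------
# alpha diversity

def alpha_observed(table: pd.DataFrame) -> pd.Series:
    """Observed richness: number of ASVs with count > 0 per sample."""
    return (table > 0).sum(axis=1).rename("observed_asvs")


def alpha_shannon(table: pd.DataFrame, base: float = math.e) -> pd.Series:
    """Shannon entropy of per-sample proportions (natural log by default)."""
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(table.index[totals <= 0])
        raise ValueError(f"samples with zero total count: {bad}")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / math.log(base)
    return pd.Series(h, index=table.index, name="shannon")


def alpha_faith_pd(table: pd.DataFrame, tree: TreeNode) -> pd.Series:
    """Faith phylogenetic diversity (root-inclusive) per sample."""
    tips = {t.name for t in tree.tips()}
    missing = [a for a in table.columns if a not in tips]
    if missing:
        raise ValueError(f"ASVs absent from tree: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    pd_vals = alpha_diversity(
        "faith_pd", table.to_numpy(dtype=int), ids=list(table.index),
        taxa=list(table.columns), tree=tree)
    return pd.Series(pd_vals, index=table.index, name="faith_pd")


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, 1 − 2·Σmin/(Σx+Σy)."""
    counts = table.to_numpy(dtype=float)
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    d = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class OrdinationResult:
    """Classical-MDS embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples × retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis


def pcoa(distance: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Principal-coordinates analysis via double-centred eigendecomposition.

    Negative eigenvalues are reported in ``eigenvalues`` but contribute
    neither axes nor proportion-explained denominator.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0])) if n else eigvals > 0
    n_keep = min(n_axes, int(pos.sum()))
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    pos_sum = eigvals[pos].sum()
    prop = (eigvals[:n_keep] / pos_sum) if pos_sum > 0 else np.zeros(n_keep)
    cols = [f"PC{i + 1}" for i in range(n_keep)]
    if n_keep < n_axes:
        # degenerate input (e.g. all-zero distances): pad with zero axes
        coords = np.hstack([coords, np.zeros((n, n_axes - n_keep))])
        prop = np.concatenate([prop, np.zeros(n_axes - n_keep)])
        cols += [f"PC{i + 1}" for i in range(n_keep, n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=distance.index, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop)


class PCoA(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`pcoa` (fit on a distance matrix)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        result = pcoa(X, self.n_components)
        self.eigenvalues_ = result.eigenvalues
        self.proportion_explained_ = result.proportion_explained
        self.embedding_ = result.coordinates
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).embedding_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).embedding_


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    method: str  # "permutation" or "exact"


def _permanova_ss(d2: np.ndarray, labels: np.ndarray,
                  groups: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared distances (Anderson)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss_within, ss_total


def _pseudo_f(ss_within: float, ss_total: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    distance: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    For a two-group factor with C(n, n1) distinct relabellings not
    exceeding ``n_permutations``, the null is enumerated exhaustively and
    ``p`` is the exact fraction of relabellings with F ≥ observed F
    (the identity relabelling included).  Otherwise ``p`` uses random
    label permutations with the add-one estimator
    (1 + #{F* ≥ F}) / (1 + n_permutations), which never returns zero.
    """
    labels = np.asarray(labels)
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match distance matrix size")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = d ** 2
    a = len(groups)
    ss_w, ss_t = _permanova_ss(d2, labels, groups)
    f_obs = _pseudo_f(ss_w, ss_t, n, a)
    r2 = (ss_t - ss_w) / ss_t

    tol = 1e-12 * max(1.0, abs(f_obs))
    if a == 2 and math.comb(n, int(counts[0])) <= n_permutations:
        n1 = int(counts[0])
        n_ge = 0
        total = 0
        idx = np.arange(n)
        for members in combinations(idx, n1):
            perm_labels = np.full(n, groups[1], dtype=labels.dtype)
            perm_labels[list(members)] = groups[0]
            ss_w_p, _ = _permanova_ss(d2, perm_labels, groups)
            if _pseudo_f(ss_w_p, ss_t, n, a) >= f_obs - tol:
                n_ge += 1
            total += 1
        return PermanovaResult(f_obs, r2, n_ge / total, total, "exact")

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ss_w_p, _ = _permanova_ss(d2, perm, groups)
        if _pseudo_f(ss_w_p, ss_t, n, a) >= f_obs - tol:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, "permutation")
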