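"""LEfSe-style differential abundance between CAD groups.

Two stages, following the linear-discriminant effect-size recipe: a
Kruskal-Wallis screen at raw alpha (no FDR — the method's convention),
then a bootstrap-averaged two-class linear-discriminant effect size on the
passing taxa, reported on a log10 scale after rescaling abundances to
parts-per-million.  Comparisons are one-vs-one between named groups; there
is no subclass (within-class) stage because the cohort has no subclass
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_PPM = 1e6


@dataclass
class LdaEffect:
    taxon: str
    kw_p: float
    lda_score: float
    enriched_in: str


def kw_screen(
    genus_table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis p per taxon; ``passed`` marks p < alpha.

    Taxa that are constant across all samples get p = 1 by convention.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    masks = [labels == g for g in groups]
    rows = []
    for taxon in genus_table.columns:
        x = genus_table[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.info("kw_screen: %s constant across samples, p=1", taxon)
            p = 1.0
        else:
            _, p = stats.kruskal(*(x[m] for m in masks))
        rows.append({"taxon": taxon, "kw_p": float(p)})
    out = pd.DataFrame(rows)
    out["passed"] = out["kw_p"] < alpha
    return out


def _lda_direction(x0: np.ndarray, x1: np.ndarray,
                   ridge: float = 1e-6) -> np.ndarray:
    """Regularised Fisher discriminant direction between two classes."""
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    c0 = x0 - mu0
    c1 = x1 - mu1
    n = len(x0) + len(x1)
    sw = (c0.T @ c0 + c1.T @ c1) / max(n - 2, 1)
    p = sw.shape[0]
    lam = ridge * (np.trace(sw) / p + 1.0)
    w = np.linalg.solve(sw + lam * np.eye(p), mu1 - mu0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_size(
    genus_table: pd.DataFrame,
    labels,
    passed_taxa,
    n_boot: int = 30,
    seed: int | None = None,
    subsample_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """Bootstrap-averaged LDA effect size for screened taxa.

    For each bootstrap round, a without-replacement subsample of each
    class (fraction ``subsample_fraction``) feeds a ridge-regularised
    two-class linear discriminant on per-million-scaled abundances; the
    per-taxon effect is the average of the raw class-mean difference and
    that taxon's share of the class-mean difference along the discriminant
    axis.  The reported score is sign(effect)·log10(1 + |effect|), with
    the sign mapped to ``enriched_in``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("LDA effect size is defined for exactly two groups")
    passed_taxa = list(passed_taxa)
    if not passed_taxa:
        return pd.DataFrame(columns=["taxon", "lda_score", "enriched_in"])
    x = genus_table[passed_taxa].to_numpy(dtype=float) * _PPM
    rng = np.random.default_rng(seed)
    m0, m1 = labels == classes[0], labels == classes[1]
    idx0, idx1 = np.flatnonzero(m0), np.flatnonzero(m1)
    k0 = max(2, int(round(subsample_fraction * len(idx0))))
    k1 = max(2, int(round(subsample_fraction * len(idx1))))
    effects = np.zeros((n_boot, len(passed_taxa)))
    for b in range(n_boot):
        s0 = rng.choice(idx0, size=min(k0, len(idx0)), replace=False)
        s1 = rng.choice(idx1, size=min(k1, len(idx1)), replace=False)
        x0, x1 = x[s0], x[s1]
        raw_diff = x1.mean(axis=0) - x0.mean(axis=0)
        w = _lda_direction(x0, x1)
        proj_diff = float(w @ raw_diff)  # >= 0 up to regularisation
        effects[b] = 0.5 * (raw_diff + w * proj_diff)
    mean_eff = effects.mean(axis=0)
    score = np.sign(mean_eff) * np.log10(1.0 + np.abs(mean_eff))
    enriched = np.where(mean_eff > 0, classes[1], classes[0])
    return pd.DataFrame({"taxon": passed_taxa, "lda_score": score,
                         "enriched_in": enriched})


def differential_abundance(
    genus_table: pd.DataFrame,
    labels,
    groups: tuple[str, str],
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full screen-then-score comparison between two named groups.

    Returns taxa with Kruskal-Wallis p < ``alpha`` and |LDA score| ≥
    ``lda_threshold``, sorted by |score| descending.
    """
    labels = np.asarray(labels)
    mask = np.isin(labels, groups)
    if set(groups) - set(np.unique(labels[mask])):
        raise ValueError(f"groups {groups} not both present in labels")
    sub = genus_table.loc[mask]
    sub_labels = labels[mask]
    screen = kw_screen(sub, sub_labels, alpha=alpha)
    passed = screen.loc[screen["passed"], "taxon"].tolist()
    scored = lda_effect_size(sub, sub_labels, passed, n_boot=n_boot,
                             seed=seed)
    merged = scored.merge(screen[["taxon", "kw_p"]], on="taxon")
    merged = merged[merged["lda_score"].abs() >= lda_threshold]
    merged = merged.reindex(
        merged["lda_score"].abs().sort_values(ascending=False).index)
    return merged[["taxon", "kw_p", "lda_score", "enriched_in"]
                  ].reset_index(drop=True)


class DifferentialAbundance(BaseEstimator):
    """Estimator form of the screen + LDA-effect-size comparison.

    Parameters mirror :func:`differential_abundance`; after ``fit(X, y)``
    (genus table, group labels) the detected taxa are in ``results_`` and
    the full screen in ``screen_``.
    """

    def __init__(self, groups: tuple[str, str] | None = None,
                 alpha: float = 0.05, lda_threshold: float = 2.0,
                 n_boot: int = 30, random_state: int | None = None):
        self.groups = groups
        self.alpha = alpha
        self.lda_threshold = lda_threshold
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        groups = self.groups or tuple(np.unique(y))
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        self.screen_ = kw_screen(X.loc[np.isin(y, groups)],
                                 y[np.isin(y, groups)], alpha=self.alpha)
        self.results_ = differential_abundance(
            X, y, groups, alpha=self.alpha,
            lda_threshold=self.lda_threshold, n_boot=self.n_boot,
            seed=self.random_state)
        return self
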