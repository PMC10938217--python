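"""Bootstrap random-forest ranking of taxa predictive of plasma ImP.

For each of ``n_resamples`` bootstrap draws of the cohort, a random-forest
regression of ImP on genus abundances is fit; taxa are scored by
permutation importance on the rows left out of that bootstrap draw, split
into a positive and a negative direction by the sign of the taxon's
marginal Spearman correlation with ImP in the draw; the top ``top_k``
important taxa within each direction are recorded.  The final ranking is
by selection frequency (share of resamples in which the taxon made a
top-k list), ties broken by mean importance.

Per-taxon permutation seeds are derived from the taxon name, and features
are processed in name-sorted order internally, so the ranking does not
depend on the column order of the input table.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor


def _marginal_spearman_sign(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sign of the Spearman correlation of every column of x with y."""
    rx = np.apply_along_axis(rankdata, 0, x)
    ry = rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum(axis=0) * (ryc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rxc.T @ ryc / denom, 0.0)
    return np.sign(rho)


def _taxon_seed(name: str, resample: int) -> int:
    return (zlib.crc32(name.encode()) ^ (0x9E3779B1 * (resample + 1))) % (2**31)


class BootstrapForestRanker(BaseEstimator):
    """sklearn-style estimator for the bootstrap RF taxa ranking.

    Parameters
    ----------
    n_resamples : int
        Bootstrap refits of the forest (200 matches the analysis design).
    top_k : int
        Taxa recorded per direction per resample.
    n_estimators : int
        Trees per forest.
    log_transform : bool
        Model log10(abundance + 1e-6) instead of raw relative abundance.
    random_state : int or None
        Master seed for bootstrap draws, forests and permutations.

    After ``fit(X, y)``, ``ranking_`` holds a DataFrame with columns
    taxon, selection_frequency, direction, mean_importance, sorted by
    frequency (ties by importance).
    """

    def __init__(self, n_resamples: int = 200, top_k: int = 20,
                 n_estimators: int = 200, max_features: float = 1 / 3,
                 log_transform: bool = False,
                 random_state: int | None = None):
        self.n_resamples = n_resamples
        self.top_k = top_k
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.log_transform = log_transform
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 30:
            raise ValueError("need at least 30 samples to rank taxa")
        if len(y) != n:
            raise ValueError("X and y must be paired")
        top_k = self.top_k
        if p < top_k:
            warnings.warn(
                f"only {p} taxa available; clipping top_k from {top_k}",
                stacklevel=2)
            top_k = p
        # name-sorted internal order -> column-order invariance
        taxa = sorted(map(str, X.columns))
        xs = X[taxa].to_numpy(dtype=float)
        if self.log_transform:
            xs = np.log10(xs + 1e-6)
        root = np.random.SeedSequence(self.random_state)
        boot_rng = np.random.default_rng(root.spawn(1)[0])
        forest_seeds = boot_rng.integers(0, 2**31 - 1, size=self.n_resamples)

        selected = np.zeros(p, dtype=int)
        importance_sum = np.zeros(p)
        importance_cnt = np.zeros(p, dtype=int)
        direction_sum = np.zeros(p)

        for b in range(self.n_resamples):
            idx = boot_rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(oob) < 5:  # pathological draw; redo deterministically
                oob = np.arange(n)
            xb, yb = xs[idx], y[idx]
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                random_state=int(forest_seeds[b]), n_jobs=1)
            rf.fit(xb, yb)
            xo, yo = xs[oob], y[oob]
            base_mse = float(np.mean((rf.predict(xo) - yo) ** 2))
            # batched permutation importance: one big predict call with
            # one permuted column per block
            m = len(oob)
            big = np.tile(xo, (p, 1))
            for j in range(p):
                block = big[j * m:(j + 1) * m, j]
                prng = np.random.default_rng(_taxon_seed(taxa[j], b))
                big[j * m:(j + 1) * m, j] = prng.permutation(block)
            perm_pred = rf.predict(big).reshape(p, m)
            perm_mse = np.mean((perm_pred - yo) ** 2, axis=1)
            importance = perm_mse - base_mse

            sign = _marginal_spearman_sign(xb, yb)
            order = np.argsort(-importance, kind="stable")
            chosen: list[int] = []
            for direction in (1.0, -1.0):
                members = [j for j in order if sign[j] == direction]
                chosen.extend(members[:top_k])
            for j in chosen:
                selected[j] += 1
                importance_sum[j] += importance[j]
                importance_cnt[j] += 1
            direction_sum += sign

        freq = selected / self.n_resamples
        with np.errstate(invalid="ignore"):
            mean_imp = np.where(importance_cnt > 0,
                                importance_sum / np.maximum(importance_cnt, 1),
                                0.0)
        direction = np.where(direction_sum >= 0, "positive", "negative")
        ranking = pd.DataFrame({
            "taxon": taxa,
            "selection_frequency": freq,
            "direction": direction,
            "mean_importance": mean_imp,
        }).sort_values(["selection_frequency", "mean_importance"],
                       ascending=False, kind="stable").reset_index(drop=True)
        self.ranking_ = ranking
        self.n_features_in_ = p
        return self


def rf_bootstrap_rank(
    genus_table: pd.DataFrame,
    imp,
    n_resamples: int = 200,
    top_k: int = 20,
    seed: int | None = None,
    n_estimators: int = 200,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`BootstrapForestRanker`."""
    ranker = BootstrapForestRanker(
        n_resamples=n_resamples, top_k=top_k, n_estimators=n_estimators,
        log_transform=log_transform, random_state=seed)
    ranker.fit(genus_table, imp)
    return ranker.ranking_
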