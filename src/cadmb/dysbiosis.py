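"""The CAD-related dysbiosis index and its correlation analyses.

The index is the natural log of the ratio of summed relative abundances of
three disease-enriched genera (Veillonella, the Ruminococcus gnavus group,
Alistipes) over nine disease-depleted genera (Prevotella 9, Megasphaera,
Moryella, Catenibacterium, Fusicatenibacter, Ruminococcaceae UCG-005 and
UCG-009, Lachnospiraceae ND3007 group, Eubacterium xylanophilum group).  A
pseudocount (default 1e-6) keeps the ratio finite on sparse samples while
perturbing typical values by well under 1%.  "Elevated" means strictly
above the cohort's 75th percentile (linear-interpolation quantile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .taxa import DENOMINATOR_GENERA, NUMERATOR_GENERA, match_genera


@dataclass
class DysbiosisIndexSpec:
    """Numerator/denominator genus lists plus pseudocount."""

    numerator_genera: tuple[str, ...] = NUMERATOR_GENERA
    denominator_genera: tuple[str, ...] = DENOMINATOR_GENERA
    pseudocount: float = 1e-6

    def __post_init__(self):
        if not self.numerator_genera or not self.denominator_genera:
            raise ValueError("numerator and denominator lists must be nonempty")
        from .taxa import normalize_genus
        num = {normalize_genus(g) for g in self.numerator_genera}
        den = {normalize_genus(g) for g in self.denominator_genera}
        if num & den:
            raise ValueError(f"genera in both lists: {sorted(num & den)}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


def aggregate_to_genus(table: pd.DataFrame,
                       taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Collapse an ASV count table to genus-level relative abundances.

    Every ASV column must be mapped in ``taxonomy`` (index = ASV id,
    'genus' column).  Rows of the result sum to 1.
    """
    unmapped = [a for a in table.columns if a not in taxonomy.index]
    if unmapped:
        raise ValueError(f"ASVs without taxonomy: {unmapped[:10]}"
                         + ("..." if len(unmapped) > 10 else ""))
    genus_of = taxonomy.loc[table.columns, "genus"]
    genus_counts = table.T.groupby(genus_of).sum().T
    totals = genus_counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("samples with zero total count cannot be normalised")
    return genus_counts.div(totals, axis=0)


def _sum_columns(genus_table: pd.DataFrame, genera) -> np.ndarray:
    mapping, missing = match_genera(genera, genus_table.columns)
    if missing:
        warnings.warn(
            f"index genera absent from table (treated as zero): {missing}",
            stacklevel=3)
    if not mapping:
        return np.zeros(len(genus_table))
    return genus_table[list(mapping.values())].sum(axis=1).to_numpy()


def cad_dysbiosis_index(
    genus_table: pd.DataFrame,
    spec: DysbiosisIndexSpec | None = None,
) -> pd.Series:
    """ln((Σ numerator + pseudocount) / (Σ denominator + pseudocount))."""
    spec = spec or DysbiosisIndexSpec()
    num = _sum_columns(genus_table, spec.numerator_genera)
    den = _sum_columns(genus_table, spec.denominator_genera)
    values = np.log(num + spec.pseudocount) - np.log(den + spec.pseudocount)
    return pd.Series(values, index=genus_table.index, name="dysbiosis_index")


def flag_elevated(values, quantile: float = 0.75) -> np.ndarray:
    """Flag values strictly above the empirical quantile (linear interp)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values to define quartiles")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    return v > np.quantile(v, quantile)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class QuartileTrend:
    """Per-quartile ImP summaries plus a rank-based trend test."""

    summary: pd.DataFrame  # quartile, n, median, q1, q3
    rho: float
    p: float


def assign_quartiles(values) -> np.ndarray:
    """Quartile membership 1-4 using the same convention as flag_elevated."""
    v = np.asarray(values, dtype=float)
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    return 1 + (v > cuts[0]).astype(int) + (v > cuts[1]) + (v > cuts[2])


def imp_by_index_quartile(index_values, imp_values) -> QuartileTrend:
    """Summarise ImP by dysbiosis-index quartile and test for a trend.

    The trend is Spearman correlation of quartile rank against ImP
    (a Jonckheere-style ordered-alternative test).
    """
    idx = np.asarray(index_values, dtype=float)
    imp = np.asarray(imp_values, dtype=float)
    if len(idx) != len(imp):
        raise ValueError("index and ImP vectors must be paired")
    if len(idx) < 8:
        raise ValueError("need at least 8 samples for a quartile analysis")
    quart = assign_quartiles(idx)
    rows = []
    for q in (1, 2, 3, 4):
        vals = imp[quart == q]
        if len(vals):
            rows.append({"quartile": q, "n": len(vals),
                         "median": float(np.median(vals)),
                         "q1": float(np.quantile(vals, 0.25)),
                         "q3": float(np.quantile(vals, 0.75))})
        else:
            rows.append({"quartile": q, "n": 0, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
    if np.ptp(imp) == 0 or np.ptp(quart) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(quart, imp)
    return QuartileTrend(summary=pd.DataFrame(rows), rho=float(rho),
                         p=float(p))


class GenusAggregator(TransformerMixin, BaseEstimator):
    """Transformer collapsing ASV counts to genus relative abundances."""

    def __init__(self, taxonomy: pd.DataFrame | None = None):
        self.taxonomy = taxonomy

    def fit(self, X: pd.DataFrame, y=None):
        if self.taxonomy is None:
            raise ValueError("taxonomy must be provided")
        self.genera_ = sorted(
            self.taxonomy.loc[X.columns, "genus"].unique())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return aggregate_to_genus(X, self.taxonomy)


class DysbiosisIndex(TransformerMixin, BaseEstimator):
    """Estimator computing the log-ratio index and its elevation threshold.

    ``fit`` learns the elevation threshold (the training cohort's
    ``quantile`` of index values); ``transform`` maps a genus table to
    index values; ``elevated`` applies the fitted threshold.
    """

    def __init__(self, spec: DysbiosisIndexSpec | None = None,
                 quantile: float = 0.75):
        self.spec = spec
        self.quantile = quantile

    def _spec(self) -> DysbiosisIndexSpec:
        return self.spec or DysbiosisIndexSpec()

    def fit(self, X: pd.DataFrame, y=None):
        values = cad_dysbiosis_index(X, self._spec())
        if len(values) < 4:
            raise ValueError("need at least 4 samples to fit a quartile cut")
        self.threshold_ = float(np.quantile(values, self.quantile))
        self.index_values_ = values
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        return cad_dysbiosis_index(X, self._spec())

    def elevated(self, X: pd.DataFrame | None = None) -> np.ndarray:
        if X is None:
            return self.index_values_.to_numpy() > self.threshold_
        return self.transform(X).to_numpy() > self.threshold_
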