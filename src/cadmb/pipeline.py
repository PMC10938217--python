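"""End-to-end orchestration of the cohort analysis.

``run_all`` chains every stage — rarefaction, α/β diversity, PERMANOVA,
differential abundance, the dysbiosis index, ImP quartile and correlation
analyses, bootstrap RF taxa ranking, logistic models, ROC and mediation —
on either a synthetic cohort or tables read from disk, and records a
manifest (configuration, named seeds, stage shapes) sufficient to
reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .assoc import SeparationError, fit_logistic, mediate_bootstrap, roc_auc
from .diffabund import differential_abundance
from .dysbiosis import (
    DysbiosisIndexSpec,
    aggregate_to_genus,
    cad_dysbiosis_index,
    flag_elevated,
    imp_by_index_quartile,
    spearman_assoc,
)
from .ecology import (
    alpha_faith_pd,
    alpha_observed,
    alpha_shannon,
    bray_curtis,
    pcoa,
    permanova,
)
from .imprank import rf_bootstrap_rank
from .simulate import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

CONTINUOUS_SUMMARY = ("age_y", "framingham", "hiv_duration_y", "il6_pg_ml",
                      "imp_nM")
CATEGORICAL_SUMMARY = ("sex_male", "msm", "cd4_nadir_lt200", "statins",
                       "abacavir", "antibiotics")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with the study defaults."""

    rarefaction_depth: int = 6247
    index_spec: DysbiosisIndexSpec = field(default_factory=DysbiosisIndexSpec)
    diffabund_alpha: float = 0.05
    lda_threshold: float = 2.0
    lda_n_boot: int = 30
    rf_resamples: int = 200
    rf_top_k: int = 20
    rf_trees: int = 200
    permanova_permutations: int = 999
    mediation_boot: int = 1000
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    run_faith_pd: bool = True
    run_rf: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    root = np.random.SeedSequence(seed)
    names = ("rarefy", "permanova", "diffabund", "rf", "mediation")
    ints = [int(np.random.default_rng(c).integers(0, 2**31 - 1))
            for c in root.spawn(len(names))]
    return dict(zip(names, ints))


def summarize_cohort(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-group descriptive table with Kruskal-Wallis / Fisher-χ² p.

    Continuous rows show median (IQR); categorical rows n (%).  Fisher's
    exact test is used for 2×2 tables, chi-square otherwise.
    """
    groups = sorted(metadata["cad_group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to summarise")
    rows = []
    for var in CONTINUOUS_SUMMARY:
        if var not in metadata:
            continue
        cells, arrays = {}, []
        for g in groups:
            vals = metadata.loc[metadata["cad_group"] == g, var].to_numpy(float)
            arrays.append(vals)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            cells[g] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
        if any(np.ptp(a) > 0 for a in arrays):
            _, p = stats.kruskal(*arrays)
        else:
            p = 1.0
        rows.append({"variable": var, **cells, "test": "kruskal",
                     "p": float(p)})
    for var in CATEGORICAL_SUMMARY:
        if var not in metadata:
            continue
        cells = {}
        table = []
        for g in groups:
            vals = metadata.loc[metadata["cad_group"] == g, var].astype(bool)
            k, n = int(vals.sum()), len(vals)
            cells[g] = f"{k} ({100 * k / n:.1f}%)"
            table.append([k, n - k])
        table = np.asarray(table)
        if table.shape[0] == 2:
            _, p = stats.fisher_exact(table)
            test = "fisher"
        else:
            if (table.sum(axis=0) == 0).any():
                p = 1.0
            else:
                _, p, *_ = stats.chi2_contingency(table)
            test = "chi2"
        rows.append({"variable": var, **cells, "test": test, "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    alpha: pd.DataFrame
    permanova: dict[str, object]
    ordination: object
    diffabund: dict[str, pd.DataFrame]
    index_values: pd.Series
    index_elevated: np.ndarray
    quartile_trend: object
    correlations: dict[str, tuple[float, float]]
    rf_ranking: pd.DataFrame | None
    logistic: dict[str, object]
    roc: dict[str, object]
    mediation: object
    manifest: dict


def run_all(config: PipelineConfig | None = None,
            cohort: Cohort | None = None) -> PipelineResult:
    """Run every analysis stage; any failure aborts naming the stage."""
    cfg = config or PipelineConfig()
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"config": cfg.to_dict(), "seeds": seeds,
                      "version": __version__, "stages": {}}
    stage = "simulate"
    try:
        if cohort is None:
            cohort = generate_cohort(cfg.cohort)
        meta = cohort.metadata
        labels = meta["cad_group"].to_numpy()
        _record(manifest, stage, cohort.counts.shape)

        stage = "summary"
        summary = summarize_cohort(meta)

        stage = "rarefy"
        from .ecology import rarefy
        t0 = time.time()
        rare = rarefy(cohort.counts, cfg.rarefaction_depth, seeds["rarefy"])
        kept = rare.index
        meta = meta.loc[kept]
        labels = meta["cad_group"].to_numpy()
        _record(manifest, stage, rare.shape, t0)

        stage = "alpha"
        t0 = time.time()
        alpha = pd.DataFrame({
            "observed_asvs": alpha_observed(rare),
            "shannon": alpha_shannon(rare)})
        if cfg.run_faith_pd:
            alpha["faith_pd"] = alpha_faith_pd(rare, cohort.tree)
        _record(manifest, stage, alpha.shape, t0)

        stage = "beta"
        t0 = time.time()
        dm = bray_curtis(rare)
        ordination = pcoa(dm, n_axes=2)
        perma = {}
        pairs = [("obstructive", "no_cad"), ("obstructive", "nonobstructive"),
                 ("nonobstructive", "no_cad")]
        for g1, g2 in pairs:
            mask = np.isin(labels, (g1, g2))
            perma[f"{g1}_vs_{g2}"] = permanova(
                dm.loc[mask, mask], labels[mask],
                cfg.permanova_permutations, seeds["permanova"])
        _record(manifest, stage, dm.shape, t0)

        stage = "genus"
        genus = aggregate_to_genus(rare, cohort.taxonomy)

        stage = "diffabund"
        t0 = time.time()
        da = {}
        for g1, g2 in pairs[:2]:
            da[f"{g1}_vs_{g2}"] = differential_abundance(
                genus, labels, (g1, g2), alpha=cfg.diffabund_alpha,
                lda_threshold=cfg.lda_threshold, n_boot=cfg.lda_n_boot,
                seed=seeds["diffabund"])
        _record(manifest, stage, {k: len(v) for k, v in da.items()}, t0)

        stage = "index"
        index_values = cad_dysbiosis_index(genus, cfg.index_spec)
        elevated = flag_elevated(index_values)
        imp = meta["imp_nM"].to_numpy(float)
        trend = imp_by_index_quartile(index_values, imp)
        correlations = {
            "index_vs_imp": spearman_assoc(index_values, imp),
            "index_vs_il6": spearman_assoc(
                index_values, meta["il6_pg_ml"].to_numpy(float)),
        }

        stage = "imprank"
        rf_ranking = None
        if cfg.run_rf:
            t0 = time.time()
            rf_ranking = rf_bootstrap_rank(
                genus, imp, n_resamples=cfg.rf_resamples,
                top_k=cfg.rf_top_k, seed=seeds["rf"],
                n_estimators=cfg.rf_trees)
            _record(manifest, stage, rf_ranking.shape, t0)

        stage = "assoc"
        imp_elevated = flag_elevated(imp)
        logistic = {}
        for exp_name, exp in (("index", elevated), ("imp", imp_elevated)):
            for model in ("unadjusted", "model1", "model2"):
                key = f"{exp_name}_{model}"
                try:
                    logistic[key] = fit_logistic(meta, exp, model=model,
                                                 exposure_name=exp_name)
                except SeparationError as exc:
                    logistic[key] = exc
        outcome = (labels == "obstructive").astype(int)
        roc = {"index": roc_auc(index_values, outcome),
               "imp": roc_auc(imp, outcome)}

        stage = "mediation"
        t0 = time.time()
        mediation = mediate_bootstrap(
            index_values.to_numpy(), imp, outcome,
            n_boot=cfg.mediation_boot, seed=seeds["mediation"])
        _record(manifest, stage, len(index_values), t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        summary=summary, alpha=alpha, permanova=perma, ordination=ordination,
        diffabund=da, index_values=index_values, index_elevated=elevated,
        quartile_trend=trend, correlations=correlations,
        rf_ranking=rf_ranking, logistic=logistic, roc=roc,
        mediation=mediation, manifest=manifest)


def _record(manifest: dict, stage: str, shape, t0: float | None = None):
    entry: dict = {"shape": shape}
    if t0 is not None:
        entry["seconds"] = round(time.time() - t0, 3)
    manifest["stages"][stage] = entry
    logger.info("stage %s: %s", stage, entry)
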