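"""Synthetic HIV-cohort generator.

Emulates the data structure of a cross-sectional coronary-CT cohort with
16S gut-microbiota profiling: a samples × ASVs count table, a genus-level
taxonomy, a rooted phylogeny over ASVs, clinical metadata for three CAD
strata (no CAD / nonobstructive / obstructive), and plasma imidazole
propionate (ImP) coupled to the abundance of producer taxa.

The community model is compositional: each cohort draws genus base
proportions (fixed, prevalent shares for the twelve dysbiosis-index genera;
a sparse symmetric Dirichlet for the background flora), perturbs the index
genera multiplicatively in the obstructive group, renormalises, adds
per-sample Dirichlet overdispersion, and samples reads multinomially at a
dispersed per-sample depth.  With all effect knobs at their null values the
three groups are exchangeable by construction, which is what makes the
generator usable for type-I-error calibration of every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .taxa import INDEX_GENERA, NUMERATOR_GENERA, PRODUCER_GENERA, match_genera

#: Fixed rarefaction depth used by the default pipeline.
DEFAULT_RAREFACTION_DEPTH = 6247

CAD_GROUPS = ("no_cad", "nonobstructive", "obstructive")

# Base per-genus community share planted for the index genera.  The index
# taxa are common gut genera in this population (they were detectable in
# every sample stratum), so the generator guarantees them a prevalent
# baseline instead of leaving their abundance to Dirichlet luck.
_NUMERATOR_BASE_SHARE = 0.02  # each of 3 genera
_DENOMINATOR_BASE_SHARE = 0.03  # each of 9 genera

# Confounded covariates: (base mean, SD, per-group offset in SD units
# scaled by confounding_shift).  Offsets follow the direction of the
# obstructive-CAD gradient seen in HIV CT-angiography cohorts.
_CONTINUOUS_COVARIATES = {
    "age_y": (50.0, 9.0, (0.0, 0.6, 1.0), 18.0),
    "framingham": (9.0, 8.0, (0.0, 0.6, 1.0), 0.0),
    "hiv_duration_y": (11.0, 7.0, (0.0, 0.6, 1.0), 0.3),
}
# log-normal IL-6 (pg/mL): base log-mean, log-SD, offsets in log-SD units
_IL6_LOG = (0.3, 0.55, (0.0, 0.5, 0.8))

# Binary covariates: base rate and per-group additive rate offsets (scaled
# by confounding_shift).
_BINARY_COVARIATES = {
    "cd4_nadir_lt200": (0.30, (0.0, 0.20, 0.25)),
    "msm": (0.67, (0.0, 0.10, 0.10)),
    "statins": (0.05, (0.0, 0.06, 0.30)),
    "abacavir": (0.27, (0.0, 0.02, -0.04)),
    "antibiotics": (0.18, (0.0, 0.03, 0.06)),
    "sex_male": (0.83, (0.0, 0.09, 0.08)),
}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions: 254 participants split
    114/80/60 across no-CAD / nonobstructive / obstructive strata, with the
    index genera enriched (numerator) or depleted (denominator) in the
    obstructive group and ImP positively coupled to producer-taxon
    abundance.
    """

    n_no_cad: int = 114
    n_nonobstructive: int = 80
    n_obstructive: int = 60
    n_asvs: int = 500
    n_genera: int = 60
    depth_mean: int = 20_000
    depth_dispersion: float = 15.0
    effect_up: float = 3.0
    effect_down: float = 0.3
    imp_coupling: float = 0.6
    imp_noise_sd: float = 0.6
    confounding_shift: float = 1.0
    seed: int = 0
    base_concentration: float = 0.3
    sample_concentration: float = 300.0
    genus_log_sd: float = 1.0

    def validate(self) -> None:
        for fld in ("n_no_cad", "n_nonobstructive", "n_obstructive"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be >= 1")
        if self.n_genera < len(INDEX_GENERA):
            raise ValueError(
                f"n_genera must be >= {len(INDEX_GENERA)} "
                "(3 numerator + 9 denominator index genera)"
            )
        if self.n_asvs < self.n_genera:
            raise ValueError("n_asvs must be >= n_genera")
        if self.depth_mean <= DEFAULT_RAREFACTION_DEPTH:
            raise ValueError(
                f"depth_mean must exceed the default rarefaction depth "
                f"({DEFAULT_RAREFACTION_DEPTH})"
            )
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0 < self.effect_down <= 1:
            raise ValueError("effect_down must lie in (0, 1]")
        if self.effect_up <= 0:
            raise ValueError("effect_up must be positive")
        if self.imp_noise_sd < 0:
            raise ValueError("imp_noise_sd must be nonnegative")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        if self.sample_concentration <= 0:
            raise ValueError("sample_concentration must be positive")
        if self.genus_log_sd < 0:
            raise ValueError("genus_log_sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.n_no_cad + self.n_nonobstructive + self.n_obstructive

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """Bundle of one synthetic cohort's tables.

    Attributes
    ----------
    counts : pandas.DataFrame
        Integer read counts, samples × ASVs.
    taxonomy : pandas.DataFrame
        ASV → (genus, family), indexed by ASV id.
    tree : skbio.TreeNode
        Rooted bifurcating phylogeny whose tips are the ASV ids.
    metadata : pandas.DataFrame
        Per-sample clinical covariates, CAD group and ImP (nM), indexed by
        sample id.
    config : CohortConfig
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    tree: TreeNode
    metadata: pd.DataFrame
    config: CohortConfig = field(repr=False)


def _named_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One master seed fans out into independent named streams."""
    root = np.random.SeedSequence(seed)
    names = ("counts", "tree", "covariates", "imp", "depth")
    return {name: np.random.default_rng(child)
            for name, child in zip(names, root.spawn(len(names)))}


def _genus_names(n_genera: int) -> list[str]:
    names = list(INDEX_GENERA)
    names += [f"Genus{i:03d}" for i in range(1, n_genera - len(names) + 1)]
    return names


def _base_proportions(n_genera: int, concentration: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Genus base shares: fixed for index genera, Dirichlet background."""
    k_idx = len(INDEX_GENERA)
    props = np.empty(n_genera)
    props[: len(NUMERATOR_GENERA)] = _NUMERATOR_BASE_SHARE
    props[len(NUMERATOR_GENERA): k_idx] = _DENOMINATOR_BASE_SHARE
    n_bg = n_genera - k_idx
    if n_bg > 0:
        remaining = 1.0 - props[:k_idx].sum()
        props[k_idx:] = remaining * rng.dirichlet(
            np.full(n_bg, concentration))
        # Dirichlet with small concentration can return exact zeros at
        # float precision; keep all genera representable.
        props[k_idx:] = np.maximum(props[k_idx:], 1e-12)
    props /= props.sum()
    return props


def _asv_layout(n_asvs: int, genus_props: np.ndarray,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign ASVs to genera and split each genus by stick-breaking.

    Returns (genus_of_asv, within_genus_weight); weights sum to 1 within
    each genus.  Abundant genera receive proportionally more ASVs.
    """
    n_genera = len(genus_props)
    genus_of = np.arange(n_genera)  # one ASV per genus guaranteed
    extra = rng.choice(n_genera, size=n_asvs - n_genera, p=genus_props)
    genus_of = np.concatenate([genus_of, extra])
    weights = np.empty(n_asvs)
    for g in range(n_genera):
        members = np.flatnonzero(genus_of == g)
        # GEM stick-breaking gives a few dominant ASVs per genus
        v = rng.beta(1.0, 1.5, size=len(members))
        stick = v * np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
        weights[members] = stick / stick.sum()
    return genus_of, weights


def _random_bifurcating_tree(tip_names: list[str],
                             rng: np.random.Generator,
                             scale: float = 0.1) -> TreeNode:
    """Random topology by successive pair joins, Exp(scale) branch lengths."""
    nodes = [TreeNode(name=name, length=float(rng.exponential(scale)))
             for name in tip_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode(length=float(rng.exponential(scale)))
        parent.extend([nodes[i], nodes[j]])
        nodes[j] = nodes[-1]
        nodes[i] = parent
        nodes.pop()
    root = nodes[0]
    root.length = None
    return root


def generate_imp(
    abundance: pd.DataFrame,
    producer_genera=PRODUCER_GENERA,
    coupling: float = 1.0,
    noise_sd: float = 0.6,
    seed: int | None = None,
    baseline_log: float = 2.71,
) -> pd.Series:
    """Simulate plasma ImP (nM) from producer-taxon relative abundance.

    log ImP = baseline + coupling × z + noise, where z is the summed
    relative abundance of the producer genera standardised across samples
    and noise is Gaussian with SD ``noise_sd``.  Output is strictly
    positive.  ``baseline_log`` = 2.71 puts the noise-free median near
    15 nM, the order of magnitude of circulating ImP.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    mapping, missing = match_genera(producer_genera, abundance.columns)
    if missing:
        raise KeyError(
            f"producer genera not present in table: {sorted(missing)}")
    rel = abundance.div(abundance.sum(axis=1), axis=0)
    producer = rel[[mapping[g] for g in mapping]].sum(axis=1).to_numpy()
    sd = producer.std()
    z = (producer - producer.mean()) / sd if sd > 0 else np.zeros_like(producer)
    rng = np.random.default_rng(seed)
    log_imp = baseline_log + coupling * z + rng.normal(0.0, noise_sd,
                                                       size=len(producer))
    return pd.Series(np.exp(log_imp), index=abundance.index, name="imp_nM")


def _sample_depths(n: int, cfg: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Dispersed sequencing depths, floored above the rarefaction depth."""
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    depths = rng.negative_binomial(r, p, size=n)
    return np.maximum(depths, DEFAULT_RAREFACTION_DEPTH + 1)


def _covariates(groups: np.ndarray, shift: float,
                rng: np.random.Generator) -> pd.DataFrame:
    g_idx = np.array([CAD_GROUPS.index(g) for g in groups])
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, offsets, floor) in _CONTINUOUS_COVARIATES.items():
        mu = mean + sd * shift * np.asarray(offsets)[g_idx]
        cols[name] = np.maximum(rng.normal(mu, sd), floor)
    log_mu = _IL6_LOG[0] + _IL6_LOG[1] * shift * np.asarray(_IL6_LOG[2])[g_idx]
    cols["il6_pg_ml"] = np.exp(rng.normal(log_mu, _IL6_LOG[1]))
    for name, (base, offsets) in _BINARY_COVARIATES.items():
        rate = np.clip(base + shift * np.asarray(offsets)[g_idx], 0.01, 0.99)
        cols[name] = rng.random(len(groups)) < rate
    return pd.DataFrame(cols)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    cfg = config or CohortConfig()
    cfg.validate()
    rngs = _named_rngs(cfg.seed)

    genus_names = _genus_names(cfg.n_genera)
    base = _base_proportions(cfg.n_genera, cfg.base_concentration,
                             rngs["counts"])

    # obstructive-group perturbation of the index genera, renormalised
    effect = np.ones(cfg.n_genera)
    effect[: len(NUMERATOR_GENERA)] = cfg.effect_up
    effect[len(NUMERATOR_GENERA): len(INDEX_GENERA)] = cfg.effect_down
    obstructive = base * effect
    obstructive /= obstructive.sum()
    group_props = {"no_cad": base, "nonobstructive": base,
                   "obstructive": obstructive}

    genus_of, within = _asv_layout(cfg.n_asvs, base, rngs["counts"])
    asv_ids = [f"ASV{i:04d}" for i in range(1, cfg.n_asvs + 1)]
    sample_ids = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    groups = np.repeat(
        CAD_GROUPS,
        [cfg.n_no_cad, cfg.n_nonobstructive, cfg.n_obstructive])

    depths = _sample_depths(cfg.n_samples, cfg, rngs["depth"])
    counts = np.empty((cfg.n_samples, cfg.n_asvs), dtype=np.int64)
    rng_c = rngs["counts"]
    for i, grp in enumerate(groups):
        # subject-level heterogeneity: genus shares vary on a log scale
        # between individuals, as in real gut communities
        w = group_props[grp] * np.exp(
            rng_c.normal(0.0, cfg.genus_log_sd, cfg.n_genera))
        p_genus = rng_c.dirichlet(cfg.sample_concentration * w / w.sum())
        p_asv = p_genus[genus_of] * within
        counts[i] = rng_c.multinomial(depths[i], p_asv / p_asv.sum())
    counts_df = pd.DataFrame(
        counts, index=pd.Index(sample_ids, name="sample_id"),
        columns=asv_ids)

    families = [f"Family{g // 5:02d}" for g in genus_of]
    taxonomy = pd.DataFrame(
        {"genus": [genus_names[g] for g in genus_of], "family": families},
        index=pd.Index(asv_ids, name="asv_id"))

    tree = _random_bifurcating_tree(asv_ids, rngs["tree"])

    metadata = _covariates(groups, cfg.confounding_shift, rngs["covariates"])
    metadata.insert(0, "cad_group", groups)
    metadata.index = pd.Index(sample_ids, name="sample_id")
    imp_seed = int(rngs["imp"].integers(0, 2**31 - 1))
    metadata["imp_nM"] = generate_imp(
        _genus_counts(counts_df, taxonomy), PRODUCER_GENERA,
        cfg.imp_coupling, cfg.imp_noise_sd, seed=imp_seed)

    return Cohort(counts=counts_df, taxonomy=taxonomy, tree=tree,
                  metadata=metadata, config=cfg)


def _genus_counts(counts: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    return counts.T.groupby(taxonomy["genus"]).sum().T
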