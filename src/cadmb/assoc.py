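"""Association models: adjusted logistic regression, ROC/AUC, and
bootstrap mediation.

The outcome throughout is obstructive CAD versus the combined reference
group (nonobstructive + no CAD).  Model 1 adjusts for the Framingham
score, HIV duration (per 5 years), mode of transmission (MSM flag), CD4
nadir < 200, statins, abacavir, antibiotics and IL-6; model 2 adds age
and sex.  Framingham, IL-6 and age enter standardised (per SD) since
their native scales are heterogeneous.  Confidence intervals are Wald.

Mediation uses the product-of-coefficients estimator on linear
regressions (linear-probability form for the binary outcome), for which
total = direct + indirect holds exactly on every draw, with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

MODEL1_COVARIATES = (
    "framingham_std", "hiv_duration_per5y", "msm", "cd4_nadir_lt200",
    "statins", "abacavir", "antibiotics", "il6_std",
)
MODEL2_COVARIATES = MODEL1_COVARIATES + ("age_std", "sex_male")


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass
class LogisticFit:
    terms: pd.DataFrame  # term, coef, odds_ratio, ci_low, ci_high, p
    model_label: str
    converged: bool
    n: int

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardise a constant covariate")
    return (x - x.mean()) / sd


def build_covariates(metadata: pd.DataFrame, model: str) -> pd.DataFrame:
    """Assemble the fixed covariate sets from cohort metadata."""
    if model == "unadjusted":
        return pd.DataFrame(index=metadata.index)
    cols = {
        "framingham_std": _standardise(
            metadata["framingham"].to_numpy(float)),
        "hiv_duration_per5y": metadata["hiv_duration_y"].to_numpy(float) / 5,
        "msm": metadata["msm"].to_numpy(float),
        "cd4_nadir_lt200": metadata["cd4_nadir_lt200"].to_numpy(float),
        "statins": metadata["statins"].to_numpy(float),
        "abacavir": metadata["abacavir"].to_numpy(float),
        "antibiotics": metadata["antibiotics"].to_numpy(float),
        "il6_std": _standardise(metadata["il6_pg_ml"].to_numpy(float)),
    }
    if model == "model2":
        cols["age_std"] = _standardise(metadata["age_y"].to_numpy(float))
        cols["sex_male"] = metadata["sex_male"].to_numpy(float)
    elif model != "model1":
        raise ValueError(f"unknown model label: {model!r}")
    return pd.DataFrame(cols, index=metadata.index)


def logistic_fit(outcome, design: pd.DataFrame,
                 model_label: str = "custom") -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald CIs.

    ``design`` should not contain an intercept; one is added.  Raises
    :class:`SeparationError` when the fit diverges (quasi-complete
    separation) instead of returning silently absurd coefficients.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    x = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["intercept", *design.columns]
    try:
        res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(str(exc)) from exc
    coefs = np.asarray(res.params)
    if not res.mle_retvals.get("converged", True) or \
            np.abs(coefs[1:]).max(initial=0.0) > 15:
        raise SeparationError(
            "logistic fit diverged; outcome is (quasi-)separated")
    se = np.asarray(res.bse)
    zcrit = stats.norm.ppf(0.975)
    terms = pd.DataFrame({
        "term": names,
        "coef": coefs,
        "odds_ratio": np.exp(coefs),
        "ci_low": np.exp(coefs - zcrit * se),
        "ci_high": np.exp(coefs + zcrit * se),
        "p": np.asarray(res.pvalues),
    })
    return LogisticFit(terms=terms, model_label=model_label,
                       converged=True, n=len(y))


def fit_logistic(
    metadata: pd.DataFrame,
    exposure,
    model: str = "unadjusted",
    exposure_name: str = "exposure",
) -> LogisticFit:
    """Fit obstructive CAD ~ exposure (+ model covariates).

    ``exposure`` is a per-sample flag (e.g. highest-quartile indicator) or
    numeric vector aligned with ``metadata``.
    """
    outcome = (metadata["cad_group"] == "obstructive").to_numpy(float)
    design = build_covariates(metadata, model)
    design.insert(0, exposure_name, np.asarray(exposure, dtype=float))
    return logistic_fit(outcome, design, model_label=model)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(score, outcome) -> RocResult:
    """ROC curve and trapezoidal AUC (ties get half credit)."""
    y = np.asarray(outcome, dtype=int)
    s = np.asarray(score, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass
class MediationResult:
    """Product-of-coefficients mediation with percentile bootstrap."""

    total_effect: float
    direct_effect: float
    indirect_effect: float
    proportion_mediated: float
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    n_boot: int


def _ols_coef(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def _mediation_effects(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                       cov: np.ndarray) -> tuple[float, float, float]:
    """(total c, direct c', indirect a·b) from three linear fits."""
    n = len(x)
    ones = np.ones((n, 1))
    dx = np.hstack([ones, x[:, None], cov])
    dxm = np.hstack([ones, x[:, None], m[:, None], cov])
    a = _ols_coef(m, dx)[1]
    coef_y = _ols_coef(y, dxm)
    c_prime, b = coef_y[1], coef_y[2]
    c = _ols_coef(y, dx)[1]
    return float(c), float(c_prime), float(a * b)


def _mediation_effects_logit(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                             cov: np.ndarray) -> tuple[float, float, float]:
    """Logit-outcome variant via average marginal effects.

    The mediator model stays linear; the outcome model is logistic and
    its coefficients are converted to probability-scale average marginal
    effects, so direct/indirect are comparable to the linear estimator.
    Total is defined as direct + indirect.
    """
    n = len(x)
    ones = np.ones((n, 1))
    dx = np.hstack([ones, x[:, None], cov])
    dxm = np.hstack([ones, x[:, None], m[:, None], cov])
    a = _ols_coef(m, dx)[1]
    res = sm.Logit(y, dxm).fit(disp=0, maxiter=100)
    p_hat = res.predict(dxm)
    scale = float(np.mean(p_hat * (1 - p_hat)))
    c_prime = float(res.params[1]) * scale
    b = float(res.params[2]) * scale
    return c_prime + a * b, c_prime, float(a * b)


def _boot_p(draws: np.ndarray) -> float:
    n = len(draws)
    lo = (np.sum(draws <= 0) + 1) / (n + 1)
    hi = (np.sum(draws >= 0) + 1) / (n + 1)
    return float(min(1.0, 2 * min(lo, hi)))


def mediate_bootstrap(
    x, m, y,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    outcome_model: str = "linear",
) -> MediationResult:
    """Does the mediator m carry part of the x → y association?

    Linear product-of-coefficients estimator: a from m ~ x + covariates,
    b and the direct effect c' from y ~ x + m + covariates (linear
    probability form when y is binary), total effect c from
    y ~ x + covariates; indirect = a·b = c − c' identically.  Percentile
    bootstrap over rows yields CIs and two-sided p for each effect.
    ``outcome_model="logit"`` swaps the outcome regression for a logistic
    fit reported as probability-scale average marginal effects; the
    linear form stays the default.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must be paired")
    if n < 50:
        raise ValueError("need at least 50 samples for mediation")
    if np.ptp(m) == 0:
        raise ValueError("mediator is constant")
    cov = (covariates.to_numpy(dtype=float) if covariates is not None
           else np.empty((n, 0)))
    if outcome_model == "linear":
        effects = _mediation_effects
    elif outcome_model == "logit":
        effects = _mediation_effects_logit
    else:
        raise ValueError("outcome_model must be 'linear' or 'logit'")
    c, c_prime, ab = effects(x, m, y, cov)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    n_kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            draws[n_kept] = effects(x[idx], m[idx], y[idx], cov[idx])
        except Exception:  # e.g. separation in a logit draw
            continue
        n_kept += 1
    draws = draws[:n_kept]
    n_boot = n_kept
    names = ("total", "direct", "indirect")
    ci = {name: (float(np.percentile(draws[:, k], 2.5)),
                 float(np.percentile(draws[:, k], 97.5)))
          for k, name in enumerate(names)}
    p = {name: _boot_p(draws[:, k]) for k, name in enumerate(names)}
    prop = ab / c if abs(c) > 1e-12 else float("nan")
    return MediationResult(
        total_effect=c, direct_effect=c_prime, indirect_effect=ab,
        proportion_mediated=prop, ci=ci, p=p, n_boot=n_boot)
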