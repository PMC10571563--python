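"""Multiple imputation of missing binary debulking status.

Debulking status (optimal vs suboptimal, a residual-disease surrogate) is
often absent from medical records. Following the White–Royston approach for
survival data, missing values are imputed from a logistic regression of the
observed statuses on clinical covariates (study site, histology, stage,
adjuvant and neoadjuvant therapy, age at diagnosis) augmented with the
Nelson–Aalen cumulative hazard at the participant's follow-up time and the
event indicator. Proper MI: each completed dataset uses a fresh coefficient
draw from the approximate posterior, and a per-participant mode across
datasets gives the consensus value used by the analysis models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter

from .cohort import CohortTable

logger = logging.getLogger(__name__)

DEBULK_CODES = {"optimal": 0, "suboptimal": 1}

#: imputation-model covariates (plus cumulative hazard and event indicator)
IMPUTATION_COVARIATES = ("site", "histology", "stage", "adjuvant", "neoadjuvant", "age_dx")


def recode_ca125(ca125_post_adjuvant: np.ndarray, threshold: float = 35.0) -> np.ndarray:
    """Map post-adjuvant-chemotherapy CA125 to debulking status.

    CA125 below the threshold is classified optimal, at or above it
    suboptimal; missing CA125 stays missing.
    """
    x = np.asarray(ca125_post_adjuvant, dtype=float)
    out = np.where(x < threshold, "optimal", "suboptimal").astype(object)
    out[np.isnan(x)] = np.nan
    return out


def nelson_aalen(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Nelson–Aalen cumulative hazard evaluated at each participant's time.

    H(t_i) = sum over event times t_j <= t_i of d_j / n_j, with d_j deaths
    and n_j at risk at t_j.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if np.any(time <= 0):
        raise ValueError("time must be positive")
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(time, event_observed=event)
    return naf.cumulative_hazard_at_times(time).to_numpy()


@dataclass
class ImputationSet:
    """m completed debulking vectors plus the per-dataset coefficient draws."""

    m: int
    datasets: list  # list of object arrays of "optimal"/"suboptimal"
    coefficients: pd.DataFrame  # one row per dataset, one column per term
    missing_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        assert len(self.datasets) == self.m


def _imputation_design(cohort: CohortTable) -> pd.DataFrame:
    """Dummy-coded covariate matrix for the imputation model."""
    df = cohort.df
    missing_cols = [c for c in IMPUTATION_COVARIATES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"imputation covariates absent from cohort: {missing_cols}")
    parts = {"const": np.ones(len(df))}
    for col in ("site", "histology", "stage"):
        series = df[col].astype(object).where(df[col].notna(), "missing")
        levels = sorted(series.unique())
        for level in levels[1:]:  # first level is the reference
            parts[f"{col}_{level}"] = (series == level).to_numpy(dtype=float)
    for col in ("adjuvant", "neoadjuvant"):
        parts[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).to_numpy(dtype=float)
    age = pd.to_numeric(df["age_dx"], errors="coerce")
    parts["age_dx"] = (age.fillna(age.mean()) - age.mean()).to_numpy(dtype=float)
    parts["cumhaz"] = nelson_aalen(df["time_days"].to_numpy(), df["event"].to_numpy())
    parts["event"] = df["event"].to_numpy(dtype=float)
    return pd.DataFrame(parts, index=df.index)


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MLE and covariance for the imputation logistic; ridge fallback on separation.

    Returns (coef, cov). The ridge fallback (small L2 on non-intercept terms)
    keeps the posterior draw proper when a dummy cell perfectly predicts the
    outcome, and logs a warning.
    """
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        coef = fit.params
        cov = fit.cov_params()
        if (np.all(np.isfinite(coef)) and np.all(np.isfinite(cov))
                and np.max(np.abs(coef)) < 15):
            return np.asarray(coef), np.asarray(cov)
    except Exception:  # perfect separation raises in some statsmodels versions
        pass
    logger.warning("imputation logistic unstable (separation?); using ridge-stabilized fit")
    lam = 1.0
    penalty = lam * np.eye(X.shape[1])
    penalty[0, 0] = 0.0  # leave the intercept unpenalized
    coef = np.zeros(X.shape[1])
    for _ in range(100):  # penalized IRLS
        eta = np.clip(X @ coef, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        H = X.T @ (X * w[:, None]) + penalty
        g = X.T @ (y - p) - penalty @ coef
        step = np.linalg.solve(H, g)
        coef = coef + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ coef, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + penalty)
    return coef, cov


def impute_mi(cohort: CohortTable, m: int = 25, seed: int = 0) -> ImputationSet:
    """White–Royston multiple imputation of debulking status.

    For each of the m datasets the imputation-model coefficients are drawn
    from the large-sample normal approximation to their posterior (mean MLE,
    covariance the inverse information), and each missing status is a
    Bernoulli draw from the resulting predicted probability of suboptimal
    debulking. Observed values are never altered. Deterministic given seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df = cohort.df
    if "debulk" not in df.columns:
        raise ValueError("cohort has no debulk column")
    debulk = df["debulk"].to_numpy(dtype=object)
    missing = pd.isna(df["debulk"]).to_numpy()
    rng = np.random.default_rng(seed)

    if not missing.any():
        coefs = pd.DataFrame(index=range(m))
        return ImputationSet(m=m, datasets=[debulk.copy() for _ in range(m)],
                             coefficients=coefs, missing_mask=missing, seed=seed)

    design = _imputation_design(cohort)
    X = design.to_numpy(dtype=float)
    y_obs = np.array([DEBULK_CODES[v] for v in debulk[~missing]], dtype=float)
    coef, cov = _fit_logistic(X[~missing], y_obs)
    # symmetrize and draw via Cholesky with a tiny jitter for safety
    cov = (cov + cov.T) / 2 + 1e-10 * np.eye(cov.shape[0])
    chol = np.linalg.cholesky(cov)

    datasets, rows = [], []
    X_mis = X[missing]
    for _ in range(m):
        beta = coef + chol @ rng.standard_normal(coef.size)
        p_sub = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ beta, -30, 30)))
        draw = rng.random(p_sub.size) < p_sub
        completed = debulk.copy()
        completed[missing] = np.where(draw, "suboptimal", "optimal")
        datasets.append(completed)
        rows.append(beta)
    coefs = pd.DataFrame(rows, columns=design.columns)
    return ImputationSet(m=m, datasets=datasets, coefficients=coefs,
                         missing_mask=missing, seed=seed)


def consensus_mode(imps: ImputationSet) -> np.ndarray:
    """Per-participant mode of debulking status across the m completed datasets.

    Observed values pass through unchanged. Ties break toward suboptimal,
    the worse-prognosis category.
    """
    stacked = np.stack([np.asarray(d, dtype=object) for d in imps.datasets])
    n = stacked.shape[1]
    out = stacked[0].copy()
    for i in np.nonzero(imps.missing_mask)[0] if imps.missing_mask.any() else []:
        n_sub = int((stacked[:, i] == "suboptimal").sum())
        out[i] = "suboptimal" if n_sub >= imps.m - n_sub else "optimal"
    assert out.shape == (n,)
    return out


def apply_consensus(cohort: CohortTable, consensus: np.ndarray) -> CohortTable:
    """Cohort copy with the consensus debulking vector substituted in."""
    df = cohort.df.copy()
    df["debulk"] = consensus
    return CohortTable(df=df, exposures=cohort.exposures)
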