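"""Bayesian joint structural-equation model for survival mediation.

The outcome is a Weibull proportional-hazards mixed model for time to death,

    h(t | X, M, C, U) = kappa t^(kappa-1) exp(eta),
    eta = beta0 + betaX X + betaM' 1[M] + betaC' C + lambdaT U_g,

jointly with a mediator model — multinomial logit for 3-level stage or
Bernoulli logit for binary debulking —

    P(M = k | X, C, U) propto exp(alpha0k + alphaXk X + alphaCk' C + lambdaM U_g),

sharing one tract-level latent effect U_g ~ Normal(0, sigma_u^2) that enters
both linear predictors with separate scalings (lambdaT constrained positive
for sign identifiability). Estimation is Metropolis-within-Gibbs with
adaptive random-walk proposals (adaptation frozen after burn-in), and
candidate modifiers can be toggled by Gibbs variable selection: one binary
indicator per modifier switches that modifier's columns in and out of the
hazard's linear predictor (the mediator model always carries the candidate
modifier set), with pseudo-priors fitted from a pilot all-modifiers run.
The recorded inclusion frequency of each modifier drives a two-phase
workflow: select modifiers with frequency above 0.5, then refit with the
selected set only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, ExposureSpec, MODIFIERS, encode_modifiers, standardize_exposure

STAGE_CODES = {"localized": 0, "regional": 1, "distant": 2}
DEBULK_CODES_MODEL = {"optimal": 0, "suboptimal": 1}


# ---------------------------------------------------------------------------
# data container


@dataclass
class ModelData:
    """Arrays the sampler consumes: one validated cohort, one exposure, one mediator."""

    time: np.ndarray
    event: np.ndarray
    x: np.ndarray
    m_code: np.ndarray
    n_levels: int
    levels: tuple
    C: np.ndarray            # (n, p) modifier design
    columns: list            # column names of C
    groups: dict             # modifier name -> list of column indices in C
    tract: np.ndarray        # participant -> tract code
    n_tracts: int
    mediator: str

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.C.shape[1]


def build_model_data(cohort: CohortTable, exposure: ExposureSpec, mediator: str,
                     modifiers: tuple = tuple(MODIFIERS)) -> ModelData:
    """Assemble sampler inputs from a cohort.

    The mediator must be complete (impute debulking first; rows with unknown
    stage must be dropped before calling). Missing exposure values are set
    to the standardized mean (zero) — a handful per index in this cohort.
    """
    df = cohort.df
    x = standardize_exposure(cohort, exposure)
    x = np.where(np.isnan(x), 0.0, x)

    if mediator == "stage3":
        codes_map, levels = STAGE_CODES, ("localized", "regional", "distant")
        col = "stage"
    elif mediator == "debulk2":
        codes_map, levels = DEBULK_CODES_MODEL, ("optimal", "suboptimal")
        col = "debulk"
    else:
        raise ValueError(f"unknown mediator {mediator!r}")
    series = df[col]
    if series.isna().any():
        raise ValueError(f"mediator column {col!r} has missing values; "
                         "impute or drop incomplete rows first")
    m_code = series.map(codes_map).to_numpy(dtype=int)

    if modifiers:
        C_df, meta = encode_modifiers(cohort, modifiers)
        C = C_df.to_numpy(dtype=float)
        columns = list(C_df.columns)
        groups: dict = {}
        for j, m in enumerate(meta):
            groups.setdefault(m["modifier"], []).append(j)
    else:
        C = np.zeros((len(df), 0))
        columns, groups = [], {}

    tract_codes, _ = pd.factorize(df["tract_id"])
    return ModelData(
        time=df["time_days"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        x=x, m_code=m_code, n_levels=len(levels), levels=levels,
        C=C, columns=columns, groups=groups,
        tract=tract_codes.astype(int), n_tracts=int(tract_codes.max()) + 1,
        mediator=mediator,
    )


def drop_missing_mediator(cohort: CohortTable, mediator: str) -> CohortTable:
    """Complete-case restriction on the mediator column."""
    col = "stage" if mediator == "stage3" else "debulk"
    df = cohort.df[cohort.df[col].notna()].reset_index(drop=True)
    return CohortTable(df=df, exposures=cohort.exposures)


# ---------------------------------------------------------------------------
# model spec and results


@dataclass
class JointModelSpec:
    """Priors, candidate modifiers and MCMC settings for one joint fit."""

    exposure: ExposureSpec
    mediator: str = "stage3"
    candidate_modifiers: tuple = tuple(MODIFIERS)
    prior_sd_coef: float = 3.16          # ~ sqrt(10), weakly informative
    prior_sd_logkappa: float = 2.0
    prior_sd_sigma_u: float = 1.0        # half-normal on the latent sd
    prior_sd_lambda: float = 1.0         # half-normal lambdaT (>0), normal lambdaM
    gvs_prior_prob: float = 0.5
    selection_threshold: float = 0.5
    chains: int = 2
    iterations: int = 1500
    burn_in: int = 500
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.selection_threshold < 1:
            raise ValueError("selection_threshold must be in (0,1)")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.mediator not in ("stage3", "debulk2"):
            raise ValueError("mediator must be 'stage3' or 'debulk2'")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in MCMC samples, per chain.

    ``params[name]`` has shape (chains, draws) for scalars and
    (chains, draws, dim...) for vectors. ``stacked(name)`` flattens chains.
    """

    params: dict
    levels: tuple
    columns: list
    mediator: str
    n_tracts: int

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value (scalars and vector components)."""
        rows = []
        for name, arr in self.params.items():
            for c in range(arr.shape[0]):
                for i in range(arr.shape[1]):
                    v = arr[c, i]
                    if np.ndim(v) == 0:
                        rows.append((c, i, name, float(v)))
                    else:
                        flat = np.ravel(v)
                        for j, vj in enumerate(flat):
                            rows.append((c, i, f"{name}[{j}]", float(vj)))
        return pd.DataFrame(rows, columns=["chain", "iteration", "parameter", "value"])


@dataclass
class GVSReport:
    """Per-modifier inclusion frequencies plus convergence flags."""

    inclusion: dict            # modifier -> frequency in [0, 1]
    threshold: float = 0.5
    max_rhat: float = float("nan")
    converged: bool = True
    notes: list = field(default_factory=list)

    @property
    def selected(self) -> set:
        return select_modifiers(self, self.threshold)


def select_modifiers(report: GVSReport, threshold: float = 0.5) -> set:
    """Modifiers whose inclusion frequency strictly exceeds the threshold.

    A frequency exactly equal to the threshold is excluded ("higher than
    0.5" is read strictly).
    """
    return {m for m, f in report.inclusion.items() if f > threshold}


# ---------------------------------------------------------------------------
# likelihood building blocks


def weibull_loglik(time, event, eta, kappa):
    """Weibull proportional-hazards log-likelihood contribution(s).

    Event: log kappa + (kappa-1) log t + eta - t^kappa e^eta.
    Censored: -t^kappa e^eta.
    Vectorized; scalar inputs give a float.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    e = np.asarray(eta, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not (np.all(np.isfinite(t)) and np.all(t > 0) and np.all(np.isfinite(e))):
        raise ValueError("non-finite or non-positive inputs to weibull_loglik")
    ll = d * (math.log(kappa) + (kappa - 1.0) * np.log(t) + e) - t**kappa * np.exp(e)
    return float(ll) if ll.ndim == 0 else ll


def mediator_loglik(m_code, x, c, u, alpha0, alpha_x, alpha_c, lambda_m, n_levels):
    """Log-probability of the observed mediator categories.

    The latent term lambda_m * u enters every non-reference linear predictor.
    Multinomial logit for 3 levels, Bernoulli logit for 2; the reference
    category's linear predictor is fixed at zero. Vectorized over rows.
    """
    m = np.atleast_1d(np.asarray(m_code, dtype=int))
    if np.any(m < 0) or np.any(m >= n_levels):
        raise ValueError("invalid mediator category code")
    eta = _mediator_eta(np.atleast_1d(np.asarray(x, dtype=float)),
                        np.atleast_2d(np.asarray(c, dtype=float)),
                        np.atleast_1d(np.asarray(u, dtype=float)),
                        alpha0, alpha_x, alpha_c, lambda_m, n_levels)
    logz = _logsumexp_rows(eta)
    ll = eta[np.arange(m.size), m] - logz
    return float(ll[0]) if np.ndim(m_code) == 0 else ll


def _mediator_eta(x, C, u, alpha0, alpha_x, alpha_c, lambda_m, n_levels):
    """(n, L) array of category linear predictors (reference column = 0)."""
    n = x.shape[0]
    eta = np.zeros((n, n_levels))
    lat = lambda_m * u
    for k in range(1, n_levels):
        eta[:, k] = alpha0[k - 1] + alpha_x[k - 1] * x + lat
        if C.shape[1]:
            eta[:, k] += C @ alpha_c[k - 1]
    return eta


def _logsumexp_rows(eta):
    mx = eta.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(eta - mx).sum(axis=1, keepdims=True))).ravel()


def _norm_logpdf(v, mean, sd):
    return -0.5 * ((v - mean) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# sampler state


class _State:
    """Mutable parameter state with cached linear predictors."""

    def __init__(self, data: ModelData, spec: JointModelSpec, rng, fixed: dict,
                 active_cols: np.ndarray, prior_only: bool):
        self.data, self.spec = data, spec
        self.prior_only = prior_only
        n_med = data.n_levels - 1
        d_sum = max(int(data.event.sum()), 1)
        self.vals = {
            "beta0": math.log(d_sum / max(data.time.sum(), 1.0)),
            "beta_x": 0.0,
            "beta_m": np.zeros(n_med),
            "beta_c": np.zeros(data.p),
            "log_kappa": 0.0,
            "log_sigma_u": math.log(0.2),
            "log_lambda_t": 0.0,
            "lambda_m": 0.0,
            "u": np.zeros(data.n_tracts),
            "alpha0": np.zeros(n_med),
            "alpha_x": np.zeros(n_med),
            "alpha_c": np.zeros((n_med, data.p)),
        }
        self.fixed = dict(fixed)
        for k, v in self.fixed.items():
            self.vals[k] = np.asarray(v, dtype=float) if np.ndim(v) else float(v)
        self.active_cols = active_cols  # boolean (p,)
        self._t = data.time
        self._logt = np.log(data.time)
        self._d = data.event.astype(float)
        self._tk_kappa = None
        self._tk = None

    # -- cached pieces ------------------------------------------------------

    @property
    def kappa(self) -> float:
        return math.exp(self.vals["log_kappa"])

    @property
    def sigma_u(self) -> float:
        return math.exp(self.vals["log_sigma_u"])

    @property
    def lambda_t(self) -> float:
        return math.exp(self.vals["log_lambda_t"])

    def tkappa(self) -> np.ndarray:
        k = self.kappa
        if self._tk_kappa != k:
            self._tk = self._t ** k
            self._tk_kappa = k
        return self._tk

    def eta_out(self, beta_c=None, beta0=None, beta_x=None, beta_m=None,
                lambda_t=None, u=None) -> np.ndarray:
        v = self.vals
        beta_c = v["beta_c"] if beta_c is None else beta_c
        beta0 = v["beta0"] if beta0 is None else beta0
        beta_x = v["beta_x"] if beta_x is None else beta_x
        beta_m = v["beta_m"] if beta_m is None else beta_m
        lambda_t = self.lambda_t if lambda_t is None else lambda_t
        u = v["u"] if u is None else u
        d = self.data
        bm_full = np.concatenate([[0.0], beta_m])
        eta = beta0 + beta_x * d.x + bm_full[d.m_code] + lambda_t * u[d.tract]
        if d.p:
            bc = np.where(self.active_cols, beta_c, 0.0)
            eta = eta + d.C @ bc
        return eta

    def ll_out_i(self, eta=None, kappa=None) -> np.ndarray:
        if self.prior_only:
            return np.zeros(self.data.n)
        eta = self.eta_out() if eta is None else eta
        kappa = self.kappa if kappa is None else kappa
        if kappa == self.kappa:
            tk = self.tkappa()
        else:
            tk = self._t ** kappa
        with np.errstate(over="ignore"):  # overflow -> -inf, proposal rejected
            return self._d * (math.log(kappa) + (kappa - 1.0) * self._logt + eta) \
                - tk * np.exp(eta)

    def eta_med(self, alpha0=None, alpha_x=None, alpha_c=None,
                lambda_m=None, u=None) -> np.ndarray:
        v = self.vals
        alpha0 = v["alpha0"] if alpha0 is None else alpha0
        alpha_x = v["alpha_x"] if alpha_x is None else alpha_x
        alpha_c = v["alpha_c"] if alpha_c is None else alpha_c
        lambda_m = v["lambda_m"] if lambda_m is None else lambda_m
        u = v["u"] if u is None else u
        d = self.data
        return _mediator_eta(d.x, d.C, u[d.tract], alpha0, alpha_x, alpha_c,
                             lambda_m, d.n_levels)

    def ll_med_i(self, eta=None) -> np.ndarray:
        if self.prior_only:
            return np.zeros(self.data.n)
        eta = self.eta_med() if eta is None else eta
        d = self.data
        return eta[np.arange(d.n), d.m_code] - _logsumexp_rows(eta)

    # -- log prior ----------------------------------------------------------

    def log_prior_scalar(self, name: str, value: float) -> float:
        s = self.spec
        if name in ("beta0", "beta_x"):
            return _norm_logpdf(value, 0.0, s.prior_sd_coef)
        if name == "log_kappa":
            return _norm_logpdf(value, 0.0, s.prior_sd_logkappa)
        if name == "log_sigma_u":
            sig = math.exp(value)
            return -0.5 * (sig / s.prior_sd_sigma_u) ** 2 + value
        if name == "log_lambda_t":
            lam = math.exp(value)
            return -0.5 * (lam / s.prior_sd_lambda) ** 2 + value
        if name == "lambda_m":
            return _norm_logpdf(value, 0.0, s.prior_sd_lambda)
        raise KeyError(name)


# ---------------------------------------------------------------------------
# pseudo-priors for GVS


@dataclass
class PseudoPriors:
    """Pilot-run posterior summaries used as GVS pseudo-priors (hazard coefficients)."""

    beta_c_mean: np.ndarray
    beta_c_sd: np.ndarray


def fit_pseudo_priors(draws: PosteriorDraws) -> PseudoPriors:
    bc = draws.stacked("beta_c")
    return PseudoPriors(
        beta_c_mean=bc.mean(axis=0),
        beta_c_sd=np.maximum(bc.std(axis=0, ddof=1), 1e-3),
    )


# ---------------------------------------------------------------------------
# MCMC driver


def _adapt(scale: float, acc: int, tries: int) -> float:
    if tries == 0:
        return scale
    rate = acc / tries
    if rate > 0.45:
        scale *= 1.35
    elif rate < 0.20:
        scale /= 1.35
    return float(np.clip(scale, 1e-4, 20.0))


def run_mcmc(data: ModelData, spec: JointModelSpec, *,
             gvs: bool = False,
             pseudo: PseudoPriors | None = None,
             active_modifiers: set | None = None,
             fixed: dict | None = None,
             prior_only: bool = False,
             iterations: int | None = None,
             burn_in: int | None = None,
             seed: int | None = None) -> tuple[PosteriorDraws, GVSReport]:
    """Metropolis-within-Gibbs sampler for the joint model.

    ``gvs=True`` samples one inclusion indicator per candidate modifier
    (requires ``pseudo`` pseudo-priors from a pilot run); otherwise the
    active set is fixed to ``active_modifiers`` (default: all candidates).
    ``fixed`` pins named parameters (e.g. ``{"log_kappa": 0.0}`` for the
    exponential limit); ``prior_only`` switches the likelihood off so the
    posterior collapses to the priors. Deterministic given the seed.
    """
    if gvs and pseudo is None:
        raise ValueError("GVS requires pseudo-priors from a pilot run")
    iterations = spec.iterations if iterations is None else iterations
    burn_in = spec.burn_in if burn_in is None else burn_in
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    base_seed = spec.seed if seed is None else seed
    fixed = fixed or {}

    modifiers = [m for m in spec.candidate_modifiers if m in data.groups]
    if active_modifiers is None:
        active_modifiers = set(modifiers)

    chain_store: list[dict] = []
    gamma_freq_chains = []
    for c in range(spec.chains):
        store, gamma_mean = _run_chain(data, spec, gvs, pseudo, modifiers,
                                       active_modifiers, fixed, prior_only,
                                       iterations, burn_in,
                                       np.random.default_rng((base_seed, c)))
        chain_store.append(store)
        gamma_freq_chains.append(gamma_mean)

    params = {k: np.stack([s[k] for s in chain_store]) for k in chain_store[0]}
    draws = PosteriorDraws(params=params, levels=data.levels,
                           columns=data.columns, mediator=data.mediator,
                           n_tracts=data.n_tracts)

    inclusion = {}
    if gvs and modifiers:
        freq = np.mean(gamma_freq_chains, axis=0)
        inclusion = {m: float(freq[j]) for j, m in enumerate(modifiers)}

    max_rhat, notes = _convergence(draws)
    report = GVSReport(inclusion=inclusion, threshold=spec.selection_threshold,
                       max_rhat=max_rhat, converged=not notes, notes=notes)
    return draws, report


def _convergence(draws: PosteriorDraws) -> tuple[float, list]:
    if draws.n_chains < 2:
        return float("nan"), []
    rhats = []
    # sigma_u, lambda_t and lambda_m are individually identified only through
    # the priors (scale redundancy); convergence is judged on the identified
    # products lt_sigma = lambdaT*sigma_u and lm_sigma = lambdaM*sigma_u.
    for name in ("beta0", "beta_x", "kappa", "lt_sigma", "lm_sigma"):
        if name in draws.params:
            rhats.append(_split_rhat(draws.params[name]))
    bm = draws.params.get("beta_m")
    if bm is not None:
        for j in range(bm.shape[2]):
            rhats.append(_split_rhat(bm[:, :, j]))
    max_rhat = float(np.nanmax(rhats)) if rhats else float("nan")
    notes = [] if (np.isnan(max_rhat) or max_rhat <= 1.1) else \
        [f"max split-R-hat {max_rhat:.3f} > 1.1: chains may not have converged"]
    return max_rhat, notes


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split-R-hat on a (chains, draws) array."""
    a = np.asarray(chains_draws, dtype=float)
    half = a.shape[1] // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([a[:, :half], a[:, half:2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _run_chain(data, spec, gvs, pseudo, modifiers, active_modifiers, fixed,
               prior_only, iterations, burn_in, rng):
    p, n_med = data.p, data.n_levels - 1
    active_cols = np.zeros(p, dtype=bool)
    gamma = np.array([m in active_modifiers for m in modifiers], dtype=bool)
    if gvs:
        gamma = rng.random(len(modifiers)) < spec.gvs_prior_prob
    for j, m in enumerate(modifiers):
        if gamma[j]:
            active_cols[data.groups[m]] = True
    # columns of non-candidate modifiers (if any) stay inactive

    st = _State(data, spec, rng, fixed, active_cols, prior_only)
    scalar_blocks = [b for b in ("beta0", "beta_x", "log_kappa",
                                 "log_sigma_u", "log_lambda_t", "lambda_m")
                     if b not in fixed]
    scales = {b: 0.2 for b in scalar_blocks}
    scales.update({f"beta_m{k}": 0.2 for k in range(n_med)})
    scales.update({f"alpha0_{k}": 0.2 for k in range(n_med)})
    scales.update({f"alpha_x{k}": 0.2 for k in range(n_med)})
    scales.update({f"bc{j}": 0.2 for j in range(p)})
    scales.update({f"ac{k}_{j}": 0.3 for k in range(n_med) for j in range(p)})
    scales["u"] = 0.3
    scales["timescale"] = 0.1
    scales["ridge"] = 0.5
    acc = {k: 0 for k in scales}
    tries = {k: 0 for k in scales}

    keep = []
    gamma_draws = []
    sd_coef = spec.prior_sd_coef

    ll_out = st.ll_out_i().sum()
    ll_med = st.ll_med_i().sum()

    for it in range(iterations):
        v = st.vals

        # ---- outcome-side scalar updates (only outcome likelihood moves) --
        for name in ("beta0", "beta_x", "log_kappa"):
            if name in fixed:
                continue
            cur = v[name]
            prop = cur + scales[name] * rng.standard_normal()
            tries[name] += 1
            if name == "log_kappa":
                new_ll = st.ll_out_i(kappa=math.exp(prop)).sum() if not prior_only else 0.0
            else:
                kw = {name: prop}
                new_ll = st.ll_out_i(eta=st.eta_out(**kw)).sum() if not prior_only else 0.0
            logr = (new_ll - ll_out
                    + st.log_prior_scalar(name, prop) - st.log_prior_scalar(name, cur))
            if math.log(rng.random()) < logr:
                v[name] = prop
                ll_out = new_ll
                acc[name] += 1

        # beta_m components
        for k in range(n_med):
            key = f"beta_m{k}"
            if "beta_m" in fixed:
                continue
            cur = v["beta_m"][k]
            prop_vec = v["beta_m"].copy()
            prop_vec[k] = cur + scales[key] * rng.standard_normal()
            tries[key] += 1
            new_ll = st.ll_out_i(eta=st.eta_out(beta_m=prop_vec)).sum() if not prior_only else 0.0
            logr = (new_ll - ll_out
                    + _norm_logpdf(prop_vec[k], 0, sd_coef) - _norm_logpdf(cur, 0, sd_coef))
            if math.log(rng.random()) < logr:
                v["beta_m"] = prop_vec
                ll_out = new_ll
                acc[key] += 1

        # active modifier columns in the outcome model
        for j in range(p):
            if not st.active_cols[j] or "beta_c" in fixed:
                continue
            key = f"bc{j}"
            cur = v["beta_c"][j]
            prop_vec = v["beta_c"].copy()
            prop_vec[j] = cur + scales[key] * rng.standard_normal()
            tries[key] += 1
            new_ll = st.ll_out_i(eta=st.eta_out(beta_c=prop_vec)).sum() if not prior_only else 0.0
            logr = (new_ll - ll_out
                    + _norm_logpdf(prop_vec[j], 0, sd_coef) - _norm_logpdf(cur, 0, sd_coef))
            if math.log(rng.random()) < logr:
                v["beta_c"] = prop_vec
                ll_out = new_ll
                acc[key] += 1

        # ---- mediator-side updates ---------------------------------------
        for k in range(n_med):
            for base, key in (("alpha0", f"alpha0_{k}"), ("alpha_x", f"alpha_x{k}")):
                if base in fixed:
                    continue
                cur = v[base][k]
                prop_vec = v[base].copy()
                prop_vec[k] = cur + scales[key] * rng.standard_normal()
                tries[key] += 1
                kw = {base: prop_vec}
                new_ll = st.ll_med_i(eta=st.eta_med(**kw)).sum() if not prior_only else 0.0
                logr = (new_ll - ll_med
                        + _norm_logpdf(prop_vec[k], 0, sd_coef) - _norm_logpdf(cur, 0, sd_coef))
                if math.log(rng.random()) < logr:
                    v[base] = prop_vec
                    ll_med = new_ll
                    acc[key] += 1
            for j in range(p):
                if "alpha_c" in fixed:
                    continue
                key = f"ac{k}_{j}"
                cur = v["alpha_c"][k, j]
                prop_mat = v["alpha_c"].copy()
                prop_mat[k, j] = cur + scales[key] * rng.standard_normal()
                tries[key] += 1
                new_ll = st.ll_med_i(eta=st.eta_med(alpha_c=prop_mat)).sum() if not prior_only else 0.0
                logr = (new_ll - ll_med
                        + _norm_logpdf(prop_mat[k, j], 0, sd_coef) - _norm_logpdf(cur, 0, sd_coef))
                if math.log(rng.random()) < logr:
                    v["alpha_c"] = prop_mat
                    ll_med = new_ll
                    acc[key] += 1

        # lambda_m (mediator side), log_lambda_t (outcome side)
        if "lambda_m" not in fixed:
            cur = v["lambda_m"]
            prop = cur + scales["lambda_m"] * rng.standard_normal()
            tries["lambda_m"] += 1
            new_ll = st.ll_med_i(eta=st.eta_med(lambda_m=prop)).sum() if not prior_only else 0.0
            logr = (new_ll - ll_med
                    + st.log_prior_scalar("lambda_m", prop) - st.log_prior_scalar("lambda_m", cur))
            if math.log(rng.random()) < logr:
                v["lambda_m"] = prop
                ll_med = new_ll
                acc["lambda_m"] += 1
        if "log_lambda_t" not in fixed:
            cur = v["log_lambda_t"]
            prop = cur + scales["log_lambda_t"] * rng.standard_normal()
            tries["log_lambda_t"] += 1
            new_ll = st.ll_out_i(eta=st.eta_out(lambda_t=math.exp(prop))).sum() if not prior_only else 0.0
            logr = (new_ll - ll_out
                    + st.log_prior_scalar("log_lambda_t", prop)
                    - st.log_prior_scalar("log_lambda_t", cur))
            if math.log(rng.random()) < logr:
                v["log_lambda_t"] = prop
                ll_out = new_ll
                acc["log_lambda_t"] += 1

        # joint timescale move: kappa and beta0 are strongly correlated
        # (both set the hazard's time scale); move along the ridge
        # beta0 + kappa * mean(log t) = const for decent mixing.
        if "log_kappa" not in fixed and "beta0" not in fixed and not prior_only:
            key = "timescale"
            delta = scales[key] * rng.standard_normal()
            k_new = math.exp(v["log_kappa"] + delta)
            b0_new = v["beta0"] - (k_new - st.kappa) * st._logt.mean()
            tries[key] += 1
            new_ll = st.ll_out_i(eta=st.eta_out(beta0=b0_new), kappa=k_new).sum()
            logr = (new_ll - ll_out
                    + st.log_prior_scalar("log_kappa", math.log(k_new))
                    - st.log_prior_scalar("log_kappa", v["log_kappa"])
                    + st.log_prior_scalar("beta0", b0_new)
                    - st.log_prior_scalar("beta0", v["beta0"]))
            if math.log(rng.random()) < logr:
                v["log_kappa"] = math.log(k_new)
                v["beta0"] = b0_new
                ll_out = new_ll
                acc[key] += 1

        # ---- latent effects: vectorized per-tract Metropolis --------------
        if "u" not in fixed:
            u = v["u"]
            prop_u = u + scales["u"] * rng.standard_normal(u.size)
            if prior_only:
                d_out = np.zeros(data.n)
                d_med = np.zeros(data.n)
            else:
                cur_out = st.ll_out_i()
                cur_med = st.ll_med_i()
                new_out = st.ll_out_i(eta=st.eta_out(u=prop_u))
                new_med = st.ll_med_i(eta=st.eta_med(u=prop_u))
                d_out = new_out - cur_out
                d_med = new_med - cur_med
            delta_ll = (np.bincount(data.tract, weights=d_out, minlength=data.n_tracts)
                        + np.bincount(data.tract, weights=d_med, minlength=data.n_tracts))
            sig = st.sigma_u
            delta_prior = -0.5 * (prop_u**2 - u**2) / sig**2
            accept = np.log(rng.random(u.size)) < delta_ll + delta_prior
            u_new = np.where(accept, prop_u, u)
            v["u"] = u_new
            tries["u"] += 1
            acc["u"] += float(accept.mean())  # fractional acceptance per sweep
            if not prior_only and accept.any():
                ll_out = st.ll_out_i().sum()
                ll_med = st.ll_med_i().sum()

        # log_sigma_u: conditional on u only (plus prior)
        if "log_sigma_u" not in fixed:
            cur = v["log_sigma_u"]
            prop = cur + scales["log_sigma_u"] * rng.standard_normal()
            tries["log_sigma_u"] += 1
            u = v["u"]
            G = u.size

            def u_prior(log_s):
                s2 = math.exp(2 * log_s)
                return -0.5 * float(u @ u) / s2 - G * log_s

            logr = (u_prior(prop) - u_prior(cur)
                    + st.log_prior_scalar("log_sigma_u", prop)
                    - st.log_prior_scalar("log_sigma_u", cur))
            if math.log(rng.random()) < logr:
                v["log_sigma_u"] = prop
                acc["log_sigma_u"] += 1

        # ridge move for the scale redundancy (sigma_u, lambdaT, lambdaM are
        # identified only through the products lambda*sigma_u): rescale
        # (u, sigma_u) by c and (lambdaT, lambdaM) by 1/c, which leaves the
        # likelihood invariant; accept against the priors (log-Jacobian -delta
        # after the u-prior term cancels).
        if not any(k in fixed for k in ("u", "log_sigma_u", "log_lambda_t", "lambda_m")):
            key = "ridge"
            delta = scales[key] * rng.standard_normal()
            ls_new = v["log_sigma_u"] + delta
            lt_new = v["log_lambda_t"] - delta
            lm_new = v["lambda_m"] * math.exp(-delta)
            tries[key] += 1
            logr = (st.log_prior_scalar("log_sigma_u", ls_new)
                    - st.log_prior_scalar("log_sigma_u", v["log_sigma_u"])
                    + st.log_prior_scalar("log_lambda_t", lt_new)
                    - st.log_prior_scalar("log_lambda_t", v["log_lambda_t"])
                    + st.log_prior_scalar("lambda_m", lm_new)
                    - st.log_prior_scalar("lambda_m", v["lambda_m"])
                    - delta)
            if math.log(rng.random()) < logr:
                v["log_sigma_u"] = ls_new
                v["log_lambda_t"] = lt_new
                v["lambda_m"] = lm_new
                v["u"] = v["u"] * math.exp(delta)
                acc[key] += 1

        # ---- Gibbs variable selection ------------------------------------
        if gvs and modifiers:  # under prior_only the likelihood terms are zero
            for jm, mod in enumerate(modifiers):
                cols = data.groups[mod]
                # hazard likelihood with modifier in vs out, at current values
                with_cols = st.active_cols.copy()
                with_cols[cols] = True
                without_cols = st.active_cols.copy()
                without_cols[cols] = False

                st.active_cols = with_cols
                ll_in = st.ll_out_i().sum()
                st.active_cols = without_cols
                ll_ex = st.ll_out_i().sum()

                lp_in = sum(_norm_logpdf(v["beta_c"][j], 0, sd_coef) for j in cols)
                lp_ex = sum(_norm_logpdf(v["beta_c"][j], pseudo.beta_c_mean[j],
                                         pseudo.beta_c_sd[j]) for j in cols)
                pi = spec.gvs_prior_prob
                log_odds = (ll_in + lp_in + math.log(pi)) - (ll_ex + lp_ex + math.log(1 - pi))
                p_in = 1.0 / (1.0 + math.exp(-np.clip(log_odds, -500, 500)))
                gamma[jm] = rng.random() < p_in
                st.active_cols = with_cols if gamma[jm] else without_cols

            # refresh the outcome likelihood cache after the sweep
            ll_out = st.ll_out_i().sum()

            # Gibbs-draw excluded hazard coefficients from their pseudo-priors
            for jm, mod in enumerate(modifiers):
                if gamma[jm]:
                    continue
                for j in data.groups[mod]:
                    v["beta_c"][j] = pseudo.beta_c_mean[j] + \
                        pseudo.beta_c_sd[j] * rng.standard_normal()

        # ---- adaptation (burn-in only) -----------------------------------
        if it < burn_in and (it + 1) % 25 == 0:
            for kkey in scales:
                scales[kkey] = _adapt(scales[kkey], acc[kkey], tries[kkey])
                acc[kkey] = 0
                tries[kkey] = 0

        # ---- storage ------------------------------------------------------
        if it >= burn_in and (it - burn_in) % spec.thin == 0:
            keep.append({
                "beta0": v["beta0"], "beta_x": v["beta_x"],
                "beta_m": v["beta_m"].copy(), "beta_c": v["beta_c"].copy(),
                "kappa": st.kappa, "sigma_u": st.sigma_u,
                "lambda_t": st.lambda_t, "lambda_m": v["lambda_m"],
                "lt_sigma": st.lambda_t * st.sigma_u,
                "lm_sigma": v["lambda_m"] * st.sigma_u,
                "u": v["u"].copy(), "alpha0": v["alpha0"].copy(),
                "alpha_x": v["alpha_x"].copy(), "alpha_c": v["alpha_c"].copy(),
                "gamma": gamma.astype(float).copy(),
            })
            gamma_draws.append(gamma.astype(float).copy())

    store = {k: np.stack([d[k] for d in keep]) for k in keep[0]}
    gamma_mean = np.mean(gamma_draws, axis=0) if gamma_draws else np.array([])
    return store, gamma_mean


# ---------------------------------------------------------------------------
# joint log posterior (used by tests and as a reference density)


def log_posterior(params: dict, data: ModelData, spec: JointModelSpec,
                  active_modifiers: set | None = None) -> float:
    """Joint log posterior at a named parameter point.

    ``params`` uses the sampler's natural-scale names: beta0, beta_x,
    beta_m, beta_c, kappa, sigma_u, lambda_t, lambda_m, u, alpha0, alpha_x,
    alpha_c. Modifiers outside ``active_modifiers`` (default: all) drop out
    of the hazard's linear predictor and lose their hazard-coefficient prior
    terms; the mediator model always carries the full modifier design.
    Returns -inf off-support.
    """
    kappa = float(params["kappa"])
    sigma_u = float(params["sigma_u"])
    lambda_t = float(params["lambda_t"])
    if kappa <= 0 or sigma_u <= 0 or lambda_t <= 0:
        return -math.inf
    active = set(data.groups) if active_modifiers is None else active_modifiers
    active_cols = np.zeros(data.p, dtype=bool)
    for m in active:
        if m in data.groups:
            active_cols[data.groups[m]] = True

    beta_m = np.asarray(params["beta_m"], dtype=float)
    beta_c = np.asarray(params.get("beta_c", np.zeros(data.p)), dtype=float)
    u = np.asarray(params["u"], dtype=float)
    bm_full = np.concatenate([[0.0], beta_m])
    eta = (params["beta0"] + params["beta_x"] * data.x + bm_full[data.m_code]
           + lambda_t * u[data.tract])
    if data.p:
        eta = eta + data.C @ np.where(active_cols, beta_c, 0.0)
    ll = float(np.sum(weibull_loglik(data.time, data.event, eta, kappa)))

    alpha_c = np.asarray(params.get("alpha_c", np.zeros((data.n_levels - 1, data.p))), dtype=float)
    ll += float(np.sum(mediator_loglik(
        data.m_code, data.x, data.C, u[data.tract],
        np.asarray(params["alpha0"], dtype=float),
        np.asarray(params["alpha_x"], dtype=float),
        alpha_c, float(params["lambda_m"]), data.n_levels)))

    sd = spec.prior_sd_coef
    lp = _norm_logpdf(params["beta0"], 0, sd) + _norm_logpdf(params["beta_x"], 0, sd)
    lp += float(np.sum(_norm_logpdf(beta_m, 0, sd)))
    if data.p:
        lp += float(np.sum(_norm_logpdf(beta_c[active_cols], 0, sd)))
        lp += float(np.sum(_norm_logpdf(alpha_c, 0, sd)))
    lp += _norm_logpdf(math.log(kappa), 0, spec.prior_sd_logkappa)
    lp += -0.5 * (sigma_u / spec.prior_sd_sigma_u) ** 2 + math.log(sigma_u)
    lp += -0.5 * (lambda_t / spec.prior_sd_lambda) ** 2 + math.log(lambda_t)
    lp += _norm_logpdf(params["lambda_m"], 0, spec.prior_sd_lambda)
    lp += float(np.sum(_norm_logpdf(u, 0, sigma_u)))
    lp += float(np.sum(_norm_logpdf(np.asarray(params["alpha0"]), 0, sd)))
    lp += float(np.sum(_norm_logpdf(np.asarray(params["alpha_x"]), 0, sd)))
    return ll + lp


# ---------------------------------------------------------------------------
# diagnostics and the two-phase workflow


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-R-hat and bulk effective sample size per retained scalar parameter."""
    import arviz as az

    flat = {}
    for name, arr in draws.params.items():
        if name in ("u", "gamma", "alpha_c", "beta_c"):
            continue
        if arr.ndim == 2:
            flat[name] = arr
        else:
            for j in range(arr.shape[2]):
                flat[f"{name}[{j}]"] = arr[:, :, j]
    ds = az.convert_to_dataset(flat)
    ess = az.ess(ds)
    rows = []
    if draws.n_chains >= 2:
        rhat = az.rhat(ds)
        for name in flat:
            rows.append({"parameter": name, "rhat": float(rhat[name]),
                         "ess": float(ess[name])})
    else:
        for name in flat:
            rows.append({"parameter": name, "rhat": float("nan"),
                         "ess": float(ess[name])})
    return pd.DataFrame(rows)


@dataclass
class TwoPhaseResult:
    """Output of the select-then-refit workflow."""

    gvs_report: GVSReport
    selected: set
    draws: PosteriorDraws        # final refit draws
    refit_report: GVSReport
    pilot_draws: PosteriorDraws


def fit_two_phase(data: ModelData, spec: JointModelSpec,
                  pilot_iterations: int | None = None) -> TwoPhaseResult:
    """Pilot run -> pseudo-priors -> GVS phase -> strict-threshold selection -> refit.

    The pilot includes every candidate modifier and supplies the GVS
    pseudo-priors; the refit keeps only the selected modifiers and yields
    the draws used for effect estimation.
    """
    pilot_it = pilot_iterations or max(spec.burn_in + 200, spec.iterations // 2)
    pilot_burn = min(spec.burn_in, pilot_it - 100)
    pilot_draws, _ = run_mcmc(data, spec, gvs=False, iterations=pilot_it,
                              burn_in=pilot_burn, seed=spec.seed + 101)
    pseudo = fit_pseudo_priors(pilot_draws)
    _, gvs_report = run_mcmc(data, spec, gvs=True, pseudo=pseudo,
                             seed=spec.seed + 202)
    selected = select_modifiers(gvs_report, spec.selection_threshold)
    draws, refit_report = run_mcmc(data, spec, gvs=False,
                                   active_modifiers=selected,
                                   seed=spec.seed + 303)
    refit_report.inclusion = gvs_report.inclusion
    return TwoPhaseResult(gvs_report=gvs_report, selected=selected,
                          draws=draws, refit_report=refit_report,
                          pilot_draws=pilot_draws)
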