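"""Posterior-predictive chi-square discrepancies and Bayesian fit
indices: PPp, pD, BRMSEA (PPMC and DevM forms), BCFI, and BTLI.

For each retained posterior draw theta_i the chi-square discrepancy

    D(S, Sigma_i) = N [ ln|Sigma_i| + tr(S Sigma_i^-1) - ln|S| - p ]

is evaluated at the observed covariance (``d_obs``) and at the
covariance of a fresh dataset simulated from theta_i (``d_rep``), with S
the divisor-N sample covariance.  Intercepts are saturated (posterior
centered on the sample means), so the fit indices are built on the
covariance-structure discrepancy alone; p* = p(p+1)/2 then counts the
modeled moments and the effective number of parameters pD approaches
the free covariance-structure parameter count q under diffuse priors.
``chi_square_discrepancy`` itself accepts optional mean vectors and adds
the N (xbar - mu)' Sigma^-1 (xbar - mu) term, which makes it exactly
-2 log LR against the saturated model — that form is used for oracle
checks, not for the index series.

The independence (null) baseline — zero covariances, free means and
variances — has a conjugate posterior that is sampled directly.

Summaries: posterior mean/SD, equal-tailed 90% credible interval,
cutoff-based rejection (BRMSEA > .06, BCFI/BTLI < .95, PPp outside
[.05, .95]), and good/poor/inconclusive interval classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs_sampler import PosteriorDraws, point_estimates
from .population_models import CfaModelSpec, count_free_parameters
from .synthetic_data import Dataset

__all__ = [
    "DiscrepancySeries", "FitIndexResult",
    "chi_square_discrepancy", "discrepancy_series", "fit_null_model",
    "ppp", "effective_params", "brmsea_ppmc", "brmsea_devm", "bcfi", "btli",
    "decide", "all_indices",
]

#: rejection cutoffs
BRMSEA_CUTOFF = 0.06
INCREMENTAL_CUTOFF = 0.95
PPP_BOUNDS = (0.05, 0.95)


@dataclass
class DiscrepancySeries:
    """Per-draw observed/replicated discrepancies for the hypothesized
    model and, when attached, the independence null model."""

    d_obs: np.ndarray
    d_rep: np.ndarray | None
    p_star: int
    pD: float
    N: int
    q: int
    d_obs_null: np.ndarray | None = None
    d_rep_null: np.ndarray | None = None
    pD_null: float | None = None

    @property
    def m(self) -> int:
        return self.d_obs.shape[0]


@dataclass
class FitIndexResult:
    index_name: str
    draw_series: np.ndarray | None
    posterior_mean: float
    posterior_sd: float
    ci90: tuple
    ppp: float | None = None
    rejected: bool | None = None
    ci_class: str | None = None


def _summaries(name, series) -> FitIndexResult:
    series = np.asarray(series, dtype=float)
    valid = series[np.isfinite(series)]
    if valid.size == 0:
        raise ValueError(f"no valid draws for {name}")
    lo, hi = np.quantile(valid, [0.05, 0.95])
    return FitIndexResult(
        index_name=name, draw_series=series,
        posterior_mean=float(valid.mean()),
        posterior_sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        ci90=(float(lo), float(hi)),
    )


def chi_square_discrepancy(sample_mean, sample_cov, model_mean, model_cov,
                           N: int) -> float:
    """Likelihood-ratio chi-square discrepancy against the saturated
    model.  Pass ``sample_mean = model_mean = None`` (or equal vectors)
    for the covariance-structure-only form."""
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(model_cov, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    sigma_inv = np.linalg.inv(sigma)
    d = logdet_m + np.sum(sigma_inv * S) - logdet_s - p
    if sample_mean is not None and model_mean is not None:
        diff = np.asarray(sample_mean, dtype=float) - np.asarray(model_mean, dtype=float)
        d += diff @ sigma_inv @ diff
    return float(N * d)


def _implied_sigma(draws: PosteriorDraws, i: int) -> np.ndarray:
    lam = draws.loadings[i]
    sigma = lam @ draws.factor_corr[i] @ lam.T
    sigma[np.diag_indices_from(sigma)] += draws.residual_variances[i]
    return sigma


def discrepancy_series(data: Dataset, draws: PosteriorDraws, rng,
                       compute_rep: bool = True) -> DiscrepancySeries:
    """Observed and replicated chi-square discrepancy at every retained
    draw.  ``rng`` drives the replicated-data simulation; pass
    ``compute_rep=False`` to skip it (PPp and the PPMC-form BRMSEA then
    become unavailable)."""
    X = data.values
    N, p = X.shape
    S = np.cov(X, rowvar=False, ddof=0)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")

    m = draws.m
    d_obs = np.empty(m)
    d_rep = np.empty(m) if compute_rep else None
    for i in range(m):
        sigma = _implied_sigma(draws, i)
        chol = np.linalg.cholesky(sigma)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        sigma_inv = np.linalg.inv(sigma)
        d_obs[i] = N * (logdet + np.sum(sigma_inv * S) - logdet_S - p)
        if compute_rep:
            Y = rng.standard_normal((N, p)) @ chol.T
            S_rep = np.cov(Y, rowvar=False, ddof=0)
            sign_r, logdet_r = np.linalg.slogdet(S_rep)
            d_rep[i] = N * (logdet + np.sum(sigma_inv * S_rep) - logdet_r - p)

    theta_bar = point_estimates(draws)
    lam = theta_bar["loadings"]
    sigma_bar = lam @ theta_bar["factor_corr"] @ lam.T
    sigma_bar[np.diag_indices_from(sigma_bar)] += theta_bar["residual_variances"]
    d_at_mean = chi_square_discrepancy(None, S, None, sigma_bar, N)
    q = count_free_parameters(draws.model) if draws.model is not None else 0
    return DiscrepancySeries(
        d_obs=d_obs, d_rep=d_rep,
        p_star=p * (p + 1) // 2,
        pD=float(d_obs.mean() - d_at_mean),
        N=N, q=q,
    )


def fit_null_model(data: Dataset, m: int, rng,
                   compute_rep: bool = False):
    """Bayesian fit of the independence model (diagonal covariance, free
    means and variances).  The posterior is conjugate — variances
    IG((n-3)/2, SS_j/2), means normal given the variance — so ``m``
    draws are sampled directly.  Returns (d_obs_null, d_rep_null,
    pD_null)."""
    X = data.values
    N, p = X.shape
    S = np.cov(X, rowvar=False, ddof=0)
    sign, logdet_S = np.linalg.slogdet(S)
    ss = N * np.diag(S)                                  # residual SS around the mean
    shape = 0.5 * (N - 3)
    psi = 0.5 * ss / rng.gamma(shape, size=(m, p))       # (m, p)
    # covariance-structure discrepancy of a diagonal model
    d_obs = N * (np.log(psi).sum(axis=1) + (np.diag(S) / psi).sum(axis=1)
                 - logdet_S - p)
    psi_bar = psi.mean(axis=0)
    d_at_mean = N * (np.log(psi_bar).sum() + (np.diag(S) / psi_bar).sum()
                     - logdet_S - p)
    pD_null = float(d_obs.mean() - d_at_mean)
    d_rep = None
    if compute_rep:
        d_rep = np.empty(m)
        for i in range(m):
            Y = rng.standard_normal((N, p)) * np.sqrt(psi[i])
            S_rep = np.cov(Y, rowvar=False, ddof=0)
            sign_r, logdet_r = np.linalg.slogdet(S_rep)
            d_rep[i] = N * (np.log(psi[i]).sum() + (np.diag(S_rep) / psi[i]).sum()
                            - logdet_r - p)
    return d_obs, d_rep, pD_null


def attach_null(series: DiscrepancySeries, d_obs_null, d_rep_null, pD_null) -> DiscrepancySeries:
    if d_obs_null.shape[0] != series.m:
        raise ValueError("null series length must match the hypothesized series")
    series.d_obs_null = d_obs_null
    series.d_rep_null = d_rep_null
    series.pD_null = pD_null
    return series


# -- indices -------------------------------------------------------------

def ppp(series: DiscrepancySeries) -> float:
    """Posterior predictive p-value: share of draws with observed
    discrepancy below the replicated one."""
    if series.d_rep is None:
        raise ValueError("PPp needs the replicated series")
    if series.m == 0:
        raise ValueError("empty series")
    return float(np.mean(series.d_obs < series.d_rep))


def effective_params(series: DiscrepancySeries) -> float:
    """pD = mean posterior deviance minus deviance at the posterior
    mean (already computed when the series was built)."""
    return series.pD


def _check_pd(series):
    if series.p_star <= series.pD:
        raise ValueError("p* <= pD: effective parameters exceed modeled moments")


def brmsea_ppmc(series: DiscrepancySeries) -> FitIndexResult:
    """Bayesian RMSEA with per-draw noncentrality D_obs - D_rep."""
    _check_pd(series)
    if series.d_rep is None:
        raise ValueError("PPMC form needs the replicated series")
    df = series.p_star - series.pD
    vals = np.sqrt(np.maximum(0.0, (series.d_obs - series.d_rep - df)
                              / (df * series.N)))
    return _summaries("BRMSEA_ppmc", vals)


def brmsea_devm(series: DiscrepancySeries) -> FitIndexResult:
    """Bayesian RMSEA with noncentrality D_obs - pD (DevM form)."""
    _check_pd(series)
    df = series.p_star - series.pD
    vals = np.sqrt(np.maximum(0.0, (series.d_obs - series.p_star)
                              / (df * series.N)))
    return _summaries("BRMSEA_devm", vals)


def bcfi(series: DiscrepancySeries) -> FitIndexResult:
    """Bayesian CFI against the independence null, clamped to [0, 1]."""
    if series.d_obs_null is None:
        raise ValueError("BCFI needs the null-model series")
    denom = series.d_obs_null - series.p_star
    vals = np.where(np.abs(denom) < 1e-12, np.nan,
                    1.0 - (series.d_obs - series.p_star) / denom)
    return _summaries("BCFI", np.clip(vals, 0.0, 1.0))


def btli(series: DiscrepancySeries) -> FitIndexResult:
    """Bayesian TLI against the independence null (unclamped)."""
    if series.d_obs_null is None or series.pD_null is None:
        raise ValueError("BTLI needs the null-model series")
    if series.p_star <= series.pD or series.p_star <= series.pD_null:
        raise ValueError("p* <= pD")
    r_o = (series.d_obs_null - series.pD_null) / (series.p_star - series.pD_null)
    r_h = (series.d_obs - series.pD) / (series.p_star - series.pD)
    vals = np.where(np.abs(r_o - 1.0) < 1e-12, np.nan, (r_o - r_h) / (r_o - 1.0))
    return _summaries("BTLI", vals)


def decide(result: FitIndexResult, index_name: str | None = None):
    """Cutoff rejection and 90%-interval classification for one index.

    BRMSEA rejects when the posterior mean exceeds .06 (good if the
    interval upper bound < .06, poor if the lower bound >= .06); BCFI
    and BTLI reject below .95 with the mirrored interval rule; PPp
    rejects outside (.05, .95) and has no interval classification.
    """
    name = index_name or result.index_name
    lo, hi = result.ci90
    if name.startswith("BRMSEA"):
        rejected = result.posterior_mean > BRMSEA_CUTOFF
        if hi < BRMSEA_CUTOFF:
            ci_class = "good"
        elif lo >= BRMSEA_CUTOFF:
            ci_class = "poor"
        else:
            ci_class = "inconclusive"
    elif name in ("BCFI", "BTLI"):
        rejected = result.posterior_mean < INCREMENTAL_CUTOFF
        if lo >= INCREMENTAL_CUTOFF:
            ci_class = "good"
        elif hi < INCREMENTAL_CUTOFF:
            ci_class = "poor"
        else:
            ci_class = "inconclusive"
    elif name == "PPp":
        val = result.ppp if result.ppp is not None else result.posterior_mean
        rejected = not (PPP_BOUNDS[0] <= val <= PPP_BOUNDS[1])
        ci_class = None
    else:
        raise ValueError(f"unknown index {name!r}")
    result.rejected = bool(rejected)
    result.ci_class = ci_class
    return result.rejected, ci_class


def all_indices(series: DiscrepancySeries) -> dict:
    """Every available index with decisions attached."""
    out = {}
    if series.d_rep is not None:
        p_val = ppp(series)
        res = FitIndexResult("PPp", None, p_val, 0.0, (p_val, p_val), ppp=p_val)
        decide(res)
        out["PPp"] = res
        out["BRMSEA_ppmc"] = brmsea_ppmc(series)
        decide(out["BRMSEA_ppmc"])
    out["BRMSEA_devm"] = brmsea_devm(series)
    decide(out["BRMSEA_devm"])
    if series.d_obs_null is not None:
        out["BCFI"] = bcfi(series)
        decide(out["BCFI"])
        out["BTLI"] = btli(series)
        decide(out["BTLI"])
    return out
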