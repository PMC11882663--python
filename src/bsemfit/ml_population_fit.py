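"""Maximum-likelihood CFA fits to covariance matrices and the
frequentist fit indices RMSEA, CFI, and TLI.

Fitting a misspecified analysis model directly to the analytic population
covariance matrix (with a nominal N = 1,000,000 plugged into the index
formulas) yields the population values of the indices; the same routine
fits sample covariance matrices.

The discrepancy minimized is the normal-theory ML fit function

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over free loadings, factor correlations, and residual variances, with all
latent variances fixed to 1.  chi^2 = (N - 1) * F_min and df = p* - q with
p* = p(p+1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .population_models import CfaModelSpec, count_free_parameters

__all__ = ["MlFitResult", "fit_ml", "rmsea", "cfi_tli", "population_fit", "null_discrepancy"]

DEFAULT_N = 1_000_000


@dataclass
class MlFitResult:
    f_min: float
    chi_square: float
    df: int
    rmsea: float
    cfi: float
    tli: float
    estimates: dict
    converged: bool
    n_used: int


def rmsea(chi_square: float, df: int, N: int) -> float:
    """Steiger-Lind root mean square error of approximation."""
    if df <= 0:
        raise ValueError("df must be positive")
    if N <= 1:
        raise ValueError("N must exceed 1")
    return float(np.sqrt(max(0.0, (chi_square - df) / (df * (N - 1)))))


def cfi_tli(chi_h: float, df_h: int, chi_0: float, df_0: int) -> tuple[float, float]:
    """Comparative fit index and Tucker-Lewis index against the
    independence baseline."""
    if df_h <= 0 or df_0 <= 0:
        raise ValueError("degrees of freedom must be positive")
    num = max(chi_h - df_h, 0.0)
    den = max(chi_h - df_h, chi_0 - df_0, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    r0 = chi_0 / df_0
    if r0 <= 1:
        raise ValueError("degenerate null model (chi0/df0 <= 1)")
    tli = (r0 - chi_h / df_h) / (r0 - 1.0)
    return float(cfi), float(tli)


def null_discrepancy(S: np.ndarray) -> float:
    """ML fit function of the independence model (diagonal covariance,
    free variances) at its optimum: ln|diag(S)| - ln|S|."""
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("target covariance is not positive definite")
    return float(np.sum(np.log(np.diag(S))) - logdet)


# -- parameter packing ---------------------------------------------------

def _pack_info(model: CfaModelSpec):
    rows, cols = np.nonzero(model.free_mask)
    q = model.n_factors
    iu = np.triu_indices(q, k=1)
    return rows, cols, iu


def _unpack(theta, model, rows, cols, iu):
    p, q = model.n_items, model.n_factors
    n_load = rows.size
    n_corr = iu[0].size
    lam = np.zeros((p, q))
    lam[rows, cols] = theta[:n_load]
    phi = np.eye(q)
    phi[iu] = theta[n_load:n_load + n_corr]
    phi[(iu[1], iu[0])] = theta[n_load:n_load + n_corr]
    psi = theta[n_load + n_corr:]
    return lam, phi, psi


def _objective(theta, S, logdet_S, model, rows, cols, iu):
    p = model.n_items
    lam, phi, psi = _unpack(theta, model, rows, cols, iu)

    w = np.linalg.eigvalsh(phi)
    if w.min() < 1e-10:
        # push back toward the feasible region
        pen = 1e6 * (1e-10 - w.min())
        grad = np.zeros_like(theta)
        return 1e8 + pen, grad

    sigma = lam @ phi @ lam.T
    sigma[np.diag_indices_from(sigma)] += psi
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e8, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.sum(sigma_inv * S) - logdet_S - p

    # dF/dSigma = Sigma^-1 - Sigma^-1 S Sigma^-1  (symmetric)
    G = sigma_inv - sigma_inv @ S @ sigma_inv
    lam_phi = lam @ phi
    g_load = 2.0 * (G @ lam_phi)[rows, cols]
    M = lam.T @ G @ lam
    g_corr = 2.0 * M[iu]
    g_psi = np.diag(G)
    return f, np.concatenate([g_load, g_corr, g_psi])


def fit_ml(target_cov: np.ndarray, model: CfaModelSpec, N: int = DEFAULT_N,
           n_starts: int = 8) -> MlFitResult:
    """Fit an analysis model to a covariance matrix by normal-theory ML.

    Misspecified models can have local minima (notably when population
    factors are merged), so the optimization always runs a deterministic
    multi-start: the model's anchor values (loadings 0.6, correlations
    0.3, residual variances 0.5 where no anchor exists) plus ``n_starts - 1``
    seeded random starts, keeping the best optimum.
    """
    S = np.asarray(target_cov, dtype=float)
    p = model.n_items
    if S.shape != (p, p):
        raise ValueError("target covariance has the wrong dimension")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("target covariance is not positive definite")

    rows, cols, iu = _pack_info(model)
    n_load, n_corr = rows.size, iu[0].size

    start_load = model.loadings[rows, cols]
    start_load = np.where(start_load != 0, start_load, 0.6)
    start_corr = model.factor_corr[iu]
    start_corr = np.where(start_corr != 0, start_corr, 0.3)
    start_psi = np.where(model.residual_variances > 0, model.residual_variances, 0.5)
    x0 = np.concatenate([start_load, start_corr, start_psi])

    bounds = ([(None, None)] * n_load
              + [(-0.999, 0.999)] * n_corr
              + [(1e-6, None)] * p)

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(n_starts):
        if attempt == 0:
            x_init = x0
        else:
            x_init = np.concatenate([
                rng.uniform(0.2, 0.9, n_load),
                rng.uniform(-0.5, 0.9, n_corr),
                rng.uniform(0.1, 1.0, p),
            ])
        res = optimize.minimize(
            _objective, x_init, args=(S, logdet_S, model, rows, cols, iu),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res

    lam, phi, psi = _unpack(best.x, model, rows, cols, iu)
    f_min = float(max(best.fun, 0.0))
    q_free = count_free_parameters(model)
    p_star = p * (p + 1) // 2
    df_h = p_star - q_free
    chi_h = (N - 1) * f_min
    chi_0 = (N - 1) * null_discrepancy(S)
    df_0 = p_star - p
    if df_h == 0:
        # just-identified model: perfect fit by construction
        rmsea_val, cfi, tli = 0.0, 1.0, 1.0
    else:
        rmsea_val = rmsea(chi_h, df_h, N)
        cfi, tli = cfi_tli(chi_h, df_h, chi_0, df_0)
    return MlFitResult(
        f_min=f_min,
        chi_square=chi_h,
        df=df_h,
        rmsea=rmsea_val,
        cfi=cfi,
        tli=tli,
        estimates={"loadings": lam, "factor_corr": phi, "residual_variances": psi},
        converged=bool(best.fun < 1e7),
        n_used=N,
    )


def population_fit(generation_spec: CfaModelSpec, analysis_model: CfaModelSpec,
                   N: int = DEFAULT_N) -> MlFitResult:
    """Population fit: analysis model against the analytic implied
    covariance of the generating model."""
    from .population_models import implied_covariance

    return fit_ml(implied_covariance(generation_spec), analysis_model, N=N)
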