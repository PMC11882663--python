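"""Gibbs sampler for Bayesian CFA with latent variances fixed to 1.

One sweep updates, in order:

1. factor scores ``xi_i | rest`` — multivariate normal with precision
   ``Lambda' Psi^-1 Lambda + Phi^-1``;
2. per item, the intercept and free loadings jointly — conjugate normal
   regression of the item on its factor scores (flat intercept prior,
   normal loading priors);
3. residual variances — conjugate inverse-gamma with the limiting
   IG(-1, 0) prior (posterior shape n/2 - 1, scale SSR/2);
4. the factor correlation matrix — parameter expansion: an unconstrained
   latent covariance is drawn from its inverse-Wishart conditional under
   a flat prior, decomposed into scales and a correlation matrix, and the
   scales are absorbed into the loadings and factor scores.

Chains start from overdispersed points (prior-mean loadings plus a
chain-specific offset).  Convergence is declared when the Gelman-Rubin
potential scale reduction factor, computed across chains on the second
half of each chain, drops below the threshold for every free parameter;
iterations continue on a geometric schedule up to ``max_iterations``
otherwise.  Retained draws are the second halves of all chains, after
per-draw sign reflection (any factor whose free loadings average
negative is flipped together with its correlations and scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population_models import CfaModelSpec
from .priors import PriorSpec
from .synthetic_data import Dataset

__all__ = ["McmcSettings", "PosteriorDraws", "sample_posterior", "psr", "point_estimates"]


@dataclass
class McmcSettings:
    n_chains: int = 3
    min_iterations: int = 10_000
    max_iterations: int = 500_000
    psr_threshold: float = 1.10
    check_interval: int | None = None   # default: 10% of current length
    seed: int = 0

    def __post_init__(self):
        if self.min_iterations > self.max_iterations:
            raise ValueError("min_iterations must not exceed max_iterations")
        if self.psr_threshold <= 1:
            raise ValueError("psr_threshold must exceed 1")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws, chains stacked along the first axis."""

    loadings: np.ndarray            # (m, p, q)
    factor_corr: np.ndarray         # (m, q, q)
    residual_variances: np.ndarray  # (m, p)
    intercepts: np.ndarray          # (m, p)
    chain: np.ndarray               # (m,)
    converged: bool
    iterations_used: int
    psr_final: np.ndarray           # per monitored parameter
    model: CfaModelSpec = None

    @property
    def m(self) -> int:
        return self.loadings.shape[0]


def psr(chain_segments) -> float:
    """Gelman-Rubin potential scale reduction for one scalar parameter.

    ``chain_segments`` is a (chains, draws) array.  Returns 1.0 for
    degenerate but agreeing chains (W = B = 0) and +inf when chains are
    each constant but disagree (W = 0, B > 0).
    """
    seg = np.asarray(chain_segments, dtype=float)
    if seg.ndim != 2 or seg.shape[0] < 2 or seg.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 equal-length draws each")
    L = seg.shape[1]
    w = seg.var(axis=1, ddof=1).mean()
    b = L * seg.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    # floored at 1: values below 1 only reflect Monte Carlo noise
    return float(max(1.0, np.sqrt(((L - 1) / L * w + b / L) / w)))


def _psr_vector(segments: np.ndarray) -> np.ndarray:
    """Vectorized PSR over the trailing parameter axis of a
    (chains, draws, k) array."""
    L = segments.shape[1]
    w = segments.var(axis=1, ddof=1).mean(axis=0)
    b = L * segments.mean(axis=1).var(axis=0, ddof=1)
    out = np.full(w.shape, np.inf)
    ok = w > 0
    out[ok] = np.maximum(1.0, np.sqrt(((L - 1) / L * w[ok] + b[ok] / L) / w[ok]))
    out[(w == 0) & (b == 0)] = 1.0
    return out


def point_estimates(draws: PosteriorDraws) -> dict:
    """Posterior means of all parameter blocks, chains pooled."""
    if draws.m == 0:
        raise ValueError("empty posterior draws")
    return {
        "loadings": draws.loadings.mean(axis=0),
        "factor_corr": draws.factor_corr.mean(axis=0),
        "residual_variances": draws.residual_variances.mean(axis=0),
        "intercepts": draws.intercepts.mean(axis=0),
    }


# --------------------------------------------------------------------------
# sampler internals

def _invwishart_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """One inverse-Wishart draw; density |S|^{df/2} |X|^{-(df+q+1)/2}
    exp(-tr(S X^-1)/2).  Requires df > q - 1."""
    q = scale.shape[0]
    L = np.linalg.cholesky(scale)
    # Bartlett factor of a Wishart(df, I) draw
    A = np.zeros((q, q))
    A[np.diag_indices(q)] = np.sqrt(rng.chisquare(df - np.arange(q)))
    A[np.tril_indices(q, -1)] = rng.standard_normal(q * (q - 1) // 2)
    # U U' = scale^-1, so M M' ~ Wishart(df, scale^-1) with M = U A
    U = np.linalg.inv(L).T
    M = U @ A
    X = M @ M.T
    return np.linalg.inv(X)


class _ItemGroups:
    """Items batched by number of free loadings, for vectorized
    conjugate regression updates."""

    def __init__(self, mask):
        p = mask.shape[0]
        by_k = {}
        for j in range(p):
            idx = np.flatnonzero(mask[j])
            by_k.setdefault(idx.size, []).append((j, idx))
        self.groups = []
        for k in sorted(by_k):
            items = np.array([j for j, _ in by_k[k]])
            idx = np.stack([ix for _, ix in by_k[k]])
            self.groups.append((items, idx))


class _ChainState:
    def __init__(self, X, model, prior, chain_index, rng):
        self.rng = rng
        p, q = model.n_items, model.n_factors
        n = X.shape[0]
        mask = model.free_mask
        magnitude = 0.25 * (chain_index // 2 + 1)
        offset = magnitude * (-1.0) ** chain_index
        self.lam = np.where(mask, prior.loading_mean + offset, 0.0)
        self.tau = X.mean(axis=0)
        self.psi = np.ones(p)
        self.phi = np.eye(q)
        self.xi = np.zeros((n, q))


def _sweep(X, stats, model, prior, groups, st):
    """One Gibbs sweep, updating the chain state in place."""
    n, p = X.shape
    q = model.n_factors
    rng = st.rng

    # 1. factor scores
    lam_w = st.lam / st.psi[:, None]                    # Psi^-1 Lambda
    prec = st.lam.T @ lam_w + np.linalg.inv(st.phi)
    cov = np.linalg.inv(prec)
    cov = (cov + cov.T) / 2.0
    mean = (X - st.tau) @ lam_w @ cov
    st.xi = mean + rng.standard_normal((n, q)) @ np.linalg.cholesky(cov).T

    _measurement_update(X, stats, model, prior, groups, st)

    # 4. factor correlations via parameter expansion (flat prior)
    if q > 1:
        df = n - q - 1
        sigma_star = _invwishart_rvs(df, st.xi.T @ st.xi, rng)
        d = np.sqrt(np.diag(sigma_star))
        st.phi = sigma_star / np.outer(d, d)
        np.fill_diagonal(st.phi, 1.0)
        st.lam = st.lam * d[None, :]
        st.xi = st.xi / d[None, :]


def _measurement_update(X, stats, model, prior, groups, st):
    """Conjugate intercept+loading regression update and inverse-gamma
    residual update, batched over items with equal loading counts;
    conditions on the current factor scores ``st.xi``."""
    n = X.shape[0]
    rng = st.rng
    xtx = st.xi.T @ st.xi                               # (q, q)
    xsum = st.xi.sum(axis=0)                            # (q,)
    Xtxi = X.T @ st.xi                                  # (p, q)
    col_sum, col_sq = stats                             # (p,), (p,)

    for items, idx in groups.groups:
        g, k = idx.shape
        C = np.empty((g, k + 1, k + 1))
        C[:, 0, 0] = n
        xs = xsum[idx]
        C[:, 0, 1:] = xs
        C[:, 1:, 0] = xs
        C[:, 1:, 1:] = xtx[idx[:, :, None], idx[:, None, :]]
        c1 = np.concatenate([col_sum[items, None], Xtxi[items[:, None], idx]], axis=1)
        prior_prec = np.concatenate(
            [np.zeros((g, 1)), 1.0 / prior.loading_var[items[:, None], idx]], axis=1)
        prior_mean = np.concatenate(
            [np.zeros((g, 1)), prior.loading_mean[items[:, None], idx]], axis=1)
        psi_g = st.psi[items]
        A = C / psi_g[:, None, None]
        A[:, np.arange(k + 1), np.arange(k + 1)] += prior_prec
        b = c1 / psi_g[:, None] + prior_prec * prior_mean
        mean_b = np.linalg.solve(A, b[..., None])[..., 0]
        La = np.linalg.cholesky(A)
        z = rng.standard_normal((g, k + 1))
        beta = mean_b + np.linalg.solve(np.swapaxes(La, 1, 2), z[..., None])[..., 0]
        st.tau[items] = beta[:, 0]
        st.lam[items[:, None], idx] = beta[:, 1:]

        ssr = (col_sq[items]
               - 2.0 * np.einsum("gi,gi->g", beta, c1)
               + np.einsum("gi,gij,gj->g", beta, C, beta))
        np.clip(ssr, 1e-12, None, out=ssr)
        st.psi[items] = 0.5 * ssr / rng.gamma(0.5 * n - 1.0, size=g)


def _reflect(lam, phi, mask):
    """Per-draw sign identification: flip any factor whose mean free
    loading is negative.  Operates on (m, p, q) and (m, q, q) arrays."""
    col_counts = mask.sum(axis=0)
    sums = (lam * mask[None, :, :]).sum(axis=1)
    signs = np.where(sums / np.maximum(col_counts, 1) < 0, -1.0, 1.0)
    lam = lam * signs[:, None, :]
    phi = phi * signs[:, None, :] * signs[:, :, None]
    return lam, phi


def sample_posterior(data: Dataset, model: CfaModelSpec, prior: PriorSpec,
                     settings: McmcSettings) -> PosteriorDraws:
    """Sample the Bayesian CFA posterior with PSR-monitored chains."""
    X = data.values
    n, p = X.shape
    q = model.n_factors
    if p != model.n_items:
        raise ValueError("data column count does not match the model")
    if prior.loading_mean.shape != (p, q):
        raise ValueError("prior dimensions do not match the model")
    if n <= 2 * q + 2:
        raise ValueError("sample too small for the latent covariance update")

    mask = model.free_mask
    stats = (X.sum(axis=0), (X ** 2).sum(axis=0))
    groups = _ItemGroups(mask)
    chains = []
    for c in range(settings.n_chains):
        ss = np.random.SeedSequence(entropy=int(settings.seed), spawn_key=(c,))
        chains.append(_ChainState(X, model, prior, c, np.random.default_rng(ss)))

    C = settings.n_chains
    cap = settings.min_iterations
    lam_h = np.empty((C, cap, p, q))
    phi_h = np.empty((C, cap, q, q))
    psi_h = np.empty((C, cap, p))
    tau_h = np.empty((C, cap, p))

    rows, cols = np.nonzero(mask)
    iu = np.triu_indices(q, k=1)

    def monitored(lo, hi):
        """(chains, draws, k) array of monitored free parameters with
        sign reflection applied."""
        segs = []
        for c in range(C):
            lam_c, phi_c = _reflect(lam_h[c, lo:hi], phi_h[c, lo:hi], mask)
            segs.append(np.concatenate([
                lam_c[:, rows, cols],
                phi_c[:, iu[0], iu[1]],
                psi_h[c, lo:hi],
                tau_h[c, lo:hi],
            ], axis=1))
        return np.stack(segs)

    done = 0
    converged = False
    failed = False
    psr_final = None
    T = settings.min_iterations
    while True:
        if T > cap:
            extra = T - cap
            lam_h = np.concatenate([lam_h, np.empty((C, extra, p, q))], axis=1)
            phi_h = np.concatenate([phi_h, np.empty((C, extra, q, q))], axis=1)
            psi_h = np.concatenate([psi_h, np.empty((C, extra, p))], axis=1)
            tau_h = np.concatenate([tau_h, np.empty((C, extra, p))], axis=1)
            cap = T
        try:
            for c, st in enumerate(chains):
                for it in range(done, T):
                    _sweep(X, stats, model, prior, groups, st)
                    lam_h[c, it] = st.lam
                    phi_h[c, it] = st.phi
                    psi_h[c, it] = st.psi
                    tau_h[c, it] = st.tau
        except np.linalg.LinAlgError:
            failed = True
            T = max(done, 2)
            break
        done = T
        psr_final = _psr_vector(monitored(T // 2, T))
        if np.all(psr_final < settings.psr_threshold):
            converged = True
            break
        if T >= settings.max_iterations:
            break
        step = settings.check_interval or max(1, T // 10)
        T = min(settings.max_iterations, T + step)

    lo, hi = T // 2, done
    lam_all, phi_all, psi_all, tau_all, chain_ix = [], [], [], [], []
    for c in range(C):
        lam_c, phi_c = _reflect(lam_h[c, lo:hi], phi_h[c, lo:hi], mask)
        lam_all.append(lam_c)
        phi_all.append(phi_c)
        psi_all.append(psi_h[c, lo:hi])
        tau_all.append(tau_h[c, lo:hi])
        chain_ix.append(np.full(hi - lo, c))
    if psr_final is None:
        psr_final = np.full(rows.size + iu[0].size + 2 * p, np.inf)
    return PosteriorDraws(
        loadings=np.concatenate(lam_all),
        factor_corr=np.concatenate(phi_all),
        residual_variances=np.concatenate(psi_all),
        intercepts=np.concatenate(tau_all),
        chain=np.concatenate(chain_ix),
        converged=converged and not failed,
        iterations_used=done,
        psr_final=psr_final,
        model=model,
    )
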