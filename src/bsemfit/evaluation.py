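"""Monte Carlo orchestration: run replications for design conditions and
summarize rejection rates, interval classifications, and ANOVA effect
sizes.

A replication generates a dataset from the condition's population model,
fits the (possibly misspecified) analysis model by Gibbs sampling, fits
the independence baseline, and computes every fit index with its
decision.  Non-converged replications are recorded and replaced by
continuing the replication counter, so summaries always cover the
requested number of converged solutions (up to an attempt cap).
Everything is deterministic given the base seed: replication r of
condition c draws from a stream keyed by (base_seed, c, r), regardless
of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit_indices import all_indices, attach_null, discrepancy_series, fit_null_model
from .gibbs_sampler import McmcSettings, sample_posterior
from .population_models import as_analysis_model, misspecify
from .priors import make_prior
from .synthetic_data import Condition, generate, replication_rng

__all__ = ["ConditionResult", "run_condition", "rejection_rates", "eta_squared",
           "summarize", "run_study"]

INDEX_NAMES = ("PPp", "BRMSEA_ppmc", "BRMSEA_devm", "BCFI", "BTLI")


@dataclass
class ConditionResult:
    condition: Condition
    replications: list            # dicts: seeds, convergence, per-index results
    n_converged: int
    n_attempted: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.replications:
            if not rep["converged"]:
                continue
            for name, res in rep["indices"].items():
                rows.append({
                    "condition_id": self.condition.condition_id,
                    "replication": rep["replication"],
                    "index": name,
                    "mean": res.posterior_mean,
                    "sd": res.posterior_sd,
                    "ci_lo": res.ci90[0],
                    "ci_hi": res.ci90[1],
                    "rejected": res.rejected,
                    "ci_class": res.ci_class,
                })
        return pd.DataFrame(rows)


def run_replication(condition: Condition, replication: int, settings: McmcSettings,
                    base_seed: int, compute_rep: bool = True) -> dict:
    """One fully seeded replication of one condition."""
    gen = condition.generation_spec()
    plan = condition.analysis_plan()
    analysis = as_analysis_model(gen) if plan is None else misspecify(gen, plan)
    prior = make_prior(condition.prior_label, gen, analysis)

    rng = replication_rng(base_seed, condition.index, replication)
    data = generate(gen, condition.n, rng=rng,
                    condition_id=condition.condition_id, replication=replication)
    chain_seed = int(rng.integers(2 ** 31))
    run_settings = McmcSettings(
        n_chains=settings.n_chains, min_iterations=settings.min_iterations,
        max_iterations=settings.max_iterations, psr_threshold=settings.psr_threshold,
        check_interval=settings.check_interval, seed=chain_seed)
    out = {"replication": replication, "seed": chain_seed,
           "converged": False, "indices": {}}
    try:
        draws = sample_posterior(data, analysis, prior, run_settings)
    except (np.linalg.LinAlgError, ValueError):
        return out
    out["converged"] = draws.converged
    if not draws.converged:
        return out
    try:
        series = discrepancy_series(data, draws, rng, compute_rep=compute_rep)
        d0, dr0, pd0 = fit_null_model(data, series.m, rng)
        attach_null(series, d0, dr0, pd0)
        out["indices"] = all_indices(series)
        out["pD"] = series.pD
    except (np.linalg.LinAlgError, ValueError):
        out["converged"] = False
    return out


def run_condition(condition: Condition, n_reps: int, settings: McmcSettings,
                  base_seed: int, compute_rep: bool = True,
                  max_attempt_factor: int = 5) -> ConditionResult:
    """Collect ``n_reps`` converged replications, replacing failures by
    advancing the replication counter (up to ``max_attempt_factor`` times
    the target)."""
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    reps = []
    converged = 0
    attempt = 0
    while converged < n_reps:
        if attempt >= max_attempt_factor * n_reps:
            raise RuntimeError(
                f"persistent non-convergence in {condition.condition_id}: "
                f"{converged}/{n_reps} after {attempt} attempts")
        rep = run_replication(condition, attempt, settings, base_seed, compute_rep)
        reps.append(rep)
        converged += int(rep["converged"])
        attempt += 1
    return ConditionResult(condition=condition, replications=reps,
                           n_converged=converged, n_attempted=attempt)


def rejection_rates(result: ConditionResult, is_correctly_specified: bool | None = None) -> dict:
    """Share of converged replications each index flagged as misfitting.

    Interpreted as a false positive rate for correctly specified
    conditions and a true positive rate otherwise.
    """
    if result.n_converged == 0:
        raise ValueError("no converged replications")
    if is_correctly_specified is None:
        is_correctly_specified = result.condition.severity == "correct"
    out = {"condition_id": result.condition.condition_id,
           "rate_type": "false_positive" if is_correctly_specified else "true_positive"}
    for name in INDEX_NAMES:
        flags = [rep["indices"][name].rejected for rep in result.replications
                 if rep["converged"] and name in rep["indices"]]
        out[name] = float(np.mean(flags)) if flags else np.nan
    return out


def eta_squared(values: pd.DataFrame, design_factors: list[str],
                response: str = "value", interactions: list[tuple] | None = None,
                subsample_seed: int = 0) -> pd.DataFrame:
    """Factorial ANOVA effect sizes eta^2 = SS_effect / SS_total.

    The design is balanced before decomposition: cells are subsampled to
    the minimum cell count with a fixed seed.  Returns one row per main
    effect and requested interaction, flagged at the conventional 0.0588
    (moderate) and 0.1379 (large) thresholds.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = values.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError("no data for ANOVA")
    counts = df.groupby(design_factors, observed=True).size()
    if counts.empty or counts.min() == 0:
        raise ValueError("empty design cells")
    n_min = int(counts.min())
    rng = np.random.default_rng(subsample_seed)
    keep = []
    for _, g in df.groupby(design_factors, observed=True):
        keep.extend(g.index[np.sort(rng.permutation(len(g))[:n_min])])
    balanced = df.loc[keep].reset_index(drop=True)

    terms = [f"C({f})" for f in design_factors]
    if interactions:
        terms += [":".join(f"C({f})" for f in pair) for pair in interactions]
    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=balanced).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ss_total = table["sum_sq"].sum()
    var_total = balanced[response].var(ddof=0)
    rows = []
    for term in table.index:
        if term == "Residual":
            continue
        # a constant response has no variance to decompose
        eta2 = 0.0 if var_total < 1e-30 else table.loc[term, "sum_sq"] / ss_total
        rows.append({"effect": term.replace("C(", "").replace(")", ""),
                     "eta_squared": float(eta2),
                     "moderate": bool(eta2 > 0.0588),
                     "large": bool(eta2 > 0.1379)})
    return pd.DataFrame(rows)


def summarize(results: list[ConditionResult]) -> dict:
    """Study-level summary tables.

    Returns mean/SD of every index per condition, rejection rates,
    interval-classification proportions, and convergence rates, each as
    a tidy DataFrame keyed by condition.
    """
    frames = [r.to_frame() for r in results if r.replications]
    if not frames or all(f.empty for f in frames):
        empty = pd.DataFrame()
        return {"mean_sd": empty, "rejection_rates": empty,
                "ci_classes": empty, "convergence": empty}
    long = pd.concat([f for f in frames if not f.empty], ignore_index=True)

    mean_sd = (long.groupby(["condition_id", "index"], observed=True)["mean"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1))
               .reset_index())

    rej = pd.DataFrame([rejection_rates(r) for r in results if r.n_converged])

    ci = (long[long["ci_class"].notna()]
          .groupby(["condition_id", "index", "ci_class"], observed=True)
          .size().unstack(fill_value=0))
    if not ci.empty:
        for col in ("good", "poor", "inconclusive"):
            if col not in ci:
                ci[col] = 0
        ci = ci[["good", "inconclusive", "poor"]]
        ci = ci.div(ci.sum(axis=1), axis=0).reset_index()

    conv = pd.DataFrame([{
        "condition_id": r.condition.condition_id,
        "n_converged": r.n_converged,
        "n_attempted": r.n_attempted,
        "convergence_rate": r.n_converged / r.n_attempted if r.n_attempted else np.nan,
    } for r in results])

    return {"mean_sd": mean_sd, "rejection_rates": rej,
            "ci_classes": ci, "convergence": conv}


def run_study(conditions, n_reps: int, settings: McmcSettings, base_seed: int,
              n_jobs: int = 1, compute_rep: bool = True) -> list[ConditionResult]:
    """Run a list of conditions; with ``n_jobs > 1`` conditions are
    dispatched to a joblib process pool (results are seed-deterministic
    regardless of worker count)."""
    if n_jobs == 1:
        return [run_condition(c, n_reps, settings, base_seed, compute_rep)
                for c in conditions]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_jobs)(
        delayed(run_condition)(c, n_reps, settings, base_seed, compute_rep)
        for c in conditions)
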