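"""Replication datasets and the Monte Carlo condition grids.

Data are multivariate normal draws from a population model's implied
covariance (means zero).  Replication seeds derive from
``(base_seed, condition index, replication index)`` through a
counter-based ``numpy`` SeedSequence, so any replication can be
regenerated in isolation and non-converged replications can be replaced
without perturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population_models import (
    CfaModelSpec,
    MisspecificationPlan,
    build_generation_model,
    implied_covariance,
    study_misspecification_plans,
)

__all__ = ["Dataset", "Condition", "generate", "build_condition_grid", "replication_rng"]

#: sample sizes by study
SAMPLE_SIZES = {1: (75, 200, 500, 2000), 2: (200, 500)}

#: loading-prior labels by study
PRIOR_LABELS = {
    1: ("Diffuse", "AlignedSV", "AlignedLV", "DivergentSV", "DivergentLV"),
    2: ("Diffuse", "AlignedSV", "DivergentSV"),
}


@dataclass
class Dataset:
    values: np.ndarray
    n: int
    condition_id: str = ""
    replication: int = 0
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be an n x p matrix")
        if self.n != self.values.shape[0] or self.n < 2:
            raise ValueError("n must match the row count and be >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in dataset")

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"x{j + 1}" for j in range(self.p)]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition_id="", replication=0) -> "Dataset":
        df = pd.read_csv(path)
        return cls(df.to_numpy(float), n=len(df),
                   condition_id=condition_id, replication=replication)


@dataclass
class Condition:
    """One cell of the simulation design."""

    condition_id: str
    study: int
    family: str
    factor_corr: float | None
    cross_loading: float | None
    severity: str               # correct | moderate | severe
    prior_label: str
    n: int
    index: int = 0              # position in the grid, used for seeding

    def generation_spec(self) -> CfaModelSpec:
        return build_generation_model(self.family, self.factor_corr, self.cross_loading)

    def analysis_plan(self) -> MisspecificationPlan | None:
        return study_misspecification_plans(self.family)[self.severity]


def replication_rng(base_seed: int, condition_index: int, replication: int) -> np.random.Generator:
    """Independent stream for one replication of one condition."""
    ss = np.random.SeedSequence(entropy=int(base_seed),
                                spawn_key=(int(condition_index), int(replication)))
    return np.random.default_rng(ss)


def generate(spec: CfaModelSpec, n: int, seed=None,
             rng: np.random.Generator | None = None,
             condition_id: str = "", replication: int = 0) -> Dataset:
    """Draw n i.i.d. rows from N(tau, Lambda Phi Lambda' + Psi)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = implied_covariance(spec)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, spec.n_items))
    values = spec.intercepts + z @ chol.T
    return Dataset(values, n=n, condition_id=condition_id,
                   replication=replication, seed=seed)


def _data_conditions(study: int):
    if study == 1:
        for family, values in (("A", (0.35, 0.85)), ("B", (0.2, 0.5))):
            for v in values:
                for n in SAMPLE_SIZES[1]:
                    if family == "A":
                        yield family, v, None, n
                    else:
                        yield family, None, v, n
    elif study == 2:
        for family in ("C1", "C2", "C3", "D1", "D2", "D3"):
            for n in SAMPLE_SIZES[2]:
                yield family, 0.85, 0.5 if family.startswith("D") else None, n
    else:
        raise ValueError(f"unknown study {study!r}")


def build_condition_grid(study: int) -> list[Condition]:
    """All analysis conditions of a study.

    Study 1: 16 data conditions x 3 analysis severities x 5 priors = 240.
    Study 2: 6 generation models x {correct, severe} x 2 sample sizes
    x 3 priors = 72.
    """
    severities = ("correct", "moderate", "severe") if study == 1 else ("correct", "severe")
    out = []
    idx = 0
    for family, corr, cld, n in _data_conditions(study):
        for severity in severities:
            for prior in PRIOR_LABELS[study]:
                parts = [family]
                if corr is not None:
                    parts.append(f"cor{corr:g}")
                if cld is not None:
                    parts.append(f"cld{cld:g}")
                parts += [severity, prior, f"n{n}"]
                out.append(Condition(
                    condition_id="_".join(parts), study=study, family=family,
                    factor_corr=corr, cross_loading=cld, severity=severity,
                    prior_label=prior, n=n, index=idx))
                idx += 1
    return out


def grid_manifest(conditions: list[Condition]) -> pd.DataFrame:
    """Condition grid as a tidy manifest table."""
    return pd.DataFrame([{
        "index": c.index, "condition_id": c.condition_id, "study": c.study,
        "family": c.family, "factor_corr": c.factor_corr,
        "cross_loading": c.cross_loading, "severity": c.severity,
        "prior": c.prior_label, "n": c.n,
    } for c in conditions])
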