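"""Prior families for Bayesian CFA loadings and the default priors on
the remaining parameters.

Five normal loading priors are studied, crossed over accuracy (centered
on the population value, on 0.5, or on 0) and informativeness (variance
0.01, 1, or 1000):

=============  ====================  ==========
label          mean                  variance
=============  ====================  ==========
Diffuse        0                     1000
AlignedSV      population loading    0.01
AlignedLV      population loading    1
DivergentSV    0.5                   0.01
DivergentLV    0.5                   1
=============  ====================  ==========

Intercepts get an improper flat prior, residual variances the limiting
inverse-gamma IG(-1, 0) (flat on the variance), and the latent
covariance an improper flat inverse-Wishart, handled inside the sampler
by parameter expansion.

When the analysis model frees a loading that has no population
counterpart (a merged factor), the Aligned priors center it on the
item's population primary loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .population_models import CfaModelSpec

__all__ = ["PriorSpec", "make_prior", "PRIOR_LABELS"]

PRIOR_LABELS = ("Diffuse", "AlignedSV", "AlignedLV", "DivergentSV", "DivergentLV")


@dataclass
class PriorSpec:
    label: str
    loading_mean: np.ndarray      # (p, q) meaningful where free_mask
    loading_var: np.ndarray       # (p, q)
    residual_shape: float = -1.0  # IG shape
    residual_scale: float = 0.0   # IG scale
    intercept_mean: float = 0.0   # flat prior: infinite variance
    intercept_var: float = np.inf

    def __post_init__(self):
        self.loading_mean = np.asarray(self.loading_mean, dtype=float)
        self.loading_var = np.asarray(self.loading_var, dtype=float)
        if self.loading_mean.shape != self.loading_var.shape:
            raise ValueError("loading mean/variance shapes differ")
        if np.any(self.loading_var <= 0):
            raise ValueError("loading variances must be positive")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump({
            "label": self.label,
            "loading_mean": self.loading_mean.tolist(),
            "loading_var": self.loading_var.tolist(),
            "residual_shape": self.residual_shape,
            "residual_scale": self.residual_scale,
        }, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def make_prior(label: str, generation_spec: CfaModelSpec,
               analysis_spec: CfaModelSpec) -> PriorSpec:
    """Build the loading priors of one family for an analysis model."""
    if label not in PRIOR_LABELS:
        raise ValueError(f"unknown prior label {label!r}")
    p, q = analysis_spec.n_items, analysis_spec.n_factors
    mean = np.zeros((p, q))
    if label == "Diffuse":
        var = np.full((p, q), 1000.0)
    elif label in ("DivergentSV", "DivergentLV"):
        mean[:] = 0.5
        var = np.full((p, q), 0.01 if label == "DivergentSV" else 1.0)
    else:  # Aligned
        var = np.full((p, q), 0.01 if label == "AlignedSV" else 1.0)
        gen_primary = generation_spec.primary_factor
        primary_value = generation_spec.loadings[
            np.arange(generation_spec.n_items), gen_primary]
        same_structure = (q == generation_spec.n_factors)
        for j, k in zip(*np.nonzero(analysis_spec.free_mask)):
            pop = generation_spec.loadings[j, k] if same_structure else 0.0
            mean[j, k] = pop if pop != 0 else primary_value[j]
    return PriorSpec(label=label, loading_mean=mean, loading_var=var)
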