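"""Synthetic sparse baseline generator.

Stand-in for real taxonomic profiles (gut WGS / 16S cohorts): heavy-tailed
feature abundances, lognormal library sizes, negative-binomial
overdispersion and extra zero-inflation concentrated on rare features.  It
is a test fixture for the implantation framework, not a parametric
simulator under benchmark, and makes no claim of indistinguishability from
any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix

__all__ = ["BaselineSpec", "generate_baseline"]


@dataclass
class BaselineSpec:
    """Parameters of the baseline generative model.

    The defaults are tuned so that a filtered table shows mean per-sample
    sparsity around 0.75, in the range reported for human gut WGS profiles.

    Attributes
    ----------
    n_features, n_samples
        Table dimensions (taxa x samples).
    depth_log_mean, depth_log_sd
        Per-sample library sizes are ``10**Normal(depth_log_mean, depth_log_sd)``.
    feature_log_mean_sd
        SD of per-feature log10 mean abundances; larger values give a
        heavier-tailed rank-abundance curve.
    sample_noise_sd
        SD of per-(feature, sample) log10 compositional noise.
    dispersion
        Negative-binomial size parameter (smaller = more overdispersed).
    zero_inflation
        Extra-zero masking probability, damped for abundant features.
    seed
        RNG seed; identical seeds give identical tables.
    """

    n_features: int = 300
    n_samples: int = 400
    depth_log_mean: float = 4.0
    depth_log_sd: float = 0.25
    feature_log_mean_sd: float = 1.4
    sample_noise_sd: float = 1.0
    dispersion: float = 0.5
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0 or self.n_samples <= 0:
            raise ValueError("n_features and n_samples must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate_baseline(spec: BaselineSpec) -> CountMatrix:
    """Draw a taxa x samples count table from the baseline model.

    Model: per-feature log10 means are Normal(0, feature_log_mean_sd); each
    sample's composition is the softmax of these log-means plus independent
    per-sample noise; counts are NegativeBinomial(mean = composition x depth,
    size = dispersion); finally entries are masked to zero with probability
    ``zero_inflation / (1 + mean)`` so rare features lose more entries.
    """
    rng = np.random.default_rng(spec.seed)
    f, s = spec.n_features, spec.n_samples

    feature_logmean = rng.normal(0.0, spec.feature_log_mean_sd, size=f)
    noise = rng.normal(0.0, spec.sample_noise_sd, size=(f, s))
    logw = feature_logmean[:, None] + noise
    w = np.power(10.0, logw - logw.max(axis=0))
    composition = w / w.sum(axis=0)

    depth = np.round(np.power(10.0, rng.normal(spec.depth_log_mean, spec.depth_log_sd, size=s)))
    depth = np.maximum(depth, 1.0)

    mu = composition * depth
    r = spec.dispersion
    # NB with mean mu and size r: p = r / (r + mu)
    counts = rng.negative_binomial(r, r / (r + mu))

    if spec.zero_inflation > 0:
        mask_prob = spec.zero_inflation / (1.0 + mu)
        counts = np.where(rng.random(size=(f, s)) < mask_prob, 0, counts)

    feature_ids = [f"taxon_{i:04d}" for i in range(f)]
    sample_ids = [f"sample_{j:04d}" for j in range(s)]
    return CountMatrix(counts.astype(np.int64), feature_ids, sample_ids)
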