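"""Confounded benchmarks: dual implantation and biased resampling.

A confounder (e.g. medication intake) is emulated by implanting a second
signal, on features disjoint from the main ground truth, for an independent
binary label.  The label x confounder combination divides samples into four
strata; *biased resampling* then draws case/control testing subsets with
stratum quotas tuned so that the expected phi coefficient between the two
labels equals a chosen bias in [0, 1].  Bias 0 is the unconfounded negative
control (four equal quotas); bias 1 collapses to two perfectly aligned
strata.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .containers import ConfoundedDataset, CountMatrix, SimulatedDataset
from .implant import (
    _assign_directions,
    _build_truth,
    implant_abundance,
    implant_prevalence,
    select_da_features,
    split_groups,
)

__all__ = [
    "implant_confounder",
    "biased_resample",
    "phi_coefficient",
    "combine_studies",
]


def implant_confounder(
    ds: SimulatedDataset,
    fraction: float = 0.1,
    scale: float = 1.0,
    shift: float = 0.0,
    seed: Optional[int] = None,
    rounding: str = "half_up",
) -> ConfoundedDataset:
    """Implant a second signal for an independent random binary label.

    The confounder's features are drawn from the pool outside the main
    ground truth (including its rejected picks), with the same implantation
    mechanics and gFC rejection rule as the main signal.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    conf_label = split_groups(ds.cm, ss[0])
    used = set(ds.truth.features) | set(ds.truth.rejected)
    features = select_da_features(ds.cm, fraction, "all", ss[1], exclude=used)
    direction = _assign_directions(features, balanced=True)
    out = implant_prevalence(ds.cm, conf_label, features, shift, direction, ss[2])
    out = implant_abundance(out, conf_label, features, scale, direction, rounding)
    conf_truth = _build_truth(out, conf_label, features, direction, scale, shift)
    base = SimulatedDataset(cm=out, labels=ds.labels, truth=ds.truth, seed=ds.seed, params=ds.params)
    return ConfoundedDataset(base=base, confounder=conf_label, confounder_truth=conf_truth)


def _largest_remainder_pair(total: int, frac: float) -> Tuple[int, int]:
    """Split ``total`` into two integer quotas with fractions (frac, 1-frac)."""
    exact = total * frac
    a = int(np.floor(exact))
    if exact - a >= 0.5:
        a += 1
    return a, total - a


def biased_resample(
    cd: ConfoundedDataset,
    n: int,
    bias: float,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw a testing subset of ``n`` samples with calibrated confounding.

    ``n/2`` cases and ``n/2`` controls are drawn without replacement; among
    cases the confounder-positive fraction is ``(1+bias)/2``, among controls
    ``(1-bias)/2`` (largest-remainder rounding), which makes the expected
    phi coefficient of the subset equal to ``bias``.  Raises if a stratum
    cannot fill its quota, naming the stratum and the maximum feasible bias.
    """
    if n % 2:
        raise ValueError("n must be even")
    if not 0 <= bias <= 1:
        raise ValueError("bias must lie in [0, 1]")
    half = n // 2
    q_case_pos, q_case_neg = _largest_remainder_pair(half, (1 + bias) / 2)
    q_ctrl_pos, q_ctrl_neg = _largest_remainder_pair(half, (1 - bias) / 2)
    quotas = {
        (1, 1): q_case_pos,
        (1, 0): q_case_neg,
        (0, 1): q_ctrl_pos,
        (0, 0): q_ctrl_neg,
    }
    labels, conf = cd.labels, cd.confounder
    rng = np.random.default_rng(seed)
    chosen = []
    for (lab, c), quota in quotas.items():
        stratum = np.flatnonzero((labels == lab) & (conf == c))
        if quota > stratum.size:
            max_bias = _max_feasible_bias(cd, n)
            raise ValueError(
                f"stratum (label={lab}, confounder={c}) holds {stratum.size} samples "
                f"but quota is {quota}; maximum feasible bias at n={n} is {max_bias:.3f}"
            )
        if quota:
            chosen.append(rng.choice(stratum, size=quota, replace=False))
    return np.sort(np.concatenate(chosen))


def _max_feasible_bias(cd: ConfoundedDataset, n: int) -> float:
    half = n // 2
    sizes = {
        (lab, c): int(np.sum((cd.labels == lab) & (cd.confounder == c)))
        for lab in (0, 1)
        for c in (0, 1)
    }
    # binding constraints: case/pos and ctrl/neg quotas grow with bias
    b1 = 2 * sizes[(1, 1)] / half - 1
    b2 = 2 * sizes[(0, 0)] / half - 1
    return float(max(0.0, min(1.0, b1, b2)))


def phi_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient of two binary vectors from their 2x2 table.

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0); raises for
    constant inputs, for which the statistic is undefined.
    """
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("phi undefined for a constant variable")
    n11 = np.sum((x == 1) & (y == 1))
    n10 = np.sum((x == 1) & (y == 0))
    n01 = np.sum((x == 0) & (y == 1))
    n00 = np.sum((x == 0) & (y == 0))
    denom = np.sqrt(float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return float((n11 * n00 - n10 * n01) / denom)


def combine_studies(cm1: CountMatrix, cm2: CountMatrix) -> Tuple[CountMatrix, np.ndarray]:
    """Column-concatenate two studies over the union of their features.

    Features absent from one study are zero-filled; the returned binary
    label (0 for ``cm1`` samples, 1 for ``cm2``) can serve as the study-of-
    origin confounder in biased resampling.  Sample id collisions are an
    error.
    """
    if set(cm1.sample_ids) & set(cm2.sample_ids):
        raise ValueError("sample id collision between studies")
    features = list(cm1.feature_ids) + [f for f in cm2.feature_ids if f not in set(cm1.feature_ids)]
    fidx = {f: i for i, f in enumerate(features)}
    n1, n2 = cm1.n_samples, cm2.n_samples
    counts = np.zeros((len(features), n1 + n2), dtype=np.int64)
    for src, off in ((cm1, 0), (cm2, n1)):
        rows = [fidx[f] for f in src.feature_ids]
        counts[rows, off : off + src.n_samples] = src.counts
    study = np.concatenate([np.zeros(n1, dtype=np.int8), np.ones(n2, dtype=np.int8)])
    combined = CountMatrix(counts, features, list(cm1.sample_ids) + list(cm2.sample_ids))
    return combined, study
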