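"""Preprocessing transformations applied before differential abundance tests.

Supported methods: ``TSS`` (total sum scaling), ``TSS.log`` (log10 of TSS
plus pseudocount), ``TSS.arcsin`` (arcsine square root), ``clr`` (centered
log-ratio on counts + pseudocount), ``rclr`` (robust clr over non-zero
entries), ``rarefaction`` and the composites ``rarefaction-TSS`` /
``rarefaction-TSS.log``.  All transforms are column-local: each sample's
output depends only on its own counts.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .containers import CountMatrix

__all__ = ["METHODS", "normalize", "rarefy", "TSS_LOG_PSEUDOCOUNT", "CLR_PSEUDOCOUNT"]

TSS_LOG_PSEUDOCOUNT = 1e-5  # on relative abundances
CLR_PSEUDOCOUNT = 1.0  # on counts

METHODS = (
    "TSS",
    "TSS.log",
    "TSS.arcsin",
    "clr",
    "rclr",
    "rarefaction",
    "rarefaction-TSS",
    "rarefaction-TSS.log",
)


def _tss(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-total sample; cannot total-sum scale")
    return counts / totals


def normalize(
    cm: CountMatrix,
    method: str,
    pseudocount: Optional[float] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Transform a count matrix; returns a float features x samples array.

    ``seed`` is only consulted by the rarefaction-based methods.
    """
    counts = cm.counts.astype(float)
    if method == "TSS":
        return _tss(counts)
    if method == "TSS.log":
        pc = TSS_LOG_PSEUDOCOUNT if pseudocount is None else pseudocount
        return np.log10(_tss(counts) + pc)
    if method == "TSS.arcsin":
        return np.arcsin(np.sqrt(_tss(counts)))
    if method == "clr":
        pc = CLR_PSEUDOCOUNT if pseudocount is None else pseudocount
        logc = np.log(counts + pc)
        return logc - logc.mean(axis=0)
    if method == "rclr":
        rel = _tss(counts)
        out = np.zeros_like(rel)
        nz = rel > 0
        logrel = np.where(nz, np.log(np.where(nz, rel, 1.0)), 0.0)
        with np.errstate(invalid="ignore"):
            gmean_log = np.where(nz.sum(axis=0) > 0, logrel.sum(axis=0) / np.maximum(nz.sum(axis=0), 1), 0.0)
        out[nz] = (logrel - gmean_log)[nz]
        return out
    if method == "rarefaction":
        return rarefy(cm, seed=seed).counts.astype(float)
    if method == "rarefaction-TSS":
        return _tss(rarefy(cm, seed=seed).counts.astype(float))
    if method == "rarefaction-TSS.log":
        pc = TSS_LOG_PSEUDOCOUNT if pseudocount is None else pseudocount
        return np.log10(_tss(rarefy(cm, seed=seed).counts.astype(float)) + pc)
    raise ValueError(f"unknown normalization method: {method!r}")


def rarefy(
    cm: CountMatrix,
    depth: Union[int, str] = "q25",
    seed: Optional[int] = None,
) -> CountMatrix:
    """Subsample each sample without replacement to a common depth.

    ``depth="q25"`` resolves to the 25th percentile of sample totals.
    Samples already at or below the target depth are left unchanged (rather
    than dropped, so stored test indices stay valid across methods).  The
    draw is multivariate hypergeometric, i.e. exact subsampling of reads.
    """
    totals = cm.counts.sum(axis=0)
    if depth == "q25":
        target = int(np.quantile(totals, 0.25))
    else:
        target = int(depth)
    if target <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    out = cm.counts.copy()
    for j in range(cm.n_samples):
        if totals[j] > target:
            out[:, j] = rng.multivariate_hypergeometric(cm.counts[:, j], target)
    return CountMatrix(out, list(cm.feature_ids), list(cm.sample_ids))
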