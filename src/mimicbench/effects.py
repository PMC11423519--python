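"""Effect-size statistics: generalized fold change and prevalence difference.

The generalized fold change (gFC) is the mean, over a grid of quantiles, of
the difference in per-group quantiles of log10 relative abundance.  Being a
quantile-based location shift it is robust to the zero-heavy distributions
typical of taxonomic profiles.  Sign convention: positive when group 1
(label == 1) is enriched.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_QUANTILE_GRID",
    "DEFAULT_PSEUDOCOUNT",
    "generalized_fold_change",
    "gfc_matrix",
    "prevalence_difference",
]

#: 0.05, 0.10, ..., 0.95
DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
#: added to relative abundances before log10
DEFAULT_PSEUDOCOUNT = 1e-5


def _check_groups(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both groups must be non-empty")
    return labels


def generalized_fold_change(
    values: np.ndarray,
    labels: np.ndarray,
    quantile_grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """gFC of one feature's relative abundances between two groups.

    ``values`` are per-sample relative (TSS) abundances; quantiles use
    linear interpolation (type-7 convention, numpy default).
    """
    labels = _check_groups(labels)
    logv = np.log10(np.asarray(values, dtype=float) + pseudocount)
    q1 = np.quantile(logv[labels == 1], quantile_grid)
    q0 = np.quantile(logv[labels == 0], quantile_grid)
    return float(np.mean(q1 - q0))


def gfc_matrix(
    rel_abundance: np.ndarray,
    labels: np.ndarray,
    quantile_grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Vectorized gFC for every feature (rows) of a relative-abundance matrix."""
    labels = _check_groups(labels)
    logv = np.log10(np.asarray(rel_abundance, dtype=float) + pseudocount)
    q1 = np.quantile(logv[:, labels == 1], quantile_grid, axis=1)
    q0 = np.quantile(logv[:, labels == 0], quantile_grid, axis=1)
    return np.mean(q1 - q0, axis=0)


def prevalence_difference(values: np.ndarray, labels: np.ndarray) -> float:
    """Difference in the fraction of non-zero samples: group 1 minus group 0."""
    labels = _check_groups(labels)
    values = np.asarray(values)
    return float((values[labels == 1] > 0).mean() - (values[labels == 0] > 0).mean())
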