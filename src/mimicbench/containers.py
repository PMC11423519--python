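"""Core in-memory containers shared by the simulation and testing modules.

The substrate of everything is a taxa-by-samples integer count table
(:class:`CountMatrix`).  Simulations attach binary group labels and a
:class:`GroundTruth` record of which features carry an implanted signal,
yielding a :class:`SimulatedDataset`; confounded simulations additionally
carry a second label and a disjoint second ground truth
(:class:`ConfoundedDataset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GroundTruth",
    "SimulatedDataset",
    "ConfoundedDataset",
]


@dataclass
class CountMatrix:
    """Taxa x samples non-negative integer count table.

    Parameters
    ----------
    counts
        Integer array of shape ``(n_features, n_samples)``; all entries >= 0.
    feature_ids
        Unique feature (taxon) identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    """

    counts: np.ndarray
    feature_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (features x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != self.counts.shape[0]:
            raise ValueError("feature_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), list(self.feature_ids), list(self.sample_ids))

    def relative_abundance(self) -> np.ndarray:
        """Total-sum-scaled (per-sample) relative abundances as floats.

        Zero-total samples map to all-zero columns rather than NaN.
        """
        totals = self.counts.sum(axis=0).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


@dataclass
class GroundTruth:
    """Bookkeeping of implanted differential-abundance signals.

    ``features`` holds the retained implanted feature ids; ``rejected`` the
    ones removed post hoc because their realized generalized fold change fell
    below the rejection threshold (|gFC| < 0.001).  Per-feature maps record
    the target group (``direction``), the abundance scaling factor, the
    prevalence-shift fraction and the realized gFC (including for rejected
    features, for diagnostics).
    """

    features: List[str] = field(default_factory=list)
    direction: Dict[str, int] = field(default_factory=dict)
    abundance_scale: Dict[str, float] = field(default_factory=dict)
    prev_shift: Dict[str, float] = field(default_factory=dict)
    gfc: Dict[str, float] = field(default_factory=dict)
    rejected: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.features) & set(self.rejected):
            raise ValueError("rejected and retained feature sets overlap")

    @property
    def feature_set(self) -> set:
        return set(self.features)


@dataclass
class SimulatedDataset:
    """A count matrix plus group labels and the implanted ground truth."""

    cm: CountMatrix
    labels: np.ndarray  # 0/1 per sample
    truth: GroundTruth
    seed: Optional[int] = None
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.cm.n_samples,):
            raise ValueError("labels must have one entry per sample")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")


@dataclass
class ConfoundedDataset:
    """A simulated dataset with a second, disjoint implanted signal.

    The confounder label partitions samples independently of the main label;
    together they define four strata used by biased resampling.
    """

    base: SimulatedDataset
    confounder: np.ndarray  # 0/1 per sample
    confounder_truth: GroundTruth
    bias: Optional[float] = None

    def __post_init__(self) -> None:
        self.confounder = np.asarray(self.confounder, dtype=np.int8)
        if self.confounder.shape != (self.base.cm.n_samples,):
            raise ValueError("confounder must have one entry per sample")
        overlap = self.base.truth.feature_set & self.confounder_truth.feature_set
        if overlap:
            raise ValueError(f"main and confounder truth overlap: {sorted(overlap)[:5]}")

    @property
    def cm(self) -> CountMatrix:
        return self.base.cm

    @property
    def labels(self) -> np.ndarray:
        return self.base.labels

    def strata(self) -> np.ndarray:
        """Stratum index per sample: 2*label + confounder (0..3)."""
        return (2 * self.base.labels + self.confounder).astype(np.int8)
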