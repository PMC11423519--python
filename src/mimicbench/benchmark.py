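"""Benchmark orchestration: grids, test indices and the evaluation sweep.

The full design is a Cartesian grid of abundance scales x prevalence shifts
x implantation repeats x sample sizes x testing subsamples (the default
grid enumerates 980,000 configurations per DA method).  Test indices are
generated once per (sample size, subsample) and shared by every method so
all tests see byte-identical inputs; per-task failures are recorded as
missing results (p = 1 downstream) rather than aborting the sweep.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CountMatrix, SimulatedDataset
from . import da_tests
from .da_tests import DEFAULT_TRANSFORM
from .evaluate import auroc_from_pvalues, fdr_recall, p_adjust
from .implant import DEFAULT_ABUNDANCE_SCALES, DEFAULT_PREV_SHIFTS, implant_signal
from .transforms import normalize

__all__ = [
    "BenchmarkGrid",
    "enumerate_configs",
    "generate_test_indices",
    "run_da_method",
    "run_benchmark",
]

logger = logging.getLogger("mimicbench")

DEFAULT_SAMPLE_SIZES = (12, 24, 50, 100, 200, 400, 800)


@dataclass
class BenchmarkGrid:
    """The benchmark's configuration grid with the published defaults."""

    abundance_scales: Sequence[float] = DEFAULT_ABUNDANCE_SCALES
    prev_shifts: Sequence[float] = DEFAULT_PREV_SHIFTS
    n_implant_repeats: int = 100
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    n_subsamples: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.abundance_scales) and len(self.prev_shifts) and len(self.sample_sizes)):
            raise ValueError("grid lists must be non-empty")
        if any(s % 2 for s in self.sample_sizes):
            raise ValueError("sample sizes must be even")

    @property
    def size(self) -> int:
        return (
            len(self.abundance_scales)
            * len(self.prev_shifts)
            * self.n_implant_repeats
            * len(self.sample_sizes)
            * self.n_subsamples
        )

    def child_seed(self, *key: int) -> int:
        """Deterministic per-task seed derived from the master seed."""
        h = hashlib.sha256(("%d:" % self.master_seed + ":".join(map(str, key))).encode())
        return int.from_bytes(h.digest()[:4], "big") % (2**31)


def enumerate_configs(grid: BenchmarkGrid) -> List[Tuple[float, float, int, int, int]]:
    """All (scale, shift, repeat, sample_size, subsample) tuples.

    Deterministic order: scales outermost, subsamples innermost.
    """
    return list(
        itertools.product(
            grid.abundance_scales,
            grid.prev_shifts,
            range(grid.n_implant_repeats),
            grid.sample_sizes,
            range(grid.n_subsamples),
        )
    )


def generate_test_indices(
    labels: np.ndarray,
    sizes: Sequence[int],
    n_subsamples: int,
    seed: Optional[int] = None,
) -> Dict[Tuple[int, int], np.ndarray]:
    """Per (size, subsample): n/2 sample positions from each group.

    Drawn without replacement and identical for every DA method.
    """
    labels = np.asarray(labels)
    g0 = np.flatnonzero(labels == 0)
    g1 = np.flatnonzero(labels == 1)
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[int, int], np.ndarray] = {}
    for size in sizes:
        half = size // 2
        if half > min(g0.size, g1.size):
            raise ValueError(f"sample size {size} exceeds group availability")
        for rep in range(n_subsamples):
            pick = np.concatenate(
                [rng.choice(g0, half, replace=False), rng.choice(g1, half, replace=False)]
            )
            out[(size, rep)] = np.sort(pick)
    return out


_METHOD_FUNCS = {
    "wilcoxon": lambda m, lab, conf: da_tests.wilcoxon_test(m, lab),
    "wilcoxon-blocked": lambda m, lab, conf: da_tests.wilcoxon_test(m, lab, block=conf),
    "ttest": lambda m, lab, conf: da_tests.t_test(m, lab),
    "ks": lambda m, lab, conf: da_tests.ks_test(m, lab),
    "lm": lambda m, lab, conf: da_tests.linear_model_test(m, lab),
    "lm-fixed": lambda m, lab, conf: da_tests.linear_model_test(m, lab, conf, "fixed"),
    "lmem": lambda m, lab, conf: da_tests.linear_model_test(m, lab, conf, "random"),
    "modt": lambda m, lab, conf: da_tests.moderated_t_test(m, lab),
    "ancomw": lambda m, lab, conf: da_tests.ancom_w_test(m, lab),
}


def run_da_method(
    method: str,
    cm: CountMatrix,
    labels: np.ndarray,
    confounder: Optional[np.ndarray] = None,
    transform: Optional[str] = "auto",
    seed: Optional[int] = None,
):
    """Apply one DA method with its default (or an explicit) transform."""
    if method not in _METHOD_FUNCS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHOD_FUNCS)}")
    if transform == "auto":
        transform = DEFAULT_TRANSFORM[method]
    matrix = cm.counts.astype(float) if transform is None else normalize(cm, transform, seed=seed)
    res = _METHOD_FUNCS[method](matrix, labels, confounder)
    res.transform_used = transform
    return res


def run_benchmark(
    cm: CountMatrix,
    methods: Sequence[str],
    grid: BenchmarkGrid,
    mode: str = "all",
    fraction: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full (typically scaled-down) sweep in memory.

    For each (scale, shift, repeat) an implantation simulation is created;
    test indices per (size, subsample) are drawn once per repeat and shared
    by every method.  Returns a tidy frame with one row per (method, scale,
    shift, repeat, size, subsample) holding observed FDR, recall and AUROC.
    A failing task is logged and recorded with NaN metrics, never aborting
    the sweep.
    """
    rows = []
    for scale, shift, rep in itertools.product(
        grid.abundance_scales, grid.prev_shifts, range(grid.n_implant_repeats)
    ):
        sim_seed = grid.child_seed(1, int(scale * 100), int(shift * 100), rep)
        ds = implant_signal(cm, sim_seed, fraction=fraction, mode=mode, scale=scale, shift=shift)
        if not ds.truth.features:
            logger.warning("no retained truth at scale=%s shift=%s rep=%d", scale, shift, rep)
            continue
        idx_seed = grid.child_seed(2, int(scale * 100), int(shift * 100), rep)
        indices = generate_test_indices(ds.labels, grid.sample_sizes, grid.n_subsamples, idx_seed)
        for (size, sub), idx in indices.items():
            sub_cm = CountMatrix(
                ds.cm.counts[:, idx],
                list(ds.cm.feature_ids),
                [ds.cm.sample_ids[j] for j in idx],
            )
            sub_labels = ds.labels[idx]
            checksum = hashlib.sha256(sub_cm.counts.tobytes()).hexdigest()[:12]
            for method in methods:
                row = {
                    "method": method,
                    "abundance_scale": scale,
                    "prev_shift": shift,
                    "repeat": rep,
                    "sample_size": size,
                    "subsample": sub,
                    "input_checksum": checksum,
                }
                try:
                    res = run_da_method(method, sub_cm, sub_labels, seed=sim_seed)
                    p_raw = np.where(np.isnan(res.p), 1.0, res.p)
                    if res.is_pvalue:
                        p_eff = p_adjust(p_raw, "BH")
                    else:
                        p_eff = p_raw  # ANCOM-W scores: no adjustment
                    fdr, recall = fdr_recall(p_eff, ds.cm.feature_ids, ds.truth.features, alpha)
                    auroc = auroc_from_pvalues(p_raw, ds.cm.feature_ids, ds.truth.features)
                    row.update({"observed_fdr": fdr, "recall": recall, "auroc": auroc})
                except Exception as exc:  # isolation contract
                    logger.error("task failed (%s, %s, %s, %d): %s", method, scale, shift, rep, exc)
                    row.update({"observed_fdr": np.nan, "recall": np.nan, "auroc": np.nan})
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the metrics per (method, scale, shift, sample size)."""
    return (
        results.groupby(["method", "abundance_scale", "prev_shift", "sample_size"])[
            ["observed_fdr", "recall", "auroc"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
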