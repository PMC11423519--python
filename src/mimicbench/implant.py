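"""Signal implantation: editing a real count table under a known ground truth.

Differential abundance is created between two randomly chosen mock groups by
two composable edits on a selected feature subset:

* **prevalence shift** -- non-zero entries of the donor group are exchanged
  with zero entries of the target group, raising the target group's
  prevalence while conserving the feature's total zero count; and
* **abundance scaling** -- non-zero counts of the target group are
  multiplied by a constant factor (zeros stay zero, so scaling never
  changes prevalence).

By default the target group alternates across implanted features to avoid a
systematic depth difference between groups; a one-sided ("compositional")
mode implants into a single group and rarefies each altered sample back to
its original depth, inducing spurious depletion of background features.

Each implanted feature's realized generalized fold change is recorded;
features with |gFC| < 0.001 (typically very low prevalence picks) are
rejected and not recorded as signals.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set

import numpy as np

from .containers import CountMatrix, GroundTruth, SimulatedDataset
from .effects import gfc_matrix
from .transforms import rarefy

__all__ = [
    "GFC_REJECTION_THRESHOLD",
    "split_groups",
    "select_da_features",
    "implant_prevalence",
    "implant_abundance",
    "implant_signal",
    "implant_compositional",
]

GFC_REJECTION_THRESHOLD = 1e-3

#: abundance-scaling factors explored in the default benchmark grid
DEFAULT_ABUNDANCE_SCALES = (1.0, 1.25, 1.5, 2.0, 5.0, 10.0, 20.0)
#: prevalence-shift fractions explored in the default benchmark grid
DEFAULT_PREV_SHIFTS = (0.0, 0.1, 0.2, 0.3)


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def split_groups(cm: CountMatrix, seed: Optional[int] = None) -> np.ndarray:
    """Uniformly random balanced 0/1 partition of the samples.

    With an odd sample count the extra sample goes to group 1.
    """
    n = cm.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split into two groups")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.permutation(n)[: (n + 1) // 2]] = 1
    return labels


def select_da_features(
    cm: CountMatrix,
    fraction: float = 0.1,
    mode: str = "all",
    seed: Optional[int] = None,
    exclude: Optional[Iterable[str]] = None,
) -> List[str]:
    """Randomly select features to become differentially abundant.

    ``mode="all"`` draws uniformly from all features; ``mode="low"``
    restricts eligibility to low-abundance features, defined as those whose
    75th percentile count across all samples equals 0.  The number selected
    is ``round(fraction * n_features)`` (of the full matrix, not the
    eligible pool).  ``exclude`` removes ids from the eligible pool (used
    for disjoint confounder signals).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n_select = int(_round_half_up(fraction * cm.n_features))
    if n_select == 0:
        return []
    if mode == "all":
        eligible = np.ones(cm.n_features, dtype=bool)
    elif mode == "low":
        eligible = np.percentile(cm.counts, 75, axis=1) <= 0
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    if exclude:
        excl = set(exclude)
        eligible &= np.array([f not in excl for f in cm.feature_ids])
    pool = [f for f, e in zip(cm.feature_ids, eligible) if e]
    if len(pool) < n_select:
        raise ValueError(f"eligible pool ({len(pool)}) smaller than requested ({n_select})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_select, replace=False)
    return [pool[i] for i in sorted(chosen)]


def implant_prevalence(
    cm: CountMatrix,
    labels: np.ndarray,
    features: Sequence[str],
    shift: float,
    direction: dict,
    seed: Optional[int] = None,
) -> CountMatrix:
    """Shift prevalence toward each feature's target group by zero exchange.

    For each feature, ``k = round(shift * #non-zero donor entries)`` swaps
    are attempted between non-zero entries of the donor (non-target) group
    and zero entries of the target group; the realized number of swaps is
    limited by whichever side runs out first ("if possible").  The feature's
    total zero count across all samples is conserved.
    """
    if not 0 <= shift <= 1:
        raise ValueError("shift must lie in [0, 1]")
    if shift == 0 or not features:
        return cm
    rng = np.random.default_rng(seed)
    counts = cm.counts.copy()
    labels = np.asarray(labels)
    for fid in features:
        i = cm.feature_index(fid)
        target = direction[fid]
        donor_cols = np.flatnonzero((labels != target) & (counts[i] > 0))
        target_zero_cols = np.flatnonzero((labels == target) & (counts[i] == 0))
        k = int(_round_half_up(shift * donor_cols.size))
        k = min(k, donor_cols.size, target_zero_cols.size)
        if k == 0:
            continue
        take = rng.choice(donor_cols, size=k, replace=False)
        put = rng.choice(target_zero_cols, size=k, replace=False)
        counts[i, put] = counts[i, take]
        counts[i, take] = 0
    return CountMatrix(counts, list(cm.feature_ids), list(cm.sample_ids))


def implant_abundance(
    cm: CountMatrix,
    labels: np.ndarray,
    features: Sequence[str],
    scale: float,
    direction: dict,
    rounding: str = "half_up",
) -> CountMatrix:
    """Multiply non-zero target-group counts of each feature by ``scale``.

    Scaled values are integer-rounded per ``rounding`` ("half_up", "floor"
    or "ceil") with a floor of 1, so scaling can never silently change a
    feature's prevalence; the zero pattern is untouched.  ``scale=1`` is the
    identity.
    """
    if scale < 1:
        raise ValueError("abundance scale must be >= 1")
    if scale == 1 or not features:
        return cm
    rounders = {"half_up": _round_half_up, "floor": np.floor, "ceil": np.ceil}
    if rounding not in rounders:
        raise ValueError(f"unknown rounding policy: {rounding!r}")
    counts = cm.counts.copy()
    labels = np.asarray(labels)
    for fid in features:
        i = cm.feature_index(fid)
        cols = np.flatnonzero((labels == direction[fid]) & (counts[i] > 0))
        scaled = rounders[rounding](counts[i, cols] * scale)
        counts[i, cols] = np.maximum(scaled, 1).astype(np.int64)
    return CountMatrix(counts, list(cm.feature_ids), list(cm.sample_ids))


def _assign_directions(features: Sequence[str], balanced: bool, one_sided_group: int = 1) -> dict:
    """Target group per feature; balanced mode alternates in sorted-id order."""
    if balanced:
        return {fid: i % 2 for i, fid in enumerate(sorted(features))}
    return {fid: one_sided_group for fid in features}


def _build_truth(
    cm_after: CountMatrix,
    labels: np.ndarray,
    features: Sequence[str],
    direction: dict,
    scale: float,
    shift: float,
) -> GroundTruth:
    rel = cm_after.relative_abundance()
    idx = [cm_after.feature_index(f) for f in features]
    gfc = gfc_matrix(rel[idx], labels) if idx else np.array([])
    gfc_map = {fid: float(g) for fid, g in zip(features, gfc)}
    rejected = [fid for fid in features if abs(gfc_map[fid]) < GFC_REJECTION_THRESHOLD]
    kept = [fid for fid in features if fid not in set(rejected)]
    return GroundTruth(
        features=kept,
        direction={fid: int(direction[fid]) for fid in features},
        abundance_scale={fid: float(scale) for fid in features},
        prev_shift={fid: float(shift) for fid in features},
        gfc=gfc_map,
        rejected=rejected,
    )


def implant_signal(
    cm: CountMatrix,
    seed: int,
    fraction: float = 0.1,
    mode: str = "all",
    scale: float = 1.0,
    shift: float = 0.0,
    balanced: bool = True,
    rounding: str = "half_up",
) -> SimulatedDataset:
    """Full implantation pipeline for one simulated repetition.

    Composes group split -> feature selection -> prevalence shift ->
    abundance scaling, records the realized gFC per implanted feature and
    rejects features with |gFC| below the rejection threshold.  With
    ``balanced=True`` implanted features alternate their target group
    (sorted-id order) to prevent a systematic depth difference between
    groups.  At ``scale=1, shift=0`` the count matrix is returned unchanged
    (internal negative control).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    labels = split_groups(cm, ss[0])
    features = select_da_features(cm, fraction, mode, ss[1])
    direction = _assign_directions(features, balanced)
    out = implant_prevalence(cm, labels, features, shift, direction, ss[2])
    out = implant_abundance(out, labels, features, scale, direction, rounding)
    truth = _build_truth(out, labels, features, direction, scale, shift)
    return SimulatedDataset(
        cm=out,
        labels=labels,
        truth=truth,
        seed=seed,
        params={
            "fraction": fraction,
            "mode": mode,
            "scale": scale,
            "shift": shift,
            "balanced": balanced,
            "rounding": rounding,
            "kind": "implantation",
        },
    )


def implant_compositional(
    cm: CountMatrix,
    seed: int,
    fraction: float = 0.1,
    scale: float = 1.0,
    shift: float = 0.0,
    mode: str = "all",
    rounding: str = "half_up",
) -> SimulatedDataset:
    """One-sided implantation followed by per-sample rarefaction to depth.

    All implanted features target group 1; afterwards every sample whose
    total count increased is rarefied (without replacement) back to its
    pre-implantation total, so group depths are preserved and background
    features are spuriously depleted in the implanted group.  Samples whose
    totals did not increase are untouched; no modification means no
    rarefaction at all.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    labels = split_groups(cm, ss[0])
    features = select_da_features(cm, fraction, mode, ss[1])
    direction = _assign_directions(features, balanced=False, one_sided_group=1)
    out = implant_prevalence(cm, labels, features, shift, direction, ss[2])
    out = implant_abundance(out, labels, features, scale, direction, rounding)

    orig_totals = cm.counts.sum(axis=0)
    new_totals = out.counts.sum(axis=0)
    if np.any(new_totals > orig_totals):
        rng = np.random.default_rng(ss[3])
        counts = out.counts.copy()
        for j in np.flatnonzero(new_totals > orig_totals):
            counts[:, j] = rng.multivariate_hypergeometric(counts[:, j], int(orig_totals[j]))
        out = CountMatrix(counts, list(out.feature_ids), list(out.sample_ids))

    truth = _build_truth(out, labels, features, direction, scale, shift)
    return SimulatedDataset(
        cm=out,
        labels=labels,
        truth=truth,
        seed=seed,
        params={
            "fraction": fraction,
            "mode": mode,
            "scale": scale,
            "shift": shift,
            "balanced": False,
            "rounding": rounding,
            "kind": "implantation-compositional",
        },
    )
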