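"""Scoring DA results against ground truth.

Conventions: missing p-values are imputed to 1 *before* adjustment;
discoveries use strict inequality p_adj < alpha; with zero discoveries the
observed FDR is defined as 0 (a method that discovers nothing makes no
false discoveries).  ANCOM-W scores bypass adjustment entirely and are
thresholded directly at 0.05.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "p_adjust",
    "fdr_recall",
    "auroc_from_pvalues",
    "fdr_control_flag",
    "classify_feature_robustness",
]


def p_adjust(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Benjamini-Yekutieli step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        p = np.where(np.isnan(p), 1.0, p)  # missing-p convention
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError("method must be 'BH' or 'BY'")
    return multipletests(p, method=key)[1]


def fdr_recall(
    p_adj: np.ndarray,
    feature_ids: Sequence[str],
    truth: Iterable[str],
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Observed FDR and recall of the discovery set {p_adj < alpha}."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    truth = set(truth)
    if not truth:
        raise ValueError("ground truth set is empty; recall undefined")
    p_adj = np.asarray(p_adj, dtype=float)
    discovered = {f for f, p in zip(feature_ids, p_adj) if p < alpha}
    if discovered:
        fdr = len(discovered - truth) / len(discovered)
    else:
        fdr = 0.0
    recall = len(discovered & truth) / len(truth)
    return float(fdr), float(recall)


def auroc_from_pvalues(
    p_raw: np.ndarray, feature_ids: Sequence[str], truth: Iterable[str]
) -> float:
    """AUROC of ranking ground-truth features above background by small p.

    Rank-sum (Mann-Whitney) formulation; ties contribute 1/2.
    """
    from sklearn.metrics import roc_auc_score

    truth = set(truth)
    y = np.array([f in truth for f in feature_ids], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both truth and background must be non-empty")
    p_raw = np.where(np.isnan(np.asarray(p_raw, dtype=float)), 1.0, p_raw)
    return float(roc_auc_score(y, -p_raw))


def fdr_control_flag(setting_mean_fdrs: Sequence[float], fdr_cut: float = 0.10,
                     fraction_cut: float = 0.10) -> str:
    """'sufficient' unless mean observed FDR exceeds 10% in >10% of settings."""
    fdrs = np.asarray(list(setting_mean_fdrs), dtype=float)
    if fdrs.size == 0:
        raise ValueError("need at least one setting")
    frac = (fdrs > fdr_cut).mean()
    return "insufficient" if frac > fraction_cut else "sufficient"


def classify_feature_robustness(
    p_naive_disease: float,
    p_naive_drug: float,
    p_adj_disease: float,
    p_adj_drug: float,
    fdr: float = 0.05,
) -> str:
    """Four-model classification of a feature's disease/drug association.

    Inputs are BH-adjusted p-values from the naive disease model, the naive
    drug model and the corresponding confounder-adjusted models.  Returns
    one of 'drug-and-disease', 'disease-associated', 'drug-confounded',
    'drug-associated', 'none'.
    """
    vals = [p_naive_disease, p_naive_drug, p_adj_disease, p_adj_drug]
    if any(v is None or np.isnan(v) for v in vals):
        raise ValueError("all four adjusted p-values are required")
    dis_naive = p_naive_disease < fdr
    drug_naive = p_naive_drug < fdr
    dis_adj = p_adj_disease < fdr
    drug_adj = p_adj_drug < fdr
    if dis_naive and drug_naive and dis_adj and drug_adj:
        return "drug-and-disease"
    if dis_naive and dis_adj and not drug_adj:
        return "disease-associated"
    if dis_naive and drug_naive and not dis_adj:
        return "drug-confounded"
    if drug_naive and drug_adj and not dis_naive and not dis_adj:
        return "drug-associated"
    return "none"
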