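"""Per-DRG discrimination metrics, subset slicing and cross-model aggregation.

AUC is one-vs-rest per DRG code, aggregated by macro- (unweighted mean over
codes with both a positive and a negative case) and micro-averaging (pooled
binary indicators over all (code, stay) pairs).  F1 is reported macro
(averaged over the subset's full code list, so codes never predicted and
never observed contribute 0) and micro (pooled TP/FP/FN).  Subsets mirror a
clinical reporting table: everything, per major diagnostic category, the
most frequent codes, and the smallest code prefix covering 80% of stays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .synthgen import DrgCatalog


class NoEligibleLabelError(ValueError):
    """Raised when a subset leaves no label with both positives and negatives."""


class ReportMismatchError(ValueError):
    """Raised when per-model reports to aggregate do not share subsets."""


@dataclass(frozen=True)
class MetricReport:
    subset_name: str
    macro_auc: float
    micro_auc: float
    macro_f1: float
    micro_f1: float
    n_targets: int      # unique DRGs in the subset definition
    n_stays: int        # test stays covered by the subset
    stay_share: float   # n_stays / total test stays
    n_dropped_labels: int = 0  # labels without both classes, excluded from macro-AUC


def auc_scores(probs: np.ndarray, true_codes, label_space,
               subset_codes=None) -> tuple[float, float]:
    """(macro, micro) one-vs-rest AUC, restricted to stays whose true code
    lies in ``subset_codes`` and to the subset's columns."""
    label_space = list(label_space)
    subset = list(subset_codes) if subset_codes is not None else label_space
    col = {c: i for i, c in enumerate(label_space)}
    true_codes = np.asarray(true_codes)
    probs = np.asarray(probs)
    keep = np.isin(true_codes, subset)
    probs, true_codes = probs[keep], true_codes[keep]

    aucs = []
    dropped = 0
    cols, bins = [], []
    for c in subset:
        y = (true_codes == c).astype(int)
        cols.append(probs[:, col[c]])
        bins.append(y)
        if 0 < y.sum() < len(y):
            aucs.append(roc_auc_score(y, probs[:, col[c]]))
        else:
            dropped += 1
    if not aucs:
        raise NoEligibleLabelError("no label in the subset has both classes")
    y_flat = np.concatenate(bins)
    s_flat = np.concatenate(cols)
    micro = roc_auc_score(y_flat, s_flat)
    return float(np.mean(aucs)), float(micro)


def f1_scores(pred_codes, true_codes, subset_codes) -> tuple[float, float]:
    """(macro, micro) F1 over the subset's code list.

    Stays whose true code is outside the subset are excluded; predictions
    falling outside the subset then count against recall but not precision.
    """
    subset = list(subset_codes)
    pred_codes = np.asarray(pred_codes)
    true_codes = np.asarray(true_codes)
    keep = np.isin(true_codes, subset)
    pred_codes, true_codes = pred_codes[keep], true_codes[keep]
    macro = f1_score(true_codes, pred_codes, labels=subset, average="macro",
                     zero_division=0)
    micro = f1_score(true_codes, pred_codes, labels=subset, average="micro",
                     zero_division=0)
    return float(macro), float(micro)


def make_subsets(test_stays, catalog: DrgCatalog,
                 top_ks: tuple[int, ...] = (30, 50),
                 coverage: float = 0.80) -> dict[str, tuple[str, ...]]:
    """Subset name -> DRG code tuple.

    ``all`` is the whole catalog; one subset per MDC; ``top_<k>_drgs`` are the
    k most frequent codes among the test stays (frequency ties broken by code
    order, k clipped to the number of distinct codes); ``top_80pct_cases`` is
    the smallest frequency-ranked prefix whose cumulative stay share reaches
    ``coverage``.
    """
    codes = sorted(catalog.codes())
    counts: dict[str, int] = {c: 0 for c in codes}
    for s in test_stays:
        if s.drg_code in counts:
            counts[s.drg_code] += 1
    ranked = sorted((c for c in codes if counts[c] > 0),
                    key=lambda c: (-counts[c], c))
    total = sum(counts.values())

    subsets: dict[str, tuple[str, ...]] = {"all": tuple(codes)}
    mdcs = sorted({e.mdc for e in catalog.entries})
    for m in mdcs:
        subsets[m] = tuple(sorted(e.code for e in catalog.entries if e.mdc == m))
    for k in top_ks:
        subsets[f"top_{k}_drgs"] = tuple(ranked[:k]) if ranked else tuple(codes)
    if total > 0:
        cum = 0
        prefix = []
        for c in ranked:
            prefix.append(c)
            cum += counts[c]
            if cum >= coverage * total:
                break
        subsets[f"top_{int(coverage * 100)}pct_cases"] = tuple(prefix)
    return subsets


def evaluate_predictions(probs: np.ndarray, pred_codes, true_codes, label_space,
                         subsets: dict[str, tuple[str, ...]]) -> dict[str, MetricReport]:
    """One MetricReport per computable subset (Table-style rows)."""
    true_codes = np.asarray(true_codes)
    n_total = len(true_codes)
    reports: dict[str, MetricReport] = {}
    for name, codes in subsets.items():
        n_stays = int(np.isin(true_codes, list(codes)).sum())
        if n_stays == 0:
            continue
        try:
            macro_auc, micro_auc = auc_scores(probs, true_codes, label_space, codes)
        except (NoEligibleLabelError, ValueError):
            continue
        macro_f1, micro_f1 = f1_scores(pred_codes, true_codes, codes)
        reports[name] = MetricReport(
            subset_name=name, macro_auc=macro_auc, micro_auc=micro_auc,
            macro_f1=macro_f1, micro_f1=micro_f1, n_targets=len(codes),
            n_stays=n_stays, stay_share=n_stays / n_total if n_total else 0.0)
    return reports


_METRICS = ("macro_auc", "micro_auc", "macro_f1", "micro_f1")


def aggregate_over_models(reports: list[dict[str, MetricReport]]
                          ) -> dict[str, dict[str, tuple[float, float]]]:
    """Mean and sample SD (ddof=1) of each metric over the per-fold models."""
    if len(reports) < 2:
        raise ReportMismatchError("need at least two model reports to aggregate")
    keys = set(reports[0])
    for r in reports[1:]:
        if set(r) != keys:
            raise ReportMismatchError("model reports cover different subsets")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for name in sorted(keys):
        out[name] = {}
        for m in _METRICS:
            vals = np.array([getattr(r[name], m) for r in reports])
            out[name][m] = (float(vals.mean()), float(vals.std(ddof=1)))
        out[name]["n_targets"] = reports[0][name].n_targets
        out[name]["n_stays"] = reports[0][name].n_stays
    return out
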