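"""Evaluation protocol: lesion-group AUCs, fixed-sensitivity operating
point, and cross-run significance testing.

Patch classifiers are scored per lesion group (type × size) with two
metrics:

* **normal vs. abnormal AUC** — can the model detect lesions of this group?
  Computed on a balanced subset: all patches of the group as positives
  (abnormality score = 1 − P(background)) against an equal number of
  background patches subsampled with a fixed seed, so every model is
  compared on the same subset.
* **benign vs. malignant AUC** — can it grade them? Computed only on the
  group's patches, malignancy score = P(malignant calc) + P(malignant
  mass), malignant as positive class.

Either metric is *missing* (None) when a group lacks enough examples.

Whole-image classifiers report AUC plus specificity/accuracy at the
operating point whose sensitivity is fixed at 0.75 (the smallest
sensitivity ≥ 0.75 attainable on the score set; no ROC interpolation).
Models are compared across repeated runs with the one-sided Welch t-test
(unequal variances, Welch–Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .patch_extraction import BACKGROUND, CLASSES

_MALIGNANT_COLS = [CLASSES.index("malignant_calc"), CLASSES.index("malignant_mass")]
_BACKGROUND_COL = CLASSES.index(BACKGROUND)


class SingleClassError(ValueError):
    """AUC is undefined without both classes."""


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    se: float
    sp: float
    acc: float


def auc(scores, labels) -> float:
    """Area under the empirical ROC (Mann–Whitney with tie half-credit)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise SingleClassError("both classes required for AUC")
    return float(roc_auc_score(labels, scores))


def abnormality_scores(probs: np.ndarray) -> np.ndarray:
    """1 − P(background) from 5-class probabilities."""
    return 1.0 - np.asarray(probs)[:, _BACKGROUND_COL]


def malignancy_scores(probs: np.ndarray) -> np.ndarray:
    """P(malignant calcification) + P(malignant mass)."""
    p = np.asarray(probs)
    return p[:, _MALIGNANT_COLS[0]] + p[:, _MALIGNANT_COLS[1]]


def _group_mask(records: pd.DataFrame, lesion_type: str, size_group: str) -> np.ndarray:
    return ((records["lesion_type"] == lesion_type)
            & (records["size_group"] == size_group)).to_numpy()


def normal_vs_abnormal_auc(
    probs: np.ndarray,
    records: pd.DataFrame,
    lesion_type: str,
    size_group: str,
    seed: int = 0,
    min_n: int = 2,
) -> float | None:
    """Detection AUC for one lesion group on a balanced subset, or None
    (missing) when the group or the normals are too few.

    `records` needs columns label, lesion_type, size_group; the background
    subsample depends only on (group, seed), never on the model, so that
    different models share the same subset."""
    probs = np.asarray(probs)
    pos = np.flatnonzero(_group_mask(records, lesion_type, size_group)
                         & (records["label"] != BACKGROUND).to_numpy())
    neg = np.flatnonzero((records["label"] == BACKGROUND).to_numpy())
    if len(pos) < min_n or len(neg) < len(pos):
        return None
    rng = np.random.default_rng(seed)
    neg = np.sort(rng.choice(neg, size=len(pos), replace=False))
    idx = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return auc(abnormality_scores(probs[idx]), y)


def benign_vs_malignant_auc(
    probs: np.ndarray,
    records: pd.DataFrame,
    lesion_type: str,
    size_group: str,
    min_n: int = 2,
) -> float | None:
    """Pathology AUC within one lesion group (malignant positive), or None
    when only one pathology is present / too few examples."""
    probs = np.asarray(probs)
    sel = np.flatnonzero(_group_mask(records, lesion_type, size_group)
                         & (records["label"] != BACKGROUND).to_numpy())
    if len(sel) < min_n:
        return None
    y = records["label"].iloc[sel].str.startswith("malignant").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        return None
    return auc(malignancy_scores(probs[sel]), y)


def operating_point(scores, labels, target_se: float = 0.75) -> OperatingPoint:
    """The largest threshold whose sensitivity is ≥ `target_se`
    (score ≥ threshold ⇒ positive); Se is minimal subject to the floor."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0:
        raise ValueError("no positive examples")
    thresholds = np.unique(pos)[::-1]
    se = np.array([(pos >= t).mean() for t in thresholds])
    ok = np.flatnonzero(se >= target_se)
    i = ok[0]  # largest threshold meeting the floor
    thr = float(thresholds[i])
    sp = float((neg < thr).mean()) if len(neg) else float("nan")
    tp = int((pos >= thr).sum())
    tn = int((neg < thr).sum())
    acc = (tp + tn) / (len(pos) + len(neg))
    return OperatingPoint(threshold=thr, se=float(se[i]), sp=sp, acc=float(acc))


def welch_t_one_sided(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Upper-tail p-value for H1: mean_a > mean_b, unequal variances."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        return 0.5 if mean_a == mean_b else (0.0 if mean_a > mean_b else 1.0)
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(stats.t.sf(t, df))


def significance_stars(p: float) -> str:
    """ns / * (p<0.1) / ** (p<0.05) / *** (p<0.01) / **** (p<0.001),
    strict inequalities at every boundary."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "****"
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "ns"


def summarize_runs(
    results_by_model: dict[str, list],
    baseline: str,
    target_se: float = 0.75,
) -> pd.DataFrame:
    """Cross-run summary table: one row per model with mean ± sd of AUC,
    Sp and Acc (at the fixed-sensitivity operating point) and one-sided
    Welch p-values vs. the named baseline (H1: baseline > model).

    Every run of every model must score the same evaluation set."""
    if baseline not in results_by_model:
        raise ValueError(f"baseline {baseline!r} not among models")
    ref_labels = None
    per_model: dict[str, dict[str, np.ndarray]] = {}
    for name, runs in results_by_model.items():
        if len(runs) < 2:
            raise ValueError(f"model {name!r} needs >= 2 runs")
        metrics = {"auc": [], "sp": [], "acc": []}
        for run in runs:
            labels = np.asarray(run.labels)
            if ref_labels is None:
                ref_labels = labels
            elif not np.array_equal(labels, ref_labels):
                raise ValueError("mismatched evaluation sets across runs")
            scores = np.asarray(run.scores).reshape(-1)
            metrics["auc"].append(auc(scores, labels))
            op = operating_point(scores, labels, target_se)
            metrics["sp"].append(op.sp)
            metrics["acc"].append(op.acc)
        per_model[name] = {k: np.asarray(v) for k, v in metrics.items()}

    rows = []
    base = per_model[baseline]
    for name, m in per_model.items():
        row = {"model": name, "n_runs": len(m["auc"])}
        for key in ("auc", "sp", "acc"):
            a, b = base[key], m[key]
            row[f"{key}_mean"] = b.mean()
            row[f"{key}_sd"] = b.std(ddof=1)
            if name == baseline:
                row[f"{key}_p"] = np.nan
                row[f"{key}_stars"] = "n.a."
            else:
                p = welch_t_one_sided(
                    a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
                )
                row[f"{key}_p"] = p
                row[f"{key}_stars"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)
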