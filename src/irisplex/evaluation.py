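"""Forensic accuracy evaluation: confusion counts, predictive values, ROC/AUC.

Calls below the probability threshold are *inconclusive* and count as
negative for every category, so they feed the false-negative cell of their
true category and the true-negative cells of the other two.  ROC analysis
deliberately ignores the threshold: each category's raw predicted
probability is the score in a one-vs-rest comparison, so AUC measures the
ranking quality of the probabilities themselves while sensitivity,
specificity, PPV and NPV measure the thresholded calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import EyeColorCall, PhenotypeRecord
from .panel import CATEGORIES

#: Rendered value for an undefined metric (zero denominator), as in a
#: category that never receives a positive call and therefore has no PPV.
UNDEFINED_MARKER = "x"


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts for one category under one-vs-rest calling."""

    category: str
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percent metrics for one category; ``None`` marks an undefined value."""

    category: str
    sensitivity_pct: float | None
    specificity_pct: float | None
    ppv_pct: float | None
    npv_pct: float | None


@dataclass(frozen=True)
class RocResult:
    """One-vs-rest ROC curve and its area for one category."""

    category: str
    auc: float
    curve: tuple[tuple[float, float], ...]  # (FPR, TPR), (0,0) .. (1,1)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def confusion_for_category(
    calls: Sequence[EyeColorCall],
    truths: Sequence[PhenotypeRecord],
    category: str,
    sample_ids: Sequence[str] | None = None,
) -> ConfusionSummary:
    """Tabulate one-vs-rest confusion counts for ``category``.

    A sample is positive-called iff its call equals the category;
    inconclusive and other-category calls are negative.  When
    ``sample_ids`` is given, it is checked against the truth records.
    """
    if len(calls) != len(truths):
        raise ValueError(f"{len(calls)} calls vs {len(truths)} truths")
    if sample_ids is not None:
        bad = [
            (sid, t.sample_id)
            for sid, t in zip(sample_ids, truths)
            if sid != t.sample_id
        ]
        if bad:
            raise ValueError(f"sample-id mismatch between calls and truths: {bad[:10]}")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    tp = fp = tn = fn = 0
    for call, truth in zip(calls, truths):
        called_pos = call.call == category
        is_pos = truth.category == category
        if called_pos and is_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(category, tp, fp, tn, fn)


def metrics(c: ConfusionSummary) -> MetricReport:
    """Sensitivity, specificity, PPV and NPV as percentages.

    Zero-denominator cases (e.g. PPV with no positive calls) yield the
    undefined marker ``None`` rather than NaN or an exception.
    """
    return MetricReport(
        category=c.category,
        sensitivity_pct=_pct(c.tp, c.tp + c.fn),
        specificity_pct=_pct(c.tn, c.tn + c.fp),
        ppv_pct=_pct(c.tp, c.tp + c.fp),
        npv_pct=_pct(c.tn, c.tn + c.fn),
    )


def roc_auc(scores: Sequence[float], is_positive: Sequence[bool],
            category: str = "") -> RocResult:
    """One-vs-rest ROC via the Mann-Whitney U statistic.

    AUC is the probability that a random positive outscores a random
    negative, ties counting 1/2 — computed from midranks.  The curve sweeps
    the distinct score values from high to low; tied samples enter as a
    single (possibly diagonal) step, which makes the trapezoidal integral
    of the curve equal the U-statistic AUC exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    ranks = rankdata(s)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    return RocResult(category=category, auc=float(auc), curve=tuple(curve))


@dataclass(frozen=True)
class CategoryEvaluation:
    confusion: ConfusionSummary
    metrics: MetricReport
    roc: RocResult


@dataclass(frozen=True)
class CohortEvaluation:
    """Per-category accuracy bundle plus a publication-style report table."""

    threshold: float
    per_category: dict[str, CategoryEvaluation]

    def to_table(self) -> pd.DataFrame:
        """Rows AUC/sensitivity/specificity/PPV/NPV, one column per colour.

        Display convention: AUC to 3 decimals, percentages to 1 decimal,
        undefined values rendered as ``x``.  Internal values are unrounded.
        """
        def fmt_pct(v):
            return UNDEFINED_MARKER if v is None else f"{v:.1f}"

        rows = {
            "AUC": {c: f"{self.per_category[c].roc.auc:.3f}" for c in CATEGORIES},
            "Sensitivity (%)": {
                c: fmt_pct(self.per_category[c].metrics.sensitivity_pct) for c in CATEGORIES
            },
            "Specificity (%)": {
                c: fmt_pct(self.per_category[c].metrics.specificity_pct) for c in CATEGORIES
            },
            "Positive predictive value (%)": {
                c: fmt_pct(self.per_category[c].metrics.ppv_pct) for c in CATEGORIES
            },
            "Negative predictive value (%)": {
                c: fmt_pct(self.per_category[c].metrics.npv_pct) for c in CATEGORIES
            },
        }
        return pd.DataFrame(rows).T[list(CATEGORIES)]


def evaluate_cohort(
    probabilities: np.ndarray,
    calls: Sequence[EyeColorCall],
    truths: Sequence[PhenotypeRecord],
    threshold: float = 0.7,
    sample_ids: Sequence[str] | None = None,
) -> CohortEvaluation:
    """Full accuracy assessment of a predicted cohort.

    ``probabilities`` is (n, 3) in (blue, intermediate, brown) order; calls
    and truths are aligned with its rows.
    """
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if P.shape != (len(truths), 3):
        raise ValueError(f"probabilities must be ({len(truths)}, 3), got {P.shape}")
    per = {}
    for idx, cat in enumerate(CATEGORIES):
        conf = confusion_for_category(calls, truths, cat, sample_ids=sample_ids)
        is_pos = [t.category == cat for t in truths]
        per[cat] = CategoryEvaluation(
            confusion=conf,
            metrics=metrics(conf),
            roc=roc_auc(P[:, idx], is_pos, category=cat),
        )
    return CohortEvaluation(threshold=threshold, per_category=per)
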