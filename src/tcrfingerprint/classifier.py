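"""ROC analysis of recognition scores against activation outcomes.

A peptide is called cross-reactive when its combined recognition score
reaches a cutoff.  The cutoff is chosen from the ROC curve under a
maximum-sensitivity policy: among all thresholds achieving the maximal
sensitivity, pick the one with maximal specificity (ties resolved toward
the largest threshold).  Minimizing false negatives is the safety-relevant
objective — a missed off-target peptide is worse than an extra candidate
to test.  The positive call is boundary-inclusive (score >= cutoff), so
the maximal-sensitivity guarantee is achievable at a realized score.

The ROC sweep and AUC are self-contained (the AUC is the Mann-Whitney
statistic with half credit for ties); labels derive from observed
activation via the 75%-of-epitope threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ValidationError

DEFAULT_ACTIVATION_THRESHOLD = 0.75


@dataclass(frozen=True)
class LabelledScore:
    """A peptide's recognition score with its observed activation outcome."""

    peptide: str
    score: float
    activation_observed: float
    label: bool

    @classmethod
    def from_activation(
        cls, peptide: str, score: float, activation_observed: float,
        activation_threshold: float = DEFAULT_ACTIVATION_THRESHOLD,
    ) -> "LabelledScore":
        """Derive the binary label: activating iff observed activation
        (normalized to the epitope) exceeds the threshold."""
        return cls(
            peptide=peptide,
            score=float(score),
            activation_observed=float(activation_observed),
            label=float(activation_observed) > activation_threshold,
        )


@dataclass(frozen=True)
class ClassifierResult:
    """ROC points, AUC and (after cutoff selection) operating metrics."""

    roc_points: tuple[tuple[float, float, float], ...]  # (fpr, tpr, threshold)
    auc: float
    n_positive: int
    n_negative: int
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None


def roc_curve(items: Sequence[LabelledScore]) -> ClassifierResult:
    """Sweep thresholds over the unique scores (plus a +inf sentinel).

    The classification rule is "positive iff score >= threshold".  The AUC
    equals the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    scores = np.array([it.score for it in items], dtype=float)
    labels = np.array([it.label for it in items], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"ROC needs both classes; got {n_pos} positive / {n_neg} negative"
        )

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for t in thresholds:
        called = scores >= t
        tp = int((called & labels).sum())
        fp = int((called & ~labels).sum())
        points.append((fp / n_neg, tp / n_pos, float(t)))

    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return ClassifierResult(
        roc_points=tuple(points), auc=float(auc),
        n_positive=n_pos, n_negative=n_neg,
    )


def select_cutoff(result: ClassifierResult, policy: str = "max-sensitivity") -> ClassifierResult:
    """Pick the operating threshold and fill in the metrics at it.

    ``max-sensitivity``: maximal sensitivity first, then maximal
    specificity, then the largest threshold.  With at least one positive a
    threshold at or below the minimum positive score always exists, so the
    selected sensitivity is always 1.
    """
    if policy != "max-sensitivity":
        raise ValueError(f"unknown cutoff policy {policy!r}")
    # key: sensitivity (tpr), then specificity (1-fpr), then threshold
    best = max(result.roc_points, key=lambda p: (p[1], 1.0 - p[0], p[2]))
    fpr, tpr, threshold = best
    tp = tpr * result.n_positive
    tn = (1.0 - fpr) * result.n_negative
    n = result.n_positive + result.n_negative
    return replace(
        result,
        cutoff=threshold,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        accuracy=(tp + tn) / n,
    )


def classify(scores: Mapping[str, float], cutoff: float) -> dict[str, bool]:
    """Binary cross-reactivity call: positive iff score >= cutoff."""
    return {pep: float(s) >= cutoff for pep, s in scores.items()}


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score groups.

    Returns (statistic, p-value); thin wrapper over the standard rank-sum
    test for comparing activating vs. non-activating score distributions.
    """
    res = stats.ranksums(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
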