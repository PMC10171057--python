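"""Train/test splitting, confusion matrices and diagnostic-accuracy metrics.

Evaluation follows standard diagnostic-accuracy reporting: a seeded
unstratified random split (default 7:3), a confusion matrix with the
"signs of ICH" class as positive, and sensitivity, specificity, PPV,
NPV and the positive-class F-score with Wilson score 95% confidence
intervals on each proportion.  A macro-averaged F-score (mean of the
per-class F-scores) is reported alongside, since the two conventions
are both common in clinical NLP papers.  Metrics with a zero
denominator are reported as undefined (NaN), never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform permutation split into (train, test) index arrays.

    The train size is ``train_fraction * n`` rounded half-up; a split
    that would leave either side empty raises.
    """
    if n < 2:
        raise DataError(f"cannot split {n} record(s)")
    n_train = _round_half_up(spec.train_fraction * n)
    if n_train == 0 or n_train == n:
        raise DataError(
            f"degenerate split: fraction {spec.train_fraction} of {n} records "
            f"leaves an empty side"
        )
    perm = np.random.default_rng(spec.random_seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def split(items: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Split any sequence into (train, test) lists."""
    train_idx, test_idx = split_indices(len(items), spec)
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Fourfold error matrix; positive class = "signs of ICH"."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def to_csv(self) -> str:
        return (
            ",predicted_positive,predicted_negative\n"
            f"gold_positive,{self.tp},{self.fn}\n"
            f"gold_negative,{self.fp},{self.tn}\n"
        )


def confusion(gold: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Tally a confusion matrix from 0/1 gold and predicted labels."""
    gold = np.asarray(gold, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if gold.shape != predicted.shape:
        raise DataError(
            f"gold has {gold.size} labels but predictions have {predicted.size}"
        )
    return ConfusionMatrix(
        tp=int(((gold == 1) & (predicted == 1)).sum()),
        fp=int(((gold == 0) & (predicted == 1)).sum()),
        fn=int(((gold == 1) & (predicted == 0)).sum()),
        tn=int(((gold == 0) & (predicted == 0)).sum()),
    )


def wilson_interval(count: int, nobs: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float
    f_score_macro: float
    ci: dict  # metric name -> (lo, hi) or None when undefined
    ci_level: float
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        def clean(x):
            return None if isinstance(x, float) and math.isnan(x) else x

        return {
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "ppv": clean(self.ppv),
            "npv": clean(self.npv),
            "f_score": clean(self.f_score),
            "f_score_macro": clean(self.f_score_macro),
            "ci_level": self.ci_level,
            "ci": {k: (list(v) if v else None) for k, v in self.ci.items()},
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [f"{'metric':<14}{'value':>8}  {int(self.ci_level * 100)}% CI"]
        for name in METRIC_NAMES:
            value = getattr(self, name)
            interval = self.ci.get(name)
            if math.isnan(value):
                lines.append(f"{name:<14}{'undef':>8}")
            else:
                lo, hi = interval
                lines.append(f"{name:<14}{value:>8.3f}  [{lo:.3f}, {hi:.3f}]")
        for name in ("f_score", "f_score_macro"):
            value = getattr(self, name)
            shown = "undef" if math.isnan(value) else f"{value:.3f}"
            lines.append(f"{name:<14}{shown:>8}")
        lines.append(f"gold positives {self.n_positive}, gold negatives {self.n_negative}")
        return "\n".join(lines)


def _f(precision: float, recall: float) -> float:
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return math.nan
    return 2 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> MetricsReport:
    """Diagnostic-accuracy metrics with Wilson score confidence intervals.

    F-score for the positive class is the harmonic mean of PPV and
    sensitivity; the macro variant averages it with the negative-class
    analogue (harmonic mean of NPV and specificity).  No interval is
    computed for F-scores.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie strictly between 0 and 1")
    values = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    point = {k: _ratio(num, den) for k, (num, den) in values.items()}
    ci = {
        k: (wilson_interval(num, den, ci_level) if den > 0 else None)
        for k, (num, den) in values.items()
    }
    f_pos = _f(point["ppv"], point["sensitivity"])
    f_neg = _f(point["npv"], point["specificity"])
    f_macro = (f_pos + f_neg) / 2  # NaN propagates if either side is undefined
    return MetricsReport(
        sensitivity=point["sensitivity"],
        specificity=point["specificity"],
        ppv=point["ppv"],
        npv=point["npv"],
        f_score=f_pos,
        f_score_macro=f_macro,
        ci=ci,
        ci_level=ci_level,
        n_positive=cm.n_positive,
        n_negative=cm.n_negative,
    )
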