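"""Deliberately naive CART reference implementation.

This module re-implements the same split rule as :mod:`reportriage.tree`
— exhaustive midpoint search, Gini impurity, lowest-feature/lowest-
threshold tie-breaks, tied leaves predicting negative — but with plain
Python loops and exact :class:`fractions.Fraction` arithmetic and no
shared code.  It exists purely as an independent cross-check for the
optimized trainer on small instances; it is far too slow for real
corpora and is not part of the pipeline.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

# Tree representation: ("leaf", prediction) or
# ("split", feature, threshold, left, right)


def ref_gini(labels: Sequence[int]) -> Fraction:
    n = len(labels)
    pos = sum(labels)
    neg = n - pos
    return 1 - (Fraction(pos, n) ** 2 + Fraction(neg, n) ** 2)


def ref_best_split(rows: Sequence[Sequence[float]], labels: Sequence[int]):
    """Best (feature, threshold) by Gini decrease, or None.

    Returns ``(feature, threshold, decrease)`` with the decrease as an
    exact Fraction.
    """
    n = len(labels)
    n_features = len(rows[0]) if rows else 0
    parent = ref_gini(labels)
    best = None  # (decrease, feature, threshold)
    for f in range(n_features):
        values = sorted(set(row[f] for row in rows))
        for lo, hi in zip(values, values[1:]):
            threshold = (lo + hi) / 2
            left = [lab for row, lab in zip(rows, labels) if row[f] <= threshold]
            right = [lab for row, lab in zip(rows, labels) if row[f] > threshold]
            decrease = parent - (
                Fraction(len(left), n) * ref_gini(left)
                + Fraction(len(right), n) * ref_gini(right)
            )
            if best is None or decrease > best[0]:
                best = (decrease, f, threshold)
    if best is None or best[0] <= 0:
        return None
    return best[1], best[2], best[0]


def ref_train(
    rows: Sequence[Sequence[float]],
    labels: Sequence[int],
    max_depth: int,
    min_samples_split: int = 2,
    depth: int = 0,
):
    n = len(labels)
    pos = sum(labels)
    neg = n - pos
    leaf = ("leaf", 1 if pos > neg else 0)
    if pos == 0 or neg == 0 or depth >= max_depth or n < min_samples_split:
        return leaf
    found = ref_best_split(rows, labels)
    if found is None:
        return leaf
    f, threshold, _ = found
    left_rows = [(row, lab) for row, lab in zip(rows, labels) if row[f] <= threshold]
    right_rows = [(row, lab) for row, lab in zip(rows, labels) if row[f] > threshold]
    left = ref_train(
        [r for r, _ in left_rows], [l for _, l in left_rows],
        max_depth, min_samples_split, depth + 1,
    )
    right = ref_train(
        [r for r, _ in right_rows], [l for _, l in right_rows],
        max_depth, min_samples_split, depth + 1,
    )
    return ("split", f, threshold, left, right)


def ref_predict(tree, row: Sequence[float]) -> int:
    while tree[0] == "split":
        _, f, threshold, left, right = tree
        tree = left if row[f] <= threshold else right
    return tree[1]


def ref_structure(tree):
    """Hashable structural form (features/thresholds/predictions only)."""
    if tree[0] == "leaf":
        return ("leaf", tree[1])
    _, f, threshold, left, right = tree
    return ("split", f, float(threshold), ref_structure(left), ref_structure(right))
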