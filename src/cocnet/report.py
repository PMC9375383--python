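"""Descriptive report arithmetic: the small printed statistics of the COC
selection and mtDNA experiments (proportions, fold ratios, crude odds
ratios), at the rounding precision used in the study's reporting style.
Raw precision is always available via ``rounded=False``.
"""

from __future__ import annotations

from collections.abc import Sequence

__all__ = ["proportion_summary", "fold_ratio", "crude_odds_ratio"]


def proportion_summary(counts: Sequence[int], rounded: bool = True):
    """Percentages of each count relative to the total.

    ``proportion_summary([302, 395])`` -> ``[43, 57]`` (integer rounding,
    the reporting precision for the BCB classification proportions).
    """
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all counts are zero")
    pct = [c / total * 100.0 for c in counts]
    if rounded:
        return [round(p) for p in pct]
    return pct


def fold_ratio(mean_a: float, mean_b: float, rounded: bool = True) -> float:
    """Ratio of two group means, rounded to one decimal.

    ``fold_ratio(1_908_041, 1_475_377)`` -> ``1.3`` (the mtDNA copy-number
    fold between BCB-negative and BCB-positive oocytes).
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive")
    ratio = mean_a / mean_b
    return round(ratio, 1) if rounded else ratio


def crude_odds_ratio(p1: float, p2: float) -> float:
    """Crude (unadjusted) odds ratio of two proportions.

    ``crude_odds_ratio(0.18, 0.09)`` -> ``2.2195...`` — the unadjusted
    counterpart of a replicate-adjusted model estimate; the two are not
    interchangeable and no adjustment is attempted here.
    """
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie strictly inside (0, 1)")
    return (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))
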