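"""Karyotype and microscopy-count statistics.

Chromosome-number summaries, the variance-heterogeneity F-test,
event-proportion comparisons, the spindle-stability channel-intensity
ratio, and the Mann-Whitney rank test for speed distributions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CountSample",
    "EventTable",
    "ChannelPair",
    "karyotype_summary",
    "variance_f_test",
    "proportion_compare",
    "intensity_ratio",
    "mann_whitney",
]


@dataclass(frozen=True)
class CountSample:
    """Labelled vector of per-cell integer counts (e.g. chromosomes/nucleus)."""

    label: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class EventTable:
    """Two-condition (events, n_cells) pairs for one scored event type."""

    event: str
    condition_a: str
    events_a: int
    n_a: int
    condition_b: str
    events_b: int
    n_b: int

    def __post_init__(self) -> None:
        for events, n in ((self.events_a, self.n_a), (self.events_b, self.n_b)):
            if not 0 <= events <= n:
                raise ValueError("events must satisfy 0 <= events <= n_cells")


@dataclass
class ChannelPair:
    """Two registered single-channel images plus an optional foreground mask."""

    signal: np.ndarray
    reference: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.signal.shape != self.reference.shape:
            raise ValueError("signal and reference must have identical shape")
        if (self.signal < 0).any() or (self.reference < 0).any():
            raise ValueError("intensities must be >= 0")
        if self.mask is not None:
            if self.mask.shape != self.signal.shape:
                raise ValueError("mask must match image shape")
            if not self.mask.any():
                raise ValueError("mask is empty")


def karyotype_summary(sample: CountSample) -> tuple[float, float, int]:
    """(mean, unbiased variance, n) of per-cell chromosome counts."""
    if sample.n < 2:
        raise ValueError("variance needs n >= 2")
    counts = np.asarray(sample.counts, dtype=float)
    return float(counts.mean()), float(counts.var(ddof=1)), sample.n


def variance_f_test(a: CountSample, b: CountSample) -> tuple[float, int, int, float]:
    """Two-sided variance-ratio F-test.

    F = var(a)/var(b) on F(n_a - 1, n_b - 1); two-sided p doubles the
    smaller tail, capped at 1. Zero variance in the denominator is an
    explicit error rather than an infinite statistic.
    """
    _, var_a, n_a = karyotype_summary(a)
    _, var_b, n_b = karyotype_summary(b)
    if var_b == 0:
        raise ValueError(f"denominator sample {b.label!r} has zero variance")
    f = var_a / var_b
    df1, df2 = n_a - 1, n_b - 1
    dist = scipy.stats.f(df1, df2)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), df1, df2, float(min(p, 1.0))


def proportion_compare(table: EventTable) -> tuple[float | None, float, float]:
    """(fold change a/b, risk difference a-b, two-sided Fisher exact p).

    Fold change is None when condition b has zero events.
    """
    p_a = table.events_a / table.n_a if table.n_a else 0.0
    p_b = table.events_b / table.n_b if table.n_b else 0.0
    fold = p_a / p_b if p_b > 0 else None
    contingency = [
        [table.events_a, table.n_a - table.events_a],
        [table.events_b, table.n_b - table.events_b],
    ]
    _, p = scipy.stats.fisher_exact(contingency, alternative="two-sided")
    return fold, p_a - p_b, float(p)


def intensity_ratio(pair: ChannelPair) -> float:
    """Mean background-subtracted signal over the mask, divided by the same
    quantity for the reference channel.

    Background per channel is the median outside the mask (0 if no mask).
    """
    signal = pair.signal.astype(float)
    reference = pair.reference.astype(float)
    if pair.mask is not None:
        mask = pair.mask.astype(bool)
        outside = ~mask
        bg_s = float(np.median(signal[outside])) if outside.any() else 0.0
        bg_r = float(np.median(reference[outside])) if outside.any() else 0.0
    else:
        mask = np.ones_like(signal, dtype=bool)
        bg_s = bg_r = 0.0
    num = float((signal[mask] - bg_s).mean())
    den = float((reference[mask] - bg_r).mean())
    if den == 0:
        raise ValueError("reference channel has zero background-subtracted intensity")
    return num / den


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact null distribution when min(n) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity
    correction. Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples need n >= 1")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
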