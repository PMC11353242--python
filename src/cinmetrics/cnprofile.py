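"""Binned read counts -> GC-corrected ratio profile -> segmentation -> CN calls.

A self-contained, desk-scale stand-in for an external shallow-WGS caller:
median-of-ratios normalization, recursive binary segmentation with
permutation-calibrated split acceptance, and integer copy-number rounding.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinTrack",
    "RatioProfile",
    "SegmentSet",
    "correct_gc_bias",
    "compute_ratio_profile",
    "segment_profile",
    "call_copy_numbers",
]


@dataclass
class BinTrack:
    """Per-bin (chrom, start, end, gc, count) records.

    Bins are sorted and non-overlapping within each chromosome; width is
    constant except possibly the last bin of a chromosome.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.bins.reset_index(drop=True)
        required = {"chrom", "start", "end", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"bins must have columns {sorted(required)}")
        if "gc" not in df.columns:
            df = df.assign(gc=np.nan)
        if (df["count"] < 0).any():
            raise ValueError("counts must be >= 0")
        if "gc" in df.columns and df["gc"].notna().any():
            gcv = df["gc"].dropna()
            if ((gcv < 0) | (gcv > 1)).any():
                raise ValueError("gc must be in [0, 1]")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: bins must have end > start")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: bins overlap or are unsorted")
        self.bins = df

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class RatioProfile:
    """Normalized per-bin copy-number ratios.

    ``bins`` carries chrom/start/end/gc/count/corrected/ratio/log2/mask;
    masked bins (zero counts) are excluded from downstream comparison.
    ``median_ratio`` is the genome-wide median of corrected counts — the
    copy-neutral reference. ``dispersion`` is filled in by the classifier
    stage when estimated.
    """

    bins: pd.DataFrame
    median_ratio: float
    dispersion: float | None = None

    def unmasked(self) -> pd.DataFrame:
        return self.bins[~self.bins["mask"]]


@dataclass
class SegmentSet:
    """Piecewise-constant segments with mean log2 ratio and integer CN."""

    segments: pd.DataFrame  # chrom, start, end, n_bins, mean_log2[, cn]
    ploidy: int | None = None

    def __post_init__(self) -> None:
        df = self.segments.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: empty or inverted segment")
            if not (starts[1:] == ends[:-1]).all():
                raise ValueError(f"{chrom}: segments must tile without gaps")
        self.segments = df

    def __len__(self) -> int:
        return len(self.segments)


def correct_gc_bias(track: BinTrack) -> BinTrack:
    """Remove GC dependence of counts by quadratic loess-style rescaling.

    Expected count is fit as a quadratic polynomial in GC over
    copy-neutral-candidate bins (counts within the interquartile range);
    each count is rescaled by (global median expected / bin expected).
    Degenerate GC (all equal) leaves counts untouched.
    """
    df = track.bins
    if len(df) < 50:
        raise ValueError("GC correction needs >= 50 bins")
    gc = df["gc"].to_numpy(dtype=float)
    counts = df["count"].to_numpy(dtype=float)
    if np.isnan(gc).any() or np.ptp(gc) == 0:
        logger.info("degenerate GC track; GC correction is the identity")
        return BinTrack(df.assign(corrected=counts))
    q1, q3 = np.quantile(counts, [0.25, 0.75])
    neutral = (counts >= q1) & (counts <= q3)
    if neutral.sum() < 3:
        neutral = np.ones_like(neutral, dtype=bool)
    coef = np.polyfit(gc[neutral], counts[neutral], deg=2)
    expected = np.clip(np.polyval(coef, gc), 1e-9, None)
    corrected = counts * (np.median(expected) / expected)
    return BinTrack(df.assign(corrected=np.maximum(corrected, 0.0)))


def compute_ratio_profile(track: BinTrack) -> RatioProfile:
    """Normalize corrected counts by their genome-wide median (MedianRatio).

    Zero-count bins are masked and excluded from the median and from all
    downstream comparison; the median of unmasked ratios is exactly 1.
    """
    df = track.bins
    counts = df["corrected" if "corrected" in df.columns else "count"].to_numpy(dtype=float)
    mask = df["count"].to_numpy(dtype=float) <= 0
    if mask.all():
        raise ValueError("all bins have zero counts")
    median_ratio = float(np.median(counts[~mask]))
    if median_ratio <= 0:
        raise ValueError("median corrected count is not positive")
    ratio = counts / median_ratio
    log2 = np.full_like(ratio, np.nan)
    pos = ratio > 0
    log2[pos] = np.log2(ratio[pos])
    out = df.assign(ratio=ratio, log2=log2, mask=mask | ~pos)
    return RatioProfile(bins=out, median_ratio=median_ratio)


def _max_t_split(values: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best single split of ``values`` by two-sample t statistic.

    Returns (split index k, |t|); k = -1 when no admissible split exists.
    Zero pooled variance with distinct means maps to +inf.
    """
    n = values.size
    if n < 2 * min_bins:
        return -1, 0.0
    cs = np.cumsum(values)
    cs2 = np.cumsum(values**2)
    total, total2 = cs[-1], cs2[-1]
    k = np.arange(min_bins, n - min_bins + 1)
    n1 = k.astype(float)
    n2 = n - n1
    m1 = cs[k - 1] / n1
    m2 = (total - cs[k - 1]) / n2
    ss1 = cs2[k - 1] - n1 * m1**2
    ss2 = (total2 - cs2[k - 1]) - n2 * m2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / (n - 2)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.where((sp2 <= 0) & (np.abs(m1 - m2) > 0), np.inf, t)
    t = np.nan_to_num(t, nan=0.0)
    best = int(np.argmax(t))
    return int(k[best]), float(t[best])


def _split_is_significant(
    values: np.ndarray,
    observed_t: float,
    min_bins: int,
    alpha: float,
    rng: np.random.Generator,
    n_perm: int,
) -> bool:
    """Permutation calibration: shuffle values, re-scan for the max |t|."""
    if observed_t == 0.0:
        return False
    exceed = 0
    v = values.copy()
    for _ in range(n_perm):
        rng.shuffle(v)
        _, t = _max_t_split(v, min_bins)
        if t >= observed_t:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return p <= alpha


def segment_profile(
    profile: RatioProfile,
    min_bins: int = 3,
    alpha: float = 0.01,
    seed: int = 0,
    n_perm: int = 999,
) -> SegmentSet:
    """Recursive binary segmentation of per-bin log2 ratios.

    Each chromosome is split at the bin maximizing the two-sample t
    statistic; a split is accepted when its permutation p-value (n_perm
    shuffles) is <= alpha and both sides keep >= min_bins bins. Masked
    bins are dropped before splitting; segment boundaries absorb masked
    gaps so segments tile the binned extent exactly.
    """
    if min_bins < 2:
        raise ValueError("min_bins must be >= 2")
    if alpha < 1.0 / (n_perm + 1):
        raise ValueError(
            f"alpha={alpha} is unattainable with {n_perm} permutations "
            f"(minimum p-value is {1.0 / (n_perm + 1):.4g})"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub_all in profile.bins.groupby("chrom", sort=False):
        extent_start = int(sub_all["start"].iloc[0])
        extent_end = int(sub_all["end"].iloc[-1])
        sub = sub_all[~sub_all["mask"]]
        if sub.empty:
            rows.append((chrom, extent_start, extent_end, 0, np.nan))
            continue
        values = sub["log2"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy(dtype=np.int64)

        breakpoints: list[int] = []

        def _recurse(lo: int, hi: int) -> None:
            v = values[lo:hi]
            k, t = _max_t_split(v, min_bins)
            if k < 0:
                return
            if not _split_is_significant(v, t, min_bins, alpha, rng, n_perm):
                return
            breakpoints.append(lo + k)
            _recurse(lo, lo + k)
            _recurse(lo + k, hi)

        _recurse(0, len(values))
        bounds = [0] + sorted(breakpoints) + [len(values)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_start = extent_start if a == 0 else int(starts[a])
            seg_end = extent_end if b == len(values) else int(starts[b])
            rows.append((chrom, seg_start, seg_end, b - a, float(np.mean(values[a:b]))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean_log2"])
    return SegmentSet(segments=df)


def call_copy_numbers(segments: SegmentSet, ploidy: int) -> SegmentSet:
    """Integer CN per segment = round(ploidy x 2^mean_log2), half away from 0."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    df = segments.segments.copy()
    raw = ploidy * np.power(2.0, df["mean_log2"].to_numpy(dtype=float))
    cn = np.floor(raw + 0.5)  # raw >= 0, so this is round-half-away-from-zero
    df["cn"] = np.where(np.isnan(raw), -1, cn).astype(np.int64)
    df.loc[df["cn"] < 0, "cn"] = 0
    return SegmentSet(segments=df, ploidy=ploidy)
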