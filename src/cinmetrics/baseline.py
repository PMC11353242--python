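"""Baseline-distance comparison of two copy-number profiles.

Subtracts locus-matched log2 ratios (knock-down minus control) and labels
every locus as closer to / further from the copy-neutral zero-baseline,
or unchanged within a band of 2 x the control profile's ratio dispersion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnprofile import RatioProfile, SegmentSet

__all__ = [
    "PairedProfile",
    "ClassifierConfig",
    "DeltaClassification",
    "BaselineDistanceSummary",
    "pair_profiles",
    "classify_loci",
    "estimate_dispersion",
    "summarize",
    "affected_chromosomes",
]

_ESTIMATORS = ("mad", "sd", "iqr")


@dataclass
class PairedProfile:
    """Locus-matched control and knock-down log2 ratios.

    ``loci`` columns: chrom, start, end, control, knockdown, delta with
    delta = knockdown - control, recomputable exactly.
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.loci.reset_index(drop=True)
        required = {"chrom", "start", "end", "control", "knockdown"}
        if not required.issubset(df.columns):
            raise ValueError(f"loci must have columns {sorted(required)}")
        df["delta"] = df["knockdown"] - df["control"]
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (ends <= starts).any() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: loci must be sorted and non-overlapping")
        self.loci = df

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class ClassifierConfig:
    """Unchanged-band half-width and tie policy.

    ``half_width`` should be 2 x the dispersion of the control profile's
    normalized ratios (see :func:`estimate_dispersion`). ``sign_flip``
    decides pure sign flips (equal magnitude, opposite sign): the
    knock-down state is then a new alteration, so the default is
    ``"further"``.
    """

    half_width: float
    dispersion_estimator: str = "mad"
    sign_flip: str = "further"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.sign_flip not in ("closer", "further", "unchanged"):
            raise ValueError("sign_flip must be closer|further|unchanged")


@dataclass
class DeltaClassification:
    """Per-locus closer/further/unchanged calls with the delta track."""

    loci: pd.DataFrame  # chrom, start, end, control, knockdown, delta, cls
    config: ClassifierConfig

    def bp(self, cls: str) -> int:
        sub = self.loci[self.loci["cls"] == cls]
        return int((sub["end"] - sub["start"]).sum())

    def total_bp(self) -> int:
        return int((self.loci["end"] - self.loci["start"]).sum())


@dataclass
class BaselineDistanceSummary:
    closer_mbp: float
    further_mbp: float
    unchanged_mbp: float
    closer_pct: float | None   # over changed loci only; None if none changed
    further_pct: float | None
    per_chromosome: pd.DataFrame  # chrom, changed_mbp, compared_mbp, changed_fraction

    def to_dict(self) -> dict:
        return {
            "closer_mbp": self.closer_mbp,
            "further_mbp": self.further_mbp,
            "unchanged_mbp": self.unchanged_mbp,
            "closer_pct": self.closer_pct,
            "further_pct": self.further_pct,
            "per_chromosome": self.per_chromosome.to_dict(orient="records"),
        }


def _as_intervals(obj: SegmentSet | RatioProfile) -> pd.DataFrame:
    """(chrom, start, end, value) intervals with masked/NaN entries dropped."""
    if isinstance(obj, SegmentSet):
        df = obj.segments.rename(columns={"mean_log2": "value"})[
            ["chrom", "start", "end", "value"]
        ]
    elif isinstance(obj, RatioProfile):
        df = obj.unmasked().rename(columns={"log2": "value"})[
            ["chrom", "start", "end", "value"]
        ]
    else:
        raise TypeError("expected SegmentSet or RatioProfile")
    return df[df["value"].notna()].reset_index(drop=True)


def pair_profiles(
    control: SegmentSet | RatioProfile, knockdown: SegmentSet | RatioProfile
) -> PairedProfile:
    """Intersect two profiles into their finest common tiling.

    Loci masked or uncovered in either input are excluded from both.
    Raises when the inputs share no chromosome.
    """
    a = _as_intervals(control)
    b = _as_intervals(knockdown)
    if len(a) == 0 or len(b) == 0:
        return PairedProfile(
            loci=pd.DataFrame(columns=["chrom", "start", "end", "control", "knockdown"])
        )
    chroms_a, chroms_b = set(a["chrom"]), set(b["chrom"])
    common = chroms_a & chroms_b
    if not common:
        raise ValueError(
            f"no shared chromosomes: control has {sorted(chroms_a)}, "
            f"knockdown has {sorted(chroms_b)}"
        )
    rows = []
    for chrom in [c for c in a["chrom"].unique() if c in common]:
        sa = a[a["chrom"] == chrom]
        sb = b[b["chrom"] == chrom]
        ia = sa[["start", "end"]].to_numpy()
        va = sa["value"].to_numpy()
        ib = sb[["start", "end"]].to_numpy()
        vb = sb["value"].to_numpy()
        # sweep over merged boundaries; emit pieces covered by both inputs
        bounds = np.unique(np.concatenate([ia.ravel(), ib.ravel()]))
        j_a = j_b = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            while j_a < len(ia) and ia[j_a, 1] <= lo:
                j_a += 1
            while j_b < len(ib) and ib[j_b, 1] <= lo:
                j_b += 1
            cov_a = j_a < len(ia) and ia[j_a, 0] <= lo
            cov_b = j_b < len(ib) and ib[j_b, 0] <= lo
            if cov_a and cov_b:
                rows.append((chrom, int(lo), int(hi), float(va[j_a]), float(vb[j_b])))
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "control", "knockdown"])
    return PairedProfile(loci=loci)


def estimate_dispersion(
    profile: RatioProfile,
    segments: SegmentSet | None = None,
    estimator: str = "mad",
) -> float:
    """Robust dispersion of normalized bin log2 ratios about segment means.

    Without segments, residuals are taken about the global median. The
    estimator is pluggable: 'mad' (x1.4826), 'sd', or 'iqr' (/1.349).
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")
    bins = profile.unmasked()
    if len(bins) < 50:
        raise ValueError("dispersion estimation needs >= 50 unmasked bins")
    values = bins["log2"].to_numpy(dtype=float)
    if segments is None:
        residuals = values - np.median(values)
    else:
        residuals = np.empty_like(values)
        pos = 0
        for chrom, sub in bins.groupby("chrom", sort=False):
            seg = segments.segments[segments.segments["chrom"] == chrom]
            idx = (
                np.searchsorted(seg["start"].to_numpy(), sub["start"].to_numpy(), side="right")
                - 1
            )
            means = seg["mean_log2"].to_numpy()[np.clip(idx, 0, len(seg) - 1)]
            residuals[pos : pos + len(sub)] = sub["log2"].to_numpy() - means
            pos += len(sub)
    if estimator == "mad":
        return float(1.4826 * np.median(np.abs(residuals - np.median(residuals))))
    if estimator == "sd":
        return float(np.std(residuals, ddof=1))
    q1, q3 = np.quantile(residuals, [0.25, 0.75])
    return float((q3 - q1) / 1.349)


def classify_loci(paired: PairedProfile, config: ClassifierConfig) -> DeltaClassification:
    """Label each locus closer/further/unchanged relative to zero-baseline.

    Distance from baseline is |log2 ratio|. A locus is unchanged when
    |delta| <= half_width; otherwise it is further when the knock-down
    lies further from zero than the control, closer when nearer, and a
    pure sign flip (equal distance, |delta| > half_width) follows the
    configured policy.
    """
    df = paired.loci.copy()
    if df.empty:
        df["cls"] = pd.Series(dtype=object)
        return DeltaClassification(loci=df, config=config)
    ctrl = df["control"].to_numpy(dtype=float)
    kd = df["knockdown"].to_numpy(dtype=float)
    delta = df["delta"].to_numpy(dtype=float)
    d_ctrl = np.abs(ctrl)
    d_kd = np.abs(kd)
    cls = np.where(
        np.abs(delta) <= config.half_width,
        "unchanged",
        np.where(d_kd > d_ctrl, "further", np.where(d_kd < d_ctrl, "closer", config.sign_flip)),
    )
    df["cls"] = cls
    return DeltaClassification(loci=df, config=config)


def summarize(classification: DeltaClassification) -> BaselineDistanceSummary:
    """Mbp per class; percentages over changed (closer+further) loci only."""
    closer_bp = classification.bp("closer")
    further_bp = classification.bp("further")
    unchanged_bp = classification.bp("unchanged")
    changed_bp = closer_bp + further_bp
    if changed_bp > 0:
        closer_pct = 100.0 * closer_bp / changed_bp
        further_pct = 100.0 * further_bp / changed_bp
    else:
        closer_pct = further_pct = None
    df = classification.loci
    per_chrom_rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        widths = sub["end"] - sub["start"]
        changed = int(widths[sub["cls"] != "unchanged"].sum())
        compared = int(widths.sum())
        per_chrom_rows.append(
            (chrom, changed / 1e6, compared / 1e6, changed / compared if compared else 0.0)
        )
    per_chrom = pd.DataFrame(
        per_chrom_rows, columns=["chrom", "changed_mbp", "compared_mbp", "changed_fraction"]
    )
    return BaselineDistanceSummary(
        closer_mbp=closer_bp / 1e6,
        further_mbp=further_bp / 1e6,
        unchanged_mbp=unchanged_bp / 1e6,
        closer_pct=closer_pct,
        further_pct=further_pct,
        per_chromosome=per_chrom,
    )


def affected_chromosomes(
    classification: DeltaClassification, min_changed_fraction: float = 0.1
) -> list[str]:
    """Chromosomes whose changed-bp fraction meets the threshold,
    sorted by changed Mbp descending."""
    if not 0.0 < min_changed_fraction <= 1.0:
        raise ValueError("min_changed_fraction must be in (0, 1]")
    summary = summarize(classification)
    hits = summary.per_chromosome[
        summary.per_chromosome["changed_fraction"] >= min_changed_fraction
    ]
    hits = hits.sort_values("changed_mbp", ascending=False)
    return hits["chrom"].tolist()
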