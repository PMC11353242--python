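"""Genome coordinate model and ground-truth copy-number profiles.

All coordinates are 0-based, half-open, in bp. Mbp appears only in
reporting layers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MBP = 1_000_000

# 22 autosomes, lengths proportional to hg38 but scaled to 720 Mbp total
# so whole-genome runs stay desk-scale.
_TOY_LENGTHS_MBP = (
    61, 60, 49, 48, 45, 43, 40, 36, 35, 34, 34,
    33, 29, 27, 26, 23, 21, 20, 15, 16, 12, 13,
)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus the binning grid and base ploidy."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin size must be > 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        return int(self.lengths[self.names.index(chrom)])

    def n_bins(self, chrom: str) -> int:
        length = self.length_of(chrom)
        return -(-length // self.bin_size)

    def bins(self) -> pd.DataFrame:
        """Tile every chromosome with bins (last bin may be short)."""
        rows = []
        for name, length in zip(self.names, self.lengths):
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


def toy_genome(bin_size: int = MBP, ploidy: int = 2) -> GenomeModel:
    """Desk-scale 22-autosome genome, 720 Mbp total."""
    names = tuple(f"chr{i}" for i in range(1, 23))
    lengths = tuple(l * MBP for l in _TOY_LENGTHS_MBP)
    return GenomeModel(names=names, lengths=lengths, bin_size=bin_size, ploidy=ploidy)


@dataclass
class TrueCNProfile:
    """Ground-truth integer copy numbers tiling a genome exactly.

    ``segments`` has columns chrom, start, end, cn; segments are sorted,
    non-overlapping and tile each chromosome.
    """

    segments: pd.DataFrame
    condition: str = "control"

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True)
        required = {"chrom", "start", "end", "cn"}
        if not required.issubset(seg.columns):
            raise ValueError(f"segments must have columns {sorted(required)}")
        if (seg["cn"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if (seg["end"] <= seg["start"]).any():
            raise ValueError("segments must have end > start")
        for _, sub in seg.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (starts[1:] == ends[:-1]).all():
                raise ValueError("segments must tile each chromosome without gaps")
        self.segments = seg

    def validate_against(self, genome: GenomeModel) -> None:
        for name, length in zip(genome.names, genome.lengths):
            sub = self.segments[self.segments["chrom"] == name]
            if sub.empty:
                raise ValueError(f"profile missing chromosome {name}")
            if sub["start"].iloc[0] != 0 or sub["end"].iloc[-1] != length:
                raise ValueError(f"profile does not span chromosome {name}")

    def total_bp(self) -> int:
        return int((self.segments["end"] - self.segments["start"]).sum())

    def cn_at_bins(self, genome: GenomeModel) -> np.ndarray:
        """Copy number per bin (bin assigned the CN covering its start)."""
        bins = genome.bins()
        cn = np.empty(len(bins), dtype=np.int64)
        for chrom, sub in bins.groupby("chrom", sort=False):
            seg = self.segments[self.segments["chrom"] == chrom]
            idx = np.searchsorted(seg["start"].to_numpy(), sub["start"].to_numpy(), side="right") - 1
            cn[sub.index] = seg["cn"].to_numpy()[idx]
        return cn

    def merged(self) -> "TrueCNProfile":
        """Merge adjacent same-CN segments."""
        out = []
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            cur = None
            for row in sub.itertuples(index=False):
                if cur is not None and cur[3] == row.cn and cur[2] == row.start:
                    cur[2] = row.end
                else:
                    if cur is not None:
                        out.append(cur)
                    cur = [row.chrom, row.start, row.end, row.cn]
            if cur is not None:
                out.append(cur)
        df = pd.DataFrame(out, columns=["chrom", "start", "end", "cn"])
        return TrueCNProfile(segments=df, condition=self.condition)
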