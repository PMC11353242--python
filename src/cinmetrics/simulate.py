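"""Simulators for every pipeline input: CN profiles, binned read counts,
karyotype spreads, event counts, and comet movies.

Every simulator takes an explicit seed; identical seeds give identical
output. Dispersion/noise of 0 always means "return the expectation".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, TrueCNProfile
from .cnprofile import BinTrack

__all__ = [
    "ReadDepthParams",
    "KaryotypeParams",
    "CometMovieParams",
    "CNGroundTruth",
    "simulate_cn_profiles",
    "simulate_bin_counts",
    "simulate_karyotypes",
    "simulate_event_counts",
    "simulate_comet_movie",
]


# ---------------------------------------------------------------------------
# copy-number profiles


@dataclass(frozen=True)
class CNGroundTruth:
    """bp totals the downstream classifier should recover."""

    closer_bp: int          # altered in control, reverted in knock-down
    further_bp: int         # neutral in control, newly altered in knock-down
    altered_bp_control: int # total non-neutral bp in the control profile


def simulate_cn_profiles(
    genome: GenomeModel,
    n_alterations: int,
    attenuation_fraction: float,
    new_alteration_fraction: float,
    seed: int,
    alteration_length: int = 10_000_000,
    alteration_cns: tuple[int, ...] | None = None,
) -> tuple[TrueCNProfile, TrueCNProfile, CNGroundTruth]:
    """Draw a control profile with ``n_alterations`` non-neutral segments and a
    knock-down that reverts a fraction of the altered bp to base ploidy
    (closer-eligible) and adds a fraction as novel alterations
    (further-eligible).

    Alterations are bin-aligned and non-overlapping. ``alteration_cns``
    lists the copy numbers alterations are drawn from; the default is
    halving/doubling of the base ploidy (|log2 ratio| >= 1), which keeps
    true changes well clear of the read-depth noise band.
    Returns (control, knockdown, ground truth bp totals).
    """
    if not 0.0 <= attenuation_fraction <= 1.0:
        raise ValueError("attenuation_fraction must be in [0, 1]")
    if not 0.0 <= new_alteration_fraction <= 1.0:
        raise ValueError("new_alteration_fraction must be in [0, 1]")
    if n_alterations < 0:
        raise ValueError("n_alterations must be >= 0")
    if alteration_length % genome.bin_size:
        raise ValueError("alteration_length must be a multiple of the bin size")

    rng = np.random.default_rng(seed)
    ploidy = genome.ploidy

    # candidate slots: disjoint alteration_length tiles across all chromosomes
    slots: list[tuple[str, int, int]] = []
    for name, length in zip(genome.names, genome.lengths):
        for start in range(0, length - alteration_length + 1, alteration_length):
            slots.append((name, start, start + alteration_length))
    # new alterations (up to n_alterations more slots) need room too
    needed = n_alterations + int(np.ceil(new_alteration_fraction * n_alterations))
    if needed > len(slots):
        raise ValueError(
            f"requested {needed} alteration slots but the genome holds only "
            f"{len(slots)} of length {alteration_length}"
        )

    order = rng.permutation(len(slots))
    control_slots = [slots[i] for i in order[:n_alterations]]
    spare_slots = [slots[i] for i in order[n_alterations:]]

    if alteration_cns is None:
        candidates = (2 * ploidy,) if ploidy == 1 else (ploidy // 2, 2 * ploidy)
    else:
        candidates = tuple(alteration_cns)
        if any(cn < 0 or cn == ploidy for cn in candidates):
            raise ValueError("alteration_cns must be >= 0 and differ from ploidy")

    def _altered_cn() -> int:
        return int(rng.choice(candidates))

    control_alts = [(c, s, e, _altered_cn()) for c, s, e in control_slots]
    altered_bp = sum(e - s for c, s, e, _ in control_alts)

    # choose the prefix of a shuffled alteration list whose bp is closest to
    # attenuation_fraction * altered_bp
    target = attenuation_fraction * altered_bp
    shuffled = [control_alts[i] for i in rng.permutation(len(control_alts))]
    attenuated: list[tuple[str, int, int, int]] = []
    cum = 0
    for alt in shuffled:
        length = alt[2] - alt[1]
        if abs(cum + length - target) <= abs(cum - target) and cum < target:
            attenuated.append(alt)
            cum += length
        else:
            break
    closer_bp = cum

    # novel alterations in spare neutral slots, bp closest to the new target
    new_target = new_alteration_fraction * altered_bp
    n_full = int(new_target // alteration_length)
    remainder = int(round((new_target - n_full * alteration_length) / genome.bin_size)) * genome.bin_size
    new_alts: list[tuple[str, int, int, int]] = []
    further_bp = 0
    for c, s, e in spare_slots[:n_full]:
        new_alts.append((c, s, e, _altered_cn()))
        further_bp += e - s
    if remainder and n_full < len(spare_slots):
        c, s, e = spare_slots[n_full]
        new_alts.append((c, s, s + remainder, _altered_cn()))
        further_bp += remainder

    attenuated_keys = {(c, s, e) for c, s, e, _ in attenuated}

    def _build(alts: Sequence[tuple[str, int, int, int]], condition: str) -> TrueCNProfile:
        by_chrom: dict[str, list[tuple[int, int, int]]] = {n: [] for n in genome.names}
        for c, s, e, cn in alts:
            by_chrom[c].append((s, e, cn))
        rows = []
        for name, length in zip(genome.names, genome.lengths):
            pos = 0
            for s, e, cn in sorted(by_chrom[name]):
                if s > pos:
                    rows.append((name, pos, s, ploidy))
                rows.append((name, s, e, cn))
                pos = e
            if pos < length:
                rows.append((name, pos, length, ploidy))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
        return TrueCNProfile(segments=df, condition=condition)

    kd_alts = [
        alt for alt in control_alts if (alt[0], alt[1], alt[2]) not in attenuated_keys
    ] + new_alts

    control = _build(control_alts, "control")
    knockdown = _build(kd_alts, "knockdown")
    truth = CNGroundTruth(
        closer_bp=int(closer_bp),
        further_bp=int(further_bp),
        altered_bp_control=int(altered_bp),
    )
    return control, knockdown, truth


# ---------------------------------------------------------------------------
# binned read counts


@dataclass(frozen=True)
class ReadDepthParams:
    """Negative-binomial read-depth model.

    ``dispersion`` parameterizes var = mean + dispersion * mean^2;
    dispersion 0 returns the expectation exactly (noise-free mode).
    """

    mean_count: float = 100.0
    dispersion: float = 0.1
    gc_linear: float = 0.0
    gc_quad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_count <= 0:
            raise ValueError("mean_count must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _smooth_gc(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-bin GC fraction in [0.3, 0.6]."""
    x = np.arange(n_bins)
    phase = rng.uniform(0, 2 * np.pi)
    period = rng.uniform(30, 60)
    gc = 0.45 + 0.15 * np.sin(2 * np.pi * x / period + phase)
    return np.clip(gc, 0.3, 0.6)


def simulate_bin_counts(
    profile: TrueCNProfile, genome: GenomeModel, params: ReadDepthParams
) -> BinTrack:
    """Binned read counts with GC bias and negative-binomial noise.

    Expected count per bin = mean_count x (CN / ploidy) x GC factor where
    the GC factor is 1 + gc_linear*(gc-0.45) + gc_quad*(gc-0.45)^2.
    """
    profile.validate_against(genome)
    rng = np.random.default_rng(params.seed)
    bins = genome.bins()
    cn = profile.cn_at_bins(genome)
    gc = _smooth_gc(len(bins), rng)
    gdev = gc - 0.45
    gc_factor = np.clip(1.0 + params.gc_linear * gdev + params.gc_quad * gdev**2, 1e-9, None)
    mu = params.mean_count * (cn / genome.ploidy) * gc_factor
    if params.dispersion == 0:
        counts = mu
    else:
        size = 1.0 / params.dispersion
        p = size / (size + np.maximum(mu, 1e-12))
        counts = rng.negative_binomial(size, p).astype(float)
        counts[mu == 0] = 0.0
    df = bins.assign(gc=gc, count=counts)
    return BinTrack(df)


# ---------------------------------------------------------------------------
# karyotypes


@dataclass(frozen=True)
class KaryotypeParams:
    """Per-cell chromosome counts after repeated missegregating divisions."""

    n_cells: int = 500
    base_count: int = 107
    missegregation_rate: float = 0.01
    divisions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.base_count < 0 or self.divisions < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.missegregation_rate <= 1.0:
            raise ValueError("missegregation_rate must be in [0, 1]")


def simulate_karyotypes(params: KaryotypeParams) -> pd.DataFrame:
    """Each chromosome missegregates independently per division with the
    given rate; gains and losses are equiprobable, so the mean is preserved
    while variance grows with rate and divisions.

    Returns a two-column table (cell, count).
    """
    rng = np.random.default_rng(params.seed)
    counts = np.full(params.n_cells, params.base_count, dtype=np.int64)
    if params.missegregation_rate > 0:
        for _ in range(params.divisions):
            events = rng.binomial(counts, params.missegregation_rate)
            gains = rng.binomial(events, 0.5)
            counts = np.maximum(counts + 2 * gains - events, 0)
    return pd.DataFrame({"cell": np.arange(params.n_cells), "count": counts})


# ---------------------------------------------------------------------------
# event counts


def simulate_event_counts(p_event: float, n_cells: int, seed: int) -> tuple[int, int]:
    """Binomial draw of scored events (micronuclei, misalignments, ...)."""
    if not 0.0 <= p_event <= 1.0:
        raise ValueError("p_event must be in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_cells, p_event)), int(n_cells)


# ---------------------------------------------------------------------------
# comet movies


@dataclass(frozen=True)
class CometMovieParams:
    n_frames: int = 90
    frame_interval_s: float = 2.0
    pixel_size_um: float = 0.1
    n_emitters: int = 20
    speed_um_min: float | Sequence[float] = 3.0
    headings_rad: Sequence[float] | None = None
    psf_sigma_px: float = 1.5
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        speeds = np.atleast_1d(np.asarray(self.speed_um_min, dtype=float))
        if (speeds < 0).any():
            raise ValueError("speeds must be >= 0")

    def speeds(self) -> np.ndarray:
        speeds = np.atleast_1d(np.asarray(self.speed_um_min, dtype=float))
        if speeds.size == 1:
            speeds = np.repeat(speeds, self.n_emitters)
        if speeds.size != self.n_emitters:
            raise ValueError("speed_um_min must be scalar or length n_emitters")
        return speeds

    def displacement_px_per_frame(self) -> np.ndarray:
        return self.speeds() / 60.0 * self.frame_interval_s / self.pixel_size_um


def simulate_comet_movie(
    params: CometMovieParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render point emitters moving on straight lines with a Gaussian PSF.

    Returns (stack, truth) where stack is float32 (frames, height, width)
    and truth lists (emitter, frame, x, y, speed_um_min) with x = column,
    y = row in pixel units.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    step = params.displacement_px_per_frame()
    if params.headings_rad is None:
        headings = rng.uniform(0, 2 * np.pi, params.n_emitters)
    else:
        headings = np.asarray(params.headings_rad, dtype=float)
        if headings.size != params.n_emitters:
            raise ValueError("headings_rad must have length n_emitters")
    dx = step * np.cos(headings)
    dy = step * np.sin(headings)
    travel = step * (params.n_frames - 1)
    margin = 4.0 * params.psf_sigma_px + 1.0
    if (travel + 2 * margin >= min(h, w)).any():
        raise ValueError("emitters do not fit in the frame for the full movie")
    # start positions chosen so the full trajectory stays inside the margin
    x0 = np.empty(params.n_emitters)
    y0 = np.empty(params.n_emitters)
    for i in range(params.n_emitters):
        lo_x = margin + max(0.0, -dx[i] * (params.n_frames - 1))
        hi_x = w - margin - max(0.0, dx[i] * (params.n_frames - 1))
        lo_y = margin + max(0.0, -dy[i] * (params.n_frames - 1))
        hi_y = h - margin - max(0.0, dy[i] * (params.n_frames - 1))
        x0[i] = rng.uniform(lo_x, hi_x)
        y0[i] = rng.uniform(lo_y, hi_y)

    frames = np.arange(params.n_frames)
    xs = x0[:, None] + dx[:, None] * frames[None, :]
    ys = y0[:, None] + dy[:, None] * frames[None, :]

    stack = np.full((params.n_frames, h, w), params.background, dtype=np.float64)
    win = int(np.ceil(4 * params.psf_sigma_px)) + 1
    two_s2 = 2.0 * params.psf_sigma_px**2
    for t in range(params.n_frames):
        img = stack[t]
        for i in range(params.n_emitters):
            cx, cy = xs[i, t], ys[i, t]
            r0, r1 = int(np.floor(cy)) - win, int(np.floor(cy)) + win + 1
            c0, c1 = int(np.floor(cx)) - win, int(np.floor(cx)) + win + 1
            rr = np.arange(max(r0, 0), min(r1, h))
            cc = np.arange(max(c0, 0), min(c1, w))
            gy = np.exp(-((rr - cy) ** 2) / two_s2)
            gx = np.exp(-((cc - cx) ** 2) / two_s2)
            img[np.ix_(rr, cc)] += params.amplitude * np.outer(gy, gx)
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    speeds = params.speeds()
    truth = pd.DataFrame(
        {
            "emitter": np.repeat(np.arange(params.n_emitters), params.n_frames),
            "frame": np.tile(frames, params.n_emitters),
            "x": xs.ravel(),
            "y": ys.ravel(),
            "speed_um_min": np.repeat(speeds, params.n_frames),
        }
    )
    return stack.astype(np.float32), truth
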